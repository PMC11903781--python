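"""Seeded multichannel full-band-like ECoG generator with injected SDs.

Channels carry a large DC offset (~70 mV) with slow drift and background
noise; SD episodes are injected as smooth negative DC shifts (default peak
≈ 5.4 mV, duration ≈ 2 min, spectral energy in the low-mHz band) that spread
across a contiguous subset of channels with per-channel onset delays.  Every
injected waveform is annotated with its per-channel peak-negativity time, so
the full pipeline is testable without patient data.

The waveform family is piecewise half-cosine: a stereotyped event is a
raised-cosine trough (optionally followed by a positive afterpotential);
atypical variants deform amplitude, duration, afterpotential size, or split
the negativity into a double hump.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sdstrip.io import Annotation, AnnotationSet, Recording

VARIANTS = ("typical", "low_amplitude", "prolonged", "double_hump", "large_afterpotential")


@dataclass
class GeneratorSpec:
    n_subjects: int = 5
    channels_per_subject: int = 6
    duration_s: float = 7200.0
    fs: float = 256.0
    dc_offset_mv: float = 70.0
    drift_scale_mv: float = 0.3          # random-walk scale per 100-s step
    noise_scale_mv: float = 0.3
    hf_background: bool = False          # 0.5–50 Hz band energy
    hf_scale_mv: float = 0.2
    sd_rate_per_hour: float = 3.0        # SD episodes per subject-hour
    amplitude_mean_mv: float = 5.4
    amplitude_sd_mv: float = 3.6         # truncated at > 0.5 mV
    duration_mean_s: float = 120.0
    duration_sd_s: float = 30.0
    afterpotential_fraction: float = 0.5
    atypical_mix: dict = field(default_factory=dict)  # variant -> fraction
    interchannel_delay_s: tuple = (60.0, 300.0)
    artifact_rate_per_hour: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_rate_per_hour, self.artifact_rate_per_hour) < 0:
            raise ValueError("rates must be non-negative")
        if sum(self.atypical_mix.values()) > 1 + 1e-9:
            raise ValueError("atypical_mix fractions must sum to <= 1")
        unknown = set(self.atypical_mix) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants {sorted(unknown)}")


def _half_cosine_path(knots: list[tuple[float, float]], fs: float) -> np.ndarray:
    """Concatenated half-cosine ramps through (time, value) knots."""
    total = int(round(knots[-1][0] * fs))
    t = np.arange(total) / fs
    out = np.empty(total)
    for (t0, v0), (t1, v1) in zip(knots[:-1], knots[1:]):
        m = (t >= t0) & (t < t1)
        s = (t[m] - t0) / (t1 - t0)
        out[m] = v0 + (v1 - v0) * (1 - np.cos(np.pi * s)) / 2
    return out


def sd_waveform(
    amplitude_mv: float,
    duration_s: float,
    variant: str = "typical",
    afterpotential_mv: float = 0.0,
    fs: float = 256.0,
) -> tuple[np.ndarray, int]:
    """An SD voltage deflection at ``fs``; returns (wave, peak-negativity index).

    ``duration_s`` spans the negative phase; the optional positive
    afterpotential extends beyond it.  The stereotyped trough is a pure
    raised cosine, so its non-DC energy sits at ~1/duration Hz (a few mHz
    for the 2-min default).
    """
    if amplitude_mv <= 0 or duration_s <= 0:
        raise ValueError("amplitude and duration must be positive")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    a, t = amplitude_mv, duration_s
    post = afterpotential_mv
    if variant == "low_amplitude":
        a *= 0.25
    elif variant == "prolonged":
        t *= 2.5
    elif variant == "large_afterpotential":
        post = max(post, 1.2 * a)

    if variant == "double_hump":
        # two distinct negative lobes, both deeper than half the amplitude
        knots = [
            (0.0, 0.0),
            (0.25 * t, -a),
            (0.50 * t, -0.3 * a),
            (0.75 * t, -0.9 * a),
            (t, 0.0),
        ]
        peak_idx = int(round(0.25 * t * fs))
    else:
        knots = [(0.0, 0.0), (t / 2, -a), (t, 0.0)]
        peak_idx = int(round(t / 2 * fs))
    if post > 0:
        tail = 0.8 * t
        knots += [(t + tail / 2, post), (t + tail, 0.0)]
    return _half_cosine_path(knots, fs), peak_idx


def _drift(rng: np.random.Generator, n: int, fs: float, scale_mv: float) -> np.ndarray:
    """Slow (< ~5 mHz) drift: random walk on a 100-s grid, interpolated."""
    step_s = 100.0
    n_knots = int(np.ceil(n / fs / step_s)) + 2
    walk = np.cumsum(rng.normal(0.0, scale_mv, n_knots))
    knot_t = np.arange(n_knots) * step_s
    return np.interp(np.arange(n) / fs, knot_t, walk)


def _artifact(rng: np.random.Generator, fs: float) -> np.ndarray:
    width = int(rng.uniform(1, 30) * fs)
    amp = rng.uniform(10, 100) * rng.choice([-1, 1])
    if rng.random() < 0.5:
        return np.full(width, amp)
    return amp * np.exp(-np.arange(width) / (0.3 * width + 1))


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    """Sample a floor-truncated normal whose *truncated* mean equals ``mean``.

    The pre-truncation location is solved so that clipping at ``floor`` does
    not bias the realized mean upward.
    """
    from scipy import stats
    from scipy.optimize import brentq

    def truncated_mean(loc):
        a = (floor - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd)

    if truncated_mean(mean) - mean < 1e-9:
        loc = mean
    else:
        loc = brentq(lambda m: truncated_mean(m) - mean, mean - 5 * sd, mean)
    a = (floor - loc) / sd
    return float(stats.truncnorm.ppf(rng.uniform(), a, np.inf, loc=loc, scale=sd))


def generate_subject(
    spec: GeneratorSpec, subject_index: int = 0
) -> tuple[Recording, AnnotationSet]:
    """One subject's multichannel recording + ground-truth annotations.

    Deterministic given (spec, spec.seed, subject_index).  SD episodes
    spread across a contiguous channel run with cumulative onset delays;
    each affected channel gets its own annotation at its peak-negativity
    time.  Artifacts (if enabled) are injected unannotated.
    """
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_index,))
    rng = np.random.default_rng(ss)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    n_ch = spec.channels_per_subject
    subject_id = f"S{subject_index + 1:02d}"
    labels = [f"ch{i + 1}" for i in range(n_ch)]

    data = np.empty((n_ch, n))
    for c in range(n_ch):
        data[c] = (
            spec.dc_offset_mv + rng.normal(0, 3)
            + _drift(rng, n, fs, spec.drift_scale_mv)
            + rng.normal(0, spec.noise_scale_mv, n)
        )
        if spec.hf_background and fs > 2:
            from scipy import signal as sps

            high = min(50.0, 0.45 * fs)
            sos = sps.butter(4, [0.5, high], btype="band", fs=fs, output="sos")
            data[c] += sps.sosfilt(sos, rng.normal(0, 1, n)) * spec.hf_scale_mv

    hours = spec.duration_s / 3600
    n_events = rng.poisson(spec.sd_rate_per_hour * hours)
    margin = max(600.0, spec.duration_mean_s * 3)
    records: list[Annotation] = []
    if spec.duration_s < 2 * margin:
        if n_events:
            warnings.warn("duration too short to place SDs; zero-SD record",
                          stacklevel=2)
        n_events = 0

    # onset times with a minimum separation so episodes stay distinct
    onsets: list[float] = []
    for _ in range(n_events * 10):
        if len(onsets) == n_events:
            break
        cand = rng.uniform(margin, spec.duration_s - margin)
        if all(abs(cand - o) > 900 for o in onsets):
            onsets.append(cand)

    mix_variants = list(spec.atypical_mix)
    mix_p = np.array([spec.atypical_mix[v] for v in mix_variants])
    for onset in sorted(onsets):
        amp = _draw_positive(rng, spec.amplitude_mean_mv, spec.amplitude_sd_mv, 0.5)
        dur = _draw_positive(rng, spec.duration_mean_s, spec.duration_sd_s, 40.0)
        u = rng.random()
        variant = "typical"
        acc = 0.0
        for v, p in zip(mix_variants, mix_p):
            acc += p
            if u < acc:
                variant = v
                break
        post = amp * rng.uniform(0.2, 0.5) if rng.random() < spec.afterpotential_fraction else 0.0
        span = int(rng.integers(1, n_ch + 1))
        first = int(rng.integers(0, n_ch - span + 1))
        delay_lo, delay_hi = spec.interchannel_delay_s
        t_ch = onset
        for c in range(first, first + span):
            wave, peak_idx = sd_waveform(
                amp * rng.uniform(0.85, 1.15), dur, variant, post, fs
            )
            start_idx = int(round(t_ch * fs))
            if start_idx + len(wave) > n:
                break
            data[c, start_idx : start_idx + len(wave)] += wave
            records.append(
                Annotation(subject_id, labels[c], (start_idx + peak_idx) / fs)
            )
            t_ch += rng.uniform(delay_lo, delay_hi)

    n_artifacts = rng.poisson(spec.artifact_rate_per_hour * hours * n_ch)
    for _ in range(n_artifacts):
        c = rng.integers(0, n_ch)
        art = _artifact(rng, fs)
        start_idx = rng.integers(0, max(1, n - len(art)))
        data[c, start_idx : start_idx + len(art)] += art

    rec = Recording(
        subject_id=subject_id,
        channel_labels=labels,
        sample_rate_hz=fs,
        data=data,
    )
    return rec, AnnotationSet(records)


def generate_cohort(spec: GeneratorSpec) -> list[tuple[Recording, AnnotationSet]]:
    """Independent subjects with per-subject seeds derived from the master."""
    if spec.n_subjects < 1:
        raise ValueError("need at least one subject")
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]
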