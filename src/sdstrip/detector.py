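"""Sliding-window P_SD(t) and dual-threshold event extraction.

A trained segment classifier is advanced across a 1-Hz preprocessed channel
in ``stride_s`` increments; each 400-s window is decimated to 0.1 Hz,
featurized and scored, and the probability is stamped at the window center.
Runs of P_SD ≥ θ_P lasting ≥ θ_D seconds become detection events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sdstrip import features as feat


@dataclass
class DetectionParams:
    theta_p: float = 0.5
    theta_d: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.theta_p < 1:
            raise ValueError("theta_p must be in (0, 1)")
        if self.theta_d <= 0:
            raise ValueError("theta_d must be positive")


@dataclass
class ProbabilityTrace:
    channel: str
    times: np.ndarray  # window-center seconds, constant step stride_s
    p_sd: np.ndarray
    window_s: float
    stride_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.p_sd = np.asarray(self.p_sd, dtype=np.float64)
        if len(self.times) != len(self.p_sd):
            raise ValueError("times and p_sd must have equal length")
        if len(self.p_sd) and not ((self.p_sd >= 0) & (self.p_sd <= 1)).all():
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class DetectionEvent:
    channel: str
    t_start: float
    t_end: float
    t_peak: float
    peak_p: float


def n_windows(len_s: float, window_s: float, stride_s: float) -> int:
    """Edge-exact count of full window positions: floor((L−W)/S) + 1."""
    if len_s < window_s:
        return 0
    return int((len_s - window_s) // stride_s) + 1


def windows_per_day(n_channels: int = 6, stride_s: float = 1.0) -> int:
    """Window evaluations in one day of multichannel data at the per-day
    rate convention: one evaluation per stride per channel (24·3600/stride
    positions per channel)."""
    return int(round(86400 / stride_s)) * n_channels


def sliding_probability(
    x: np.ndarray,
    model,
    channel: str = "",
    window_s: float = 400.0,
    stride_s: float = 1.0,
) -> ProbabilityTrace:
    """Evaluate ``model`` on every full 400-s window of a 1-Hz channel.

    Each window is decimated to 0.1 Hz at phase 0 from the window start.
    Probabilities are stamped at window centers.  Input shorter than one
    window yields an empty trace with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    window = int(window_s)
    stride = int(stride_s)
    if abs(model.config.segment_length_s - window_s) > 1e-9:
        raise ValueError(
            f"model segment length {model.config.segment_length_s} != window {window_s}"
        )
    count = n_windows(len(x), window, stride)
    if count == 0:
        warnings.warn("input shorter than one window; empty trace", stacklevel=2)
        return ProbabilityTrace(channel, np.array([]), np.array([]), window_s, stride_s)

    starts = np.arange(count) * stride
    # all windows as a (count, 40) matrix of 0.1-Hz segments, then one
    # vectorized featurization pass per window
    idx = starts[:, None] + np.arange(0, window, 10)[None, :]
    segments = x[idx]
    all_names = feat.feature_names(segments.shape[1])
    rows = np.empty((count, len(all_names)))
    for i in range(count):
        fmap = feat.extract_features(segments[i])
        rows[i] = [fmap[n] for n in all_names]
    table = pd.DataFrame(rows, columns=all_names)
    p = model.predict_proba(table)
    times = starts + window_s / 2
    return ProbabilityTrace(channel, times, p, window_s, stride_s)


def threshold_events(
    trace: ProbabilityTrace, params: DetectionParams
) -> list[DetectionEvent]:
    """Maximal runs with p ≥ θ_P spanning ≥ θ_D seconds, in time order.

    A run of n consecutive samples spans n·stride_s seconds (each sample
    stands for one stride interval); both threshold comparisons are
    inclusive.
    """
    if params.theta_d < trace.stride_s:
        raise ValueError("theta_d must be at least the trace stride")
    above = trace.p_sd >= params.theta_p
    events: list[DetectionEvent] = []
    n = len(above)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            span = (j - i + 1) * trace.stride_s
            if span >= params.theta_d:
                run = trace.p_sd[i : j + 1]
                k = i + int(np.argmax(run))
                # t_end closes the last sample's stride interval, so
                # t_end - t_start equals the run span
                events.append(
                    DetectionEvent(
                        channel=trace.channel,
                        t_start=float(trace.times[i]),
                        t_end=float(trace.times[j] + trace.stride_s),
                        t_peak=float(trace.times[k]),
                        peak_p=float(run.max()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return events


def detect_recording(
    rec,
    model,
    params: DetectionParams | None = None,
    window_s: float = 400.0,
    stride_s: float = 1.0,
) -> tuple[list[DetectionEvent], list[ProbabilityTrace]]:
    """Run detection on every channel of a 1-Hz Recording."""
    params = params or DetectionParams()
    events, traces = [], []
    for label, x in zip(rec.channel_labels, rec.data):
        trace = sliding_probability(x, model, channel=label,
                                    window_s=window_s, stride_s=stride_s)
        traces.append(trace)
        events.extend(threshold_events(trace, params))
    return events, traces


def events_to_frame(events: list[DetectionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.channel, e.t_start, e.t_end, e.t_peak, e.peak_p) for e in events],
        columns=["channel", "t_start", "t_end", "t_peak", "peak_p"],
    )


def events_from_frame(df: pd.DataFrame) -> list[DetectionEvent]:
    return [
        DetectionEvent(str(r.channel), float(r.t_start), float(r.t_end),
                       float(r.t_peak), float(r.peak_p))
        for r in df.itertuples()
    ]
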