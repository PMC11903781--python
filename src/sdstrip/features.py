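"""The 80 candidate features of a fixed-length 0.1-Hz ECoG segment.

Layout of the vector (names in :data:`feature_names`):

- 30 time-domain: 10 statistics on the full segment, then 10 per 30-sample
  sub-window advanced by 10 samples (two sub-windows for the default
  40-sample segment).
- 50 frequency-domain: (x, y) of the five most prominent peaks of the FT
  magnitude and of the PSD (20), the absolute maximum of each (2), quadrant
  counts of all local maxima after rescaling both axes to [-1, 1] (8), and
  the 10 statistics applied to each spectrum's values (20).

Conventions fixed here so stored models stay valid: population (1/N)
moments; excess kurtosis; entropy from a 10-bin equal-width histogram with
natural log; the forward transform is the unnormalized one-sided DFT over
bins 0..N/2 with the DC bin excluded from peak search and quadrant counting
but included in the spectral statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REGISTRY_VERSION = "1"

STAT_NAMES = (
    "mean", "variance", "skewness", "kurtosis", "entropy",
    "mean_cross_rate", "zero_cross_rate", "q1", "q2", "q3",
)

DEFAULT_SEGMENT_SAMPLES = 40
SUB_LEN = 30
SUB_ADVANCE = 10
N_PEAKS = 5
ENTROPY_BINS = 10


@dataclass
class Segment:
    """A 0.1-Hz voltage snippet with provenance metadata."""

    samples: np.ndarray
    subject: str = ""
    channel: str = ""
    center_time_s: float = 0.0
    label: str | None = None  # "sd" | "non_sd" | None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains non-finite samples")

    @property
    def length_s(self) -> float:
        return len(self.samples) * 10.0  # 0.1 Hz sampling


@dataclass
class Spectrum:
    freqs: np.ndarray  # Hz, ascending, freqs[0] == 0 (DC)
    values: np.ndarray  # magnitude (ft) or power (psd)
    kind: str

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.freqs) != len(self.values):
            raise ValueError("freqs and values must have equal length")


def time_stats(x: np.ndarray) -> dict[str, float]:
    """The 10 time-domain statistics of a series.

    Population moments throughout; excess kurtosis.  Cross rates count sign
    changes of (x − mean) and of x between consecutive samples.  Quartiles
    use linear interpolation.  Zero-variance input returns skewness =
    kurtosis = entropy = 0 so flat segments never produce NaNs.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    n = len(x)
    mu = x.sum() / n
    dev = x - mu
    var = float(np.mean(dev**2))
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean(dev**3) / sd**3)
        kurt = float(np.mean(dev**4) / sd**4 - 3.0)
    else:
        skew = kurt = 0.0
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return {
        "mean": float(mu),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": _histogram_entropy(x),
        "mean_cross_rate": _cross_count(dev),
        "zero_cross_rate": _cross_count(x),
        "q1": float(q1),
        "q2": float(q2),
        "q3": float(q3),
    }


def _histogram_entropy(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log(p)).sum())


def _cross_count(s: np.ndarray) -> float:
    return float(np.count_nonzero(s[:-1] * s[1:] < 0))


def subsegment_starts(n: int, sub_len: int = SUB_LEN, advance: int = SUB_ADVANCE):
    """Start indices of the full sub-windows: 0, advance, 2·advance, …"""
    return list(range(0, n - sub_len + 1, advance))


def subsegment_time_features(
    x: np.ndarray, sub_len: int = SUB_LEN, advance: int = SUB_ADVANCE
) -> dict[str, float]:
    """Full-segment statistics plus statistics of each full sub-window.

    A 40-sample segment yields sub-windows [0..29] and [10..39]: 30 features.
    Segments shorter than ``sub_len`` return only the 10 full-segment values.
    """
    x = np.asarray(x, dtype=np.float64)
    out = {f"time_full_{k}": v for k, v in time_stats(x).items()}
    if len(x) >= sub_len:
        for j, start in enumerate(subsegment_starts(len(x), sub_len, advance), 1):
            stats = time_stats(x[start : start + sub_len])
            out.update({f"time_sub{j}_{k}": v for k, v in stats.items()})
    return out


def spectrum(x: np.ndarray, kind: str = "ft") -> Spectrum:
    """One-sided discrete spectrum over bins 0..N/2 at 0.1-Hz sampling.

    ``ft`` is the unnormalized DFT magnitude; ``psd`` its square.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 4:
        raise ValueError("need at least 4 samples for a spectrum")
    if kind not in ("ft", "psd"):
        raise ValueError(f"unknown spectrum kind {kind!r}")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=10.0)  # 0.1 Hz sampling
    values = mag if kind == "ft" else mag**2
    return Spectrum(freqs=freqs, values=values, kind=kind)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus report their leftmost index.

    Endpoints cannot be maxima (both neighbors required).
    """
    idx = []
    n = len(values)
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def _prominences(values: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Topographic prominence: height above the higher bounding saddle.

    The saddle on each side is the minimum between the peak and the nearest
    strictly higher value (or the series end if none is higher).
    """
    proms = np.empty(len(peaks))
    for k, p in enumerate(peaks):
        h = values[p]
        left = values[:p][::-1]
        higher = np.nonzero(left > h)[0]
        lmin = left[: higher[0]].min() if len(higher) else (left.min() if len(left) else h)
        right = values[p + 1 :]
        higher = np.nonzero(right > h)[0]
        rmin = right[: higher[0]].min() if len(higher) else (right.min() if len(right) else h)
        proms[k] = h - max(lmin, rmin)
    return proms


def peak_features(sp: Spectrum, n_peaks: int = N_PEAKS) -> dict[str, float]:
    """(x, y) of the top-``n_peaks`` most prominent non-DC peaks + global max.

    Ranking is by prominence, ties broken toward lower frequency.  Missing
    slots are (0, 0).  The absolute maximum is taken over the non-DC bins.
    """
    vals = sp.values[1:]  # DC excluded from peak search
    freqs = sp.freqs[1:]
    peaks = _local_maxima(vals)
    out = {}
    if len(peaks):
        proms = _prominences(vals, peaks)
        order = np.lexsort((peaks, -proms))
    else:
        order = np.array([], dtype=int)
    for rank in range(n_peaks):
        if rank < len(order):
            p = peaks[order[rank]]
            fx, fy = float(freqs[p]), float(vals[p])
        else:
            fx = fy = 0.0
        out[f"{sp.kind}_peak{rank + 1}_x"] = fx
        out[f"{sp.kind}_peak{rank + 1}_y"] = fy
    out[f"{sp.kind}_max"] = float(vals.max()) if len(vals) else 0.0
    return out


def quadrant_counts(sp: Spectrum) -> dict[str, float]:
    """Counts of all non-DC local maxima per quadrant after axis rescaling.

    Frequency and value spans of the searched bins are linearly mapped to
    [-1, 1]; points landing exactly on an axis count to the positive side.
    Quadrants are numbered counter-clockwise from (+, +).
    """
    vals = sp.values[1:]
    freqs = sp.freqs[1:]
    counts = [0, 0, 0, 0]
    peaks = _local_maxima(vals)
    vspan = vals.max() - vals.min() if len(vals) else 0.0
    fspan = freqs[-1] - freqs[0] if len(freqs) else 0.0
    if len(peaks) and vspan > 0 and fspan > 0:
        xs = 2 * (freqs[peaks] - freqs[0]) / fspan - 1
        ys = 2 * (vals[peaks] - vals.min()) / vspan - 1
        for x, y in zip(xs, ys):
            if x >= 0 and y >= 0:
                counts[0] += 1
            elif x < 0 and y >= 0:
                counts[1] += 1
            elif x < 0 and y < 0:
                counts[2] += 1
            else:
                counts[3] += 1
    return {f"{sp.kind}_quadrant{q + 1}": float(c) for q, c in enumerate(counts)}


def extract_features(seg: Segment | np.ndarray) -> dict[str, float]:
    """The full 80-entry feature mapping of a 0.1-Hz segment."""
    x = seg.samples if isinstance(seg, Segment) else np.asarray(seg, dtype=np.float64)
    if len(x) < SUB_LEN:
        raise ValueError(f"segment must have at least {SUB_LEN} samples")
    ft = spectrum(x, "ft")
    psd = spectrum(x, "psd")
    out: dict[str, float] = {}
    out.update(subsegment_time_features(x))
    for sp in (ft, psd):
        out.update(peak_features(sp))
    for sp in (ft, psd):
        out.update(quadrant_counts(sp))
    for sp in (ft, psd):
        out.update({f"{sp.kind}_{k}": v for k, v in time_stats(sp.values).items()})
    return out


def feature_names(n_samples: int = DEFAULT_SEGMENT_SAMPLES) -> list[str]:
    """The fixed, versioned feature registry for a given segment length."""
    names = [f"time_full_{s}" for s in STAT_NAMES]
    for j, _ in enumerate(subsegment_starts(n_samples), 1):
        names += [f"time_sub{j}_{s}" for s in STAT_NAMES]
    for kind in ("ft", "psd"):
        for r in range(1, N_PEAKS + 1):
            names += [f"{kind}_peak{r}_x", f"{kind}_peak{r}_y"]
        names.append(f"{kind}_max")
    for kind in ("ft", "psd"):
        names += [f"{kind}_quadrant{q}" for q in range(1, 5)]
    for kind in ("ft", "psd"):
        names += [f"{kind}_{s}" for s in STAT_NAMES]
    return names


def feature_vector(seg: Segment | np.ndarray) -> np.ndarray:
    """Feature values in registry order."""
    feats = extract_features(seg)
    x = seg.samples if isinstance(seg, Segment) else seg
    return np.array([feats[n] for n in feature_names(len(x))])
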