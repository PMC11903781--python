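"""Raw full-band ECoG → baseline-corrected, low-passed, decimated series.

The three stages run in fixed order: (1) subtract a centered moving-median
baseline (default 10-min window), (2) zero-phase FIR low-pass at 0.5 Hz,
(3) integer decimation to the 1-Hz analysis rate.  Feature extraction later
decimates 1-Hz windows to 0.1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

#: Hamming-window main-lobe factor: transition width ≈ 3.3 / numtaps cycles/sample
_HAMMING_TRANSITION = 3.3


@dataclass
class PreprocessConfig:
    median_window_s: float = 600.0
    fir_cutoff_hz: float = 0.5
    target_rate_hz: float = 1.0
    feature_rate_hz: float = 0.1

    def __post_init__(self) -> None:
        if min(self.median_window_s, self.fir_cutoff_hz, self.target_rate_hz,
               self.feature_rate_hz) <= 0:
            raise ValueError("all preprocessing parameters must be positive")


def moving_median_baseline(
    x: np.ndarray, fs: float, window_s: float = 600.0
) -> np.ndarray:
    """Subtract the centered moving median of ``x`` over ``window_s`` seconds.

    Each output sample is ``x[i] - median(x[i-h : i+h])`` where the window is
    clipped to the available samples at the edges (no padding).  Invariant to
    additive constants; a transient occupying less than half the window on a
    flat baseline passes through untouched.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    w = int(round(window_s * fs))
    if w < 3:
        raise ValueError("median window must span at least 3 samples")
    w |= 1  # odd width keeps the window symmetric about each sample
    med = pd.Series(x).rolling(window=w, center=True, min_periods=1).median()
    return x - med.to_numpy()


def design_lowpass_fir(
    fs: float, cutoff_hz: float, transition_hz: float = 0.2
) -> np.ndarray:
    """Linear-phase windowed-sinc low-pass with unit DC gain.

    Hamming window; tap count chosen for the requested transition width,
    giving ≥ 40 dB stopband attenuation.
    """
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    numtaps = int(np.ceil(_HAMMING_TRANSITION * fs / transition_hz)) | 1
    return signal.firwin(numtaps, cutoff_hz, fs=fs)


def lowpass_fir(
    x: np.ndarray, fs: float, cutoff_hz: float = 0.5, transition_hz: float = 0.2
) -> np.ndarray:
    """Zero-phase FIR low-pass; output length equals input length.

    The symmetric kernel is applied by centered convolution with
    edge-replicated padding, so the linear-phase group delay cancels exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    h = design_lowpass_fir(fs, cutoff_hz, transition_hz)
    half = len(h) // 2
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    return signal.fftconvolve(padded, h, mode="valid")


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Keep every n-th sample (phase 0) for integer factor n = fs_in/fs_out."""
    x = np.asarray(x)
    factor = fs_in / fs_out
    n = int(round(factor))
    if n < 1 or abs(factor - n) > 1e-9:
        raise ValueError(f"fs_in/fs_out = {factor} is not a positive integer")
    return x[::n]


def preprocess_channel(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """median-correct → FIR low-pass → decimate to ``cfg.target_rate_hz``."""
    cfg = cfg or PreprocessConfig()
    corrected = moving_median_baseline(x, fs, cfg.median_window_s)
    filtered = lowpass_fir(corrected, fs, cfg.fir_cutoff_hz)
    return downsample(filtered, fs, cfg.target_rate_hz)


def preprocess_recording(rec, cfg: PreprocessConfig | None = None):
    """Apply :func:`preprocess_channel` to every channel of a Recording."""
    from sdstrip.io import Recording

    cfg = cfg or PreprocessConfig()
    out = np.stack(
        [preprocess_channel(ch, rec.sample_rate_hz, cfg) for ch in rec.data]
    )
    return Recording(
        subject_id=rec.subject_id,
        channel_labels=list(rec.channel_labels),
        sample_rate_hz=cfg.target_rate_hz,
        data=out,
        start_time=rec.start_time,
    )
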