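"""Minimal European Data Format (EDF) reader/writer.

Supports the plain-EDF subset this package needs: monopolar continuous
signals, identical sample counts per channel, 16-bit samples.  EDF+ features
(embedded annotations, discontinuous records) are out of scope.

No EDF library is available in the runtime image, so the 256-byte fixed-field
header is parsed directly per the format definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass
class EdfSignal:
    label: str
    physical_dim: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int


@dataclass
class EdfFile:
    patient_id: str
    recording_id: str
    n_records: int
    record_duration_s: float
    signals: list[EdfSignal]
    data: np.ndarray  # (n_signals, n_samples), physical units as stored

    @property
    def sample_rate_hz(self) -> float:
        return self.signals[0].samples_per_record / self.record_duration_s


def _field(raw: bytes, offset: int, width: int) -> str:
    return raw[offset : offset + width].decode("ascii", errors="replace").strip()


def read_edf(path) -> EdfFile:
    """Parse an EDF file into per-signal physical-unit arrays."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise ValueError(f"{path}: too short to be an EDF file")
    header_bytes = int(_field(raw, 184, 8))
    n_records = int(_field(raw, 236, 8))
    record_dur = float(_field(raw, 244, 8))
    ns = int(_field(raw, 252, 4))
    if ns <= 0 or header_bytes != 256 + 256 * ns:
        raise ValueError(f"{path}: inconsistent EDF header")

    sig_hdr = raw[256:header_bytes]
    signals = []
    for i in range(ns):
        signals.append(
            EdfSignal(
                label=_sig(sig_hdr, ns, i, 0, 16),
                physical_dim=_sig(sig_hdr, ns, i, 96, 8),
                physical_min=float(_sig(sig_hdr, ns, i, 104, 8)),
                physical_max=float(_sig(sig_hdr, ns, i, 112, 8)),
                digital_min=int(_sig(sig_hdr, ns, i, 120, 8)),
                digital_max=int(_sig(sig_hdr, ns, i, 128, 8)),
                samples_per_record=int(_sig(sig_hdr, ns, i, 216, 8)),
            )
        )
    spr = {s.samples_per_record for s in signals}
    if len(spr) != 1:
        raise ValueError(f"{path}: channels of unequal length are unsupported")

    counts = [s.samples_per_record for s in signals]
    rec_len = sum(counts)
    payload = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    if payload.size < n_records * rec_len:
        raise ValueError(f"{path}: truncated data section")
    payload = payload[: n_records * rec_len].reshape(n_records, rec_len)

    data = np.empty((ns, n_records * counts[0]), dtype=np.float64)
    pos = 0
    for i, sig in enumerate(signals):
        dig = payload[:, pos : pos + sig.samples_per_record].reshape(-1)
        pos += sig.samples_per_record
        dig_span = sig.digital_max - sig.digital_min
        if dig_span == 0:
            raise ValueError(f"{path}: signal {sig.label} has zero digital span")
        gain = (sig.physical_max - sig.physical_min) / dig_span
        data[i] = (dig.astype(np.float64) - sig.digital_min) * gain + sig.physical_min

    return EdfFile(
        patient_id=_field(raw, 8, 80),
        recording_id=_field(raw, 88, 80),
        n_records=n_records,
        record_duration_s=record_dur,
        signals=signals,
        data=data,
    )


def _sig(sig_hdr: bytes, ns: int, i: int, base: int, width: int) -> str:
    off = base * ns + i * width
    return sig_hdr[off : off + width].decode("ascii", errors="replace").strip()


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # densest float rendering that still fits the fixed-width field
        for prec in range(width - 2, 0, -1):
            s = f"{float(value):.{prec}g}"
            if len(s) <= width:
                break
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    sample_rate_hz: float,
    channel_labels: list[str],
    physical_dim: str = "mV",
    patient_id: str = "X",
    recording_id: str = "Startdate X",
) -> None:
    """Write channels × samples ``data`` (physical units) as plain EDF.

    Uses 1-s data records when the sample count divides evenly at an integer
    rate, otherwise a single record spanning the whole signal.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] == 0:
        raise ValueError("data must be a non-empty (channels, samples) array")
    ns, n = data.shape
    if ns != len(channel_labels):
        raise ValueError("channel_labels length must match data rows")

    fs_int = int(round(sample_rate_hz))
    if math.isclose(sample_rate_hz, fs_int) and n % fs_int == 0:
        record_dur, spr = 1.0, fs_int
    else:
        record_dur, spr = n / sample_rate_hz, n
    n_records = n // spr

    digital = np.empty((ns, n), dtype=np.int16)
    pmins, pmaxs = [], []
    for i in range(ns):
        lo, hi = float(data[i].min()), float(data[i].max())
        if hi == lo:  # avoid a degenerate gain for constant channels
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        scaled = (data[i] - lo) / (hi - lo) * (_DIG_MAX - _DIG_MIN) + _DIG_MIN
        digital[i] = np.round(scaled).astype(np.int16)

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient_id, 80),
            _ascii(recording_id, 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 + 256 * ns, 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(record_dur, 8),
            _ascii(ns, 4),
        ]
    )
    blocks = [
        (16, channel_labels),
        (80, [""] * ns),
        (8, [physical_dim] * ns),
        (8, pmins),
        (8, pmaxs),
        (8, [_DIG_MIN] * ns),
        (8, [_DIG_MAX] * ns),
        (80, [""] * ns),
        (8, [spr] * ns),
        (32, [""] * ns),
    ]
    sig_hdr = b"".join(_ascii(v, w) for w, vals in blocks for v in vals)

    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        fh.write(np.ascontiguousarray(records, dtype="<i2").tobytes())
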