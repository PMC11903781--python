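"""Recording / annotation / model I/O.

Recordings travel as EDF or HDF5 (internal voltages always mV), annotations
as CSV with columns ``subject,channel,t_peak_s[,label_class]``, feature
tables as CSV, and trained models as a joblib dump with a JSON sidecar
describing the feature registry and preprocessing parameters.

HDF5 layout (this package's own, documented here): a single 2-D float dataset
``/data`` of shape (n_channels, n_samples) with root attributes
``subject_id``, ``sample_rate_hz``, ``start_time`` and ``channel_labels``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from sdstrip import _edf

LABEL_CLASSES = ("definite", "probable", "possible")

#: multiplicative factors that bring an EDF physical dimension to mV
_UNIT_TO_MV = {"mv": 1.0, "uv": 1e-3, "µv": 1e-3, "v": 1e3}


@dataclass
class Recording:
    """Multichannel voltage time series, channels × samples, in mV.

    ``start_time`` is a recording-relative offset in seconds (0 at the first
    sample); wall-clock time is out of scope.
    """

    subject_id: str
    channel_labels: list[str]
    sample_rate_hz: float
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels, samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data rows")
        if self.data.shape[1] == 0:
            raise ValueError("recording has empty channels")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voltages must be finite (mark gaps explicitly)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass(frozen=True, order=True)
class Annotation:
    """One expert mark: the timestamp of an SD waveform's peak negativity."""

    subject_id: str
    channel: str
    t_peak_s: float
    label_class: str = "definite"


@dataclass
class AnnotationSet:
    records: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.t_peak_s < 0 or not np.isfinite(rec.t_peak_s):
                raise ValueError(f"t_peak must be a non-negative number, got {rec.t_peak_s}")
            if rec.label_class not in LABEL_CLASSES:
                raise ValueError(f"unknown label_class {rec.label_class!r}")
        self.records = sorted(self.records, key=lambda r: (r.channel, r.t_peak_s))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_channel(self, channel: str) -> list[Annotation]:
        return [r for r in self.records if r.channel == channel]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.subject_id, r.channel, r.t_peak_s, r.label_class) for r in self.records],
            columns=["subject", "channel", "t_peak_s", "label_class"],
        )


def read_recording(path, format: str | None = None) -> Recording:
    """Read an EDF or HDF5 recording; voltages are normalized to mV.

    The native sampling rate from the file header is preserved — reading
    never resamples.
    """
    fmt = format or _infer_format(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _edf.write_edf(
            path,
            rec.data,
            rec.sample_rate_hz,
            rec.channel_labels,
            physical_dim="mV",
            patient_id=rec.subject_id or "X",
        )
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=rec.data)
            dset.attrs["units"] = "mV"
            f.attrs["subject_id"] = rec.subject_id
            f.attrs["sample_rate_hz"] = rec.sample_rate_hz
            f.attrs["start_time"] = rec.start_time
            f.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer recording format from {path!r}")


def _read_edf(path) -> Recording:
    try:
        edf = _edf.read_edf(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"failed to parse {path} as EDF: {exc}") from exc
    data = edf.data.copy()
    for i, sig in enumerate(edf.signals):
        factor = _UNIT_TO_MV.get(sig.physical_dim.lower())
        if factor is None:
            factor = 1.0  # dimensionless or unknown: assume mV
        data[i] *= factor
    return Recording(
        subject_id=edf.patient_id,
        channel_labels=[s.label for s in edf.signals],
        sample_rate_hz=edf.sample_rate_hz,
        data=data,
    )


def _read_hdf5(path) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            return Recording(
                subject_id=str(f.attrs.get("subject_id", "")),
                channel_labels=[str(c) for c in f.attrs["channel_labels"]],
                sample_rate_hz=float(f.attrs["sample_rate_hz"]),
                data=data,
                start_time=float(f.attrs.get("start_time", 0.0)),
            )
    except (OSError, KeyError) as exc:
        raise ValueError(f"failed to parse {path} as HDF5 recording: {exc}") from exc


def read_annotations(path) -> AnnotationSet:
    """Read a ``subject,channel,t_peak_s[,label_class]`` CSV."""
    df = pd.read_csv(path, dtype={"subject": str, "channel": str})
    required = {"subject", "channel", "t_peak_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    t = pd.to_numeric(df["t_peak_s"], errors="coerce")
    if t.isna().any() or (t < 0).any():
        raise ValueError("t_peak_s values must be non-negative numbers")
    classes = df["label_class"] if "label_class" in df.columns else "definite"
    df = df.assign(t_peak_s=t, label_class=classes)
    return AnnotationSet(
        [
            Annotation(row.subject, row.channel, float(row.t_peak_s), row.label_class)
            for row in df.itertuples()
        ]
    )


def write_annotations(aset: AnnotationSet, path) -> None:
    aset.to_frame().to_csv(path, index=False)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(model, path) -> None:
    """Persist a TrainedModel: joblib dump + JSON sidecar (<path>.json)."""
    import joblib

    joblib.dump(model, path)
    sidecar = {
        "model_kind": model.config.model_kind,
        "segment_length_s": model.config.segment_length_s,
        "selected_features": list(model.selected_features),
        "feature_registry_version": model.registry_version,
        "preprocessing": model.preprocessing,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path):
    import joblib

    model = joblib.load(path)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar["feature_registry_version"] != model.registry_version:
            raise ValueError("model feature-registry version mismatch")
    return model
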