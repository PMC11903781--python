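"""Training-set construction, feature ranking, model fitting, LOPO-CV.

The gradient-boosted-tree backend is scikit-learn's
``GradientBoostingClassifier`` (split-gain feature importances); the SVM
backend is an RBF-kernel ``SVC`` with Platt-calibrated probabilities.
Cross-validation is leave-one-patient-out: every subject serves exactly once
as the held-out test set and metrics are pooled over all held-out
predictions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.svm import SVC

from sdstrip import features as feat
from sdstrip.io import AnnotationSet, Recording
from sdstrip.preprocess import downsample

POS_LABEL = "sd"
NEG_LABEL = "non_sd"

_META_COLS = ["label", "subject", "channel", "center_time_s", "segment_abs_max_mv"]


@dataclass
class ModelConfig:
    model_kind: str = "gbt"  # "gbt" | "svm_rbf"
    segment_length_s: float = 400.0
    k_features: int = 30
    hyperparameters: dict = dc_field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("gbt", "svm_rbf"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.segment_length_s < 300:
            raise ValueError("segment_length_s must be >= 300")
        if not 1 <= self.k_features <= 80:
            raise ValueError("k_features must be in [1, 80]")


@dataclass
class TrainingSet:
    """Feature rows + labels + provenance, carried as one DataFrame.

    Feature columns follow the registry; metadata columns are ``label``,
    ``subject``, ``channel``, ``center_time_s`` and ``segment_abs_max_mv``
    (the absolute maximum of the source analysis segment, used for
    curation).
    """

    frame: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _META_COLS]

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    @property
    def y(self) -> np.ndarray:
        return (self.frame["label"] == POS_LABEL).to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject"].to_numpy()

    def n_positive(self) -> int:
        return int((self.frame["label"] == POS_LABEL).sum())

    def n_negative(self) -> int:
        return int((self.frame["label"] == NEG_LABEL).sum())


@dataclass
class TrainedModel:
    config: ModelConfig
    selected_features: list[str]
    backend: object
    registry_version: str = feat.REGISTRY_VERSION
    preprocessing: dict = dc_field(default_factory=dict)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(SD) for rows of a feature table (columns selected by name)."""
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ValueError(f"feature table missing model features: {missing}")
        proba = self.backend.predict_proba(X[self.selected_features].to_numpy())
        return proba[:, 1]


def _segment_row(
    x1hz: np.ndarray,
    subject: str,
    channel: str,
    center_s: float,
    label: str,
    analysis_len_s: float,
) -> dict:
    """Center-trim a 1-Hz window to the analysis length, decimate to 0.1 Hz,
    extract features."""
    n = len(x1hz)
    half = int(analysis_len_s) // 2
    mid = n // 2
    trimmed = x1hz[mid - half : mid - half + int(analysis_len_s)]
    seg = downsample(trimmed, 1.0, 0.1)
    row = feat.extract_features(seg)
    row.update(
        label=label,
        subject=subject,
        channel=channel,
        center_time_s=center_s,
        segment_abs_max_mv=float(np.abs(trimmed).max()),
    )
    return row


def build_training_set(
    rec: Recording,
    ann: AnnotationSet,
    pos_len_s: float = 1000.0,
    analysis_len_s: float = 400.0,
) -> TrainingSet:
    """Labeled segments from a 1-Hz preprocessed recording + annotations.

    Positives: one ``pos_len_s`` window centered on each annotated peak.
    Negatives: greedy left-to-right tiling of every channel that has at
    least one annotation with non-overlapping ``pos_len_s`` windows
    containing no annotation.  Windows extending past the recording are
    dropped; annotations outside the recording are skipped with a warning.
    Each window is center-trimmed to ``analysis_len_s`` and decimated to
    0.1 Hz before feature extraction.
    """
    if abs(rec.sample_rate_hz - 1.0) > 1e-9:
        raise ValueError("recording must be preprocessed to 1 Hz")
    rows = []
    duration = rec.n_samples
    pos_len = int(pos_len_s)
    for label_idx, channel in enumerate(rec.channel_labels):
        marks = ann.for_channel(channel)
        if not marks:
            continue  # negatives come only from channels with >= 1 SD
        x = rec.data[label_idx]
        mark_times = np.array([m.t_peak_s for m in marks])
        for m in marks:
            start = int(round(m.t_peak_s)) - pos_len // 2
            if m.t_peak_s < 0 or m.t_peak_s > duration:
                warnings.warn(
                    f"annotation at t={m.t_peak_s} outside recording; skipped",
                    stacklevel=2,
                )
                continue
            if start < 0 or start + pos_len > duration:
                continue  # window would extend past the recording
            rows.append(
                _segment_row(
                    x[start : start + pos_len],
                    rec.subject_id, channel, m.t_peak_s, POS_LABEL, analysis_len_s,
                )
            )
        start = 0
        while start + pos_len <= duration:
            inside = (mark_times >= start) & (mark_times < start + pos_len)
            if not inside.any():
                rows.append(
                    _segment_row(
                        x[start : start + pos_len],
                        rec.subject_id, channel, start + pos_len / 2,
                        NEG_LABEL, analysis_len_s,
                    )
                )
            start += pos_len
    columns = feat.feature_names(int(analysis_len_s / 10)) + _META_COLS
    return TrainingSet(pd.DataFrame(rows, columns=columns))


def concat_training_sets(sets: list[TrainingSet]) -> TrainingSet:
    return TrainingSet(pd.concat([s.frame for s in sets], ignore_index=True))


def curate_positives(ts: TrainingSet, max_abs_mv: float = 30.0) -> tuple[TrainingSet, int]:
    """Drop positive rows whose source segment exceeds ``max_abs_mv``.

    Returns (curated set, number of rows removed).  Negatives are untouched.
    """
    if max_abs_mv <= 0:
        raise ValueError("max_abs_mv must be positive")
    is_pos = ts.frame["label"] == POS_LABEL
    drop = is_pos & (ts.frame["segment_abs_max_mv"] > max_abs_mv)
    return TrainingSet(ts.frame[~drop].reset_index(drop=True)), int(drop.sum())


def _make_backend(cfg: ModelConfig):
    hp = dict(cfg.hyperparameters)
    if cfg.model_kind == "gbt":
        return GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 300),
            max_depth=hp.pop("max_depth", 3),
            learning_rate=hp.pop("learning_rate", 0.1),
            random_state=cfg.random_seed,
            **hp,
        )
    svc = SVC(
        kernel="rbf",
        C=hp.pop("C", 1.0),
        gamma=hp.pop("gamma", "scale"),
        random_state=cfg.random_seed,
        **hp,
    )
    # Platt-style sigmoid calibration fitted on training folds
    return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)


def _lopo_folds(subjects: np.ndarray):
    for subject in pd.unique(subjects):
        yield subject, subjects != subject, subjects == subject


def rank_features(ts: TrainingSet, cfg: ModelConfig | None = None) -> pd.DataFrame:
    """Features ordered by split-gain importance averaged over LOPO folds.

    Fits the gradient-boosted backend once per leave-one-patient-out fold
    and averages the per-fold gain importances; ties keep registry order.
    """
    cfg = cfg or ModelConfig()
    subjects = ts.subjects
    if len(pd.unique(subjects)) < 2:
        raise ValueError("feature ranking needs at least 2 subjects")
    names = ts.feature_names
    X, y = ts.X.to_numpy(), ts.y
    gains = []
    for _, train_mask, _ in _lopo_folds(subjects):
        model = _make_backend(ModelConfig(model_kind="gbt", random_seed=cfg.random_seed,
                                          hyperparameters=cfg.hyperparameters))
        model.fit(X[train_mask], y[train_mask])
        gains.append(model.feature_importances_)
    mean_gain = np.mean(gains, axis=0)
    order = np.lexsort((np.arange(len(names)), -mean_gain))
    return pd.DataFrame(
        {"feature": [names[i] for i in order], "importance": mean_gain[order]}
    )


def select_top_k(ranking: pd.DataFrame, k: int) -> list[str]:
    return ranking["feature"].head(k).tolist()


def train(
    ts: TrainingSet, cfg: ModelConfig, selected: list[str] | None = None
) -> TrainedModel:
    """Fit the configured backend on the selected feature columns."""
    y = ts.y
    if y.all() or not y.any():
        raise ValueError("training needs both classes present")
    selected = list(selected) if selected is not None else ts.feature_names
    backend = _make_backend(cfg)
    backend.fit(ts.frame[selected].to_numpy(), y)
    return TrainedModel(config=cfg, selected_features=selected, backend=backend)


def _pooled_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> dict:
    y_pred = y_prob >= 0.5
    out = {
        "accuracy": float(skmetrics.accuracy_score(y_true, y_pred)),
        "precision": float(
            skmetrics.precision_score(y_true, y_pred, zero_division=0)
        ),
        "recall": float(skmetrics.recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(skmetrics.f1_score(y_true, y_pred, zero_division=0)),
    }
    out["auc"] = (
        float(skmetrics.roc_auc_score(y_true, y_prob))
        if len(np.unique(y_true)) == 2
        else float("nan")
    )
    return out


def lopo_cv(ts: TrainingSet, cfg: ModelConfig | None = None) -> dict:
    """Leave-one-patient-out CV with per-fold feature selection.

    Within each fold the ranking is refit on the training subjects only
    (single-fit gain importances), the top-k features are selected, the
    model is trained and the held-out subject scored.  Returns pooled
    metrics plus the per-row prediction table.
    """
    cfg = cfg or ModelConfig()
    subjects = ts.subjects
    uniq = pd.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("LOPO-CV needs at least 2 subjects")
    names = ts.feature_names
    X, y = ts.X.to_numpy(), ts.y
    pred_rows = []
    for subject, train_mask, test_mask in _lopo_folds(subjects):
        ranker = _make_backend(ModelConfig(model_kind="gbt", random_seed=cfg.random_seed))
        ranker.fit(X[train_mask], y[train_mask])
        order = np.lexsort((np.arange(len(names)), -ranker.feature_importances_))
        cols = order[: cfg.k_features]
        model = _make_backend(cfg)
        model.fit(X[np.ix_(train_mask, cols)], y[train_mask])
        prob = model.predict_proba(X[np.ix_(test_mask, cols)])[:, 1]
        for i, p in zip(np.nonzero(test_mask)[0], prob):
            pred_rows.append({"row": i, "subject": subject, "y_true": bool(y[i]), "p_sd": float(p)})
    preds = pd.DataFrame(pred_rows)
    result = _pooled_metrics(preds["y_true"].to_numpy(), preds["p_sd"].to_numpy())
    result["n_folds"] = len(uniq)
    result["predictions"] = preds
    return result


def grid_search(
    ts: TrainingSet, cfg: ModelConfig, grid: dict[str, list]
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by pooled LOPO F1.

    Ties are broken by first-in-grid order.  Returns (best hyperparameters,
    full results table).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = list(grid)
    rows = []
    best, best_f1 = None, -1.0
    for values in itertools.product(*(grid[k] for k in keys)):
        hp = dict(zip(keys, values))
        trial_cfg = ModelConfig(
            model_kind=cfg.model_kind,
            segment_length_s=cfg.segment_length_s,
            k_features=cfg.k_features,
            hyperparameters={**cfg.hyperparameters, **hp},
            random_seed=cfg.random_seed,
        )
        result = lopo_cv(ts, trial_cfg)
        rows.append({**hp, "f1": result["f1"], "auc": result["auc"],
                     "accuracy": result["accuracy"]})
        if result["f1"] > best_f1:  # strict: ties keep the earlier point
            best, best_f1 = hp, result["f1"]
    return best, pd.DataFrame(rows)
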