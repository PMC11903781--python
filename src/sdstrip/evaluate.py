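"""Scoring of detection events against ground-truth annotations.

Each ground-truth mark owns a 400-s window centered on its peak time.  A
detection event overlapping at least one such window is assigned to the
nearest mark (by peak-to-peak distance); a mark with any assigned event
counts once as a true positive, unassigned events are false positives, and
unmatched marks are false negatives.  Specificity is not reported for
continuous data: no true-negative unit is defined there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sdstrip.detector import DetectionEvent, DetectionParams, ProbabilityTrace, threshold_events
from sdstrip.io import AnnotationSet


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    recording_hours: float
    sensitivity: float
    precision: float
    f1: float
    obj: float
    obj_1e5: float
    fp_per_day: float
    adjusted_fp: int | None = None
    adjusted_fp_per_day: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def match_detections(
    events: list[DetectionEvent],
    ann: AnnotationSet,
    window_s: float = 400.0,
    channels: list[str] | None = None,
) -> tuple[int, int, int, pd.DataFrame]:
    """Assign events to ground-truth marks per channel.

    If ``channels`` is given, events or marks on labels outside it raise a
    ValueError.  Returns (TP, FP, FN, assignment table).  Conservation holds
    by construction: TP + FN = number of marks; every event is either
    assigned to exactly one mark or counted as one FP.
    """
    half = window_s / 2
    if channels is not None:
        known = set(channels)
        bad = {e.channel for e in events} | {m.channel for m in ann}
        bad -= known
        if bad:
            raise ValueError(f"unknown channel labels: {sorted(bad)}")
    rows = []
    fp = 0
    matched_marks: set[tuple[str, float]] = set()
    for e in events:
        marks = ann.for_channel(e.channel)
        overlapping = [
            m for m in marks
            if e.t_start <= m.t_peak_s + half and e.t_end >= m.t_peak_s - half
        ]
        if overlapping:
            nearest = min(overlapping, key=lambda m: abs(m.t_peak_s - e.t_peak))
            matched_marks.add((nearest.channel, nearest.t_peak_s))
            rows.append({"channel": e.channel, "t_peak": e.t_peak,
                         "assigned_mark": nearest.t_peak_s, "outcome": "tp"})
        else:
            fp += 1
            rows.append({"channel": e.channel, "t_peak": e.t_peak,
                         "assigned_mark": np.nan, "outcome": "fp"})
    tp = len(matched_marks)
    fn = len(ann) - tp
    assignment = pd.DataFrame(rows, columns=["channel", "t_peak", "assigned_mark", "outcome"])
    return tp, fp, fn, assignment


def metrics(tp: int, fp: int, fn: int, recording_hours: float) -> EvalReport:
    """Sensitivity, precision, F1, OBJ = TP² − 2·FP², and FP/day.

    Zero-denominator conventions: sensitivity/precision/F1 are 0 when
    undefined.  OBJ is reported raw and in units of 1e5.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if recording_hours <= 0:
        raise ValueError("recording_hours must be positive")
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    obj = float(tp**2 - 2 * fp**2)
    return EvalReport(
        tp=tp, fp=fp, fn=fn,
        recording_hours=recording_hours,
        sensitivity=sens, precision=prec, f1=f1,
        obj=obj, obj_1e5=obj / 1e5,
        fp_per_day=fp / (recording_hours / 24),
    )


def evaluate_events(
    events: list[DetectionEvent],
    ann: AnnotationSet,
    recording_hours: float,
    window_s: float = 400.0,
) -> EvalReport:
    tp, fp, fn, _ = match_detections(events, ann, window_s)
    return metrics(tp, fp, fn, recording_hours)


def threshold_sweep(
    traces: list[ProbabilityTrace],
    ann: AnnotationSet,
    theta_p_grid: list[float],
    theta_d_grid: list[float],
    recording_hours: float,
    window_s: float = 400.0,
) -> pd.DataFrame:
    """EvalReport rows for every (θ_P, θ_D) pair, sorted by F1 descending."""
    if not theta_p_grid or not theta_d_grid:
        raise ValueError("threshold grids must be non-empty")
    rows = []
    for tp_thresh in theta_p_grid:
        for td in theta_d_grid:
            params = DetectionParams(theta_p=tp_thresh, theta_d=td)
            events = []
            for trace in traces:
                events.extend(threshold_events(trace, params))
            report = evaluate_events(events, ann, recording_hours, window_s)
            rows.append({"theta_p": tp_thresh, "theta_d": td, **report.to_dict()})
    return (
        pd.DataFrame(rows)
        .sort_values("f1", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def apply_adjudication(report: EvalReport, adjudicated_real: int) -> EvalReport:
    """Subtract expert-confirmed real SDs from the FP count.

    Original counts are retained; ``adjusted_fp`` and its per-day rate are
    added alongside.
    """
    if not 0 <= adjudicated_real <= report.fp:
        raise ValueError("adjudicated count must be in [0, FP]")
    adjusted = report.fp - adjudicated_real
    return EvalReport(
        **{**report.__dict__,
           "adjusted_fp": adjusted,
           "adjusted_fp_per_day": adjusted / (report.recording_hours / 24)},
    )
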