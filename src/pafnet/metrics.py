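"""Binary classification metrics and AF boundary/episode evaluation.

Accuracy, sensitivity, specificity, precision, F1, FPR and the Matthews
correlation coefficient computed from TP/FP/TN/FN with AF as the positive
class.  Metrics with a zero denominator are reported as ``None``
("undefined"), never silently as 0.  Boundary evaluation matches detected
onsets/offsets to annotated ones within a +/-3-beat tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import EpisodeSet, ValidationError
from .segmentation import BeatLabels

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "report",
    "boundary_sensitivity",
    "episode_metrics",
    "BOUNDARY_TOL_BEATS",
]

BOUNDARY_TOL_BEATS = 3


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    """Fractions in [0, 1] (mcc in [-1, 1]); ``None`` marks an undefined
    (zero-denominator) metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    fpr: float | None
    mcc: float | None

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def confusion(true_labels, pred_labels) -> ConfusionCounts:
    """Exact TP/FP/TN/FN counts; AF (truthy) is the positive class."""
    t = np.asarray(true_labels, dtype=bool)
    p = np.asarray(pred_labels, dtype=bool)
    if t.shape != p.shape:
        raise ValidationError("label sequences differ in length")
    return ConfusionCounts(
        TP=int(np.sum(t & p)), FP=int(np.sum(~t & p)),
        TN=int(np.sum(~t & ~p)), FN=int(np.sum(t & ~p)))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def report(counts: ConfusionCounts) -> MetricReport:
    """Standard formulas on the counts; AF positive."""
    if counts.total <= 0:
        raise ValidationError("empty confusion table")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    if sens is None or prec is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    return MetricReport(
        accuracy=_ratio(tp + tn, counts.total),
        sensitivity=sens,
        specificity=_ratio(tn, fp + tn),
        precision=prec,
        f1=f1,
        fpr=_ratio(fp, fp + tn),
        mcc=mcc,
    )


def _match_boundaries(true_pts: list[int], pred_pts: list[int],
                      tol: int) -> int:
    """Greedy nearest-first one-to-one matching; returns matched count."""
    pairs = sorted(
        (abs(t - p), ti, pi)
        for ti, t in enumerate(true_pts)
        for pi, p in enumerate(pred_pts)
        if abs(t - p) <= tol)
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched = 0
    for _, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matched += 1
    return matched


def boundary_sensitivity(pred: EpisodeSet, truth: EpisodeSet,
                         tol_beats: int = BOUNDARY_TOL_BEATS
                         ) -> tuple[float | None, float | None, dict]:
    """Onset/offset detection sensitivity at a +/-``tol_beats`` tolerance.

    Each annotated onset counts as detected when an unmatched predicted
    onset lies within the tolerance (one-to-one, nearest first); offsets
    likewise.  Returns (se_onset, se_offset, counts).
    """
    t_on = [on for on, _ in truth.episodes]
    t_off = [off for _, off in truth.episodes]
    p_on = [on for on, _ in pred.episodes]
    p_off = [off for _, off in pred.episodes]
    m_on = _match_boundaries(t_on, p_on, tol_beats)
    m_off = _match_boundaries(t_off, p_off, tol_beats)
    counts = {"true_episodes": len(truth.episodes),
              "pred_episodes": len(pred.episodes),
              "matched_onsets": m_on, "matched_offsets": m_off}
    return (_ratio(m_on, len(t_on)), _ratio(m_off, len(t_off)), counts)


def episode_metrics(pred_beats: BeatLabels, true_beats: BeatLabels) -> MetricReport:
    """Beat-level (duration-weighted) confusion over a recording."""
    if len(pred_beats) != len(true_beats):
        raise ValidationError("beat label sequences differ in length")
    return report(confusion(true_beats.labels, pred_beats.labels))
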