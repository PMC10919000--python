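"""Evaluation metrics that account for unvalidatable predictions.

In target fishing, a compound is scored against a large candidate-target
universe, but experimental records exist for only a handful of those
targets, and a model may not exist — or the compound may fall outside its
applicability domain — for some of the annotated ones.  The confusion
matrix therefore carries an explicit *unknown* cell alongside TP/FP/TN/FN,
and two additional rates describe coverage:

recovery rate
    Of the targets that have both an experimental record and a model, the
    fraction for which an evaluable (in-domain) prediction was produced.
unknown rate
    Of the whole candidate universe, the fraction of predictions that
    cannot be validated at all.

Zero-denominator metrics yield :data:`UNDEFINED` (NaN), never an
exception, and are excluded from aggregation rather than zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import ACTIVE, INACTIVE
from .modeling import CompoundProfile

#: Marker for a metric whose denominator is zero.
UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return not np.isnan(x)


@dataclass
class TruthTable:
    """Known experimental labels over a candidate-target universe.

    ``labels`` maps (compound_id, target_id) to "active"/"inactive";
    ``universe`` is the full list of candidate targets (size T) a profile
    predicts over.
    """

    labels: Mapping[tuple[str, str], str]
    universe: Sequence[str]

    def __post_init__(self):
        bad = {v for v in self.labels.values()} - {ACTIVE, INACTIVE}
        if bad:
            raise ValueError(f"unknown truth labels: {sorted(bad)}")

    @property
    def T(self) -> int:
        return len(self.universe)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, universe: Sequence[str] | None = None) -> "TruthTable":
        """Build from a (compound_id, target_id, label) table."""
        labels = {
            (str(r.compound_id), str(r.target_id)): str(r.label)
            for r in df.itertuples(index=False)
        }
        if universe is None:
            universe = sorted({t for _, t in labels})
        return cls(labels=labels, universe=list(universe))


@dataclass
class ConfusionWithUnknown:
    """Confusion counts plus the unvalidatable remainder of the universe.

    ``n_model_covered`` counts the targets having both a truth record and a
    model — the denominator of the recovery rate.  The invariant
    ``tp + fp + tn + fn + unknown == T`` always holds.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    unknown: int = 0
    n_model_covered: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn, self.unknown) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n_evaluable > self.n_model_covered:
            raise ValueError("evaluable count cannot exceed model-covered count")

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def T(self) -> int:
        return self.n_evaluable + self.unknown

    def __add__(self, other: "ConfusionWithUnknown") -> "ConfusionWithUnknown":
        return ConfusionWithUnknown(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn,
            self.fn + other.fn, self.unknown + other.unknown,
            self.n_model_covered + other.n_model_covered,
        )


def tally(
    profile: CompoundProfile,
    truth: TruthTable,
    threshold: float = 0.5,
) -> ConfusionWithUnknown:
    """Score one compound's prediction profile against the truth table.

    A prediction contributes to TP/FP/TN/FN only when the target has a
    truth record, a model produced a prediction for it, and the compound is
    inside that model's applicability domain; every other target of the
    universe counts as unknown.  The predicted label is active when
    ``p_active >= threshold`` (boundary inclusive, matching the
    active-inclusive IC50 cutoff convention).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    cid = profile.compound_id
    predicted = {}
    for e in profile.entries:
        if e.target_id not in set(truth.universe):
            raise ValueError(
                f"profile target {e.target_id!r} is outside the truth universe"
            )
        predicted[e.target_id] = e

    cm = ConfusionWithUnknown()
    tp = fp = tn = fn = unknown = covered = 0
    for tid in truth.universe:
        true_label = truth.labels.get((cid, tid))
        entry = predicted.get(tid)
        if true_label is None or entry is None:
            unknown += 1
            continue
        covered += 1
        if not entry.in_ad:
            unknown += 1
            continue
        pred_active = entry.p_active >= threshold
        if true_label == ACTIVE:
            tp, fn = (tp + 1, fn) if pred_active else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred_active else (fp, tn + 1)
    return ConfusionWithUnknown(tp, fp, tn, fn, unknown, covered)


def recovery_rate(cm: ConfusionWithUnknown) -> float:
    """Evaluable fraction of the model-covered, truth-annotated targets."""
    if cm.n_model_covered == 0:
        return UNDEFINED
    return cm.n_evaluable / cm.n_model_covered


def unknown_rate(cm: ConfusionWithUnknown, T: int | None = None) -> float:
    """Fraction of the candidate universe that cannot be validated."""
    T = cm.T if T is None else T
    if T <= 0:
        raise ValueError("universe size T must be positive")
    return (T - cm.n_evaluable) / T


@dataclass
class RateReport:
    """Derived rates; any zero-denominator entry is NaN (the undefined marker)."""

    tpr: float = UNDEFINED
    tnr: float = UNDEFINED
    fpr: float = UNDEFINED
    fnr: float = UNDEFINED
    precision: float = UNDEFINED
    recall: float = UNDEFINED
    f1: float = UNDEFINED

    def as_dict(self) -> dict:
        return {
            "tpr": self.tpr, "tnr": self.tnr, "fpr": self.fpr, "fnr": self.fnr,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def rates(cm: ConfusionWithUnknown) -> RateReport:
    """TPR/TNR/FPR/FNR, precision, recall and f1 from confusion counts."""
    tpr = _ratio(cm.tp, cm.tp + cm.fn)
    tnr = _ratio(cm.tn, cm.tn + cm.fp)
    fpr = _ratio(cm.fp, cm.fp + cm.tn)
    fnr = _ratio(cm.fn, cm.fn + cm.tp)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = tpr
    if is_defined(precision) and is_defined(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif is_defined(precision) and is_defined(recall):
        f1 = 0.0
    else:
        f1 = UNDEFINED
    return RateReport(tpr, tnr, fpr, fnr, precision, recall, f1)


@dataclass
class MetricSummary:
    mean: float
    sd: float
    n: int


def aggregate(reports: Sequence[RateReport]) -> dict[str, MetricSummary]:
    """Mean and SD per metric over reports, skipping undefined entries.

    A metric undefined in every report propagates the undefined marker with
    ``n == 0``.  The SD is the population SD (0 for a single contributing
    report).
    """
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    out: dict[str, MetricSummary] = {}
    for key in RateReport().as_dict():
        vals = np.array([r.as_dict()[key] for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[key] = MetricSummary(UNDEFINED, UNDEFINED, 0)
        else:
            out[key] = MetricSummary(float(vals.mean()), float(vals.std()), int(vals.size))
    return out


@dataclass
class CompoundEvaluation:
    """Full per-compound evaluation: counts, rates, and coverage measures."""

    compound_id: str
    confusion: ConfusionWithUnknown
    report: RateReport = field(default=None)  # type: ignore[assignment]
    recovery: float = UNDEFINED
    unknown: float = UNDEFINED

    def __post_init__(self):
        if self.report is None:
            self.report = rates(self.confusion)
            self.recovery = recovery_rate(self.confusion)
            self.unknown = unknown_rate(self.confusion)

    def as_row(self) -> dict:
        row = {"compound_id": self.compound_id,
               "tp": self.confusion.tp, "fp": self.confusion.fp,
               "tn": self.confusion.tn, "fn": self.confusion.fn,
               "unknown": self.confusion.unknown,
               "recovery_rate": self.recovery, "unknown_rate": self.unknown}
        row.update(self.report.as_dict())
        return row


def evaluate_profiles(
    profiles: Sequence[CompoundProfile],
    truth: TruthTable,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-compound evaluation table over a list of prediction profiles."""
    rows = [
        CompoundEvaluation(p.compound_id, tally(p, truth, threshold)).as_row()
        for p in profiles
    ]
    return pd.DataFrame(rows)
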