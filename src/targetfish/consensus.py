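"""Consensus ranking over heterogeneous model prediction profiles.

Individual models score (compound, target) pairs on different scales, so
raw scores are first normalized to [0, 1].  Because many models are
near-duplicates of each other, a diverse subset is selected by hierarchical
clustering of the model prediction profiles: profiles are compared with a
Pearson-derived similarity, clustered with average linkage, the tree is cut
at a similarity cutoff, and the best-f1 model represents each cluster.  The
consensus score of a pair is the mean of the selected models' probabilities
(missing entries excluded), thresholded at 0.5, and ranked target lists are
evaluated at increasing top fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .evaluation import (
    ConfusionWithUnknown,
    RateReport,
    TruthTable,
    rates,
    recovery_rate,
    unknown_rate,
)
from .curation import ACTIVE

DEFAULT_FRACTIONS = (0.01,) + tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
PRESET_CUTOFFS = (0.72, 0.75, 0.8)


def normalize_scores(raw_scores, mode: str = "minmax") -> np.ndarray:
    """Map raw scores or ranks onto [0, 1].

    ``minmax``: linear rescale; a constant list maps to all 0.5 (no
    information about relative order, so every item sits at the midpoint).
    ``rank``: best (lowest) rank maps to 1, worst to 0, linear in between;
    ties share the mean of their positions.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty score list")
    if mode == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.full_like(x, 0.5)
        return (x - lo) / (hi - lo)
    if mode == "rank":
        from scipy.stats import rankdata

        r = rankdata(x, method="average")  # 1 = lowest value = best rank input
        if x.size == 1:
            return np.ones(1)
        return 1.0 - (r - 1) / (x.size - 1)
    raise ValueError(f"unknown normalization mode {mode!r}")


class ModelProfileMatrix:
    """Prediction instances (rows) by models (columns); entries p_active or NaN."""

    def __init__(self, frame: pd.DataFrame):
        # frame: index = (compound_id, target_id) MultiIndex, columns = model ids
        self.frame = frame

    @classmethod
    def from_entries(cls, entries: pd.DataFrame) -> "ModelProfileMatrix":
        """Pivot a long table (compound_id, target_id, model_id, p_active)."""
        wide = entries.pivot_table(
            index=["compound_id", "target_id"],
            columns="model_id",
            values="p_active",
            aggfunc="mean",
        )
        return cls(wide)

    @property
    def model_ids(self) -> list[str]:
        return list(self.frame.columns)


def profile_similarity(profiles: ModelProfileMatrix) -> pd.DataFrame:
    """Model-by-model similarity: Pearson r on common rows, mapped to [0, 1].

    For each model pair, the correlation of p_active over rows where both
    predict is computed and rescaled as ``(r + 1) / 2``; the diagonal is 1.
    A pair sharing fewer than two rows has no defined correlation and is an
    error.
    """
    F = profiles.frame
    models = list(F.columns)
    if len(models) < 2:
        raise ValueError("similarity needs at least two models")
    n = len(models)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = F.iloc[:, i], F.iloc[:, j]
            mask = a.notna() & b.notna()
            if mask.sum() < 2:
                raise ValueError(
                    f"models {models[i]!r} and {models[j]!r} share fewer than "
                    "two common predictions"
                )
            x, y = a[mask].to_numpy(), b[mask].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r = 1.0 if np.allclose(x, y) else 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            S[i, j] = S[j, i] = np.clip((r + 1.0) / 2.0, 0.0, 1.0)
    return pd.DataFrame(S, index=models, columns=models)


def select_representatives(
    similarity: pd.DataFrame,
    f1_per_model: dict[str, float],
    cutoff: float = 0.75,
) -> list[str]:
    """Cluster models by profile similarity and keep the best-f1 one per cluster.

    Average-linkage hierarchical clustering runs on distance ``1 - similarity``
    and the dendrogram is cut so that two models end up in the same cluster
    only when they merged at similarity strictly above ``cutoff``.  Within a
    cluster the model with the highest f1 wins; ties go to the
    lexicographically smallest model id.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    models = list(similarity.columns)
    missing = [m for m in models if m not in f1_per_model]
    if missing:
        raise ValueError(f"f1 missing for models: {missing}")
    if len(models) == 1:
        return list(models)
    D = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    # merges at distance < 1 - cutoff (i.e. similarity > cutoff) stay together
    labels = fcluster(Z, t=(1.0 - cutoff) - 1e-12, criterion="distance")
    reps = []
    for c in np.unique(labels):
        members = [m for m, lab in zip(models, labels) if lab == c]
        reps.append(sorted(members, key=lambda m: (-f1_per_model[m], m))[0])
    return sorted(reps)


@dataclass
class ConsensusEntry:
    """Fused score for one (compound, target) pair."""

    compound_id: str
    target_id: str
    consensus_score: float
    n_models_contributing: int

    @property
    def predicted_label(self) -> str:
        return ACTIVE if self.consensus_score >= 0.5 else "inactive"


def consensus_score(
    profiles: ModelProfileMatrix,
    selected_models: list[str] | None = None,
) -> list[ConsensusEntry]:
    """Mean of the selected models' probabilities per (compound, target) pair.

    Missing entries (e.g. a compound outside one model's applicability
    domain) are excluded from the mean rather than imputed; a pair with no
    contributing model at all is omitted.
    """
    F = profiles.frame
    if selected_models is not None:
        unknown = set(selected_models) - set(F.columns)
        if unknown:
            raise ValueError(f"selected models not in profile matrix: {sorted(unknown)}")
        F = F[list(selected_models)]
    entries = []
    means = F.mean(axis=1, skipna=True)
    counts = F.notna().sum(axis=1)
    for (cid, tid), m, k in zip(F.index, means, counts):
        if k == 0:
            continue
        entries.append(ConsensusEntry(str(cid), str(tid), float(m), int(k)))
    return entries


def rank_entries(entries: list[ConsensusEntry]) -> list[ConsensusEntry]:
    """Sort by consensus score descending, ties broken by target id ascending."""
    return sorted(entries, key=lambda e: (-e.consensus_score, e.target_id, e.compound_id))


@dataclass
class FractionRow:
    fraction: float
    n_evaluated: int
    confusion: ConfusionWithUnknown
    report: RateReport
    recovery: float
    unknown: float


@dataclass
class FractionSweep:
    rows: list[FractionRow]

    def to_frame(self) -> pd.DataFrame:
        out = []
        for r in self.rows:
            row = {"fraction": r.fraction, "n_evaluated": r.n_evaluated,
                   "recovery_rate": r.recovery, "unknown_rate": r.unknown}
            row.update(r.report.as_dict())
            out.append(row)
        return pd.DataFrame(out)


def _tally_entries(
    entries: list[ConsensusEntry],
    truth: TruthTable,
    universe_size: int,
    threshold: float = 0.5,
) -> ConfusionWithUnknown:
    tp = fp = tn = fn = covered = 0
    for e in entries:
        label = truth.labels.get((e.compound_id, e.target_id))
        if label is None:
            continue
        covered += 1
        pred_active = e.consensus_score >= threshold
        if label == ACTIVE:
            tp, fn = (tp + 1, fn) if pred_active else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred_active else (fp, tn + 1)
    unknown = universe_size - (tp + fp + tn + fn)
    return ConfusionWithUnknown(tp, fp, tn, fn, unknown, covered)


def fraction_sweep(
    entries: list[ConsensusEntry],
    truth: TruthTable,
    fractions=DEFAULT_FRACTIONS,
    threshold: float = 0.5,
) -> FractionSweep:
    """Evaluate the ranked consensus list truncated at each top fraction.

    At fraction f the top ``ceil(f * N)`` entries of the ranking are scored;
    the universe for the unknown rate is the full entry list, so shallower
    cuts leave more of the universe unvalidated.  The 100% row coincides
    with evaluating the entire ranking.
    """
    if not entries:
        raise ValueError("cannot sweep an empty entry list")
    fracs = sorted(set(float(f) for f in fractions))
    if any(not 0 < f <= 1 for f in fracs):
        raise ValueError("fractions must lie in (0, 1]")
    ranked = rank_entries(entries)
    N = len(ranked)
    rows = []
    for f in fracs:
        depth = math.ceil(f * N)
        cm = _tally_entries(ranked[:depth], truth, universe_size=N, threshold=threshold)
        rows.append(
            FractionRow(
                fraction=f,
                n_evaluated=depth,
                confusion=cm,
                report=rates(cm),
                recovery=recovery_rate(cm),
                unknown=unknown_rate(cm, T=N),
            )
        )
    return FractionSweep(rows)


def entries_to_frame(entries: list[ConsensusEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": e.compound_id,
                "target_id": e.target_id,
                "consensus_score": e.consensus_score,
                "n_models": e.n_models_contributing,
                "label": e.predicted_label,
            }
            for e in entries
        ]
    )
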