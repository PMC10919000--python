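"""Bioactivity curation: from raw assay rows to labeled compound-target pairs.

The curation pipeline applies four rules to raw interaction tables:

1. keep only IC50 endpoints;
2. convert every potency value to micromolar;
3. aggregate replicate measurements of the same (compound, target) pair
   with a MAD-based outlier rejection followed by the median;
4. label a pair *active* when its aggregated IC50 is at or below the
   activity cutoff (10 uM by default), *inactive* otherwise.

Targets are then gated by a minimum number of interactions per class so
that every retained target can support a classifier, and external
validation sets are formed as release differences (pairs present in a
newer data release but absent from the reference releases).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"

#: Conversion factors from declared units to micromolar.
UNIT_TO_UM: dict[str, float] = {
    "pM": 1e-6,
    "nM": 1e-3,
    "uM": 1.0,
    "µM": 1.0,
    "umol/L": 1.0,
    "mM": 1e3,
    "M": 1e6,
}


class UnknownUnitError(ValueError):
    """Raised when an assay row carries a unit missing from the conversion table."""


@dataclass(frozen=True)
class InteractionRecord:
    """One raw assay measurement of a compound against a target."""

    compound_id: str
    smiles: str
    target_id: str
    endpoint: str
    value: float
    unit: str
    assay_id: str = ""


@dataclass(frozen=True)
class CuratedInteraction:
    """A deduplicated, labeled compound-target pair after replicate aggregation."""

    compound_id: str
    target_id: str
    ic50_um: float
    label: str
    n_replicates: int
    smiles: str = ""


@dataclass
class CurationConfig:
    """Thresholds controlling curation.

    activity_cutoff_um
        IC50 at or below this value (in micromolar) labels a pair active.
    mad_zscore_cutoff
        Replicates whose modified z-score exceeds this magnitude are
        discarded before the final median is taken.
    min_active_train / min_inactive_train
        Per-class minimum interaction counts for a target to be modelled.
    min_per_class_external
        Looser per-class minimum used when gating external validation sets.
    """

    activity_cutoff_um: float = 10.0
    mad_zscore_cutoff: float = 3.5
    min_active_train: int = 10
    min_inactive_train: int = 10
    min_per_class_external: int = 5
    unit_table: Mapping[str, float] = field(default_factory=lambda: dict(UNIT_TO_UM))

    def __post_init__(self) -> None:
        for name in ("activity_cutoff_um", "mad_zscore_cutoff",
                     "min_active_train", "min_inactive_train",
                     "min_per_class_external"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def filter_and_convert(
    records: Sequence[InteractionRecord],
    config: CurationConfig | None = None,
) -> list[InteractionRecord]:
    """Keep IC50 rows only and express all values in micromolar.

    Rows with an endpoint other than ``IC50`` are dropped silently (they are
    out of scope, not erroneous); rows with a non-positive value are dropped
    with a warning; rows with a unit absent from the conversion table raise
    :class:`UnknownUnitError` naming the unit and the row. Order is preserved.
    """
    config = config or CurationConfig()
    out: list[InteractionRecord] = []
    for i, rec in enumerate(records):
        if rec.endpoint != "IC50":
            continue
        if rec.unit not in config.unit_table:
            raise UnknownUnitError(
                f"row {i} (compound {rec.compound_id!r}, target {rec.target_id!r}): "
                f"unknown unit {rec.unit!r}"
            )
        if not np.isfinite(rec.value) or rec.value <= 0:
            warnings.warn(
                f"dropping row {i} (compound {rec.compound_id!r}): "
                f"non-positive value {rec.value!r}",
                stacklevel=2,
            )
            continue
        out.append(
            InteractionRecord(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                target_id=rec.target_id,
                endpoint="IC50",
                value=rec.value * config.unit_table[rec.unit],
                unit="uM",
                assay_id=rec.assay_id,
            )
        )
    return out


def aggregate_replicates(
    values: Sequence[float],
    config: CurationConfig | None = None,
) -> float:
    """Aggregate replicate IC50 measurements (in uM) into one value.

    Outliers are flagged by the modified z-score
    ``0.6745 * (x - median) / MAD`` and removed when its magnitude exceeds
    ``config.mad_zscore_cutoff``; the median of the survivors is returned.
    When the MAD is zero (at least half the replicates identical) nothing is
    flagged and the plain median is returned.
    """
    config = config or CurationConfig()
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    if x.size == 1:
        return float(x[0])
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    z = 0.6745 * (x - med) / mad
    keep = np.abs(z) <= config.mad_zscore_cutoff
    return float(np.median(x[keep]))


def label_activity(ic50_um: float, config: CurationConfig | None = None) -> str:
    """Label an aggregated IC50: active iff at or below the cutoff (inclusive)."""
    config = config or CurationConfig()
    if not np.isfinite(ic50_um) or ic50_um <= 0:
        raise ValueError(f"IC50 must be positive and finite, got {ic50_um!r}")
    return ACTIVE if ic50_um <= config.activity_cutoff_um else INACTIVE


def curate(
    records: Sequence[InteractionRecord],
    config: CurationConfig | None = None,
) -> list[CuratedInteraction]:
    """Run the full curation chain on raw records.

    Filters and unit-converts, groups rows by (compound, target), aggregates
    replicates and labels each pair.  The output is deduplicated on
    (compound_id, target_id).
    """
    config = config or CurationConfig()
    filtered = filter_and_convert(records, config)
    groups: dict[tuple[str, str], list[InteractionRecord]] = {}
    for rec in filtered:
        groups.setdefault((rec.compound_id, rec.target_id), []).append(rec)
    curated: list[CuratedInteraction] = []
    for (cid, tid), recs in groups.items():
        ic50 = aggregate_replicates([r.value for r in recs], config)
        curated.append(
            CuratedInteraction(
                compound_id=cid,
                target_id=tid,
                ic50_um=ic50,
                label=label_activity(ic50, config),
                n_replicates=len(recs),
                smiles=recs[0].smiles,
            )
        )
    return curated


def gate_targets(
    curated: Sequence[CuratedInteraction],
    min_active: int = 10,
    min_inactive: int = 10,
) -> tuple[dict[str, list[CuratedInteraction]], dict[str, str]]:
    """Keep targets with at least ``min_active`` actives and ``min_inactive`` inactives.

    Returns ``(retained, dropped)`` where ``retained`` maps target_id to its
    interactions and ``dropped`` maps each rejected target_id to a human
    readable reason.  Raises if the input contains duplicate
    (compound, target) pairs — aggregation must happen first.
    """
    seen: set[tuple[str, str]] = set()
    by_target: dict[str, list[CuratedInteraction]] = {}
    for ci in curated:
        key = (ci.compound_id, ci.target_id)
        if key in seen:
            raise ValueError(f"duplicate (compound, target) pair {key}; aggregate first")
        seen.add(key)
        by_target.setdefault(ci.target_id, []).append(ci)

    retained: dict[str, list[CuratedInteraction]] = {}
    dropped: dict[str, str] = {}
    for tid, items in by_target.items():
        n_act = sum(1 for i in items if i.label == ACTIVE)
        n_inact = len(items) - n_act
        if n_act >= min_active and n_inact >= min_inactive:
            retained[tid] = items
        else:
            dropped[tid] = (
                f"{n_act} active (need {min_active}), "
                f"{n_inact} inactive (need {min_inactive})"
            )
    return retained, dropped


def release_difference(
    reference_pairs: Iterable[tuple[str, str]],
    new_pairs: Iterable[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Pairs present in the new release but absent from the reference releases."""
    return set(new_pairs) - set(reference_pairs)


# ---------------------------------------------------------------------------
# Tabular I/O

DEFAULT_COLUMNS = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "endpoint": "endpoint",
    "value": "value",
    "unit": "unit",
    "assay_id": "assay_id",
}


def read_interactions(
    path, column_map: Mapping[str, str] | None = None, sep: str = ","
) -> list[InteractionRecord]:
    """Read raw assay rows from a CSV/TSV file with a configurable column mapping."""
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype={cmap["compound_id"]: str, cmap["target_id"]: str})
    missing = [v for v in cmap.values() if v not in df.columns and v != cmap["assay_id"]]
    if missing:
        raise ValueError(f"input table missing columns: {missing}")
    has_assay = cmap["assay_id"] in df.columns
    return [
        InteractionRecord(
            compound_id=str(row[cmap["compound_id"]]),
            smiles=str(row[cmap["smiles"]]),
            target_id=str(row[cmap["target_id"]]),
            endpoint=str(row[cmap["endpoint"]]),
            value=float(row[cmap["value"]]),
            unit=str(row[cmap["unit"]]),
            assay_id=str(row[cmap["assay_id"]]) if has_assay else "",
        )
        for _, row in df.iterrows()
    ]


def curated_to_frame(curated: Sequence[CuratedInteraction]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in curated])


def frame_to_curated(df: pd.DataFrame) -> list[CuratedInteraction]:
    return [
        CuratedInteraction(
            compound_id=str(r.compound_id),
            target_id=str(r.target_id),
            ic50_um=float(r.ic50_um),
            label=str(r.label),
            n_replicates=int(r.n_replicates),
            smiles=str(getattr(r, "smiles", "")),
        )
        for r in df.itertuples(index=False)
    ]


def write_curation_outputs(
    curated: Sequence[CuratedInteraction],
    out_csv,
    audit_json=None,
    audit: Mapping[str, int] | None = None,
) -> None:
    """Write the curated interaction table and, optionally, a JSON audit of counts."""
    curated_to_frame(curated).to_csv(out_csv, index=False)
    if audit_json is not None:
        with open(audit_json, "w") as fh:
            json.dump(dict(audit or {}), fh, indent=2)
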