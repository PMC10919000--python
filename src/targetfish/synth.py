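"""Synthetic bioactivity panels for exercising the whole pipeline offline.

The generator emulates a curated-database-style interaction table: each
simulated protein target has an *active* compound family built on one
scaffold (aromatic cores) and an *inactive* family on a chemically distant
scaffold (aliphatic cores), so actives and inactives are separated both in
descriptor space and in potency.  Replicate IC50 measurements are drawn
lognormally around a family median (1 uM for actives, 50 uM for inactives
by default — straddling the 10 uM activity cutoff), occasionally corrupted
by a 100-fold outlier, reported in mixed units, and mixed with a few
off-endpoint (Ki) rows, so the curation rules all have work to do.

Everything is reproducible from a single seed, fanned out to per-stage
seeds through a fixed derivation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import ACTIVE, INACTIVE, InteractionRecord

# Aromatic cores host active families, aliphatic cores inactive families;
# one (active, inactive) core pair per simulated target.
ACTIVE_CORES = (
    "c1ccccc1", "c1ccc2ccccc2c1", "c1ccncc1", "c1cncnc1", "c1ccoc1",
    "c1ccsc1", "c1cc[nH]c1", "c1cnc[nH]1", "c1ccc2ncccc2c1", "c1ccc2[nH]ccc2c1",
)
INACTIVE_CORES = (
    "C1CCCCC1", "C1CCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCC(=O)CC1",
    "C1CCCCCC1", "C1COCCN1", "C1CCC1", "C1CCC2CCCCC2C1", "C1CCOC1",
)
_HEADS = ("", "O", "N", "OC(=O)", "NC(=O)", "FC(F)(F)", "CC(C)", "OC(C)", "CN(C)")
_MAX_CHAIN = 12


def derive_seed(seed: int, *tags) -> int:
    """Deterministic sub-seed below 2**31 derived from a base seed and tags."""
    h = zlib.crc32("/".join(str(t) for t in tags).encode())
    return int(np.random.SeedSequence([seed, h]).generate_state(1)[0] % (2**31))


def enumerate_family(core: str, n_members: int) -> list[str]:
    """Enumerate ``n_members`` distinct canonical SMILES on one scaffold core.

    Substituents are linear/branched C/N/O/F fragments prepended to the
    core; enumeration order is deterministic.
    """
    seen: set[str] = set()
    family: list[str] = []
    for head, n in product(_HEADS, range(_MAX_CHAIN)):
        smi = head + "C" * n + core
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - all cores/heads verified to parse
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
            family.append(canon)
        if len(family) == n_members:
            return family
    raise ValueError(
        f"scaffold family on core {core!r} too small: "
        f"{len(family)} members available, {n_members} requested"
    )


@dataclass
class PanelSpec:
    """Parameters of a synthetic interaction panel.

    The default shape — 5 targets, 30 actives and 90 inactives each — gives
    every target a 3:1 class imbalance for the balancing stage to fix while
    still passing the 10+10 training gate after curation.
    """

    n_targets: int = 5
    actives_per_target: int = 30
    inactives_per_target: int = 90
    replicate_count_range: tuple[int, int] = (3, 5)
    outlier_probability: float = 0.05
    active_median_um: float = 1.0
    inactive_median_um: float = 50.0
    noise_sd: float = 0.3
    activity_cutoff_um: float = 10.0
    n_offendpoint_rows: int = 2
    cap_outliers: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (self.active_median_um < self.activity_cutoff_um < self.inactive_median_um):
            raise ValueError("family medians must straddle the activity cutoff")
        if not 0 <= self.outlier_probability <= 1:
            raise ValueError("outlier_probability must lie in [0, 1]")
        if self.n_targets > len(ACTIVE_CORES):
            raise ValueError(f"at most {len(ACTIVE_CORES)} targets supported")


@dataclass
class PanelData:
    """A generated panel: raw assay rows plus the ground truth behind them."""

    records: list[InteractionRecord]
    compounds: pd.DataFrame  # compound_id, smiles, origin_target, true_label (vs origin)
    truth: pd.DataFrame  # complete (compound_id, target_id, label) cross table
    spec: PanelSpec = field(repr=False, default=None)  # type: ignore[assignment]

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound_id": r.compound_id, "smiles": r.smiles,
                    "target_id": r.target_id, "endpoint": r.endpoint,
                    "value": r.value, "unit": r.unit, "assay_id": r.assay_id,
                }
                for r in self.records
            ]
        )


def generate_panel(spec: PanelSpec | None = None) -> PanelData:
    """Generate a raw interaction table with known ground truth.

    Per target, actives come from the target's aromatic scaffold family
    with replicate IC50s lognormal around ``active_median_um``; inactives
    from the aliphatic family around ``inactive_median_um``.  A replicate
    is multiplied by 100 with probability ``outlier_probability``.  Units
    alternate between nM and uM.  Cross-target truth labels every compound
    inactive against every target other than its own (scaffolds are target
    specific), and actives active only against their origin target.
    """
    spec = spec or PanelSpec()
    rng = np.random.default_rng(derive_seed(spec.seed, "panel"))
    records: list[InteractionRecord] = []
    compound_rows = []
    target_ids = [f"T{i + 1:03d}" for i in range(spec.n_targets)]

    all_smiles: set[str] = set()
    assay_counter = 0
    for t_idx, tid in enumerate(target_ids):
        fam_active = enumerate_family(ACTIVE_CORES[t_idx], spec.actives_per_target)
        fam_inactive = enumerate_family(INACTIVE_CORES[t_idx], spec.inactives_per_target)
        overlap = (set(fam_active) | set(fam_inactive)) & all_smiles
        if overlap or set(fam_active) & set(fam_inactive):
            raise ValueError("scaffold families are not disjoint")
        all_smiles |= set(fam_active) | set(fam_inactive)

        for family, median, label in (
            (fam_active, spec.active_median_um, ACTIVE),
            (fam_inactive, spec.inactive_median_um, INACTIVE),
        ):
            for j, smi in enumerate(family):
                cid = f"{tid}_{label[:3].upper()}{j + 1:03d}"
                compound_rows.append(
                    {"compound_id": cid, "smiles": smi,
                     "origin_target": tid, "true_label": label}
                )
                n_rep = int(rng.integers(spec.replicate_count_range[0],
                                         spec.replicate_count_range[1] + 1))
                # outliers stay a minority of each pair's replicates when
                # capped, so the aggregated median remains label-faithful
                max_outliers = (n_rep - 1) // 2 if spec.cap_outliers else n_rep
                n_outliers = 0
                for _ in range(n_rep):
                    value_um = median * float(np.exp(rng.normal(0.0, spec.noise_sd)))
                    if rng.random() < spec.outlier_probability and n_outliers < max_outliers:
                        value_um *= 100.0
                        n_outliers += 1
                    if rng.random() < 0.5:
                        value, unit = value_um * 1e3, "nM"
                    else:
                        value, unit = value_um, "uM"
                    assay_counter += 1
                    records.append(
                        InteractionRecord(
                            compound_id=cid, smiles=smi, target_id=tid,
                            endpoint="IC50", value=value, unit=unit,
                            assay_id=f"A{assay_counter:06d}",
                        )
                    )
        # off-endpoint rows that curation rule 1 must discard
        for k in range(spec.n_offendpoint_rows):
            assay_counter += 1
            records.append(
                InteractionRecord(
                    compound_id=f"{tid}_ACT001", smiles=fam_active[0], target_id=tid,
                    endpoint="Ki", value=float(rng.uniform(1, 100)), unit="nM",
                    assay_id=f"A{assay_counter:06d}",
                )
            )

    compounds = pd.DataFrame(compound_rows)
    truth_rows = []
    for row in compound_rows:
        for tid in target_ids:
            if tid == row["origin_target"]:
                label = row["true_label"]
            else:
                label = INACTIVE
            truth_rows.append(
                {"compound_id": row["compound_id"], "target_id": tid, "label": label}
            )
    truth = pd.DataFrame(truth_rows)
    return PanelData(records=records, compounds=compounds, truth=truth, spec=spec)
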