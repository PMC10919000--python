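"""End-to-end orchestration: curate -> featurize -> train -> predict -> evaluate -> consensus.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
chains them and writes every intermediate table (CSV with JSON sidecars)
into an artifacts directory, so any stage can also be re-run from files via
the command-line interface.  A single global seed is fanned out to
per-stage, per-target seeds through a fixed derivation, making every stage
independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cons
from . import curation, evaluation, featurization, modeling
from .synth import PanelSpec, derive_seed, generate_panel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "artifacts"
    input_table: str | None = None  # raw interaction CSV; None -> synthesize
    panel: PanelSpec = field(default_factory=PanelSpec)
    kinds: tuple[str, ...] = featurization.KINDS
    algorithms: tuple[str, ...] = modeling.ALGORITHMS
    test_fraction: float = 0.30
    ad_k: float = 3.0
    select_cutoff: float = 0.75
    threshold: float = 0.5
    fractions: tuple[float, ...] = cons.DEFAULT_FRACTIONS
    curation: curation.CurationConfig = field(default_factory=curation.CurationConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "panel":
                cfg.panel = PanelSpec(**val)
            elif key == "curation":
                cfg.curation = curation.CurationConfig(**val)
            elif hasattr(cfg, key):
                setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Stage functions


def featurize_compounds(
    smiles_by_id: dict[str, str], kinds
) -> dict[str, pd.DataFrame]:
    """Feature matrix per descriptor kind, indexed by compound id."""
    ids = list(smiles_by_id)
    smiles = [smiles_by_id[i] for i in ids]
    out = {}
    for kind in kinds:
        X = featurization.featurize_smiles(smiles, kind)
        out[kind] = pd.DataFrame(X, index=ids)
    return out


def train_panel(
    curated: list[curation.CuratedInteraction],
    features: dict[str, pd.DataFrame],
    config: PipelineConfig,
):
    """Train one model per (target, kind, algorithm); returns models and test sets.

    The train/holdout split is drawn once per target (the same compounds
    across descriptor spaces), while majority-class balancing reruns
    independently per (target, kind) because the clustering lives in each
    descriptor space.
    """
    gated, dropped = curation.gate_targets(
        curated, config.curation.min_active_train, config.curation.min_inactive_train
    )
    if dropped:
        logger.info("targets dropped at the training gate: %s", dropped)
    models: list[modeling.TrainedTCM] = []
    test_sets: dict[tuple[str, str], modeling.TargetDataset] = {}
    for tid in sorted(gated):
        items = sorted(gated[tid], key=lambda c: c.compound_id)
        cids = [c.compound_id for c in items]
        y = np.array([c.label for c in items])
        split_seed = derive_seed(config.seed, "split", tid)
        for kind in config.kinds:
            X = features[kind].loc[cids].to_numpy(dtype=float)
            ds = modeling.TargetDataset(tid, X, y, cids, kind)
            train, test = modeling.make_split(ds, config.test_fraction, split_seed)
            test_sets[(tid, kind)] = test
            bal_seed = derive_seed(config.seed, "balance", tid, kind)
            for algo in config.algorithms:
                models.append(
                    modeling.train_tcm(
                        train, algo, seed=bal_seed, test=test, ad_k=config.ad_k
                    )
                )
    return models, test_sets, dropped


def predict_panel(
    models: list[modeling.TrainedTCM],
    features: dict[str, pd.DataFrame],
    compound_ids,
) -> pd.DataFrame:
    """Long prediction table (compound, target, model type, p_active, in_ad).

    Batched per model: each fitted classifier scores every query compound in
    one call, which is equivalent to per-compound profiles but much faster.
    """
    compound_ids = list(compound_ids)
    frames = []
    for tcm in models:
        X = features[tcm.kind].loc[compound_ids].to_numpy(dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "compound_id": compound_ids,
                    "target_id": tcm.target_id,
                    "model_id": f"{tcm.kind}_{tcm.algorithm}",
                    "kind": tcm.kind,
                    "algorithm": tcm.algorithm,
                    "p_active": tcm.model.predict_proba_active(X),
                    "in_ad": tcm.model.in_ad(X),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def evaluate_model_types(
    predictions: pd.DataFrame,
    truth: evaluation.TruthTable,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-(model type, compound) evaluation, averaged over compounds per type."""
    from .modeling import CompoundProfile, PredictionEntry

    summaries = []
    for model_id, sub in predictions.groupby("model_id"):
        reports = []
        rec, unk = [], []
        for cid, rows in sub.groupby("compound_id"):
            entries = [
                PredictionEntry(
                    target_id=r.target_id, model_id=model_id, kind=r.kind,
                    algorithm=r.algorithm, p_active=r.p_active, in_ad=r.in_ad,
                )
                for r in rows.itertuples(index=False)
            ]
            cm = evaluation.tally(CompoundProfile(cid, entries), truth, threshold)
            reports.append(evaluation.rates(cm))
            r = evaluation.recovery_rate(cm)
            if evaluation.is_defined(r):
                rec.append(r)
            unk.append(evaluation.unknown_rate(cm))
        agg = evaluation.aggregate(reports)
        row = {"model_id": model_id}
        for key, s in agg.items():
            row[key] = s.mean
            row[f"{key}_sd"] = s.sd
        row["recovery_rate"] = float(np.mean(rec)) if rec else evaluation.UNDEFINED
        row["unknown_rate"] = float(np.mean(unk))
        summaries.append(row)
    return pd.DataFrame(summaries)


def consensus_stage(
    predictions: pd.DataFrame,
    models: list[modeling.TrainedTCM],
    truth: evaluation.TruthTable,
    config: PipelineConfig,
):
    """Select representative model types, fuse their probabilities, sweep fractions."""
    masked = predictions.copy()
    masked.loc[~masked["in_ad"], "p_active"] = np.nan
    matrix = cons.ModelProfileMatrix.from_entries(masked)

    f1_by_type: dict[str, list[float]] = {}
    for tcm in models:
        f1 = tcm.holdout_metrics.get("f1")
        if f1 is not None:
            f1_by_type.setdefault(f"{tcm.kind}_{tcm.algorithm}", []).append(f1)
    f1_per_model = {m: float(np.mean(v)) for m, v in f1_by_type.items()}

    sim = cons.profile_similarity(matrix)
    selected = cons.select_representatives(sim, f1_per_model, config.select_cutoff)
    entries = cons.consensus_score(matrix, selected)
    sweep = cons.fraction_sweep(entries, truth, config.fractions, config.threshold)
    return sim, selected, entries, sweep


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all artifacts; returns the artifacts directory.

    Raises :class:`StageError` naming the failing stage on any error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2fs", name, timings[name])
        return result

    # -- input
    if config.input_table is not None:
        if not Path(config.input_table).exists():
            raise StageError("input", FileNotFoundError(config.input_table))
        records = _stage("load", lambda: curation.read_interactions(config.input_table))
        truth = None
    else:
        panel = _stage("simulate", lambda: generate_panel(
            PanelSpec(**{**panel_kwargs(config.panel), "seed": derive_seed(config.seed, "panel-spec")})
        ))
        panel.records_frame().to_csv(out / "raw_interactions.csv", index=False)
        panel.truth.to_csv(out / "ground_truth.csv", index=False)
        records = panel.records
        truth = evaluation.TruthTable.from_frame(panel.truth)

    # -- curate
    curated = _stage("curate", lambda: curation.curate(records, config.curation))
    audit = {
        "n_raw": len(records),
        "n_curated_pairs": len(curated),
        "n_active": sum(1 for c in curated if c.label == curation.ACTIVE),
        "n_inactive": sum(1 for c in curated if c.label == curation.INACTIVE),
    }
    curation.write_curation_outputs(curated, out / "curated.csv", out / "curation_audit.json", audit)

    # -- featurize
    smiles_by_id = {c.compound_id: c.smiles for c in curated}
    features = _stage("featurize", lambda: featurize_compounds(smiles_by_id, config.kinds))
    for kind, df in features.items():
        featurization.write_features(
            df.to_numpy(), df.index, kind,
            out / f"features_{kind}.csv", out / f"features_{kind}.json",
        )

    # -- train
    models, test_sets, dropped = _stage(
        "train", lambda: train_panel(curated, features, config)
    )
    modeling.save_models(models, out / "models")

    # -- predict on the union of holdout compounds
    test_cids = sorted({cid for ds in test_sets.values() for cid in ds.compound_ids})
    predictions = _stage(
        "predict", lambda: predict_panel(models, features, test_cids)
    )
    predictions.to_csv(out / "predictions.csv", index=False)

    # -- evaluate + consensus need ground truth
    if truth is not None:
        per_model = _stage(
            "evaluate", lambda: evaluate_model_types(predictions, truth, config.threshold)
        )
        per_model.to_csv(out / "evaluation_per_model.csv", index=False)

        sim, selected, entries, sweep = _stage(
            "consensus", lambda: consensus_stage(predictions, models, truth, config)
        )
        sim.to_csv(out / "model_similarity.csv")
        cons.entries_to_frame(entries).to_csv(out / "consensus.csv", index=False)
        sweep.to_frame().to_csv(out / "fraction_sweep.csv", index=False)
        with open(out / "consensus_manifest.json", "w") as fh:
            json.dump({"selected_models": selected,
                       "select_cutoff": config.select_cutoff}, fh, indent=2)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "kinds": list(config.kinds),
                "algorithms": list(config.algorithms),
                "n_models": len(models),
                "n_targets": len({m.target_id for m in models}),
                "dropped_targets": dropped,
                "timings_s": timings,
            },
            fh, indent=2,
        )
    return out


def panel_kwargs(spec: PanelSpec) -> dict:
    from dataclasses import asdict

    return asdict(spec)
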