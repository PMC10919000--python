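"""Consensus layer: score normalization, model clustering, fusion, fraction sweep."""

import math

import numpy as np
import pandas as pd
import pytest

from targetfish.curation import ACTIVE, INACTIVE
from targetfish.consensus import (
    ConsensusEntry,
    ModelProfileMatrix,
    consensus_score,
    entries_to_frame,
    fraction_sweep,
    normalize_scores,
    profile_similarity,
    rank_entries,
    select_representatives,
)
from targetfish.evaluation import TruthTable


def _matrix(data: dict, rows=None):
    rows = rows or [("c1", f"t{i}") for i in range(len(next(iter(data.values()))))]
    idx = pd.MultiIndex.from_tuples(rows, names=["compound_id", "target_id"])
    return ModelProfileMatrix(pd.DataFrame(data, index=idx, dtype=float))


class TestNormalizeScores:
    def test_minmax(self):
        np.testing.assert_allclose(
            normalize_scores([0.1, 0.55, 1.0], "minmax"), [0.0, 0.5, 1.0]
        )

    def test_constant_maps_to_half(self):
        np.testing.assert_allclose(normalize_scores([3, 3, 3], "minmax"), [0.5] * 3)

    def test_rank_linear(self):
        np.testing.assert_allclose(
            normalize_scores([1, 2, 3, 4], "rank"), [1.0, 2 / 3, 1 / 3, 0.0]
        )

    def test_rank_ties_share_mean_position(self):
        out = normalize_scores([1, 2, 2, 4], "rank")
        assert out[1] == out[2] == pytest.approx(1 - (2.5 - 1) / 3)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            normalize_scores([1, 2], "softmax")

    def test_empty(self):
        with pytest.raises(ValueError):
            normalize_scores([], "minmax")


class TestProfileSimilarity:
    def test_self_similarity_one(self):
        m = _matrix({"a": [0.1, 0.5, 0.9], "b": [0.3, 0.2, 0.8]})
        S = profile_similarity(m)
        assert S.loc["a", "a"] == 1.0 and S.loc["b", "b"] == 1.0

    def test_complement_maps_to_zero(self):
        p = np.array([0.1, 0.4, 0.9, 0.7])
        m = _matrix({"a": p, "anti": 1 - p})
        S = profile_similarity(m)
        assert S.loc["a", "anti"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_profiles_near_half(self):
        rng = np.random.default_rng(7)
        m = _matrix({"a": rng.random(1000), "b": rng.random(1000)})
        S = profile_similarity(m)
        assert S.loc["a", "b"] == pytest.approx(0.5, abs=0.05)

    def test_too_few_common_rows_raises(self):
        a = [0.1, np.nan, np.nan]
        b = [np.nan, 0.5, 0.9]
        m = _matrix({"a": a, "b": b})
        with pytest.raises(ValueError, match="common"):
            profile_similarity(m)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            profile_similarity(_matrix({"a": [0.1, 0.2]}))


class TestSelectRepresentatives:
    def test_identical_profiles_single_representative(self):
        p = [0.2, 0.8, 0.5, 0.1]
        m = _matrix({"a": p, "b": p, "c": p})
        S = profile_similarity(m)
        reps = select_representatives(S, {"a": 0.7, "b": 0.9, "c": 0.8}, cutoff=0.75)
        assert reps == ["b"]  # highest f1 of the single cluster

    def test_cutoff_one_returns_all_models(self):
        rng = np.random.default_rng(1)
        m = _matrix({"a": rng.random(50), "b": rng.random(50), "c": rng.random(50)})
        S = profile_similarity(m)
        reps = select_representatives(S, {"a": 0.5, "b": 0.5, "c": 0.5}, cutoff=1.0)
        assert reps == ["a", "b", "c"]

    def test_hand_traced_three_model_case(self):
        # two near-duplicates (sim 0.99) and one dissimilar model (sim 0.1):
        # at cutoff 0.8 average linkage keeps the pair together and the
        # loner apart -> 2 representatives, the pair sending its better f1
        S = pd.DataFrame(
            [[1.0, 0.99, 0.1], [0.99, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        reps = select_representatives(S, {"a": 0.6, "b": 0.9, "c": 0.5}, cutoff=0.8)
        assert reps == ["b", "c"]

    def test_f1_tie_breaks_lexicographically(self):
        p = [0.2, 0.8, 0.5]
        S = profile_similarity(_matrix({"b": p, "a": p}))
        assert select_representatives(S, {"a": 0.5, "b": 0.5}, cutoff=0.7) == ["a"]

    def test_invalid_cutoff(self):
        S = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            select_representatives(S, {"a": 1, "b": 1}, cutoff=1.5)

    def test_missing_f1_raises(self):
        S = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="f1"):
            select_representatives(S, {"a": 1.0}, cutoff=0.8)


class TestConsensusScore:
    def test_single_model_identity(self):
        m = _matrix({"a": [0.2, 0.9, 0.4]})
        entries = consensus_score(m, ["a"])
        assert [e.consensus_score for e in entries] == pytest.approx([0.2, 0.9, 0.4])

    def test_mean_at_threshold_is_active(self):
        m = _matrix({"a": [0.2], "b": [0.8]})
        e = consensus_score(m)[0]
        assert e.consensus_score == pytest.approx(0.5)
        assert e.predicted_label == ACTIVE

    def test_missing_entries_excluded(self):
        m = _matrix({"a": [0.9], "b": [0.9], "c": [np.nan]})
        e = consensus_score(m)[0]
        assert e.consensus_score == pytest.approx(0.9)
        assert e.n_models_contributing == 2

    def test_identical_models_equal_single_model(self):
        p = [0.3, 0.6, 0.8]
        single = consensus_score(_matrix({"a": p}))
        triple = consensus_score(_matrix({"a": p, "b": p, "c": p}))
        assert [e.consensus_score for e in triple] == pytest.approx(
            [e.consensus_score for e in single], abs=1e-12
        )

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(0)
        cols = {k: rng.random(20) for k in "abcd"}
        rows = [("c1", f"t{i}") for i in range(20)]
        fwd = consensus_score(_matrix(cols, rows))
        rev = consensus_score(_matrix(dict(reversed(list(cols.items()))), rows))
        assert [e.consensus_score for e in fwd] == pytest.approx(
            [e.consensus_score for e in rev]
        )

    def test_unknown_selection_raises(self):
        with pytest.raises(ValueError):
            consensus_score(_matrix({"a": [0.1, 0.5]}), ["zz"])


class TestFractionSweep:
    @staticmethod
    def _setup(n=126, seed=5):
        rng = np.random.default_rng(seed)
        targets = [f"t{i:03d}" for i in range(n)]
        truth_labels = {}
        entries = []
        for tid in targets:
            active = rng.random() < 0.3
            truth_labels[("c", tid)] = ACTIVE if active else INACTIVE
            score = np.clip(rng.normal(0.7 if active else 0.3, 0.15), 0, 1)
            entries.append(ConsensusEntry("c", tid, float(score), 3))
        return entries, TruthTable(truth_labels, targets)

    def test_depth_is_ceiling(self):
        entries, truth = self._setup(n=126)
        sweep = fraction_sweep(entries, truth, fractions=(0.2,))
        assert sweep.rows[0].n_evaluated == 26  # ceil(0.2 * 126)

    def test_full_fraction_equals_unranked_evaluation(self):
        entries, truth = self._setup()
        sweep = fraction_sweep(entries, truth, fractions=(1.0,))
        row = sweep.rows[0]
        assert row.n_evaluated == len(entries)
        # all truth-annotated entries evaluable at 100%
        assert row.confusion.n_evaluable == sum(
            1 for e in entries if ("c", e.target_id) in truth.labels
        )

    def test_monotone_depths(self):
        entries, truth = self._setup()
        sweep = fraction_sweep(entries, truth, fractions=(0.1, 0.5, 1.0))
        depths = [r.n_evaluated for r in sweep.rows]
        assert depths == sorted(depths)
        ranked = rank_entries(entries)
        top10 = {e.target_id for e in ranked[: depths[0]]}
        top50 = {e.target_id for e in ranked[: depths[1]]}
        assert top10 <= top50

    def test_empty_entries_rejected(self):
        _, truth = self._setup()
        with pytest.raises(ValueError):
            fraction_sweep([], truth)

    def test_deterministic_tie_break_by_target_id(self):
        entries = [
            ConsensusEntry("c", "t2", 0.8, 1),
            ConsensusEntry("c", "t1", 0.8, 1),
            ConsensusEntry("c", "t3", 0.9, 1),
        ]
        ranked = rank_entries(entries)
        assert [e.target_id for e in ranked] == ["t3", "t1", "t2"]

    def test_consensus_of_noisy_models_beats_mean_individual(self):
        # five noisy, correlated views of one binary signal: at top-20% the
        # fused ranking should recover at least as many actives as a typical
        # single model does
        rng = np.random.default_rng(21)
        n = 300
        targets = [f"t{i:03d}" for i in range(n)]
        signal = rng.random(n) < 0.25
        truth = TruthTable(
            {("c", t): (ACTIVE if s else INACTIVE) for t, s in zip(targets, signal)},
            targets,
        )
        rows = [("c", t) for t in targets]
        cols = {
            f"m{k}": np.clip(signal * 0.6 + 0.2 + rng.normal(0, 0.18, n), 0, 1)
            for k in range(5)
        }
        matrix = _matrix(cols, rows)

        def tpr_at_20(entries):
            return fraction_sweep(entries, truth, fractions=(0.2,)).rows[0].report.tpr

        consensus_tpr = tpr_at_20(consensus_score(matrix))
        individual = [
            tpr_at_20(consensus_score(_matrix({k: v}, rows)))
            for k, v in cols.items()
        ]
        assert consensus_tpr >= np.mean(individual)


def test_entries_to_frame_columns():
    df = entries_to_frame([ConsensusEntry("c", "t", 0.7, 2)])
    assert list(df.columns) == [
        "compound_id", "target_id", "consensus_score", "n_models", "label",
    ]
    assert df.loc[0, "label"] == ACTIVE
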