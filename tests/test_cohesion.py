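import itertools

import numpy as np
import pandas as pd
import pytest

from coalmix import (
    CommunityMatrix,
    CommunityMatrixError,
    CorrelationSet,
    cohesion,
    cohesion_pipeline,
    compare_stability,
    connectedness,
    correlation_set,
    null_expected_correlations,
    pairwise_correlations,
    stability_ratio,
    to_relative,
)
from coalmix.simulate import simulate_independent_community


def _relative(rows, taxa=None):
    arr = np.asarray(rows, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)
    taxa = taxa or [f"t{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=taxa)
    return CommunityMatrix(df, "relative")


class TestPairwiseCorrelations:
    def test_perfect_positive_and_negative_dependence(self):
        # t1 = 2*t0 across samples -> r = 1; t2 = c - t0 -> r = -1
        base = np.array([1.0, 2.0, 3.0, 4.0])
        rows = np.stack([base, 2 * base, 10 - base], axis=1)
        r = pairwise_correlations(_relative(rows))
        assert r.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert r.iloc[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_on_hand_table(self):
        rows = np.array([[4, 1, 5], [2, 3, 5], [6, 2, 2], [1, 1, 8]], dtype=float)
        rel = rows / rows.sum(axis=1, keepdims=True)
        r = pairwise_correlations(_relative(rows))
        for i, j in itertools.combinations(range(3), 2):
            x, y = rel[:, i], rel[:, j]
            expected = np.sum((x - x.mean()) * (y - y.mean())) / (
                np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            )
            assert r.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_taxon_flagged_as_zero(self):
        rows = np.array([[1, 1, 2], [2, 1, 1], [3, 1, 3]], dtype=float)
        rows = rows / rows.sum(axis=1, keepdims=True)  # keep t1 constant post-normalise
        df = pd.DataFrame(
            np.stack([rows[:, 0], np.full(3, 0.25), 0.75 - rows[:, 0]], axis=1)
        )
        df.index = ["s0", "s1", "s2"]
        df.columns = ["a", "const", "b"]
        cm = CommunityMatrix(df.div(df.sum(axis=1), axis=0), "relative")
        r = pairwise_correlations(cm)
        assert (r["const"] == 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(CommunityMatrixError, match="3 samples"):
            pairwise_correlations(_relative([[1, 2], [2, 1]]))


class TestNullModel:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """At 4 samples the taxon-shuffle null can be enumerated exactly
        over all 24 permutations; the Monte-Carlo estimate must agree."""
        cm = simulate_independent_community(4, 5, seed=3)
        x = cm.values()
        t = x.shape[1]

        def corr(u, v):
            su, sv = u.std(), v.std()
            if su == 0 or sv == 0:
                return 0.0
            return float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))

        exact = np.zeros((t, t))
        perms = list(itertools.permutations(range(4)))
        for i in range(t):
            for j in range(t):
                if i == j:
                    continue
                exact[i, j] = np.mean([corr(x[:, i], x[list(p), j]) for p in perms])
        exact = 0.5 * (exact + exact.T)

        mc = null_expected_correlations(cm, n_iter=3000, seed=0).to_numpy()
        assert np.abs(mc - exact).max() < 0.02

    def test_mean_null_near_zero_on_independent_data(self):
        cm = simulate_independent_community(40, 30, seed=1)
        null = null_expected_correlations(cm, n_iter=300, seed=1).to_numpy()
        off = null[np.triu_indices(30, 1)]
        assert abs(off.mean()) < 0.02

    def test_shuffling_destroys_perfect_alignment(self):
        base = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0])
        rows = np.stack([base, base, 20 - 2 * base], axis=1)
        cm = _relative(rows)
        obs = pairwise_correlations(cm).iloc[0, 1]
        null = null_expected_correlations(cm, n_iter=200, seed=0).iloc[0, 1]
        assert obs == pytest.approx(1.0, abs=1e-9)
        assert null < 0.5

    def test_deterministic_under_seed(self):
        cm = simulate_independent_community(10, 8, seed=2)
        a = null_expected_correlations(cm, n_iter=50, seed=9)
        b = null_expected_correlations(cm, n_iter=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_n_iter_rejected(self):
        cm = simulate_independent_community(5, 4, seed=0)
        with pytest.raises(CommunityMatrixError):
            null_expected_correlations(cm, n_iter=0, seed=0)


def _corrset(corrected, taxa):
    """CorrelationSet whose corrected matrix equals the given entries."""
    observed = pd.DataFrame(corrected, index=taxa, columns=taxa, dtype=float)
    zero = pd.DataFrame(0.0, index=taxa, columns=taxa)
    return CorrelationSet(observed=observed, null_expected=zero,
                          n_null_iterations=1, seed=0)


class TestConnectednessAndCohesion:
    taxa = ["t1", "t2", "t3"]
    corrected = [[0.0, 0.6, -0.2], [0.6, 0.0, 0.4], [-0.2, 0.4, 0.0]]

    def test_hand_computed_connectedness(self):
        conn = connectedness(_corrset(self.corrected, self.taxa))
        assert conn.loc["t1", "connectedness_pos"] == pytest.approx(0.6)
        assert conn.loc["t1", "connectedness_neg"] == pytest.approx(-0.2)
        assert conn.loc["t2", "connectedness_pos"] == pytest.approx(0.5)
        assert conn.loc["t2", "connectedness_neg"] == 0.0
        assert conn.loc["t3", "connectedness_pos"] == pytest.approx(0.4)
        assert conn.loc["t3", "connectedness_neg"] == pytest.approx(-0.2)

    def test_all_zero_corrected_gives_zero_connectedness(self):
        conn = connectedness(_corrset(np.zeros((3, 3)), self.taxa))
        assert (conn == 0).all().all()

    def test_label_permutation_invariance(self):
        conn = connectedness(_corrset(self.corrected, self.taxa))
        order = ["t3", "t1", "t2"]
        permuted = _corrset(
            pd.DataFrame(self.corrected, index=self.taxa, columns=self.taxa)
            .loc[order, order].to_numpy(),
            order,
        )
        conn2 = connectedness(permuted)
        pd.testing.assert_frame_equal(conn.loc[order], conn2)

    def test_cohesion_is_abundance_weighted_sum(self):
        conn = connectedness(_corrset(self.corrected, self.taxa))
        cm = _relative([[0.5, 0.3, 0.2], [0.1, 0.1, 0.8]], taxa=self.taxa)
        coh = cohesion(cm, conn)
        a = cm.values()
        exp_pos = a @ conn["connectedness_pos"].to_numpy()
        exp_neg = a @ conn["connectedness_neg"].to_numpy()
        np.testing.assert_allclose(coh["cohesion_pos"], exp_pos, atol=1e-12)
        np.testing.assert_allclose(coh["cohesion_neg"], exp_neg, atol=1e-12)

    def test_single_weight_sample(self):
        conn = pd.DataFrame(
            {"connectedness_pos": [0.3, 0.0], "connectedness_neg": [0.0, 0.0]},
            index=["a", "b"],
        )
        cm = CommunityMatrix(
            pd.DataFrame([[1.0, 0.0]], index=["s"], columns=["a", "b"]), "relative"
        )
        coh = cohesion(cm, conn)
        assert coh.loc["s", "cohesion_pos"] == pytest.approx(0.3)

    def test_taxon_mismatch_rejected(self):
        conn = connectedness(_corrset(self.corrected, self.taxa))
        cm = _relative([[0.5, 0.5]], taxa=["t1", "other"])
        with pytest.raises(CommunityMatrixError, match="connectedness"):
            cohesion(cm, conn)


class TestStabilityRatio:
    def test_basic_values_and_boundary(self):
        coh = pd.DataFrame(
            {"cohesion_pos": [0.2, 0.1, 0.0], "cohesion_neg": [-0.1, -0.1, -0.1]},
            index=["a", "b", "c"],
        )
        stab = stability_ratio(coh)
        assert stab["a"] == pytest.approx(0.5)
        assert stab["b"] == pytest.approx(1.0)
        assert np.isnan(stab["c"])  # undefined, not infinite


class TestCompareStability:
    def test_identical_groups_not_significant(self):
        g = [0.5, 0.6, 0.7, 0.8, 0.9]
        out = compare_stability({"a": g, "b": g})
        assert (out["p_adj"] > 0.9).all()

    def test_complete_separation_matches_exact_rank_sum(self):
        out = compare_stability({"lo": [0.1, 0.2, 0.3, 0.4, 0.5],
                                 "hi": [1.1, 1.2, 1.3, 1.4, 1.5]})
        # exact two-sided rank-sum p for complete separation at 5 vs 5
        assert out["p_raw"].iloc[0] == pytest.approx(2 / 252, rel=1e-9)

    def test_three_groups_yield_three_bh_adjusted_pairs(self):
        out = compare_stability({
            "a": [0.1, 0.2, 0.3], "b": [0.4, 0.5, 0.6], "c": [0.7, 0.8, 0.9]
        })
        assert len(out) == 3
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = compare_stability({
                "a": [0.1, 0.2, 0.3], "b": [0.4, 0.5], "tiny": [0.9]
            })
        assert set(out["group_a"]) | set(out["group_b"]) == {"a", "b"}


class TestCohesionPipeline:
    def test_runs_on_counts_and_respects_prevalence_filter(self, small_dataset):
        res = cohesion_pipeline(small_dataset.counts, n_iter=20, seed=0)
        rel = to_relative(small_dataset.counts)
        prev = (rel.data > 0).mean(axis=0)
        assert set(res.connectedness.index) == set(prev.index[prev > 0.10])
        assert res.cohesion.shape[0] == small_dataset.counts.n_samples
        assert (res.cohesion["cohesion_pos"] >= 0).all()
        assert (res.cohesion["cohesion_neg"] <= 0).all()
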