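import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coalmix import (
    CommunityMatrix,
    CommunityMatrixError,
    aggregate_response,
    bh_adjust,
    biotic_response,
    environmental_screen,
    permutation_da_test,
)


def brute_force_bh(p):
    """Step-up definition: adj_i = min over k with p(k) >= p(i)... computed
    directly as min_{k >= rank_i} m * p_(k) / k, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for pos in range(m - 1, -1, -1):
        running = min(running, m * p[order[pos]] / (pos + 1))
        adj_sorted[pos] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def _cm(rows, prefix, taxa):
    df = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=[f"{prefix}{i}" for i in range(len(rows))],
        columns=taxa,
    )
    df = df.div(df.sum(axis=1), axis=0)
    return CommunityMatrix(df, "relative")


class TestPermutationTest:
    taxa = [f"T{j}" for j in range(6)]

    def test_identical_groups_have_p_one(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(6), 3)
        a = _cm(rows, "a", self.taxa)
        b = _cm(rows, "b", self.taxa)
        da = permutation_da_test(a, b, n_perm=999, seed=0)
        # observed statistics are exactly zero -> guarded to p = 1
        assert (da.table["p_raw"] == 1.0).all()
        assert (da.table["direction"] == "none").all()

    def test_complete_separation_attains_min_p(self):
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.ones(6))
        shifted = base.copy()
        shifted[0] *= 10
        shifted /= shifted.sum()
        a = _cm(rng.dirichlet(base * 400, 5), "a", self.taxa)
        b = _cm(rng.dirichlet(shifted * 400, 5), "b", self.taxa)
        da = permutation_da_test(a, b, n_perm=999, seed=1)
        assert da.table.loc["T0", "p_raw"] == pytest.approx(1 / 1000)
        assert da.table.loc["T0", "statistic"] > 0

    def test_min_p_formula(self):
        rng = np.random.default_rng(2)
        a = _cm(rng.dirichlet(np.ones(6), 4), "a", self.taxa)
        b = _cm(rng.dirichlet(np.ones(6), 4), "b", self.taxa)
        da = permutation_da_test(a, b, n_perm=99, seed=2)
        assert (da.table["p_raw"] >= 1 / 100 - 1e-12).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        a = _cm(rng.dirichlet(np.ones(6), 4), "a", self.taxa)
        b = _cm(rng.dirichlet(np.ones(6), 4), "b", self.taxa)
        t1 = permutation_da_test(a, b, n_perm=199, seed=5).table
        t2 = permutation_da_test(a, b, n_perm=199, seed=5).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(4)
        a = _cm(rng.dirichlet(np.ones(6), 1), "a", self.taxa)
        b = _cm(rng.dirichlet(np.ones(6), 4), "b", self.taxa)
        with pytest.raises(CommunityMatrixError, match="two samples"):
            permutation_da_test(a, b)


class TestEnvironmentalScreen:
    taxa = [f"T{j}" for j in range(5)]

    def _da(self, p_adj, stat):
        table = pd.DataFrame(
            {
                "statistic": stat,
                "p_raw": p_adj,
                "p_adj": p_adj,
                "direction": ["none"] * len(p_adj),
                "prevalence": 1.0,
            },
            index=pd.Index(self.taxa, name="taxon_id"),
        )
        from coalmix.diffabund import DiffAbundResult

        return DiffAbundResult(table=table, n_permutations=999, seed=0, alpha=0.05)

    def test_rules(self):
        parent = _cm([[5, 5, 5, 5, 5]], "p", self.taxa)
        env = _cm([[5, 0, 5, 5, 5]], "e", self.taxa)  # T1 absent after treatment
        da = self._da(
            p_adj=[0.5, 0.5, 0.01, 0.01, 0.2],
            stat=[0.1, -0.1, -0.3, +0.3, 0.0],
        )
        retained = environmental_screen(parent, env, da)
        # T0 unaffected -> retained; T1 absent in env -> excluded;
        # T2 significant decrease -> excluded; T3 significant increase -> retained
        assert retained == ["T0", "T3", "T4"]

    def test_absent_from_parent_excluded(self):
        parent = _cm([[0, 5, 5, 5, 5]], "p", self.taxa)
        env = _cm([[5, 5, 5, 5, 5]], "e", self.taxa)
        da = self._da([1.0] * 5, [0.0] * 5)
        assert "T0" not in environmental_screen(parent, env, da)


class TestBioticResponse:
    def test_identity_comparison_yields_empty_sets(self):
        rng = np.random.default_rng(0)
        taxa = [f"T{j}" for j in range(8)]
        rows = rng.dirichlet(np.ones(8), 4)
        a = _cm(rows, "a", taxa)
        b = _cm(rows, "b", taxa)
        da = biotic_response(b, a, screen=taxa, n_perm=199, seed=0)
        assert da.increased == [] and da.decreased == []

    def test_screened_out_taxon_never_reported(self):
        rng = np.random.default_rng(1)
        taxa = [f"T{j}" for j in range(10)]
        base = rng.dirichlet(np.ones(10))
        shifted = base.copy()
        shifted[:4] *= 8
        shifted /= shifted.sum()
        parent = _cm(rng.dirichlet(base * 500, 5), "p", taxa)
        coa = _cm(rng.dirichlet(shifted * 500, 5), "c", taxa)
        screen = taxa[2:]  # exclude T0, T1 despite their strong shift
        da = biotic_response(coa, parent, screen=screen, n_perm=499, seed=1)
        reported = set(da.increased) | set(da.decreased)
        assert {"T0", "T1"}.isdisjoint(reported)
        assert reported <= set(screen)

    def test_low_prevalence_taxon_not_tested(self):
        rng = np.random.default_rng(2)
        taxa = [f"T{j}" for j in range(6)]
        rows_a = rng.dirichlet(np.ones(6), 5)
        rows_b = rng.dirichlet(np.ones(6), 5)
        rows_a[:, 0] = 0.0
        rows_b[:, 0] = 0.0
        rows_b[0, 0] = 0.05  # present in 1/10 samples = 10%, not > 10%
        a = _cm(rows_a, "a", taxa)
        b = _cm(rows_b, "b", taxa)
        da = biotic_response(b, a, screen=taxa, n_perm=199, seed=2)
        assert "T0" not in da.table.index

    def test_empty_screen_rejected(self):
        rng = np.random.default_rng(3)
        taxa = [f"T{j}" for j in range(4)]
        a = _cm(rng.dirichlet(np.ones(4), 3), "a", taxa)
        with pytest.raises(CommunityMatrixError, match="screen"):
            biotic_response(a, a, screen=[], n_perm=99, seed=0)


class TestAggregateResponse:
    taxa = [f"T{j}" for j in range(4)]

    def test_full_response_set_degenerate(self):
        rng = np.random.default_rng(0)
        groups = {
            "g1": _cm(rng.dirichlet(np.ones(4), 3), "a", self.taxa),
            "g2": _cm(rng.dirichlet(np.ones(4), 3), "b", self.taxa),
        }
        totals, test = aggregate_response(groups, self.taxa)
        np.testing.assert_allclose(totals["total_relative_abundance"], 1.0)
        assert test["degenerate"] and test["p_value"] == 1.0

    def test_kruskal_matches_direct_rank_computation(self):
        rows_lo = [[1, 1, 1, 17], [2, 2, 2, 14], [1, 2, 1, 16]]
        rows_hi = [[6, 6, 6, 2], [7, 6, 6, 1], [5, 6, 6, 3]]
        groups = {
            "lo": _cm(rows_lo, "a", self.taxa),
            "hi": _cm(rows_hi, "b", self.taxa),
        }
        totals, test = aggregate_response(groups, self.taxa[:3])
        x = totals.loc[totals.group == "lo", "total_relative_abundance"].to_numpy()
        y = totals.loc[totals.group == "hi", "total_relative_abundance"].to_numpy()
        # direct rank computation (no ties): H = 12/(N(N+1)) sum n_i rbar_i^2 - 3(N+1)
        ranks = pd.Series(np.concatenate([x, y])).rank().to_numpy()
        n = len(ranks)
        rx, ry = ranks[: len(x)], ranks[len(x):]
        h = 12 / (n * (n + 1)) * (
            len(x) * rx.mean() ** 2 + len(y) * ry.mean() ** 2
        ) - 3 * (n + 1)
        assert test["statistic"] == pytest.approx(h, abs=1e-10)

    def test_empty_set_flagged_untested(self):
        rng = np.random.default_rng(1)
        groups = {"g1": _cm(rng.dirichlet(np.ones(4), 3), "a", self.taxa)}
        totals, test = aggregate_response(groups, [])
        assert (totals["total_relative_abundance"] == 0).all()
        assert test["tested"] is False
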