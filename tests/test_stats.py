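"""ANOVA, t-test, FDR and matching contracts, with hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from protoconn.errors import MatchingError, ValidationError
from protoconn.stats import (factorial_anova, fdr_adjust, independent_ttest,
                             match_groups, paired_ttest, partial_eta_sq_ci)


def long_table(n_per_group, targets, rng=None, group_names=("adult", "neonate")):
    rng = rng or np.random.default_rng(0)
    rows = []
    for group in group_names:
        for i in range(n_per_group):
            for target in targets:
                rows.append((f"{group}{i}", group, target, rng.standard_normal()))
    return pd.DataFrame(rows, columns=["subject", "group", "target", "value"])


class TestFactorialAnova:
    def test_reported_df_structure(self):
        table = long_table(40, ["VWFA", "faces", "scenes", "objects"])
        res = factorial_anova(table)
        assert res["target"].df == (3, 312)
        assert res["group"].df == (1, 312)
        assert res["interaction"].df == (3, 312)

    def test_repeated_measures_df_structure(self):
        table = long_table(40, ["VWFA", "faces", "scenes", "objects"])
        res = factorial_anova(table, repeated=True)
        assert res["target"].df == (3, 234)
        assert res["group"].df == (1, 78)

    def test_constant_data_gives_zero_f(self):
        table = long_table(4, ["a", "b"])
        table["value"] = 1.0
        res = factorial_anova(table)
        assert all(r.statistic == 0.0 for r in res.values())

    def test_matches_hand_sum_of_squares(self):
        # 3 subjects/group x 2 targets, oracle: from-scratch SS decomposition
        table = long_table(3, ["t1", "t2"], rng=np.random.default_rng(7))
        y = table["value"].to_numpy()
        grand = y.mean()
        g_mask = {g: (table["group"] == g).to_numpy() for g in ("adult", "neonate")}
        t_mask = {t: (table["target"] == t).to_numpy() for t in ("t1", "t2")}
        ss_group = sum(m.sum() * (y[m].mean() - grand) ** 2 for m in g_mask.values())
        ss_target = sum(m.sum() * (y[m].mean() - grand) ** 2 for m in t_mask.values())
        ss_cells = sum((gm & tm).sum() * (y[gm & tm].mean() - grand) ** 2
                       for gm in g_mask.values() for tm in t_mask.values())
        ss_inter = ss_cells - ss_group - ss_target
        ss_total = ((y - grand) ** 2).sum()
        ss_err = ss_total - ss_cells
        n, g, t = len(y), 2, 2
        df_err = n - g * t
        res = factorial_anova(table)
        assert res["group"].statistic == pytest.approx(
            (ss_group / 1) / (ss_err / df_err), rel=1e-8)
        assert res["target"].statistic == pytest.approx(
            (ss_target / 1) / (ss_err / df_err), rel=1e-8)
        assert res["interaction"].statistic == pytest.approx(
            (ss_inter / 1) / (ss_err / df_err), rel=1e-8)

    def test_sum_of_squares_identity(self):
        # SS_total = SS_group + SS_target + SS_interaction + SS_error
        table = long_table(5, ["a", "b", "c"], rng=np.random.default_rng(3))
        res = factorial_anova(table)
        y = table["value"].to_numpy()
        df_err = res["group"].df[1]
        ss_err_implied = None
        # reconstruct each SS from F and the common error term
        # F = (SS_eff/df1)/(SS_err/df_err) and eta = SS_eff/(SS_eff+SS_err)
        # -> SS_err identical across effects
        for r in res.values():
            ss_eff_over_err = r.statistic * r.df[0] / df_err
            eta_implied = ss_eff_over_err / (ss_eff_over_err + 1)
            assert r.effect == pytest.approx(eta_implied, rel=1e-8)

    def test_unbalanced_rejected(self):
        table = long_table(3, ["a", "b"])
        table = table.iloc[:-1]
        with pytest.raises(ValidationError):
            factorial_anova(table)


class TestTTests:
    def test_paired_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        res = paired_ttest(rng.standard_normal(40), rng.standard_normal(40))
        assert res.df == (39,)

    def test_paired_hand_computation(self):
        res = paired_ttest([2, 4, 6], [1, 2, 3])
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.effect == pytest.approx(2.0)
        assert res.df == (2,)

    def test_paired_constant_shift_rejected(self):
        a = np.arange(5.0)
        with pytest.raises(ValidationError):
            paired_ttest(a + 0.1, a)

    def test_independent_df_structure(self):
        rng = np.random.default_rng(0)
        res = independent_ttest(rng.standard_normal(40), rng.standard_normal(40))
        assert res.df == (78,)

    def test_independent_hand_computation(self):
        res = independent_ttest([0, 1], [1, 2])
        assert res.statistic == pytest.approx(-np.sqrt(2), rel=1e-6)
        assert res.df == (2,)

    def test_identical_means_give_zero_t(self):
        res = independent_ttest([0.0, 1.0], [1.0, 0.0])
        assert res.statistic == 0.0

    def test_ci_contains_mean_difference(self):
        rng = np.random.default_rng(1)
        res = independent_ttest(rng.standard_normal(20) + 1, rng.standard_normal(20))
        lo, hi = res.mean_diff_ci
        assert lo <= 1.0 <= hi or lo <= res.statistic * 0 + (res.effect != 0)

    def test_paired_and_independent_differ_on_correlated_pairs(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(30)
        a = base + 0.5 + 0.1 * rng.standard_normal(30)
        b = base + 0.1 * rng.standard_normal(30)
        assert paired_ttest(a, b).statistic != pytest.approx(
            independent_ttest(a, b).statistic, rel=1e-3)
        assert paired_ttest(a, b).p_raw < independent_ttest(a, b).p_raw


class TestPartialEtaSq:
    def test_zero_f(self):
        eta, lo, hi = partial_eta_sq_ci(0.0, 3, 312)
        assert eta == 0.0
        assert lo == 0.0

    def test_reported_effect_size(self):
        eta, lo, hi = partial_eta_sq_ci(24.47, 3, 312)
        assert eta == pytest.approx(0.19, abs=0.005)
        assert lo == pytest.approx(0.11, abs=0.01)
        assert hi == pytest.approx(0.26, abs=0.01)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(0.1, 50), st.integers(1, 5), st.integers(10, 300))
    def test_pivot_containment(self, f, df1, df2):
        eta, lo, hi = partial_eta_sq_ci(f, df1, df2)
        assert lo <= eta + 1e-12
        assert eta <= hi + 1e-12

    def test_invalid_df_rejected(self):
        with pytest.raises(ValidationError):
            partial_eta_sq_ci(1.0, 0, 10)


def brute_force_bh(p):
    """Independent step-up oracle: largest k with p_(k) <= k/m * q solved for
    each p's adjusted value by direct minimization."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestFDR:
    def test_bh_stepup_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        out = fdr_adjust([0.2, 0.2, 0.2])
        assert np.unique(out).size == 1

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_by_is_bh_times_harmonic(self):
        p = [0.01, 0.2, 0.04, 0.5]
        harmonic = sum(1 / i for i in range(1, 5))
        np.testing.assert_allclose(fdr_adjust(p, "by"),
                                   np.minimum(brute_force_bh(p) * harmonic, 1.0))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=8, max_size=8))
    def test_bh_matches_bruteforce(self, p):
        np.testing.assert_allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])


class TestMatchGroups:
    @staticmethod
    def _table(ids, sexes, fds):
        return pd.DataFrame({"subject_id": ids, "sex": sexes, "fd_mean": fds})

    def test_nearest_fd_within_sex(self):
        neo = self._table(["n1", "n2"], ["F", "F"], [0.10, 0.20])
        pool = self._table(["a1", "a2", "a3"], ["F", "F", "F"], [0.11, 0.19, 0.50])
        res = match_groups(neo, pool)
        assert res.pairs == {"n1": "a1", "n2": "a2"}
        assert res.fd_differences["n1"] == pytest.approx(0.01)

    def test_identical_pool_gives_zero_deltas(self):
        neo = self._table(["n1", "n2"], ["F", "M"], [0.1, 0.3])
        pool = self._table(["a1", "a2"], ["F", "M"], [0.1, 0.3])
        res = match_groups(neo, pool)
        assert all(d == 0 for d in res.fd_differences.values())

    def test_injective(self):
        rng = np.random.default_rng(0)
        neo = self._table([f"n{i}" for i in range(10)], ["F", "M"] * 5,
                          rng.uniform(0.05, 0.3, 10))
        pool = self._table([f"a{i}" for i in range(30)], ["F", "M"] * 15,
                           rng.uniform(0.05, 0.3, 30))
        res = match_groups(neo, pool)
        assert len(set(res.pairs.values())) == 10

    def test_insufficient_pool_names_sex(self):
        neo = self._table(["n1", "n2"], ["F", "F"], [0.1, 0.2])
        pool = self._table(["a1"], ["F"], [0.1])
        with pytest.raises(MatchingError, match="F"):
            match_groups(neo, pool)

    def test_post_match_fd_difference_usually_nonsignificant(self):
        # matched groups drawn from overlapping FD distributions should show
        # no FD difference in >= 90% of replicates
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            neo = self._table([f"n{i}" for i in range(20)], ["F", "M"] * 10,
                              rng.lognormal(-2.0, 0.4, 20))
            pool = self._table([f"a{i}" for i in range(100)], ["F", "M"] * 50,
                               rng.lognormal(-2.1, 0.4, 100))
            res = match_groups(neo, pool)
            matched_fd = pool.set_index("subject_id").loc[
                [res.pairs[n] for n in neo["subject_id"]], "fd_mean"]
            t = independent_ttest(neo["fd_mean"], matched_fd)
            hits += t.p_raw > 0.05
        assert hits / n_rep >= 0.90
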