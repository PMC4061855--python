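"""Mixed repeated-measures ANOVA with GG correction, pairwise Bonferroni
follow-ups, Spearman correlation, and the simulation harness.

pingouin serves as the independent oracle for the designs it supports; a
hand-computed sums-of-squares decomposition covers a tiny fixed design.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from toneosc.stats import (bonferroni_pairwise, follow_up_anovas, gg_epsilon,
                           rm_anova, spearman, type1_power_suite)


def long_format(Y, within_levels, groups=None, names=("A", "B")):
    """Subjects x cells matrix -> long table (cells row-major)."""
    cells = list(itertools.product(*[range(k) for k in within_levels]))
    rows = []
    for s in range(Y.shape[0]):
        for c, cell in enumerate(cells):
            row = {"subject": f"s{s}", "value": Y[s, c],
                   "group": "g0" if groups is None else groups[s]}
            for f, lv in zip(names, cell):
                row[f] = f"{f}{lv}"
            rows.append(row)
    return pd.DataFrame(rows)


class TestEpsilon:
    def test_bounds_on_random_covariances(self, rng):
        for _ in range(50):
            k = rng.integers(2, 7)
            L = rng.normal(size=(k, k))
            eps = gg_epsilon(L @ L.T)
            assert 1.0 / k <= eps <= 1.0

    def test_spherical_covariance_gives_one(self):
        assert gg_epsilon(np.eye(4) * 3.0) == pytest.approx(1.0)

    def test_compound_symmetry_estimates_near_one(self, rng):
        # CS covariance satisfies sphericity; at n=200 the estimate is ~1
        k, n = 5, 200
        cov = 0.5 * np.eye(k) + 0.5
        Y = rng.multivariate_normal(np.zeros(k), cov, size=n)
        res = rm_anova(long_format(Y, [k], names=("A",)), within=["A"], between=None)
        assert float(res.loc[res.effect == "A", "eps"].iloc[0]) > 0.9


class TestAnovaOracles:
    def test_two_level_factor_forces_eps_one(self, rng):
        Y = rng.normal(size=(10, 2))
        res = rm_anova(long_format(Y, [2], names=("A",)), within=["A"], between=None)
        row = res[res.effect == "A"].iloc[0]
        assert row["eps"] == 1.0
        assert row["p_gg"] == row["p_uncorrected"]

    def test_matches_pingouin_two_within(self, rng):
        Y = rng.normal(size=(10, 6)) + rng.normal(size=(10, 1))
        df = long_format(Y, [3, 2])
        mine = rm_anova(df, within=["A", "B"], between=None)
        ref = pg.rm_anova(df, dv="value", within=["A", "B"], subject="subject",
                          detailed=True)
        for eff, pg_name in (("A", "A"), ("B", "B"), ("A*B", "A * B")):
            m = mine[mine.effect == eff].iloc[0]
            r = ref[ref.Source == pg_name].iloc[0]
            assert m["F"] == pytest.approx(r["F"], rel=1e-9)
            assert m["p_uncorrected"] == pytest.approx(r["p_unc"], rel=1e-9)
            if not np.isnan(r["eps"]):
                assert m["eps"] == pytest.approx(r["eps"], rel=1e-9)

    def test_matches_pingouin_mixed_design(self, rng):
        k = 4
        L = rng.normal(size=(k, k))
        rows = []
        for gname in ("g1", "g2"):
            Y = rng.multivariate_normal(np.zeros(k), L @ L.T, size=9)
            if gname == "g2":
                Y = Y + np.linspace(0, 1, k)
            rows.append(long_format(Y, [k], groups=[gname] * 9, names=("A",)))
            rows[-1]["subject"] = gname + rows[-1]["subject"]
        df = pd.concat(rows, ignore_index=True)
        mine = rm_anova(df, within=["A"], between="group")
        ref = pg.mixed_anova(df, dv="value", within="A", subject="subject",
                             between="group")
        for eff, pg_name in (("group", "group"), ("A", "A"), ("A:group", "Interaction")):
            m = mine[mine.effect == eff].iloc[0]
            r = ref[ref.Source == pg_name].iloc[0]
            assert m["F"] == pytest.approx(r["F"], rel=1e-9)
            assert m["p_uncorrected"] == pytest.approx(r["p_unc"], rel=1e-9)

    def test_one_way_rm_matches_hand_computed_sums_of_squares(self):
        # 4 subjects x 3 levels, values fixed
        Y = np.array([[3.0, 5.0, 4.0],
                      [2.0, 4.0, 6.0],
                      [5.0, 7.0, 7.0],
                      [4.0, 8.0, 6.0]])
        n, k = Y.shape
        grand = Y.mean()
        ss_treat = n * ((Y.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((Y - grand) ** 2).sum()
        ss_err = ss_total - ss_treat - ss_subj
        F_expected = (ss_treat / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        res = rm_anova(long_format(Y, [k], names=("A",)), within=["A"], between=None)
        row = res[res.effect == "A"].iloc[0]
        assert row["F"] == pytest.approx(F_expected, rel=1e-9)
        assert row["df1"] == k - 1 and row["df2"] == (n - 1) * (k - 1)

    def test_gg_is_conservative_in_the_rejection_region(self, rng):
        # shrinking both dfs is conservative wherever the test rejects; a
        # GG-significant effect is always significant uncorrected too (the
        # standard formula can dip below the uncorrected p only at p >> .05)
        checked = 0
        for _ in range(80):
            Y = rng.normal(size=(8, 4)) * rng.uniform(0.2, 3.0, size=4)
            Y[:, 0] += rng.uniform(0, 1.5)  # sprinkle real effects
            res = rm_anova(long_format(Y, [4], names=("A",)), within=["A"], between=None)
            sig = res[res["p_uncorrected"] <= 0.05]
            checked += len(sig)
            assert (sig["p_gg"] >= sig["p_uncorrected"] - 1e-12).all()
            assert not ((res["p_gg"] < 0.05) & (res["p_uncorrected"] >= 0.05)).any()
        assert checked > 5

    def test_unbalanced_groups_supported(self, rng):
        rows = []
        for gname, n in (("English", 10), ("Chinese", 10), ("Thai", 11)):
            Y = rng.normal(size=(n, 2))
            part = long_format(Y, [2], groups=[gname] * n, names=("A",))
            part["subject"] = gname + part["subject"]
            rows.append(part)
        res = rm_anova(pd.concat(rows, ignore_index=True), within=["A"], between="group")
        assert set(res.effect) == {"group", "A", "A:group"}
        assert res["p_gg"].between(0, 1).all()

    def test_missing_cell_rejected(self, rng):
        df = long_format(rng.normal(size=(6, 3)), [3], names=("A",))
        df = df[~((df.subject == "s0") & (df.A == "A2"))]
        with pytest.raises(ValueError):
            rm_anova(df, within=["A"], between=None)

    def test_follow_up_runner_slices_by_level(self, rng):
        Y = rng.normal(size=(12, 4))
        df = long_format(Y, [2, 2])
        out = follow_up_anovas(df, by="B", within=["A"], between=None)
        assert set(out) == {"B0", "B1"}


class TestBonferroni:
    @staticmethod
    def _groups_df(rng, means=(0.0, 0.0, 0.0), n=8):
        rows = []
        for g, mu in zip(("a", "b", "c"), means):
            for s in range(n):
                rows.append(dict(subject=f"{g}{s}", group=g,
                                 value=rng.normal(mu, 1.0)))
        return pd.DataFrame(rows)

    def test_three_groups_three_pairs_multiplier(self, rng):
        out = bonferroni_pairwise(self._groups_df(rng), factor="group")
        assert len(out) == 3
        finite = out[out.p_bonferroni < 1]
        assert np.allclose(finite.p_bonferroni, finite.p_raw * 3)

    def test_adjusted_p_capped_at_one(self, rng):
        out = bonferroni_pairwise(self._groups_df(rng), factor="group")
        assert (out.p_bonferroni <= 1.0).all()

    def test_familywise_error_controlled_under_null(self, rng):
        hits = 0
        sims = 400
        for _ in range(sims):
            out = bonferroni_pairwise(self._groups_df(rng), factor="group")
            hits += (out.p_bonferroni < 0.05).any()
        assert hits / sims <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / sims)

    def test_within_factor_uses_paired_tests(self, rng):
        rows = []
        for s in range(10):
            base = rng.normal()
            rows += [dict(subject=f"s{s}", session="pre", value=base + rng.normal(0, .1)),
                     dict(subject=f"s{s}", session="post", value=base + 1 + rng.normal(0, .1))]
        out = bonferroni_pairwise(pd.DataFrame(rows), factor="session")
        assert out.test.iloc[0] == "paired"
        assert out.p_bonferroni.iloc[0] < 0.001

    def test_single_level_rejected(self, rng):
        df = self._groups_df(rng)
        with pytest.raises(ValueError):
            bonferroni_pairwise(df[df.group == "a"], factor="group")


class TestSpearman:
    def test_monotone_relations_hit_plus_minus_one(self):
        x = np.arange(12.0)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -x ** 3).rho == pytest.approx(-1.0)

    def test_ties_match_brute_force_rank_correlation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 8.0, 9.0, 10.0, 11.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 9.0, 9.0, 9.0, 12.0, 11.0, 15.0, 3.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(brute, abs=1e-12)

    def test_small_n_uses_exact_permutation_p(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        res = spearman(x, y)
        assert res.method == "exact-permutation"
        assert 0.0 <= res.p <= 1.0
        # the permutation distribution of a perfect monotone pair: p = 2/n!
        mono = spearman(np.arange(5.0), np.arange(5.0) ** 2)
        assert mono.p == pytest.approx(2.0 / math.factorial(5))

    def test_invariant_to_monotone_transforms(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = spearman(x, y)
        b = spearman(np.exp(x), np.arctan(y))
        assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_constant_input_flagged_degenerate(self):
        res = spearman(np.ones(8), np.arange(8.0))
        assert res.degenerate and np.isnan(res.rho)


class TestTypeOnePowerSuite:
    def test_deterministic_and_reports_ci(self):
        rng_holder = {}

        def factory(seed):
            return seed

        def analysis(seed):
            r = np.random.default_rng(seed)
            p = r.uniform()
            return pd.DataFrame([dict(effect="e", p_gg=p)])

        a = type1_power_suite({"null": factory}, analysis, ["e"], n_sims=50, seed=4)
        b = type1_power_suite({"null": factory}, analysis, ["e"], n_sims=50, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert {"rate", "ci_low", "ci_high"} <= set(a.columns)
        assert (a.ci_low <= a.rate).all() and (a.rate <= a.ci_high).all()
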