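"""Permutation group tests, FDR, pattern labels, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cereconn as cc
from cereconn.inference import pattern_label


class TestResidualize:
    def test_orthogonal_to_design(self, rng):
        x = rng.standard_normal((50, 3))
        y = rng.standard_normal(50) + x @ [1.0, -2.0, 0.5]
        r = cc.residualize(y, x)
        assert abs(r.mean()) < 1e-10
        assert np.abs(x.T @ r).max() < 1e-8

    def test_exact_linear_signal_removed(self):
        age = np.arange(20.0)
        y = 3.0 + 0.5 * age
        r = cc.residualize(y, age[:, None])
        assert np.abs(r).max() < 1e-10

    def test_categorical_covariate_via_dataframe(self, rng):
        sex = pd.Series(["F", "M"] * 25)
        y = rng.standard_normal(50) + (sex == "M") * 2.0
        r = cc.residualize(y, pd.DataFrame({"sex": sex}))
        assert abs(r[(sex == "M").to_numpy()].mean()) < 1e-10

    def test_rank_deficient_design_rejected(self, rng):
        x = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            cc.residualize(rng.standard_normal(20), x)


class TestPermGroupTest:
    def test_f_statistic_matches_scipy_anova(self, rng):
        y = rng.standard_normal(60)
        g = np.repeat(["a", "b", "c"], 20)
        f_obs, _ = cc.perm_group_test(y, g, B=99, seed=0)
        f_scipy = stats.f_oneway(y[g == "a"], y[g == "b"], y[g == "c"]).statistic
        assert f_obs == pytest.approx(f_scipy, abs=1e-10)

    def test_planted_effect_detected(self, rng):
        g = np.repeat(["HC", "MS", "NMOSD"], 40)
        y = rng.standard_normal(120)
        y[g == "MS"] += 1.5
        _, p = cc.perm_group_test(y, g, B=999, seed=1)
        assert p == pytest.approx(1 / 1000)  # smallest attainable p

    def test_null_p_not_extreme(self, rng):
        g = np.repeat(["HC", "MS", "NMOSD"], 30)
        ps = [cc.perm_group_test(rng.standard_normal(90), g, B=199, seed=k)[1]
              for k in range(20)]
        # under the null, p-values should spread over (0, 1]
        assert min(ps) > 1 / 200 - 1e-12
        assert 0.15 < np.mean(ps) < 0.85

    def test_covariate_confound_absorbed(self, rng):
        """A group difference purely driven by age vanishes after adjustment."""
        g = np.repeat(["HC", "MS"], 50)
        age = np.concatenate([rng.uniform(20, 40, 50), rng.uniform(50, 70, 50)])
        y = 0.05 * age + rng.standard_normal(100) * 0.3
        _, p_raw = cc.perm_group_test(y, g, B=999, seed=2)
        _, p_adj = cc.perm_group_test(y, g, age[:, None], B=999, seed=2)
        assert p_raw < 0.01
        assert p_adj > 0.05

    def test_constant_measure_warns_p_one(self):
        g = np.repeat(["a", "b"], 5)
        with pytest.warns(UserWarning, match="constant"):
            f, p = cc.perm_group_test(np.ones(10), g, B=99)
        assert (f, p) == (0.0, 1.0)

    def test_degenerate_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            cc.perm_group_test(rng.standard_normal(5), ["a"] * 5)
        with pytest.raises(ValueError):
            cc.perm_group_test(rng.standard_normal(5), ["a", "a", "a", "a", "b"])


class TestBHFDR:
    def test_matches_hand_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        q = cc.bh_fdr(p)
        # step-up: q_i = min_{j>=i} p_(j) * m / j
        expect = [0.04, 0.04, 0.04, 0.5]
        np.testing.assert_allclose(q, expect, atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0, 1, 40)
        q = cc.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()

    def test_empty_input(self):
        assert cc.bh_fdr([]).size == 0


class TestPatternLabels:
    MEANS = {"MS": 2.0, "NMOSD": 1.0, "HC": 0.0}

    def test_no_significance_gives_none(self):
        sig = {frozenset(p): False for p in
               [("MS", "NMOSD"), ("MS", "HC"), ("NMOSD", "HC")]}
        assert pattern_label(self.MEANS, sig) is None

    def test_single_pair(self):
        sig = {frozenset(("MS", "HC")): True,
               frozenset(("MS", "NMOSD")): False,
               frozenset(("NMOSD", "HC")): False}
        assert pattern_label(self.MEANS, sig) == "MS > HCs"

    def test_one_group_above_both(self):
        sig = {frozenset(("MS", "HC")): True,
               frozenset(("MS", "NMOSD")): True,
               frozenset(("NMOSD", "HC")): False}
        assert pattern_label(self.MEANS, sig) == "MS > [NMOSD = HCs]"

    def test_one_group_below_both(self):
        means = {"MS": -2.0, "NMOSD": 1.0, "HC": 0.5}
        sig = {frozenset(("MS", "HC")): True,
               frozenset(("MS", "NMOSD")): True,
               frozenset(("NMOSD", "HC")): False}
        assert pattern_label(means, sig) == "MS < [NMOSD = HCs]"

    def test_full_ordering(self):
        sig = {frozenset(p): True for p in
               [("MS", "NMOSD"), ("MS", "HC"), ("NMOSD", "HC")]}
        assert pattern_label(self.MEANS, sig) == "MS > NMOSD > HCs"

    def test_posthoc_end_to_end_recovers_planted_pattern(self, rng):
        g = np.repeat(["HC", "MS", "NMOSD"], 50)
        y = rng.standard_normal(150)
        y[g == "MS"] += 1.5
        _, label = cc.posthoc_pairwise(y, g, B=999, seed=3)
        # bracket order follows the (noise-driven) adjusted means
        assert label in ("MS > [NMOSD = HCs]", "MS > [HCs = NMOSD]")


class TestSpearmanPartial:
    def test_no_covariates_matches_scipy(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        rho, p = cc.spearman_partial(x, y)
        sr = stats.spearmanr(x, y)
        assert rho == pytest.approx(sr.statistic, abs=1e-10)
        assert p == pytest.approx(sr.pvalue, rel=0.05)

    def test_matches_pingouin_with_covariates(self, rng):
        import pingouin as pg

        x = rng.standard_normal(60)
        z = rng.standard_normal(60)
        y = 0.4 * x + 0.8 * z + rng.standard_normal(60)
        rho, p = cc.spearman_partial(x, y, z[:, None])
        ref = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman",
        )
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_confound_is_removed(self, rng):
        z = rng.standard_normal(200)
        x = z + 0.1 * rng.standard_normal(200)
        y = z + 0.1 * rng.standard_normal(200)
        rho_raw, _ = cc.spearman_partial(x, y)
        rho_adj, p_adj = cc.spearman_partial(x, y, z[:, None])
        assert rho_raw > 0.9
        assert abs(rho_adj) < 0.3

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            cc.spearman_partial([1, 2, 3], [1, 2, 3], np.ones((3, 1)))


class TestChiSquare:
    def test_matches_scipy_on_sex_table(self):
        table = [[124, 104], [135, 73], [175, 25]]
        chi2, p = cc.chi_square_test(table)
        ref = stats.chi2_contingency(np.array(table), correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-15)
        assert p < 0.001  # strongly female-skewed third group

    def test_hand_2x2_value(self):
        # chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 20*(100-0)^2/(10*10*10*10)
        chi2, _ = cc.chi_square_test([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            cc.chi_square_test([[0, 0], [5, 3]])


class TestCompareMeasures:
    def test_panel_flags_only_planted_measures(self, rng):
        g = np.repeat(["HC", "MS", "NMOSD"], 40)
        panel = pd.DataFrame(rng.standard_normal((120, 6)),
                             columns=[f"m{i}" for i in range(6)])
        panel.loc[g == "MS", "m0"] += 1.5
        panel.loc[g == "NMOSD", "m1"] -= 1.5
        out = cc.compare_measures(panel, g, B=499, seed=7)
        assert set(out.columns) >= {"measure", "statistic", "p", "q", "pattern"}
        sig = set(out.loc[out["q"] < 0.05, "measure"])
        assert {"m0", "m1"} <= sig
        assert len(sig) <= 3  # at most one false positive slips through
        assert out.loc[out["measure"] == "m0", "pattern"].iloc[0] in (
            "MS > [NMOSD = HCs]", "MS > [HCs = NMOSD]"
        )
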