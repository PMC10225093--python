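"""Co-expression decomposition, PLS1, gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cereconn as cc


def _expr(rng, n_genes=60, regions=("r0", "r1", "r2", "r3")):
    return pd.DataFrame(
        rng.standard_normal((n_genes, len(regions))),
        index=[f"g{i}" for i in range(n_genes)], columns=list(regions),
    )


class TestCoexpression:
    def test_matches_pearson(self, rng):
        expr = _expr(rng)
        pairs = [("r0", "r1"), ("r2", "r3"), ("r0", "r3")]
        out = cc.regional_coexpression(expr, pairs)
        for k, (a, b) in enumerate(pairs):
            ref = stats.pearsonr(expr[a], expr[b]).statistic
            assert out[k] == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_region_named(self, rng):
        expr = _expr(rng)
        expr["r1"] = 5.0
        with pytest.raises(ValueError, match="r1"):
            cc.regional_coexpression(expr, [("r0", "r1")])

    def test_too_few_genes_rejected(self, rng):
        expr = _expr(rng, n_genes=2)
        with pytest.raises(ValueError):
            cc.regional_coexpression(expr, [("r0", "r1")])


class TestContributions:
    def test_columns_sum_exactly_to_coexpression(self, rng):
        for _ in range(100):
            n_genes = int(rng.integers(5, 80))
            expr = _expr(rng, n_genes=n_genes)
            pairs = [("r0", "r1"), ("r1", "r2"), ("r0", "r3")]
            contrib = cc.gene_edge_contributions(expr, pairs)
            coexpr = cc.regional_coexpression(expr, pairs)
            np.testing.assert_allclose(
                contrib.sum(axis=0).to_numpy(), coexpr, atol=1e-10
            )

    def test_single_gene_contribution_hand_value(self):
        expr = pd.DataFrame(
            {"r0": [1.0, 2.0, 3.0], "r1": [1.0, 2.0, 3.0]},
            index=["g0", "g1", "g2"],
        )
        contrib = cc.gene_edge_contributions(expr, [("r0", "r1")])
        # identical profiles: z products are z^2; column sums to r = 1
        assert contrib["r0~r1"].sum() == pytest.approx(1.0, abs=1e-12)
        assert contrib.loc["g1", "r0~r1"] == pytest.approx(0.0, abs=1e-12)

    def test_module_pooling_means_region_edges(self, rng):
        expr = _expr(rng)
        pairs = [("r0", "r1"), ("r0", "r2"), ("r1", "r2"), ("r0", "r3")]
        labels = {"r0": "A", "r1": "A", "r2": "B", "r3": "B"}
        contrib = cc.gene_edge_contributions(expr, pairs)
        pooled = cc.module_contribution_matrix(contrib, pairs, labels, ["A", "B"])
        assert list(pooled.columns) == ["A~A", "A~B"]
        np.testing.assert_allclose(
            pooled["A~B"],
            contrib[["r0~r2", "r1~r2", "r0~r3"]].mean(axis=1),
            atol=1e-12,
        )
        np.testing.assert_allclose(pooled["A~A"], contrib["r0~r1"], atol=1e-12)


def _pls_problem(rng, n_genes=200, n_edges=25, n_drivers=12, noise=0.2):
    """Driver genes share a latent edge profile that also drives y.

    The shared profile gives the cross-covariance a dominant direction;
    with independent gene profiles and G >> n the in-sample r is near 1
    for any response and nothing is detectable.
    """
    x = pd.DataFrame(
        rng.standard_normal((n_genes, n_edges)),
        index=[f"g{i}" for i in range(n_genes)],
    )
    latent = rng.standard_normal(n_edges)
    drivers = x.index[:n_drivers]
    x.loc[drivers] = latent + 0.3 * rng.standard_normal((n_drivers, n_edges))
    y = latent + noise * rng.standard_normal(n_edges)
    return x, y, drivers


class TestPLS:
    def test_weights_proportional_to_cross_covariance(self, rng):
        x, y, _ = _pls_problem(rng)
        res = cc.pls_fit(x, y)
        xc = x.to_numpy().T - x.to_numpy().T.mean(axis=0)
        yc = y - y.mean()
        np.testing.assert_allclose(res.weights.to_numpy(), xc.T @ yc, atol=1e-10)
        # scores reproduce the projection and r matches a direct Pearson
        np.testing.assert_allclose(
            res.scores, xc @ (xc.T @ yc) / np.linalg.norm(xc.T @ yc), atol=1e-10
        )
        assert res.r == pytest.approx(stats.pearsonr(res.scores, y).statistic, abs=1e-12)

    def test_driver_genes_get_extreme_z(self, rng):
        x, y, drivers = _pls_problem(rng, noise=0.1)
        res = cc.pls_fit(x, y)
        recall = len(res.selected.intersection(drivers)) / len(drivers)
        assert recall >= 0.75
        # selected set respects the documented threshold exactly
        assert set(res.selected) == set(res.z.index[np.abs(res.z) > 1.64])

    def test_sign_flip_of_response_flips_weights(self, rng):
        x, y, _ = _pls_problem(rng)
        a = cc.pls_fit(x, y)
        b = cc.pls_fit(x, -y)
        np.testing.assert_allclose(a.weights, -b.weights, atol=1e-10)
        assert a.r == pytest.approx(b.r, abs=1e-12)  # |r| invariant

    def test_constant_response_rejected(self, rng):
        x, _, _ = _pls_problem(rng)
        with pytest.raises(ValueError, match="constant"):
            cc.pls_fit(x, np.ones(x.shape[1]))

    def test_permutation_p_small_for_real_signal(self, rng):
        x, y, _ = _pls_problem(rng, noise=0.1)
        res, p = cc.pls1_significance(x, y, B=499, seed=5)
        assert p < 0.05
        assert res.p == p

    def test_permutation_p_large_for_noise(self, rng):
        x = pd.DataFrame(rng.standard_normal((150, 25)))
        y = rng.standard_normal(25)
        _, p = cc.pls1_significance(x, y, B=499, seed=6)
        assert p > 0.05

    def test_vectorized_null_matches_refit_loop(self, rng):
        """The batched permutation r values equal per-permutation pls_fit."""
        x, y, _ = _pls_problem(rng, n_genes=40, n_edges=12)
        B = 20
        check = np.random.default_rng(123)
        perms = np.stack([check.permutation(12) for _ in range(B)])
        loop_r = np.array([cc.pls_fit(x, y[p]).r for p in perms])
        # reproduce the same permutations inside the vectorized path
        res, p = cc.pls1_significance(x, y, B=B, seed=123)
        expect = (1 + np.count_nonzero(loop_r >= res.r - 1e-12)) / (B + 1)
        assert p == pytest.approx(expect, abs=1e-12)


class TestEnrichment:
    def test_hand_hypergeometric_value(self):
        background = [f"g{i}" for i in range(20)]
        ann = pd.Series({g: ("neuron" if i < 5 else "glia")
                         for i, g in enumerate(background)})
        selected = ["g0", "g1", "g2", "g5"]
        out = cc.enrichment_test(selected, ann, background)
        row = out[out["class"] == "neuron"].iloc[0]
        expect = stats.hypergeom.sf(2, 20, 5, 4)  # P(X >= 3)
        assert row["overlap"] == 3
        assert row["p"] == pytest.approx(expect, abs=1e-12)
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_planted_class_enriched(self, rng):
        background = [f"g{i}" for i in range(500)]
        ann = pd.Series({g: ("target" if i < 50 else "rest")
                         for i, g in enumerate(background)})
        selected = background[:30] + background[100:110]  # 30/40 from target
        out = cc.enrichment_test(selected, ann, background)
        assert out.iloc[0]["class"] == "target"
        assert out.iloc[0]["p"] < 1e-6

    def test_selection_outside_background_rejected(self):
        ann = pd.Series({"g0": "a"})
        with pytest.raises(ValueError, match="subset"):
            cc.enrichment_test(["zz"], ann, ["g0", "g1"])
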