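"""Multilayer modularity, Louvain optimization, VI, stability selection."""

import numpy as np
import pytest

import cereconn as cc
from cereconn.multiplex import (
    Multiplex,
    MultilayerPartition,
    StabilityMap,
    default_gamma_grid,
    default_omega_grid,
)


def _two_triangles():
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return a


def _blocky(n, k, rng, p_in=0.9, p_out=0.1):
    """Random symmetric weights with k planted blocks."""
    labels = np.repeat(np.arange(k), n // k)
    base = np.where(labels[:, None] == labels[None, :], p_in, p_out)
    noise = rng.random((n, n)) * 0.05
    a = base + (noise + noise.T) / 2
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a, labels


class TestBuildGroupMultiplex:
    def test_identical_subjects_mean_is_subject(self, rng):
        m = np.abs(rng.random((4, 4)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        f = rng.uniform(-0.5, 0.9, (4, 4))
        f = (f + f.T) / 2
        np.fill_diagonal(f, 1.0)
        mx = cc.build_group_multiplex([m, m, m], [f, f, f], list("abcd"))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(mx.layers["morphological"][off], m[off], atol=1e-12)
        np.testing.assert_allclose(mx.layers["functional"][off], np.clip(f, 0, None)[off], atol=1e-10)

    def test_all_negative_functional_layer_zeroed(self, rng):
        m = np.eye(3)
        f = np.full((3, 3), -0.4)
        np.fill_diagonal(f, 1.0)
        with pytest.warns(UserWarning, match="non-positive"):
            mx = cc.build_group_multiplex([m], [f], list("abc"))
        assert np.all(mx.layers["functional"] == 0)

    def test_functional_mean_on_fisher_z_scale(self):
        """Three subjects with r = 0.2, 0.5, 0.8 average via atanh, not raw."""
        def corr(r):
            c = np.array([[1.0, r], [r, 1.0]])
            return c

        mx = cc.build_group_multiplex(
            [np.eye(2)] * 3, [corr(0.2), corr(0.5), corr(0.8)], ["a", "b"]
        )
        expect = np.tanh(np.mean(np.arctanh([0.2, 0.5, 0.8])))
        assert mx.layers["functional"][0, 1] == pytest.approx(expect, abs=1e-12)
        assert expect != pytest.approx(np.mean([0.2, 0.5, 0.8]), abs=1e-6)


class TestQuality:
    def test_two_triangle_hand_value(self):
        mx = Multiplex({"layer": _two_triangles()}, [str(i) for i in range(6)])
        labels = np.array([[0], [0], [0], [1], [1], [1]])
        assert cc.multilayer_quality(mx, labels, omega=0.0, gamma=1.0) == pytest.approx(0.5)

    def test_single_module_is_zero(self):
        mx = Multiplex({"layer": _two_triangles()}, [str(i) for i in range(6)])
        labels = np.zeros((6, 1), dtype=int)
        assert cc.multilayer_quality(mx, labels, omega=0.0, gamma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_omega_zero_decouples_into_layer_modularities(self, rng):
        a1, l1 = _blocky(8, 2, rng)
        a2, _ = _blocky(8, 4, rng)
        mx = Multiplex({"x": a1, "y": a2}, [str(i) for i in range(8)])
        labels = np.column_stack([l1, rng.integers(0, 3, 8)])
        q = cc.multilayer_quality(mx, labels, omega=0.0, gamma=1.0)
        # weighted mean of per-layer Newman-Girvan modularities (networkx oracle)
        import networkx as nx

        total = 0.0
        denom = 0.0
        for s, mat in enumerate([a1, a2]):
            g = nx.from_numpy_array(mat)
            comms = {}
            for node in range(8):
                comms.setdefault(labels[node, s], set()).add(node)
            two_m = mat.sum()
            total += two_m * nx.community.modularity(g, comms.values(), weight="weight")
            denom += two_m
        assert q == pytest.approx(total / denom, abs=1e-10)

    def test_empty_layer_contributes_zero(self):
        mx = Multiplex({"x": _two_triangles(), "z": np.zeros((6, 6))},
                       [str(i) for i in range(6)])
        labels = np.tile([[0], [0], [0], [1], [1], [1]], (1, 2))
        with pytest.warns(UserWarning, match="no weight"):
            q = cc.multilayer_quality(mx, labels, omega=0.0, gamma=1.0)
        assert q == pytest.approx(0.5)  # triangles' Q over the total supra-weight


class TestLouvain:
    def test_recovers_planted_blocks_across_layers(self, rng):
        a1, labels = _blocky(8, 2, rng)
        a2, _ = _blocky(8, 2, rng)
        mx = Multiplex({"x": a1, "y": a2}, [str(i) for i in range(8)])
        part = cc.louvain_optimize(mx, omega=0.3, gamma=1.0, restarts=20, seed=0)
        assert part.n_modules == 2
        assert cc.variation_of_information(part.labels[:, 0], labels) == pytest.approx(0.0)
        assert (part.labels[:, 0] == part.labels[:, 1]).all()

    def test_quality_bounds_and_self_consistency(self, rng):
        a1, _ = _blocky(8, 2, rng)
        a2, _ = _blocky(8, 4, rng)
        mx = Multiplex({"x": a1, "y": a2}, [str(i) for i in range(8)])
        part = cc.louvain_optimize(mx, 0.4, 1.2, restarts=10, seed=3)
        singles = np.arange(16).reshape(2, 8).T
        ones = np.zeros((8, 2), dtype=int)
        assert part.quality >= cc.multilayer_quality(mx, singles, 0.4, 1.2) - 1e-12
        assert part.quality >= cc.multilayer_quality(mx, ones, 0.4, 1.2) - 1e-12
        assert part.quality == pytest.approx(
            cc.multilayer_quality(mx, part.labels, 0.4, 1.2), abs=1e-12
        )

    def test_strong_coupling_forces_layer_consistency(self, rng):
        a, _ = _blocky(8, 2, rng)
        mx = Multiplex({"x": a, "y": a.copy()}, [str(i) for i in range(8)])
        part = cc.louvain_optimize(mx, omega=5.0, gamma=1.0, restarts=10, seed=1)
        assert (part.labels[:, 0] == part.labels[:, 1]).all()

    def test_deterministic_under_seed(self, hc_multiplex):
        p1 = cc.louvain_optimize(hc_multiplex, 0.3, 1.5, restarts=5, seed=42)
        p2 = cc.louvain_optimize(hc_multiplex, 0.3, 1.5, restarts=5, seed=42)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.quality == p2.quality


class TestVI:
    def test_identity_and_extremes(self):
        assert cc.variation_of_information([0, 0, 1, 1], [1, 1, 0, 0]) == 0.0
        n = 8
        assert cc.variation_of_information(np.arange(n), np.zeros(n)) == pytest.approx(np.log2(n))

    def test_four_node_worked_example(self):
        # {ab|cd} vs {a|b|cd}: H=1, H=1.5, I=1 -> VI = 0.5 bits
        assert cc.variation_of_information([0, 0, 1, 1], [0, 1, 2, 2]) == pytest.approx(0.5)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            c = rng.integers(0, 4, n)
            dab = cc.variation_of_information(a, b)
            dba = cc.variation_of_information(b, a)
            dac = cc.variation_of_information(a, c)
            dcb = cc.variation_of_information(c, b)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-10
            assert dab >= 0

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cc.variation_of_information([0, 1], [0, 1, 2])


class TestSweepAndSelection:
    def test_constant_plateau_has_zero_vi(self, rng):
        a, _ = _blocky(8, 2, rng, p_in=1.0, p_out=0.01)
        mx = Multiplex({"x": a, "y": a.copy()}, [str(i) for i in range(8)])
        sweep = cc.sweep_parameters(
            mx, np.array([0.2, 0.4]), np.array([0.8, 1.0, 1.2]), restarts=5, seed=0
        )
        assert np.allclose(sweep.vi, 0.0)
        part = cc.select_stable_partition(sweep)
        assert part.n_modules == 2

    def test_single_cell_map_returns_that_partition(self, hc_multiplex):
        sweep = cc.sweep_parameters(
            hc_multiplex, np.array([0.3]), np.array([1.5]), restarts=5, seed=0
        )
        part = cc.select_stable_partition(sweep)
        assert (part.omega, part.gamma) == (0.3, 1.5)

    def test_default_grids_span_documented_ranges(self):
        w = default_omega_grid()
        g = default_gamma_grid()
        assert w.min() == pytest.approx(0.01) and w.max() == pytest.approx(1.0)
        assert g.min() == pytest.approx(0.01) and g.max() == pytest.approx(3.0)
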