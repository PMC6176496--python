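"""Density thresholding and long/short-distance connection statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmnconn.atlas import (AREA_CODES, AreaPartition, balanced_partition,
                           default_partition, destrieux_table,
                           partition_from_table)
from mmnconn.config import ConfigError
from mmnconn.network import (area_metrics, density_sweep, minimum_density,
                             minimum_density_percent, n_kept_edges,
                             threshold_by_density)


def sym_matrix(weights, n):
    w = np.zeros((n, n))
    for (i, j), v in weights.items():
        w[i - 1, j - 1] = w[j - 1, i - 1] = v
    return w


TOY = sym_matrix({(1, 2): .9, (1, 3): .5, (1, 4): .2,
                  (2, 3): .4, (2, 4): .3, (3, 4): .8}, 4)


def brute_force_metrics(graph, partition):
    """Exhaustive edge-classification loop (independent of the array path)."""
    n_areas = partition.n_areas
    l_k = [0.0] * n_areas
    s_k = [0.0] * n_areas
    for i, j, w in zip(graph.edge_i, graph.edge_j, graph.weights):
        ai, aj = partition.area_of[i], partition.area_of[j]
        if ai == aj:
            s_k[ai] += w
        else:
            l_k[ai] += w
            l_k[aj] += w
    return np.array(l_k), np.array(s_k)


class TestMinimumDensity:
    def test_148_nodes_is_six_percent_truncated(self):
        d = minimum_density(148)
        assert d == pytest.approx(2 * math.log(148) / 147)
        assert d == pytest.approx(0.068, abs=0.001)
        assert minimum_density_percent(148) == 6  # truncation, not rounding

    def test_formula_at_average_degree_two(self):
        n = math.e  # continuous check: 2 ln N = 2
        assert 2 * math.log(n) / (n - 1) == pytest.approx(2 / (n - 1))

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ConfigError):
            minimum_density(2)


class TestThresholding:
    def test_toy_graph_half_density(self):
        g = threshold_by_density(TOY, 0.5)
        kept = set(zip(g.edge_i + 1, g.edge_j + 1))
        assert kept == {(1, 2), (3, 4), (1, 3)}
        assert np.allclose(g.weights, [.9, .8, .5])

    def test_full_density_keeps_everything(self):
        g = threshold_by_density(TOY, 1.0)
        assert g.n_edges == 6

    def test_kept_count_matches_closed_form(self, rng):
        w = rng.uniform(0, 1, (148, 148))
        w = np.triu(w, 1) + np.triu(w, 1).T
        for d in rng.uniform(0.01, 1.0, 20):
            g = threshold_by_density(w, d)
            assert g.n_edges == n_kept_edges(148, d)

    def test_ties_break_lexicographically(self):
        w = sym_matrix({(1, 2): .5, (1, 3): .5, (2, 3): .5}, 3)
        g = threshold_by_density(w, 2 / 3)
        assert set(zip(g.edge_i, g.edge_j)) == {(0, 1), (0, 2)}

    def test_invalid_density_rejected(self):
        with pytest.raises(ConfigError):
            threshold_by_density(TOY, 0.0)
        with pytest.raises(ConfigError):
            threshold_by_density(TOY, 1.5)


TWO_AREAS = AreaPartition(np.array([0, 0, 1, 1]), ["LVPF", "LT"])


class TestAreaMetrics:
    def test_hand_worked_two_area_graph(self):
        w = sym_matrix({(1, 2): .9, (3, 4): .8, (1, 3): .5, (2, 4): .3}, 4)
        m = area_metrics(threshold_by_density(w, 4 / 6), TWO_AREAS)
        assert np.allclose(m.s_k, [.9, .8])
        assert m.s_all == pytest.approx(1.7)
        assert np.allclose(m.l_k, [.8, .8])
        assert m.l_all == pytest.approx(1.6)
        assert m.ratio == pytest.approx(1.6 / 1.7)

    def test_no_inter_area_edges_gives_zero_ratio(self):
        w = sym_matrix({(1, 2): .9, (3, 4): .8}, 4)
        m = area_metrics(threshold_by_density(w, 2 / 6), TWO_AREAS)
        assert m.l_all == 0.0
        assert m.ratio == 0.0

    def test_no_intra_area_edges_gives_nan_ratio(self):
        w = sym_matrix({(1, 3): .9, (2, 4): .8}, 4)
        m = area_metrics(threshold_by_density(w, 2 / 6), TWO_AREAS)
        assert m.s_all == 0.0
        assert math.isnan(m.ratio)
        assert not math.isinf(m.ratio)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.integers(4, 6),
           st.floats(0.2, 1.0))
    def test_matches_exhaustive_classification(self, seed, n, density):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 1, (n, n))
        w = np.triu(w, 1) + np.triu(w, 1).T
        part = balanced_partition(n, n_areas=2)
        g = threshold_by_density(w, density)
        m = area_metrics(g, part)
        l_ref, s_ref = brute_force_metrics(g, part)
        assert np.array_equal(m.l_k[:2], l_ref)
        assert np.array_equal(m.s_k[:2], s_ref)

    def test_conservation_identity(self, rng):
        w = rng.uniform(0, 1, (148, 148))
        w = np.triu(w, 1) + np.triu(w, 1).T
        part = default_partition()
        for d in (0.06, 0.2, 0.5, 0.9, 1.0):
            g = threshold_by_density(w, d)
            m = area_metrics(g, part)
            assert m.s_all + m.l_all / 2 == pytest.approx(
                g.weights.sum(), abs=1e-9)


class TestDensitySweep:
    def make_w(self, rng, n=30):
        w = rng.uniform(0, 1, (n, n))
        return np.triu(w, 1) + np.triu(w, 1).T

    def test_totals_monotone_in_density(self, rng):
        w = self.make_w(rng)
        sweep = density_sweep(w, balanced_partition(30))
        l = [m.l_all for m in sweep.per_density]
        s = [m.s_all for m in sweep.per_density]
        assert all(a <= b + 1e-12 for a, b in zip(l, l[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(s, s[1:]))

    def test_sweep_agrees_with_direct_metrics(self, rng):
        w = self.make_w(rng)
        part = balanced_partition(30)
        sweep = density_sweep(w, part, grid=(0.1, 0.45, 0.9))
        for m in sweep.per_density:
            direct = area_metrics(threshold_by_density(w, m.density), part)
            assert np.allclose(m.l_k, direct.l_k)
            assert np.allclose(m.s_k, direct.s_k)

    def test_full_density_conserves_total_weight(self, rng):
        w = self.make_w(rng)
        sweep = density_sweep(w, balanced_partition(30), grid=(1.0,))
        m = sweep.per_density[0]
        assert m.s_all + m.l_all / 2 == pytest.approx(
            w[np.triu_indices(30, 1)].sum())

    def test_single_point_grid_summary_equals_value(self, rng):
        w = self.make_w(rng)
        sweep = density_sweep(w, balanced_partition(30), grid=(0.4,))
        assert sweep.summary.l_all == sweep.per_density[0].l_all
        assert sweep.summary.ratio == sweep.per_density[0].ratio

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigError):
            density_sweep(self.make_w(rng), balanced_partition(30), grid=())

    def test_raising_inter_weight_raises_ratio(self):
        w = sym_matrix({(1, 2): .9, (3, 4): .8, (1, 3): .5, (2, 4): .3}, 4)
        base = area_metrics(threshold_by_density(w, 1.0), TWO_AREAS)
        w2 = w.copy()
        w2[0, 2] = w2[2, 0] = .7  # inter-area edge up
        up = area_metrics(threshold_by_density(w2, 1.0), TWO_AREAS)
        assert up.ratio > base.ratio
        w3 = w.copy()
        w3[0, 1] = w3[1, 0] = .95  # intra-area edge up
        down = area_metrics(threshold_by_density(w3, 1.0), TWO_AREAS)
        assert down.ratio < base.ratio


class TestAtlas:
    def test_shipped_table_has_148_rois_in_14_areas(self):
        table = destrieux_table()
        part = partition_from_table(table)
        assert part.n_rois == 148
        assert part.n_areas == 14
        assert set(table["area"]) == set(AREA_CODES)
        counts = np.bincount(part.area_of)
        assert np.all(counts > 0)
        # hemispheric symmetry of the default mapping
        assert np.array_equal(counts[:7], counts[7:])

    def test_missing_roi_detected(self):
        table = destrieux_table().drop(10)
        with pytest.raises(ConfigError, match="missing"):
            partition_from_table(table, n_rois=148)

    def test_unknown_area_detected(self):
        table = destrieux_table()
        table.loc[0, "area"] = "XX"
        with pytest.raises(ConfigError, match="unknown"):
            partition_from_table(table)

    def test_empty_area_detected(self):
        with pytest.raises(ConfigError, match="empty"):
            AreaPartition(np.zeros(5, dtype=int), ["LVPF", "LT"])
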