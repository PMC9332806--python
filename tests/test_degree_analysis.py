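"""Degree distributions, metrics, and curve-family fits."""

import numpy as np
import pytest

from lungnet.degree_analysis import (
    DegreeDistribution,
    best_fit,
    degree_distribution,
    fit_distribution,
    mean_rd_sweep,
    network_metrics,
    rd_sweep,
)
from lungnet.errors import InsufficientDataError, UndefinedStatisticError
from lungnet.hu_layers import LayerMask, split_layers
from lungnet.pixel_graph import GraphParams, build_graph
from lungnet.synthetic_fixtures import PhantomSpec, make_phantom


def _graph(mask, hu=None, **kw):
    mask = np.asarray(mask, bool)
    hu = np.zeros(mask.shape) if hu is None else np.asarray(hu, float)
    return build_graph(LayerMask("test", mask, hu), GraphParams(**kw) if kw else None)


def _path3():
    """Three collinear pixels 4 apart: a path graph (ends see only the middle)."""
    mask = np.zeros((1, 9), bool)
    mask[0, [0, 4, 8]] = True
    return _graph(mask)


def _dist(degrees, counts):
    degrees = np.asarray(degrees)
    counts = np.asarray(counts)
    n_edges = int((degrees * counts).sum()) // 2
    return DegreeDistribution(degrees, counts, int(counts.sum()), n_edges)


class TestDegreeDistribution:
    def test_path_graph(self):
        d = degree_distribution(_path3())
        assert dict(zip(d.degrees, d.counts)) == {1: 2, 2: 1}

    def test_complete_graph(self):
        d = degree_distribution(_graph(np.ones((3, 3))))
        assert dict(zip(d.degrees, d.counts)) == {8: 9}

    def test_isolated_nodes(self):
        mask = np.zeros((1, 12), bool)
        mask[0, [0, 11]] = True
        d = degree_distribution(_graph(mask))
        assert dict(zip(d.degrees, d.counts)) == {0: 2}

    def test_empty_graph(self):
        d = degree_distribution(_graph(np.zeros((3, 3))))
        assert d.degrees.size == 0 and d.n_nodes == 0

    def test_degree_sum_twice_edges(self, rng):
        for _ in range(15):
            mask = rng.random((15, 15)) < 0.5
            hu = rng.uniform(-700, -400, (15, 15))
            g = _graph(mask, hu)
            d = degree_distribution(g)
            assert (d.degrees * d.counts).sum() == 2 * g.n_edges
            assert d.counts.sum() == g.n_nodes


class TestNetworkMetrics:
    def test_path_graph(self):
        m = network_metrics(_path3())
        assert (m.total_count, m.max_degree) == (4, 2)
        assert m.average_count == pytest.approx(4 / 3)

    def test_complete_graph(self):
        m = network_metrics(_graph(np.ones((3, 3))))
        assert (m.total_count, m.average_count, m.max_degree) == (72, 8.0, 8)

    def test_empty_graph_yields_zeros(self):
        m = network_metrics(_graph(np.zeros((2, 2))))
        assert (m.total_count, m.average_count, m.max_degree) == (0, 0.0, 0)


class TestFitRecovery:
    def test_planted_logarithmic(self):
        k = np.arange(1, 11)
        y = 2 * np.log(k) + 3
        d = DegreeDistribution(k, y, int(y.sum()), 0)
        fit = fit_distribution(d, "logarithmic")
        a, b = fit.coefficients
        assert a == pytest.approx(2, rel=1e-6)
        assert b == pytest.approx(3, rel=1e-6)
        assert fit.r2 == pytest.approx(1, abs=1e-9)

    def test_planted_power(self):
        k = np.arange(1, 11)
        y = 5 * k.astype(float) ** 2
        d = DegreeDistribution(k, y, int(y.sum()), 0)
        fit = fit_distribution(d, "power")
        a, b = fit.coefficients
        assert a == pytest.approx(5, rel=1e-6)
        assert b == pytest.approx(2, rel=1e-6)
        assert fit.r2 == pytest.approx(1, abs=1e-9)

    def test_planted_quadratic_selects_degree_two(self):
        k = np.arange(1, 13)
        y = k.astype(float) ** 2 - 3 * k + 10
        d = DegreeDistribution(k, y, int(y.sum()), 0)
        fit = fit_distribution(d, "polynomial")
        assert fit.poly_degree == 2
        assert fit.r2 == pytest.approx(1, abs=1e-9)
        np.testing.assert_allclose(fit.coefficients, [1, -3, 10], rtol=1e-6)

    @pytest.mark.parametrize("sigma", [1e-3, 1e-6, 1e-9])
    def test_r2_approaches_one_as_noise_vanishes(self, sigma):
        rng = np.random.default_rng(11)
        k = np.arange(1, 15)
        y = 2 * np.log(k) + 5 + rng.normal(0, sigma, k.size)
        d = DegreeDistribution(k, y, int(y.sum()), 0)
        assert fit_distribution(d, "logarithmic").r2 > 1 - 1e-2 * sigma

    def test_degree_zero_bin_excluded_from_fit(self):
        k = np.array([0, 1, 2, 3, 4])
        y = 2 * np.log(np.maximum(k, 1)) + 3
        y[0] = 99  # would wreck the fit if included
        d = DegreeDistribution(k, y, int(y.sum()), 0)
        fit = fit_distribution(d, "logarithmic")
        assert fit.coefficients[0] == pytest.approx(2, rel=1e-6)


class TestFitErrors:
    def test_too_few_distinct_degrees(self):
        d = _dist([1, 2], [3, 1])
        with pytest.raises(InsufficientDataError):
            fit_distribution(d, "logarithmic")

    def test_constant_counts_undefined_r2(self):
        d = _dist([1, 2, 3, 4], [5, 5, 5, 5])
        with pytest.raises(UndefinedStatisticError):
            fit_distribution(d, "logarithmic")

    def test_polynomial_needs_enough_points_for_adjustment(self):
        d = _dist([1, 2, 3], [9, 4, 1])
        with pytest.raises(InsufficientDataError):
            fit_distribution(d, "polynomial")


class TestRdSweep:
    def test_single_pixel_layer_all_missing(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        layer = LayerMask("test", mask, np.zeros((9, 9)))
        table = rd_sweep(layer, rd_values=[1, 4])
        assert table["r2"].isna().all()

    def test_edge_count_monotone_in_rd(self):
        phantom = make_phantom(PhantomSpec(kind="normal_like", seed=4))
        layer = [l for l in split_layers(phantom) if l.band_name == "ggo"][0]
        table = rd_sweep(layer, rd_values=[3, 4], families=("logarithmic",))
        edges = table.set_index("rd")["n_edges"]
        assert edges[4.0] >= edges[3.0]

    def test_normal_lot_prefers_logarithmic_at_rd4(self):
        layers = []
        for seed in range(5):
            phantom = make_phantom(PhantomSpec(kind="normal_like", seed=seed))
            layers += [l for l in split_layers(phantom) if l.band_name == "ggo"]
        table = mean_rd_sweep(layers, rd_values=[4])
        means = table.set_index("family")["mean_r2"]
        assert means["logarithmic"] > means["power"]


def test_dild_phantoms_best_fitted_by_polynomial():
    """Proliferative (clustered) texture yields humped degree histograms that
    the monotone logarithmic/power families cannot follow."""
    wins = 0
    for seed in range(8):
        phantom = make_phantom(PhantomSpec(kind="mixed_dild", seed=seed))
        layer = [l for l in split_layers(phantom) if l.band_name == "ggo"][0]
        d = degree_distribution(build_graph(layer))
        if best_fit(d).family == "polynomial":
            wins += 1
    assert wins >= 7
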