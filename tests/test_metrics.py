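import numpy as np
import pytest

from warpelast.dtw import TimeSeriesPair, WarpPath, dtw
from warpelast.metrics import (
    WarpDeviationSeries,
    collapse_path,
    elasticity_for_pair,
    pairwise_elasticity,
    warp_deviation,
    warp_elasticity,
    window_size,
)
from warpelast.simulate import FIG_PLAN, make_stretch_pair


def path_from_pairs(pairs):
    return WarpPath(pairs=np.array(pairs), cost=0.0)


class TestCollapsePath:
    def test_diagonal_path_zero_deviation(self):
        path = path_from_pairs([(0, 0), (1, 1), (2, 2)])
        np.testing.assert_allclose(collapse_path(path, "x").values, 0.0)

    def test_many_to_one_collapse_example(self):
        path = path_from_pairs([(0, 0), (1, 0), (2, 1)])
        np.testing.assert_allclose(collapse_path(path, "x").values, [0, 1, 1])

    def test_one_to_many_uses_mean_partner_index(self):
        path = path_from_pairs([(0, 0), (0, 1), (1, 2)])
        # reference x index 0 matched to y 0 and 1 -> mean 0.5
        np.testing.assert_allclose(collapse_path(path, "x").values, [-0.5, -1.0])

    def test_equal_length_y_is_exact_negation(self, rng):
        pair = TimeSeriesPair(rng.standard_normal(40), rng.standard_normal(40))
        path = dtw(pair, 10)
        np.testing.assert_allclose(
            collapse_path(path, "y").values, -collapse_path(path, "x").values
        )

    def test_unequal_length_direct_collapse(self):
        path = path_from_pairs([(0, 0), (1, 0), (2, 1)])
        # reference y: index 0 matched to x 0,1 -> 0 - 0.5; index 1 -> 1 - 2
        np.testing.assert_allclose(collapse_path(path, "y").values, [-0.5, -1.0])


class TestWarpDeviation:
    def test_identical_pair_zero_everywhere(self, rng):
        x = rng.standard_normal(50)
        dev = warp_deviation(TimeSeriesPair(x, x), 10)
        np.testing.assert_allclose(dev.values, 0.0)

    def test_equal_length_boundary_values_small(self, rng):
        """Every path touches (0,0) and (N-1,N-1); under mean-collapse the
        endpoint deviation is at most half an edge run, i.e. band/2."""
        pair = TimeSeriesPair(rng.standard_normal(60), rng.standard_normal(60))
        dev = warp_deviation(pair, 15)
        assert abs(dev.values[0]) <= 7.5 and abs(dev.values[-1]) <= 7.5

    def test_deviation_bounded_by_band(self, rng):
        pair = TimeSeriesPair(rng.standard_normal(80), rng.standard_normal(80))
        dev = warp_deviation(pair, band_radius=7)
        assert np.max(np.abs(dev.values)) <= 7

    def test_seconds_scaling(self, rng):
        pair = TimeSeriesPair(rng.standard_normal(30), rng.standard_normal(30), tr=2.0)
        dev = warp_deviation(pair, 8)
        np.testing.assert_allclose(dev.values_seconds, dev.values * 2.0)

    def test_shrunk_segment_raises_deviation_constant_when_unresampled(self):
        """A factor<1 segment raises WD; a factor-1 segment holds it level."""
        # noiseless fixture keeps the path structure clean
        x, y, _ = make_stretch_pair(seed=3, noise_sd=0.0)
        dev = warp_deviation(TimeSeriesPair(x, y), 89).values
        # segment 1 (factor 0.67, samples 0-29): consistent rise
        assert dev[29] - dev[0] > 5
        # segment 4 (factor 1, samples 90-119): approximately constant
        assert abs(dev[119] - dev[90]) < abs(dev[29] - dev[0])


class TestWarpElasticity:
    def test_unit_stretch_deviation_gives_unit_factor(self):
        dev = WarpDeviationSeries(reference="x", values=np.array([0.0, 1, 2, 3]))
        es = warp_elasticity(dev, smoothing_window=1)
        np.testing.assert_allclose(es.values[1:-1], 1.0)

    def test_constant_deviation_zero_elasticity(self):
        dev = WarpDeviationSeries(reference="x", values=np.full(20, 4.0))
        np.testing.assert_allclose(warp_elasticity(dev, 5).values, 0.0)

    def test_oversized_smoother_rejected(self):
        dev = WarpDeviationSeries(reference="x", values=np.zeros(10))
        with pytest.raises(ValueError, match="smoothing_window"):
            warp_elasticity(dev, smoothing_window=11)

    def test_scaled_values_use_tr(self):
        dev = WarpDeviationSeries(reference="x", values=np.arange(10.0), tr=0.72)
        es = warp_elasticity(dev, 3)
        np.testing.assert_allclose(es.values_scaled, es.values * 0.72)

    def test_segment_mean_recovers_stretch_factor(self):
        """Ensemble-average elasticity over a mid-series 30->20 segment
        interior ~ +1/3.  (The first/last segments are attenuated by the
        pinned path endpoints, so a mid-series segment is used.)"""
        acc = None
        n = 60
        for s in np.random.SeedSequence(99).spawn(n):
            x, y, _ = make_stretch_pair(seed=s)
            v = elasticity_for_pair(x, y, band_radius=89, smoothing_window=5).values
            acc = v if acc is None else acc + v
        acc /= n
        assert acc[65:85].mean() == pytest.approx(1 / 3, abs=0.10)

    def test_net_zero_over_full_run(self, rng):
        for _ in range(5):
            pair = TimeSeriesPair(rng.standard_normal(100), rng.standard_normal(100))
            dev = warp_deviation(pair, 20)
            es = warp_elasticity(dev, 5)
            assert abs(es.values.mean()) < 0.05

    def test_scale_equivariance(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        a = elasticity_for_pair(x, y, band_radius=12, smoothing_window=5)
        b = elasticity_for_pair(3.7 * x, 3.7 * y, band_radius=12, smoothing_window=5)
        np.testing.assert_allclose(a.values, b.values)

    def test_flat_series_degenerate_flag(self):
        es = elasticity_for_pair(np.zeros(20), np.ones(20), band_radius=5)
        assert es.degenerate
        np.testing.assert_allclose(es.values, 0.0)


class TestWindowRule:
    @pytest.mark.parametrize("fs, expected", [(1 / 0.72, 123), (0.5, 45)])
    def test_printed_anchors(self, fs, expected):
        assert window_size(fs, 0.01).n_window == expected

    def test_inverse_proportionality(self):
        n1 = window_size(1.0, 0.01).n_window
        n2 = window_size(1.0, 0.02).n_window
        assert n2 - 1 == pytest.approx((n1 - 1) / 2, abs=1)

    def test_rejects_nonpositive_and_nyquist_violation(self):
        with pytest.raises(ValueError):
            window_size(1.0, 0.0)
        with pytest.raises(ValueError):
            window_size(0.01, 0.01)


class TestPairwiseElasticity:
    def test_ordered_pair_count(self, rng):
        tc = rng.standard_normal((60, 3))
        out, pairs = pairwise_elasticity(tc, band_radius=10)
        assert out.shape == (60, 6)
        assert len(pairs) == 6

    def test_antisymmetry(self, rng):
        tc = rng.standard_normal((60, 3))
        out, pairs = pairwise_elasticity(tc, band_radius=10)
        lookup = {p: out[:, idx] for idx, p in enumerate(pairs)}
        for a, b in pairs:
            np.testing.assert_allclose(lookup[(a, b)], -lookup[(b, a)])

    def test_identical_components_zero(self, rng):
        col = rng.standard_normal(50)
        out, _ = pairwise_elasticity(np.column_stack([col, col]), band_radius=10)
        np.testing.assert_allclose(out, 0.0)

    def test_rejects_single_component(self, rng):
        with pytest.raises(ValueError):
            pairwise_elasticity(rng.standard_normal((50, 1)))


def test_parameter_recovery_scaled_ensemble():
    """Ensemble-mean elasticity correlates > 0.8 with the truth track."""
    truth = FIG_PLAN.truth_track("x")
    acc = None
    n = 200
    for s in np.random.SeedSequence(1).spawn(n):
        x, y, _ = make_stretch_pair(seed=s)
        v = elasticity_for_pair(x, y, band_radius=89).values
        acc = v if acc is None else acc + v
    acc /= n
    assert np.corrcoef(acc, truth)[0, 1] > 0.8
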