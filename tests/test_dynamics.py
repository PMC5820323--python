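import numpy as np
import pytest

from sinres.dynamics import (
    EmbeddingParams,
    LyapunovEstimate,
    classify_regime,
    delay_embed,
    estimate_delay,
    estimate_dimension,
    group_windows,
    max_lyapunov,
    network_lyapunov,
    sync_error,
)
from sinres.reservoir import StateTrajectory


def _traj(states, mu=1.0):
    return StateTrajectory(states=np.asarray(states, float), mu=mu, driven=False)


class TestSyncError:
    def test_identical_nodes_give_zero(self):
        states = np.tile(np.sin(np.arange(20.0))[:, None], (1, 5))
        prof = sync_error(_traj(states, mu=2.0))
        np.testing.assert_allclose(prof.delta, 0.0, atol=1e-15)
        assert prof.mean_delta < 1e-15

    def test_two_node_antisymmetric_case(self):
        # nodes at +a and -a: population std = a, delta = a / mu
        a, mu = 1.0, 2.0
        states = np.array([[a, -a]] * 4)
        prof = sync_error(_traj(states, mu=mu))
        np.testing.assert_allclose(prof.delta, a / mu)

    def test_homogeneity_in_state_scale(self):
        rng = np.random.default_rng(0)
        states = rng.normal(size=(10, 6))
        base = sync_error(_traj(states, mu=1.5)).delta
        scaled = sync_error(_traj(3.0 * states, mu=1.5)).delta
        np.testing.assert_allclose(scaled, 3.0 * base)

    def test_common_offset_invariance(self):
        # the mean field is subtracted, so a shared shift changes nothing
        rng = np.random.default_rng(1)
        states = rng.normal(size=(10, 6))
        shifted = states + 7.3
        np.testing.assert_allclose(
            sync_error(_traj(states)).delta,
            sync_error(_traj(shifted)).delta,
            atol=1e-12,
        )

    def test_mu_zero_rejected(self):
        with pytest.raises(ValueError):
            sync_error(_traj(np.zeros((3, 2)), mu=0.0))


class TestDelayEmbed:
    def test_dimension_one_returns_series(self):
        s = np.arange(10.0)
        X = delay_embed(s, EmbeddingParams(delay=3, dim=1))
        np.testing.assert_array_equal(X.ravel(), s)

    def test_point_count(self):
        s = np.arange(100.0)
        X = delay_embed(s, EmbeddingParams(delay=12, dim=4))
        assert X.shape == (64, 4)  # 100 - 3*12

    def test_coordinate_order(self):
        s = np.arange(10.0)
        X = delay_embed(s, EmbeddingParams(delay=2, dim=3))
        # first point: (s[4], s[2], s[0])
        np.testing.assert_array_equal(X[0], [4.0, 2.0, 0.0])

    def test_constant_series_collapses(self):
        X = delay_embed(np.ones(30), EmbeddingParams(delay=2, dim=3))
        assert np.ptp(X) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            delay_embed(np.arange(10.0), EmbeddingParams(delay=12, dim=4))


class TestDelayEstimate:
    def test_mackey_glass_delay_is_twelve(self, mg5000):
        assert estimate_delay(mg5000) == 12

    def test_sinusoid_dips_near_quarter_period(self):
        # the binned MI of a noise-free sinusoid flattens at the bin
        # resolution slightly before the quarter period
        period = 40
        s = np.sin(2 * np.pi * np.arange(4000) / period)
        lag = estimate_delay(s, max_lag=30)
        assert period / 8 <= lag <= period / 4 + 1

    def test_white_noise_floors_immediately(self):
        # the lagged MI of i.i.d. noise is flat at the estimator floor, so
        # jitter picks a minimum among the very first lags
        rng = np.random.default_rng(123)
        assert estimate_delay(rng.normal(size=4000), max_lag=20) <= 2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_delay(np.sin(np.arange(100.0)))


class TestDimensionEstimate:
    def test_mackey_glass_dimension(self, mg5000):
        # the noise-free discrete-map attractor unfolds by dimension 3-4
        assert estimate_dimension(mg5000, delay=12) in (3, 4)

    def test_sinusoid_needs_two_dimensions(self):
        s = np.sin(2 * np.pi * np.arange(3000) / 40)
        assert estimate_dimension(s, delay=10) == 2

    def test_line_embeds_in_one_dimension(self):
        assert estimate_dimension(np.linspace(0, 1, 2000), delay=5) == 1


class TestMaxLyapunov:
    def test_logistic_map_matches_ln_two(self, logistic_series):
        est = max_lyapunov(logistic_series, EmbeddingParams(delay=1, dim=2))
        assert est.valid
        assert est.lambda_max == pytest.approx(np.log(2), rel=0.10)

    def test_periodic_series_shows_no_divergence(self):
        s = np.sin(2 * np.pi * np.arange(3000) / 25)
        est = max_lyapunov(s, EmbeddingParams(delay=6, dim=2))
        assert (not est.valid) or est.lambda_max <= 1e-3

    def test_constant_series_invalid(self):
        est = max_lyapunov(np.ones(2000), EmbeddingParams(delay=1, dim=2))
        assert not est.valid


class TestNetworkLyapunov:
    def test_identical_nodes_equal_single_series(self, logistic_series):
        p = EmbeddingParams(delay=1, dim=2)
        states = np.tile(logistic_series[:3000, None], (1, 4))
        net = network_lyapunov(_traj(states), p, node_sample=None)
        single = max_lyapunov(logistic_series[:3000], p)
        assert net.valid
        assert net.lambda_max == pytest.approx(single.lambda_max, rel=1e-9)

    def test_max_over_mixed_nodes_picks_the_chaotic_one(self, logistic_series):
        p = EmbeddingParams(delay=1, dim=2)
        periodic = 0.5 + 0.4 * np.sin(2 * np.pi * np.arange(3000) / 25)
        states = np.column_stack([logistic_series[:3000], periodic])
        net = network_lyapunov(_traj(states), p, node_sample=None)
        assert net.lambda_max == pytest.approx(np.log(2), rel=0.10)

    def test_all_constant_nodes_invalid(self):
        net = network_lyapunov(
            _traj(np.ones((2000, 3))), EmbeddingParams(delay=1, dim=2), node_sample=None
        )
        assert not net.valid


class TestClassifyRegime:
    def test_constant_samples_are_fixed_point(self):
        lab = classify_regime(np.full(100, 0.7), mu=2.0)
        assert lab.label == "fixed_point"

    def test_clean_sinusoid_is_periodic(self):
        s = np.sin(2 * np.pi * np.arange(300) / 25)
        assert classify_regime(s, mu=1.0).label == "periodic"

    def test_logistic_samples_are_chaotic_with_their_exponent(self, logistic_series):
        lyap = LyapunovEstimate(np.log(2), True, (1, 5))
        lab = classify_regime(logistic_series[:300], lyap=lyap, mu=1.0)
        assert lab.label == "chaotic"

    def test_invalid_fit_on_large_signal_flags_hyper_chaos(self):
        lyap = LyapunovEstimate(0.0, False, (1, 5), "insufficient neighbors")
        rng = np.random.default_rng(0)
        lab = classify_regime(rng.uniform(-3, 3, 300), lyap=lyap, mu=3.0)
        assert lab.label == "hyper_chaotic_flag"

    def test_recurrence_test_rejects_aperiodic_samples(self, logistic_series):
        assert classify_regime(logistic_series[:300], mu=1.0).label == "chaotic"


class TestGroupWindows:
    def _labels(self, pattern):
        from sinres.dynamics import RegimeLabel

        return [
            RegimeLabel("periodic" if ch == "n" else "chaotic") for ch in pattern
        ]

    def test_all_chaotic_yields_nothing(self):
        grid = np.arange(5.0)
        assert group_windows(grid, self._labels("ccccc")) == []

    def test_single_run_becomes_one_interval(self):
        grid = np.round(np.arange(4.5, 5.75, 0.1), 2)
        labels = self._labels("cccnnnnnnnccc")
        assert group_windows(grid, labels) == [(4.8, 5.4)]

    def test_min_width_drops_singletons(self):
        grid = np.arange(6.0)
        labels = self._labels("nncncn")
        assert group_windows(grid, labels) == [(0.0, 1.0)]
        assert group_windows(grid, labels, min_width=1) == [
            (0.0, 1.0),
            (3.0, 3.0),
            (5.0, 5.0),
        ]
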