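import numpy as np
import pytest

from termwalk import (
    Arena,
    WalkSpec,
    generate_walk,
    regress_mu_on_turning,
    straightness_index,
    turning_angles,
    turning_frequency,
    vacf,
)
from tests.conftest import make_traj


def square_circuit(rate_hz=2.0):
    """Closed unit square sampled at corners and mid-edges; 4 corners in 4 s."""
    pts = [
        [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1],
        [0, 1], [0, 0.5], [0, 0], [0.5, 0],
    ]
    return make_traj(pts, rate_hz=rate_hz)


class TestStraightness:
    def test_straight_line_is_one(self):
        traj = make_traj(np.column_stack([np.arange(30.0), np.zeros(30)]), rate_hz=5.0)
        mean, series = straightness_index(traj)
        assert mean == pytest.approx(1.0)
        assert np.nanmin(series) == pytest.approx(1.0)

    def test_out_and_back_window_is_zero(self):
        x = np.concatenate([np.arange(13.0), np.arange(11.0, -1.0, -1.0)])
        traj = make_traj(np.column_stack([x, np.zeros_like(x)]), rate_hz=5.0)
        _, series = straightness_index(traj)
        assert series[0] == pytest.approx(0.0)

    def test_right_angle_legs(self):
        # two equal legs of an L: S = sqrt(2)/2
        xy = [[0, 0], [1, 0], [2, 0], [2, 1], [2, 2]]
        traj = make_traj(xy, rate_hz=1.0)
        mean, _ = straightness_index(traj, window_s=5.0, stride_s=1.0)
        assert mean == pytest.approx(np.sqrt(2) / 2)

    def test_too_short_rejected(self):
        traj = make_traj(np.zeros((10, 2)), rate_hz=5.0)
        with pytest.raises(ValueError):
            straightness_index(traj, window_s=5.0)

    def test_rigid_motion_invariance(self, rng):
        xy = np.cumsum(rng.normal(size=(100, 2)), axis=0)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = xy @ rot.T + [17.0, -4.0]
        a, _ = straightness_index(make_traj(xy, rate_hz=5.0))
        b, _ = straightness_index(make_traj(moved, rate_hz=5.0))
        assert a == pytest.approx(b, rel=1e-12)


class TestTurning:
    def test_collinear_motion_zero_angles(self):
        traj = make_traj(np.column_stack([np.arange(10.0), np.zeros(10)]), rate_hz=1.0)
        np.testing.assert_allclose(turning_angles(traj), 0.0)

    def test_square_circuit_right_angles(self):
        angles = turning_angles(square_circuit())
        nonzero = angles[np.abs(angles) > 1e-9]
        np.testing.assert_allclose(np.abs(nonzero), np.pi / 2)

    def test_reversal_is_pi(self):
        traj = make_traj([[0, 0], [1, 0], [0, 0]], rate_hz=1.0)
        assert turning_angles(traj)[0] == pytest.approx(np.pi)

    def test_square_turning_frequency(self):
        # 4 corners traversed in 4 s with threshold pi/4: 1 turn per second
        assert turning_frequency(square_circuit(), np.pi / 4) == pytest.approx(1.0)

    def test_zero_threshold_upper_bound(self, rng):
        xy = np.cumsum(rng.normal(size=(50, 2)), axis=0)
        traj = make_traj(xy, rate_hz=5.0)
        assert turning_frequency(traj, 0.0) <= (len(traj) - 2) / traj.duration_s


class TestVacf:
    def test_lag_zero_is_one(self, rng):
        traj = make_traj(np.cumsum(rng.normal(size=(200, 2)), axis=0), rate_hz=5.0)
        lags, cv = vacf(traj, max_lag_s=2.0)
        assert cv[0] == pytest.approx(1.0)
        assert lags[0] == 0.0

    def test_constant_velocity_stays_one(self):
        traj = make_traj(np.column_stack([np.arange(100.0), np.arange(100.0)]), rate_hz=5.0)
        _, cv = vacf(traj, max_lag_s=3.0)
        np.testing.assert_allclose(cv, 1.0, atol=1e-12)

    def test_iid_headings_decorrelate_immediately(self, rng):
        # Monte-Carlo oracle: independent unit steps have zero-mean dot products
        theta = rng.uniform(-np.pi, np.pi, 10_000)
        xy = np.cumsum(np.column_stack([np.cos(theta), np.sin(theta)]), axis=0)
        _, cv = vacf(make_traj(xy, rate_hz=5.0), max_lag_s=1.0)
        assert np.abs(cv[1:]).max() < 0.05

    def test_persistent_walker_decays_slower(self):
        base = dict(model="TPL", mu=1.5, l_min=0.5, l_max=20.0, speed=2.0,
                    jitter_sd=0.0, duration_s=600.0)
        unif = generate_walk(WalkSpec(**base, heading_model="uniform"), seed=5)
        pers = generate_walk(
            WalkSpec(**base, heading_model="wrapped_normal", heading_kappa=50.0), seed=5
        )
        _, cv_u = vacf(unif, max_lag_s=2.0)
        _, cv_p = vacf(pers, max_lag_s=2.0)
        assert cv_p[1:].mean() > cv_u[1:].mean()

    def test_stationary_input_rejected(self):
        traj = make_traj(np.zeros((50, 2)), rate_hz=5.0)
        with pytest.raises(ValueError, match="stationary"):
            vacf(traj, max_lag_s=1.0)


class TestRegression:
    def test_exact_line(self):
        pts = [(x, 2 * x + 1) for x in (0.0, 1.0, 2.0, 3.0)]
        slope, intercept, r2 = regress_mu_on_turning(pts)
        assert (slope, intercept, r2) == (
            pytest.approx(2.0), pytest.approx(1.0), pytest.approx(1.0)
        )

    def test_constant_response(self):
        slope, intercept, r2 = regress_mu_on_turning([(0, 5.0), (1, 5.0), (2, 5.0)])
        assert slope == 0.0 and intercept == 5.0 and r2 == 0.0

    def test_hand_computed_ols(self):
        # OLS on {(0,1),(1,2),(2,2)}: slope 1/2, intercept 7/6, R^2 = 3/4
        slope, intercept, r2 = regress_mu_on_turning([(0, 1.0), (1, 2.0), (2, 2.0)])
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(7 / 6)
        assert r2 == pytest.approx(0.75)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant predictor"):
            regress_mu_on_turning([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])
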