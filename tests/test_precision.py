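import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radonflow import (
    angle_change_for_dv,
    dv_from_angle_change,
    finest_detectable_angle,
    k_from_resolutions,
    max_streak_count,
    precision_report,
    rescaled_angle,
    single_streak_precision,
    speed_factor,
    streak_extents,
)


class TestAcquisitionRescaling:
    def test_worked_example_30_percent_speedup(self):
        assert rescaled_angle(60.0, 1.3) == pytest.approx(53.11, abs=0.01)

    def test_worked_example_factor_to_45(self):
        assert speed_factor(60.0, 45.0) == pytest.approx(1.73, abs=0.005)

    def test_identity_factor(self):
        assert speed_factor(45.0, 45.0) == 1.0
        assert rescaled_angle(37.0, 1.0) == pytest.approx(37.0)

    def test_slowdown_factor(self):
        assert speed_factor(30.0, 60.0) == pytest.approx(1.0 / 3.0)

    def test_mutual_inverse(self):
        k = speed_factor(60.0, 45.0)
        assert rescaled_angle(60.0, k) == pytest.approx(45.0, abs=1e-9)

    @pytest.mark.parametrize("theta", np.arange(5.0, 90.0, 5.0))
    def test_tan_theta_factor_reaches_45(self, theta):
        assert rescaled_angle(theta, math.tan(math.radians(theta))) == pytest.approx(
            45.0, abs=1e-9
        )

    def test_k_from_resolutions(self):
        assert k_from_resolutions(0.5, 0.5, 1.0, 1.0) == 1.0
        assert k_from_resolutions(0.5, 0.5, 1.0, 0.5) == 2.0
        # the two printed acquisitions of the same vessel
        assert k_from_resolutions(0.23, 0.47, 1.37, 0.9) == pytest.approx(3.11, abs=0.01)

    @pytest.mark.parametrize("args", [(0, 45), (45, 90), (-10, 45)])
    def test_speed_factor_domain(self, args):
        with pytest.raises(ValueError):
            speed_factor(*args)


class TestPixelResolutionLimits:
    @pytest.mark.parametrize(
        "theta0, w, h, expected",
        [
            (45.0, 300, 100, (100, 100)),
            (45.0, 100, 100, (100, 100)),
            (30.0, 300, 100, (58, 100)),
            (0.0, 300, 100, (1, 100)),
            (90.0, 300, 100, (300, 1)),
        ],
    )
    def test_streak_extents(self, theta0, w, h, expected):
        assert streak_extents(theta0, w, h) == expected

    def test_single_streak_precision_square(self):
        # one-pixel endpoint offset on a 100x100 streak
        assert single_streak_precision(100, 100) == pytest.approx(
            math.degrees(math.atan(100 / 99)) - 45.0, abs=1e-12
        )
        assert single_streak_precision(100, 100) == pytest.approx(0.288, abs=1e-3)

    def test_single_streak_precision_small(self):
        assert single_streak_precision(1, 2) == pytest.approx(
            45.0 - math.degrees(math.atan(0.5)), abs=1e-12
        )
        assert single_streak_precision(1, 2) == pytest.approx(18.43, abs=0.01)

    @pytest.mark.parametrize("a, k", [(10, 5), (7, 3), (20, 2)])
    def test_branch_symmetry(self, a, k):
        # mirrored geometry: (k*a, a) second branch == (a, k*a) first branch
        assert single_streak_precision(k * a, a) == pytest.approx(
            single_streak_precision(a, k * a), abs=1e-12
        )

    def test_single_streak_precision_domain(self):
        with pytest.raises(ValueError):
            single_streak_precision(1, 1)  # ws<=hs needs hs>=2

    def test_max_streak_count_spatial_branch(self):
        # 300 px at 1.19 um/px, 4 um spacing -> floor(357/4)
        assert max_streak_count(300, 100, 1.19, 1.0, ws=58, hs=100, ds=4.0) == 89
        assert max_streak_count(100, 100, 1.0, 1.0, ws=50, hs=100, ds=100.0) == 1

    def test_max_streak_count_temporal_branch(self):
        # h*dt = 100 ms = 10 * dt_streak
        assert (
            max_streak_count(100, 100, 1.0, 1.0, ws=100, hs=60, ds=4.0, dt_streak=0.01)
            == 10
        )

    def test_max_streak_count_floors_at_one_with_warning(self):
        with pytest.warns(UserWarning, match="too small"):
            assert max_streak_count(10, 100, 0.1, 1.0, ws=5, hs=100, ds=50.0) == 1

    def test_max_streak_count_inconsistent_extents(self):
        with pytest.raises(ValueError, match="inconsistent"):
            max_streak_count(100, 100, 1.0, 1.0, ws=50, hs=60, ds=4.0)

    def test_finest_detectable_angle(self):
        assert finest_detectable_angle(0.288, 89) == pytest.approx(0.0032, abs=2e-4)
        assert finest_detectable_angle(0.5, 1) == 0.5
        assert finest_detectable_angle(0.5, 10) == 2 * finest_detectable_angle(0.5, 20)

    def test_precision_report_composition(self):
        rep = precision_report(45.0, 300, 100, dx=1.19, dt=1.0, ds=4.0)
        assert (rep.ws, rep.hs) == (100, 100)
        assert rep.ns == 89
        assert rep.delta_n == pytest.approx(rep.delta_s1 / 89)
        assert rep.delta_n <= rep.delta_s1

    @pytest.mark.parametrize("theta0", np.arange(5.0, 90.0, 10.0))
    def test_delta_n_never_exceeds_delta_s1(self, theta0):
        rep = precision_report(theta0, 300, 100, dx=1.19, dt=1.0)
        assert rep.delta_n <= rep.delta_s1


class TestVelocityChangeCalculus:
    def test_small_step_at_45(self):
        assert dv_from_angle_change(45.0, 45.1) == pytest.approx(0.0035, abs=5e-5)

    def test_near_horizontal_step(self):
        assert abs(dv_from_angle_change(83.0, 82.4)) == pytest.approx(0.08, abs=0.005)

    def test_no_change(self):
        assert dv_from_angle_change(37.0, 37.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            dv_from_angle_change(0.0, 1.0)

    def test_angle_step_for_dv(self):
        assert angle_change_for_dv(45.0, 0.0035) == pytest.approx(0.1, abs=0.005)
        assert angle_change_for_dv(30.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_dv_domain(self):
        with pytest.raises(ValueError):
            angle_change_for_dv(45.0, -1.0)

    @pytest.mark.parametrize("dv", [0.001, 0.01, 0.1])
    def test_45_degrees_most_tolerant(self, dv):
        # the angle step affordable for a given dv/v peaks at 45 degrees;
        # exact in the small-change limit (for large dv the optimum drifts
        # toward arctan(1/sqrt(1+dv)), e.g. ~37 deg at dv = 0.8)
        deltas = {t: angle_change_for_dv(float(t), dv) for t in range(10, 81, 5)}
        assert max(deltas, key=deltas.get) == 45


@settings(derandomize=True, max_examples=80)
@given(theta0=st.floats(1.0, 89.0), dv=st.floats(-0.9, 4.0))
def test_dv_and_angle_step_are_mutual_inverses(theta0, dv):
    delta = angle_change_for_dv(theta0, dv)
    theta1 = theta0 + delta if dv >= 0 else theta0 - delta
    assert dv_from_angle_change(theta0, theta1) == pytest.approx(dv, abs=1e-9)
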