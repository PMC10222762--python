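import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dissopk.dissolution import (
    DissolutionProfile,
    DissolutionSpec,
    ProfileError,
    SpecPoint,
    WeibullParams,
    check_spec,
    derive_spec,
    er_reference_spec,
    fit_release,
    q_at,
    weibull_release,
)

GRID = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0])

weibull_params = st.builds(
    WeibullParams,
    fmax=st.floats(min_value=10.0, max_value=100.0),
    td=st.floats(min_value=0.5, max_value=50.0),
    b=st.floats(min_value=0.2, max_value=5.0),
)


class TestWeibullRelease:
    def test_zero_time(self):
        assert weibull_release(0.0, WeibullParams(fmax=80, td=5, b=1.3)) == 0.0

    def test_characteristic_time(self):
        """At t = td the curve has released 1 - 1/e of fmax."""
        p = WeibullParams(fmax=100, td=9, b=2.2)
        assert weibull_release(9.0, p) == pytest.approx(100 * (1 - math.exp(-1)), rel=1e-12)

    def test_first_order_closed_form(self):
        p = WeibullParams(fmax=95, td=9, b=1)
        assert weibull_release(24.0, p) == pytest.approx(95 * (1 - math.exp(-24 / 9)), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_release(-0.5, WeibullParams(fmax=95, td=9, b=1))

    @given(p=weibull_params)
    def test_monotone_and_bounded(self, p):
        t = np.linspace(0, 100, 200)
        f = weibull_release(t, p)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all(f <= p.fmax + 1e-12)


class TestFitRelease:
    def test_noise_free_round_trip(self):
        truth = WeibullParams(fmax=92.0, td=7.4, b=0.85)
        prof = DissolutionProfile(times=GRID, q=weibull_release(GRID, truth)[None, :])
        fitted, rmse = fit_release(prof)
        assert fitted.fmax == pytest.approx(truth.fmax, rel=1e-4)
        assert fitted.td == pytest.approx(truth.td, rel=1e-4)
        assert fitted.b == pytest.approx(truth.b, rel=1e-4)
        assert rmse < 1e-6

    def test_noisy_recovery_within_10_percent(self):
        rng = np.random.default_rng(1)
        truth = WeibullParams(fmax=90.0, td=8.0, b=1.0)
        clean = weibull_release(GRID, truth)
        q = np.maximum.accumulate(clean * rng.lognormal(0, 0.02, GRID.size))
        fitted, _ = fit_release(DissolutionProfile(times=GRID, q=q[None, :]))
        assert fitted.fmax == pytest.approx(truth.fmax, rel=0.10)
        assert fitted.td == pytest.approx(truth.td, rel=0.10)
        assert fitted.b == pytest.approx(truth.b, rel=0.10)

    def test_degenerate_profile_rejected(self):
        prof = DissolutionProfile(times=GRID, q=np.zeros((1, GRID.size)))
        with pytest.raises(ProfileError):
            fit_release(prof)

    def test_too_few_points_rejected(self):
        prof = DissolutionProfile(times=GRID[:3], q=np.array([[10.0, 20.0, 30.0]]))
        with pytest.raises(ProfileError):
            fit_release(prof)


class TestQAt:
    def test_exact_at_samples_and_interpolation(self):
        prof = DissolutionProfile(times=np.array([1.0, 2.0, 4.0]), q=np.array([[10.0, 20.0, 32.0]]))
        assert q_at(prof, 2.0) == 20.0
        assert q_at(prof, 1.5) == pytest.approx(15.0)
        assert q_at(prof, 3.0) == pytest.approx(26.0)
        assert q_at(prof, 0.0) == 0.0

    def test_extrapolation_rejected(self):
        prof = DissolutionProfile(times=np.array([1.0, 2.0]), q=np.array([[10.0, 20.0]]))
        with pytest.raises(ProfileError):
            q_at(prof, 3.0)


class TestCheckSpec:
    def _profile(self, values):
        return DissolutionProfile(
            times=np.array([1.0, 4.0, 8.0, 16.0, 24.0]), q=np.array([values], dtype=float)
        )

    def test_window_midpoints_pass(self):
        """A profile through the middle of every ER window passes them all."""
        per_point, overall = check_spec(self._profile([15, 43, 61, 83, 90]), er_reference_spec())
        assert overall and all(per_point.values())

    def test_first_hour_burst_fails(self):
        per_point, overall = check_spec(self._profile([25, 43, 61, 83, 90]), er_reference_spec())
        assert not overall
        assert per_point[1.0] is False
        assert per_point[4.0] is True

    def test_strict_boundary_at_first_hour(self):
        """Exactly 20% at 1 h fails the strict '< 20%' limit."""
        per_point, _ = check_spec(self._profile([20, 43, 61, 83, 90]), er_reference_spec())
        assert per_point[1.0] is False

    def test_inclusive_boundaries_elsewhere(self):
        per_point, overall = check_spec(self._profile([15, 38, 50, 72, 80]), er_reference_spec())
        assert overall

    def test_uncoverable_spec_time_rejected(self):
        prof = DissolutionProfile(times=np.array([1.0, 4.0]), q=np.array([[10.0, 40.0]]))
        with pytest.raises(ProfileError):
            check_spec(prof, er_reference_spec())


class TestDeriveSpec:
    def _weibull_profile(self, td):
        q = weibull_release(GRID, WeibullParams(fmax=95, td=td, b=0.9))
        return DissolutionProfile(times=GRID, q=q[None, :])

    def test_identical_profiles_degenerate_window(self):
        p = self._weibull_profile(7.1)
        spec = derive_spec([p, p], margin=0.0)
        mid = spec.points[1]
        assert mid.upper - mid.lower <= 2.0  # floor/ceil rounding only

    def test_constructed_window_spans_profiles(self):
        """Profiles whose 4-h values span 38-48% give that window back."""
        profiles = []
        for q4 in (38.0, 43.0, 48.0):
            q = np.array([[q4 * 0.3, q4 * 0.6, q4, q4 * 1.4, q4 * 1.6, q4 * 1.75, q4 * 1.85, min(q4 * 1.9, 100)]])
            profiles.append(DissolutionProfile(times=GRID, q=q))
        spec = derive_spec(profiles, margin=0.0)
        four_h = next(p for p in spec.points if p.time_h == 4.0)
        assert four_h.lower == 38.0
        assert four_h.upper == 48.0

    def test_single_profile_rejected(self):
        with pytest.raises(ProfileError):
            derive_spec([self._weibull_profile(7.0)])

    def test_incompatible_grids_rejected(self):
        a = self._weibull_profile(7.0)
        q = weibull_release(GRID[:-1], WeibullParams(fmax=95, td=8, b=0.9))
        b = DissolutionProfile(times=GRID[:-1], q=q[None, :])
        with pytest.raises(ProfileError):
            derive_spec([a, b])

    @pytest.mark.parametrize("margin", [0.0, 2.0, 5.0])
    def test_every_input_passes_derived_spec(self, margin):
        """check_spec(derive_spec(P, m), p) holds for all p in P, m >= 0."""
        profiles = [self._weibull_profile(td) for td in (5.5, 7.1, 9.0)]
        spec = derive_spec(profiles, margin=margin)
        for p in profiles:
            _, ok = check_spec(p, spec)
            assert ok


class TestProfileValidation:
    def test_decreasing_series_beyond_tolerance_rejected(self):
        q = np.array([[10.0, 30.0, 25.0, 40.0, 50.0, 60.0, 70.0, 80.0]])
        with pytest.raises(ProfileError):
            DissolutionProfile(times=GRID, q=q)

    def test_small_dips_tolerated_and_overshoot_flagged(self):
        q = np.array([[10.0, 30.0, 29.0, 40.0, 50.0, 60.0, 70.0, 102.0]])
        prof = DissolutionProfile(times=GRID, q=q)
        assert prof.overshoot_flag

    def test_spec_point_needs_a_bound(self):
        with pytest.raises(ValueError):
            SpecPoint(time_h=1.0)

    def test_spec_times_must_increase(self):
        with pytest.raises(ValueError):
            DissolutionSpec(points=(SpecPoint(4.0, upper=40), SpecPoint(1.0, upper=20)))
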