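import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dissopk as dk
from dissopk.datasets import BIOPREDICTIVE_RUNS_REPORTED, CONVOLUTION_PE_TABLE
from dissopk.dissolution import DissolutionProfile, WeibullParams, weibull_release
from dissopk.ivivc import IVIVCFitError, OralKernel, _uir_interval_integrals


def _staircase_observed(derived, t, frac, dose=50.0):
    """Exact convolution of a piecewise-constant input with the UIR."""
    rates = dose * np.diff(frac) / np.diff(t)
    M = _uir_interval_integrals(derived, t[1:], t)
    return dk.PlasmaProfile(times_h=t, conc_ng_ml=np.concatenate(([0.0], M @ rates)))


class TestDeconvolution:
    def test_step_input_round_trip(self, derived):
        """Deconvolving the convolution of a known step input recovers it."""
        t = np.arange(0.0, 48.001, 0.25)
        frac = np.clip(t / 6.0, 0, 1)  # zero-order release over 6 h
        obs = _staircase_observed(derived, t, frac)
        fabs = dk.deconvolve_fabs(obs, derived, dose_mg=50.0)
        assert np.max(np.abs(fabs.fabs - frac)) <= 1e-3

    def test_bolus_observed_gives_immediate_absorption(self, derived):
        """An IV-bolus-shaped curve deconvolves to absorption completed at
        the staircase resolution of the first couple of intervals."""
        t = np.arange(0.0, 48.001, 0.5)
        obs = dk.PlasmaProfile(
            times_h=t, conc_ng_ml=dk.unit_impulse_response(derived, t, dose_mg=50.0)
        )
        fabs = dk.deconvolve_fabs(obs, derived, dose_mg=50.0)
        assert fabs.fabs[1] >= 0.9
        # essentially no further absorption after the first interval
        assert fabs.fabs[-1] - fabs.fabs[1] <= 0.05

    def test_weibull_input_time_scale_recovery(self, derived):
        """The 63.2% time of a first-order input is recovered within 5%."""
        t = np.arange(0.0, 72.001, 0.25)
        frac = weibull_release(t, WeibullParams(fmax=100, td=9, b=1)) / 100
        obs = _staircase_observed(derived, t, frac)
        fabs = dk.deconvolve_fabs(obs, derived, dose_mg=50.0)
        td_recovered = np.interp(1 - np.exp(-1), fabs.fabs, fabs.times_h)
        assert td_recovered == pytest.approx(9.0, rel=0.05)

    def test_sparse_grid_rejected(self, derived):
        obs = dk.PlasmaProfile(times_h=np.array([0.0, 1.0, 2.0]), conc_ng_ml=np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            dk.deconvolve_fabs(obs, derived, dose_mg=50.0)


class TestOralKernelDeconvolution:
    def test_release_recovery_through_absorption_chain(self, derived, absorption, observed_plasma):
        """Mechanistic deconvolution recovers the in vivo *release*, not the
        lagged central input, from a CAT-simulated curve."""
        kernel = OralKernel.from_cat(derived, absorption)
        fabs = dk.deconvolve_fabs(observed_plasma, derived, dose_mg=50.0, kernel=kernel)
        true = weibull_release(fabs.times_h, WeibullParams(fmax=95, td=7.1, b=0.9)) / 100
        assert np.max(np.abs(fabs.fabs - true)) <= 0.02


class TestFitIVIVC:
    def _fabs(self, frac_fn):
        t = np.arange(0.0, 24.001, 1.0)
        return dk.InputFunction(times_h=t, fabs=frac_fn(t))

    def _fdiss(self, td=8.0, b=1.0, fmax=95.0):
        t = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0])
        q = weibull_release(t, WeibullParams(fmax=fmax, td=td, b=b))
        return DissolutionProfile(times=t, q=q[None, :])

    def test_identity_correlation(self):
        fdiss = self._fdiss()
        fabs = dk.InputFunction(
            times_h=np.concatenate(([0.0], fdiss.times)),
            fabs=np.concatenate(([0.0], fdiss.mean_q())) / 100,
        )
        m = dk.fit_ivivc(fabs, fdiss)
        assert m.slope == pytest.approx(1.0, abs=1e-9)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_proportional_correlation(self):
        fdiss = self._fdiss()
        fabs = dk.InputFunction(
            times_h=np.concatenate(([0.0], fdiss.times)),
            fabs=0.9 * np.concatenate(([0.0], fdiss.mean_q())) / 100,
        )
        m = dk.fit_ivivc(fabs, fdiss)
        assert m.slope == pytest.approx(0.9, abs=1e-9)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)

    def test_time_scale_recovery(self):
        """In vivo lagging a densely sampled in vitro profile by a factor
        1.5 is recovered within 5%."""
        t_vitro = np.arange(0.25, 24.01, 0.25)
        q = weibull_release(t_vitro, WeibullParams(fmax=95, td=6.0, b=1.0))
        fdiss = DissolutionProfile(times=t_vitro, q=q[None, :])
        t = np.arange(0.0, 24.001, 1.0)
        fabs_vals = weibull_release(t / 1.5, WeibullParams(fmax=95, td=6.0, b=1.0)) / 100
        fabs = dk.InputFunction(times_h=t, fabs=fabs_vals)
        m = dk.fit_ivivc(fabs, fdiss, time_scaling=True)
        assert m.time_scale == pytest.approx(1.5, rel=0.05)

    def test_too_few_matched_points_rejected(self):
        fdiss = self._fdiss()
        fabs = dk.InputFunction(times_h=np.array([0.0, 30.0]), fabs=np.array([0.0, 1.0]))
        with pytest.raises(IVIVCFitError):
            dk.fit_ivivc(fabs, fdiss)


class TestConvolvePredict:
    def test_zero_dissolution_gives_zero_profile(self, derived):
        t = np.array([1.0, 2.0, 4.0, 8.0])
        fdiss = DissolutionProfile(times=t, q=np.zeros((1, 4)))
        model = dk.IVIVCModel(slope=1.0, intercept=0.0)
        prof = dk.convolve_predict(model, fdiss, derived, dose_mg=50.0)
        assert np.all(prof.conc_ng_ml == 0.0)

    def test_instant_dissolution_matches_uir(self, derived):
        """A step to 100% at t ~ 0 reproduces the bolus response shape."""
        t_grid = np.arange(0.0, 48.001, 0.5)
        fdiss = DissolutionProfile(
            times=np.array([0.01, 1.0, 24.0]), q=np.array([[100.0, 100.0, 100.0]])
        )
        model = dk.IVIVCModel(slope=1.0, intercept=0.0)
        prof = dk.convolve_predict(model, fdiss, derived, dose_mg=50.0, t_grid=t_grid)
        uir = dk.unit_impulse_response(derived, t_grid[1:], dose_mg=50.0)
        assert np.max(np.abs(prof.conc_ng_ml[1:] - uir) / uir[0]) <= 0.01

    def test_deconvolve_convolve_consistency(self, derived):
        """Feeding the deconvolved input back as a 'dissolution' profile
        reproduces the observed curve within 2% sup-norm."""
        t = np.arange(0.0, 48.001, 0.25)
        frac = weibull_release(t, WeibullParams(fmax=95, td=9, b=1)) / 100
        obs = _staircase_observed(derived, t, frac)
        fabs = dk.deconvolve_fabs(obs, derived, dose_mg=50.0)
        fdiss = DissolutionProfile(times=fabs.times_h[1:], q=100 * fabs.fabs[1:][None, :])
        model = dk.IVIVCModel(slope=1.0, intercept=0.0)
        pred = dk.convolve_predict(model, fdiss, derived, dose_mg=50.0, t_grid=t)
        assert np.max(np.abs(pred.conc_ng_ml - obs.conc_ng_ml)) <= 0.02 * obs.conc_ng_ml.max()

    def test_predicted_auc_closed_form(self, derived):
        """Complete absorption implies AUC(0-inf) = dose/(Cl*BW)."""
        t_grid = np.arange(0.0, 400.001, 0.5)
        fdiss = DissolutionProfile(
            times=np.array([1.0, 2.0, 4.0, 8.0, 12.0]),
            q=np.array([[20.0, 40.0, 70.0, 95.0, 100.0]]),
        )
        model = dk.IVIVCModel(slope=1.0, intercept=0.0)
        prof = dk.convolve_predict(model, fdiss, derived, dose_mg=50.0, t_grid=t_grid)
        auc = np.trapezoid(prof.conc_ng_ml, prof.times_h)
        expected = 50.0 / (derived.cl_l_h_kg * derived.body_weight_kg) * 1000
        assert auc == pytest.approx(expected, rel=0.01)


class TestPredictionError:
    @pytest.mark.parametrize(
        "obs, pred, expected",
        [(77.23, 83.48, -8.09), (1866.80, 1596.30, 14.49), (100.0, 100.0, 0.0)],
    )
    def test_reported_pairs(self, obs, pred, expected):
        assert dk.prediction_error(obs, pred) == pytest.approx(expected, abs=0.005)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            dk.prediction_error(0.0, 10.0)

    def test_rounding_is_half_up(self):
        assert dk.prediction_error(100.0, 99.875) == 0.13  # 0.125 rounds up


class TestClassification:
    @pytest.mark.parametrize(
        "pe_cmax, pe_auc, expected",
        [(-8.09, 4.48, True), (-25.40, -1.90, False), (3.09, 14.49, False),
         (10.0, 10.0, True), (-10.0, 10.0, True), (10.01, 0.0, False)],
    )
    def test_threshold_rule(self, pe_cmax, pe_auc, expected):
        assert dk.classify_biopredictive(pe_cmax, pe_auc) is expected

    @given(
        pe_c=st.floats(min_value=-50, max_value=50),
        pe_a=st.floats(min_value=-50, max_value=50),
        shrink=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_in_absolute_error(self, pe_c, pe_a, shrink):
        """Shrinking |PE| never turns a biopredictive verdict negative."""
        if dk.classify_biopredictive(pe_c, pe_a):
            assert dk.classify_biopredictive(shrink * pe_c, shrink * pe_a)


class TestRankMethods:
    def test_reported_pe_table_flags_runs_1_3_4_9(self):
        """Applying the +/-10% rule to the reported PE values flags exactly
        the four runs reported as biopredictive."""
        flagged = [
            int(row.run)
            for row in CONVOLUTION_PE_TABLE.itertuples()
            if dk.classify_biopredictive(row.cmax_pe_reported, row.auc_pe_reported)
        ]
        assert flagged == BIOPREDICTIVE_RUNS_REPORTED

    @staticmethod
    def _row(app, speed, product, pe_c, pe_a):
        return {"apparatus": app, "speed_rpm": speed, "product": product,
                "pe_cmax": pe_c, "pe_auc": pe_a}

    def test_condition_passing_all_products_ranks_first(self):
        rows = []
        for product in ("Reference", "Generic #1", "Generic #2"):
            rows.append(self._row("paddle_sinker", 50, product, 3.0, 2.0))
            rows.append(self._row("basket", 50, product, 15.0, 2.0))
            rows.append(self._row("paddle", 100, product, -12.0, 11.0))
        ranking = dk.rank_methods(rows)
        top = ranking.iloc[0]
        assert top["apparatus"] == "paddle_sinker" and top["speed_rpm"] == 50
        assert bool(top["all_biopredictive"])
        assert not ranking.iloc[1]["all_biopredictive"]

    def test_ties_broken_by_apparatus_then_speed(self):
        rows = [
            self._row(app, speed, "Reference", 5.0, 5.0)
            for app in ("paddle", "basket")
            for speed in (100, 50)
        ]
        ranking = dk.rank_methods(rows)
        order = list(zip(ranking["apparatus"], ranking["speed_rpm"]))
        assert order == [("basket", 50), ("basket", 100), ("paddle", 50), ("paddle", 100)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dk.rank_methods([])
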