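import numpy as np
import pytest

from multicup.dissolution_models import DoubleWeibullParams, eval_double_weibull
from multicup.errors import DomainError, InsufficientDataError, ValidationError
from multicup.ivivc import (
    IVIVCParams,
    UIRParams,
    convolve_predict_plasma,
    deconvolve,
    fit_correlation,
    fit_uir,
    mean_absolute_pe,
    pe_report,
    predict_fabs,
    prediction_error,
    validate_ivivc,
)
from multicup.kernels import convolve_pwc_rate, polyexp
from multicup.synthetic_data import PKDispositionParams, add_noise, simulate_plasma
from multicup.timeseries import TimeSeries

KERNEL = UIRParams(terms=((6500.0, 1.1), (2800.0, 0.28)))
OBS_TIMES = np.array([0.083, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0,
                      6.0, 8.0, 10.0])
W_HOURS = DoubleWeibullParams(F_inf=0.9, f1=0.6, MDT1=0.5, b1=1.2,
                              MDT2=2.0, b2=1.5)

# printed observed/predicted (Cmax, AUC) pairs used as fixed input data
DGIM_CMAX = [(41300.0, 45529.0), (48100.0, 54269.0), (45400.0, 48488.0)]
DGIM_AUC = [(112853.0, 114652.0), (146143.0, 144456.0), (135015.0, 135032.0)]
USP2_CMAX = [(41300.0, 45702.0), (48100.0, 58480.0), (45400.0, 57044.0)]
USP2_AUC = [(112853.0, 108727.0), (146144.0, 149731.0), (135015.0, 126032.0)]


class TestFitUIR:
    def test_two_exponential_recovery(self):
        dose = 2.5
        t = OBS_TIMES
        iv = TimeSeries(t, dose * polyexp(KERNEL.terms, t), time_unit="h")
        uir, diag = fit_uir(iv, dose)
        assert diag["order"] == 2
        for (a, lam), (a0, lam0) in zip(uir.terms, KERNEL.terms):
            assert a == pytest.approx(a0, rel=0.01)
            assert lam == pytest.approx(lam0, rel=0.01)

    def test_mono_exponential_order_selection(self):
        dose = 2.5
        t = OBS_TIMES
        clean = dose * 4000.0 * np.exp(-0.5 * t)
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            iv = TimeSeries(t, clean * rng.lognormal(0, 0.05, t.size),
                            time_unit="h")
            uir, diag = fit_uir(iv, dose, n_starts=3, seed=seed)
            hits += diag["order"] == 1
        assert hits / n_rep >= 0.95

    def test_lambda_bounds_respected(self):
        t = OBS_TIMES
        iv = TimeSeries(t, 100 * np.exp(-0.5 * t), time_unit="h")
        uir, _ = fit_uir(iv, 1.0)
        assert all(lam > 0 for _, lam in uir.terms)

    def test_invalid_uir_terms(self):
        with pytest.raises(ValidationError):
            UIRParams(terms=((100.0, -0.5),))
        with pytest.raises(ValidationError):
            UIRParams(terms=tuple((1.0, 1.0) for _ in range(4)))


class TestDeconvolve:
    def test_staircase_round_trip_identity(self):
        # oral curve built from a known staircase input on the obs grid
        edges = np.concatenate(([0.0], OBS_TIMES))
        rng = np.random.default_rng(3)
        rates = rng.uniform(0, 5, OBS_TIMES.size)
        rates[-3:] = 0.0
        conc = convolve_pwc_rate(edges, rates, KERNEL.terms, OBS_TIMES)
        oral = TimeSeries(OBS_TIMES, conc, time_unit="h")
        dose = float(np.sum(rates * np.diff(edges))) / 0.8  # Fabs plateau 0.8
        fabs = deconvolve(oral, KERNEL, dose)
        expect = np.concatenate(([0.0], np.cumsum(rates * np.diff(edges)))) / dose
        np.testing.assert_allclose(fabs.value, expect, rtol=1e-6, atol=1e-9)

    def test_zero_curve_gives_zero_fabs(self):
        oral = TimeSeries(OBS_TIMES, np.zeros_like(OBS_TIMES), time_unit="h")
        fabs = deconvolve(oral, KERNEL, 10.0)
        np.testing.assert_array_equal(fabs.value, 0.0)

    def test_fabs_non_decreasing_from_zero(self):
        pk = PKDispositionParams(F_true=1.0)
        fabs_in = predict_fabs(IVIVCParams(0.9, 1.5, 0.0), W_HOURS,
                               np.arange(0, 10.01, 0.05))
        oral = simulate_plasma(fabs_in, pk, "oral", t_eval=OBS_TIMES)
        fabs = deconvolve(oral, KERNEL, pk.dose_oral)
        assert fabs.value[0] == 0.0
        assert np.all(np.diff(fabs.value) >= -1e-12)

    def test_convolve_deconvolve_round_trip_rmse(self):
        pk = PKDispositionParams(F_true=1.0)
        fabs_in = predict_fabs(IVIVCParams(0.95, 1.6, 0.0), W_HOURS,
                               np.arange(0, 10.01, 0.05))
        oral = simulate_plasma(fabs_in, pk, "oral", t_eval=OBS_TIMES)
        fabs = deconvolve(oral, KERNEL, pk.dose_oral)
        back = convolve_predict_plasma(fabs, KERNEL, pk.dose_oral,
                                       t_eval=OBS_TIMES)
        rmse = np.sqrt(np.mean((back.value - oral.value) ** 2))
        assert rmse < 0.01 * np.max(oral.value)


class TestCorrelation:
    def test_recovers_generator_parameters(self):
        """Published correlation parameters used as generator ground truth."""
        truth = IVIVCParams(AbsScale=0.9757, Tscale=1.629, Tshift=4.397e-5)
        t = OBS_TIMES
        fabs = predict_fabs(truth, W_HOURS, t)
        params, diag = fit_correlation([fabs], [W_HOURS])
        assert params.AbsScale == pytest.approx(0.9757, rel=0.01)
        assert params.Tscale == pytest.approx(1.629, rel=0.01)
        assert abs(params.Tshift) < 0.01

    def test_identity_mapping(self):
        t = OBS_TIMES
        fabs = TimeSeries(t, eval_double_weibull(W_HOURS, t), time_unit="h")
        params, _ = fit_correlation([fabs], [W_HOURS])
        assert params.AbsScale == pytest.approx(1.0, abs=1e-6)
        assert params.Tscale == pytest.approx(1.0, abs=1e-6)
        assert abs(params.Tshift) < 1e-6

    def test_pooling_beats_single_group(self):
        truth = IVIVCParams(AbsScale=0.95, Tscale=1.6, Tshift=0.0)
        w2 = DoubleWeibullParams(F_inf=0.8, f1=0.4, MDT1=0.7, b1=1.1,
                                 MDT2=2.5, b2=1.8)
        t = OBS_TIMES
        clean1 = predict_fabs(truth, W_HOURS, t)
        clean2 = predict_fabs(truth, w2, t)
        err_pooled, err_single = [], []
        for seed in range(200):
            f1 = add_noise(clean1, 0.05, seed=seed)
            f2 = add_noise(clean2, 0.05, seed=10_000 + seed)
            pooled, _ = fit_correlation([f1, f2], [W_HOURS, w2])
            single, _ = fit_correlation([f1], [W_HOURS])
            err_pooled.append(pooled.Tscale - truth.Tscale)
            err_single.append(single.Tscale - truth.Tscale)
        rmse_pooled = np.sqrt(np.mean(np.square(err_pooled)))
        rmse_single = np.sqrt(np.mean(np.square(err_single)))
        assert rmse_pooled < rmse_single

    def test_needs_training_group(self):
        with pytest.raises(InsufficientDataError):
            fit_correlation([], [])


class TestPredictFabs:
    def test_identity_params(self):
        t = np.linspace(0, 10, 21)
        out = predict_fabs(IVIVCParams(1.0, 1.0, 0.0), W_HOURS, t)
        np.testing.assert_allclose(out.value, eval_double_weibull(W_HOURS, t))

    def test_pre_shift_zero(self):
        out = predict_fabs(IVIVCParams(1.0, 1.0, 5.0), W_HOURS,
                           np.linspace(0, 4.9, 10))
        np.testing.assert_array_equal(out.value, 0.0)

    def test_matches_direct_formula(self):
        p = IVIVCParams(0.9757, 1.629, 4.397e-5)
        t = np.linspace(0, 10, 101)
        out = predict_fabs(p, W_HOURS, t)
        tau = p.Tscale * t - p.Tshift
        direct = np.where(tau > 0,
                          p.AbsScale * eval_double_weibull(W_HOURS,
                                                           np.maximum(tau, 0)),
                          0.0)
        np.testing.assert_allclose(out.value, direct, rtol=0, atol=1e-12)


class TestConvolvePredict:
    def test_step_fabs_gives_scaled_kernel(self):
        eps = 1e-8
        fabs = TimeSeries([0.0, eps, 10.0], [0.0, 1.0, 1.0], time_unit="h")
        t = np.linspace(0.1, 10, 30)
        out = convolve_predict_plasma(fabs, KERNEL, 10.0, t_eval=t)
        np.testing.assert_allclose(out.value,
                                   10.0 * polyexp(KERNEL.terms, t), rtol=1e-6)

    def test_grid_refinement_invariance(self):
        # a piecewise-linear Fabs gives the same closed-form result on any
        # refinement of its own breakpoints
        t_coarse = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 10.0])
        v_coarse = np.array([0.0, 0.3, 0.55, 0.8, 0.95, 1.0])
        t_fine = np.unique(np.concatenate([t_coarse,
                                           np.linspace(0, 10, 501)]))
        v_fine = np.interp(t_fine, t_coarse, v_coarse)
        t_eval = np.linspace(0.2, 10, 40)
        a = convolve_predict_plasma(TimeSeries(t_coarse, v_coarse,
                                               time_unit="h"),
                                    KERNEL, 10.0, t_eval=t_eval)
        b = convolve_predict_plasma(TimeSeries(t_fine, v_fine, time_unit="h"),
                                    KERNEL, 10.0, t_eval=t_eval)
        np.testing.assert_allclose(a.value, b.value, rtol=1e-6)

    def test_decreasing_fabs_rejected(self):
        fabs = TimeSeries([0.0, 1.0, 2.0], [0.0, 0.8, 0.5], time_unit="h")
        with pytest.raises(ValidationError):
            convolve_predict_plasma(fabs, KERNEL, 10.0)


class TestPredictionError:
    def test_printed_cmax_control(self):
        assert prediction_error(41300.0, 45529.0) == pytest.approx(10.24,
                                                                   abs=0.005)

    def test_equal_values(self):
        assert prediction_error(100.0, 100.0) == 0.0

    def test_printed_auc_negative_sign(self):
        assert prediction_error(112853.0, 108727.0) == pytest.approx(-3.66,
                                                                     abs=0.005)

    def test_opposite_convention(self):
        assert prediction_error(100.0, 110.0, convention="obs-pred") == \
            pytest.approx(-10.0)

    def test_nonpositive_observed(self):
        with pytest.raises(DomainError):
            prediction_error(0.0, 5.0)

    def test_every_printed_pe_reproduced(self):
        printed = {
            "dgim_cmax": (DGIM_CMAX, [10.24, 12.83, 6.80]),
            "dgim_auc": (DGIM_AUC, [1.59, -1.16, 0.01]),
            "usp2_cmax": (USP2_CMAX, [10.66, 21.58, 25.65]),
            "usp2_auc": (USP2_AUC, [-3.66, 2.45, -6.65]),
        }
        for name, (pairs, pes) in printed.items():
            for (obs, pred), pe in zip(pairs, pes):
                assert prediction_error(obs, pred) == pytest.approx(
                    pe, abs=0.02), name


class TestMeanAbsolutePE:
    def test_printed_cmax_mean(self):
        assert mean_absolute_pe([10.24, 12.83, 6.80]) == pytest.approx(
            9.96, abs=0.01)

    def test_printed_usp2_auc_mean(self):
        assert mean_absolute_pe([3.66, 2.45, 6.65]) == pytest.approx(
            4.25, abs=0.01)

    def test_singleton(self):
        assert mean_absolute_pe([-7.5]) == 7.5

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            mean_absolute_pe([])


class TestValidateReport:
    @staticmethod
    def _report(cmax_pairs, auc_pairs):
        observed = {f"g{i}": (c[0], a[0])
                    for i, (c, a) in enumerate(zip(cmax_pairs, auc_pairs))}
        predicted = {f"g{i}": (c[1], a[1])
                     for i, (c, a) in enumerate(zip(cmax_pairs, auc_pairs))}
        return pe_report(observed, predicted)

    def test_dgim_passes(self):
        report = self._report(DGIM_CMAX, DGIM_AUC)
        assert report.mean_abs_pe_cmax == pytest.approx(9.96, abs=0.01)
        flags = validate_ivivc(report)
        assert flags["cmax"] and flags["auc"]

    def test_usp2_cmax_fails(self):
        report = self._report(USP2_CMAX, USP2_AUC)
        assert report.mean_abs_pe_cmax == pytest.approx(19.30, abs=0.01)
        flags = validate_ivivc(report)
        assert not flags["cmax"]
        assert flags["auc"]

    def test_all_zero_passes(self):
        report = self._report([(1.0, 1.0)] * 3, [(2.0, 2.0)] * 3)
        assert validate_ivivc(report) == {"cmax": True, "auc": True}

    def test_mismatched_groups_rejected(self):
        with pytest.raises(ValidationError):
            pe_report({"a": (1, 1)}, {"b": (1, 1)})
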