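"""NanoDSF melting-temperature extraction and FP one-site binding fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ripfit.binding_assays import (
    BindingFitError,
    FPTitration,
    MeltCurve,
    NoTransitionError,
    default_fp_concentrations,
    extract_tm,
    fit_one_site,
    generate_fp,
    generate_melt,
    melt_ratio_derivative,
    polarization,
)


class TestMeltDerivative:
    def test_constant_ratio_gives_zero(self):
        T = np.arange(20.0, 90.0, 0.5)
        curve = MeltCurve(T, np.full(T.size, 900.0), np.full(T.size, 1000.0))
        _, d = melt_ratio_derivative(curve)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_linear_ratio_gives_slope(self):
        T = np.arange(20.0, 90.0, 0.5)
        ratio = 0.8 + 0.004 * (T - 20.0)
        curve = MeltCurve(T, 1000.0 * ratio, np.full(T.size, 1000.0))
        _, d = melt_ratio_derivative(curve)
        assert np.allclose(d[5:-5], 0.004, atol=1e-10)

    def test_sigmoid_extremum_matches_finite_difference_oracle(self):
        curve = generate_melt(55.0, step=0.1)
        T, d = melt_ratio_derivative(curve)
        ratio = curve.intensity_350 / curve.intensity_330
        oracle = np.gradient(ratio, T)  # dense-grid finite differences
        i_impl = int(np.argmax(d))
        i_oracle = int(np.argmax(oracle))
        assert abs(T[i_impl] - T[i_oracle]) <= 0.1 + 1e-9
        assert abs(T[i_impl] - 55.0) <= 0.2

    def test_zero_intensity_rejected(self):
        T = np.arange(20.0, 90.0, 0.5)
        with pytest.raises(ValueError):
            MeltCurve(T, np.full(T.size, 900.0), np.zeros(T.size))

    def test_bad_window_rejected(self):
        curve = generate_melt(55.0)
        with pytest.raises(ValueError):
            melt_ratio_derivative(curve, smooth_window=8)


class TestExtractTm:
    @pytest.mark.parametrize("tm", [52.7, 53.5])
    def test_recovers_generated_midpoint(self, tm):
        curve = generate_melt(tm, step=0.1)
        got = extract_tm(*melt_ratio_derivative(curve))
        assert got == pytest.approx(tm, abs=0.1)

    def test_flat_series_raises(self):
        T = np.arange(20.0, 90.0, 0.5)
        curve = MeltCurve(T, np.full(T.size, 900.0), np.full(T.size, 1000.0))
        with pytest.raises(NoTransitionError):
            extract_tm(*melt_ratio_derivative(curve))

    def test_monotone_baseline_without_transition_raises(self):
        T = np.arange(20.0, 90.0, 0.5)
        ratio = 0.8 + 0.004 * (T - 20.0)
        curve = MeltCurve(T, 1000.0 * ratio, np.full(T.size, 1000.0))
        with pytest.raises(NoTransitionError):
            extract_tm(*melt_ratio_derivative(curve))

    def test_round_trip_under_light_noise(self):
        """With ratio noise present the smoothing window must cover a fair
        fraction of the transition width for the extremum to be stable."""
        devs = [
            extract_tm(
                *melt_ratio_derivative(
                    generate_melt(52.7, noise_sd=0.001, seed=s), smooth_window=75
                )
            )
            - 52.7
            for s in range(20)
        ]
        assert np.max(np.abs(devs)) <= 0.1

    def test_tm_within_grid_and_zero_amplitude_errors(self):
        with pytest.raises(ValueError):
            generate_melt(95.0)
        flat = generate_melt(55.0, amplitude=0.0)
        with pytest.raises(NoTransitionError):
            extract_tm(*melt_ratio_derivative(flat))


class TestPolarization:
    def test_equal_intensities(self):
        assert polarization(100.0, 100.0) == 0.0

    def test_fully_parallel(self):
        assert polarization(100.0, 0.0) == 1.0

    def test_direct_arithmetic(self):
        assert polarization(150.0, 50.0) == pytest.approx(0.5)
        assert polarization(150.0, 50.0, millipolarization=True) == pytest.approx(500.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            polarization(0.0, 0.0)
        with pytest.raises(ValueError):
            polarization(-1.0, 2.0)

    @given(
        ipar=st.floats(0.0, 1e6),
        iperp=st.floats(0.0, 1e6),
    )
    def test_bounded(self, ipar, iperp):
        if ipar + iperp == 0:
            return
        assert -1.0 <= polarization(ipar, iperp) <= 1.0


class TestOneSiteFit:
    def test_noiseless_recovery(self):
        tit = generate_fp(4.7, pmax=100.0)
        fit = fit_one_site(tit)
        assert fit.kd == pytest.approx(4.7, abs=0.1)
        assert fit.pmax == pytest.approx(100.0, abs=0.5)

    def test_half_saturation_generator_self_check(self):
        tit = generate_fp(4.7, pmax=100.0, concentrations=np.array([4.7]))
        assert tit.polarization[0] == pytest.approx(50.0)

    def test_zero_concentration_gives_zero(self):
        tit = generate_fp(4.7)
        assert tit.polarization[tit.concentration == 0.0][0] == 0.0

    def test_noisy_replicates_within_25_percent(self):
        errs = [
            abs(fit_one_site(generate_fp(4.7, noise_sd=2.0, n_replicates=3, seed=s)).kd - 4.7)
            / 4.7
            for s in range(50)
        ]
        assert np.median(errs) < 0.25
        assert np.mean(np.array(errs) < 0.25) >= 0.9

    def test_background_subtraction(self):
        tit = generate_fp(4.7, pmax=100.0)
        tit.polarization = tit.polarization + 7.0  # constant instrument background
        fit = fit_one_site(tit)
        assert fit.kd == pytest.approx(4.7, abs=0.3)

    def test_fitted_curve_monotone_with_pmax_asymptote(self):
        fit = fit_one_site(generate_fp(4.7))
        c = np.linspace(0, 5000, 200)
        curve = fit.pmax * c / (fit.kd + c)
        assert np.all(np.diff(curve) > 0)
        assert curve[-1] == pytest.approx(fit.pmax, rel=0.01)

    def test_too_few_points_rejected(self):
        tit = FPTitration(np.array([0.0, 1.0, 2.0, 4.0]), np.array([0.0, 20.0, 33.0, 50.0]))
        with pytest.raises(ValueError):
            fit_one_site(tit)

    def test_narrow_span_rejected(self):
        c = np.linspace(1.0, 5.0, 8)
        tit = FPTitration(c, 100 * c / (4.7 + c))
        with pytest.raises(ValueError):
            fit_one_site(tit)

    def test_uninformative_titration_raises(self):
        # constant polarization carries no binding signal
        c = np.concatenate(([0.0], np.geomspace(0.1, 80, 12)))
        tit = FPTitration(c, np.full(c.size, 50.0) + np.linspace(0, 1e-9, c.size))
        with pytest.raises(BindingFitError):
            fit_one_site(tit)

    def test_invalid_kd_in_generator(self):
        with pytest.raises(ValueError):
            generate_fp(-1.0)

    def test_default_concentrations(self):
        c = default_fp_concentrations()
        assert c[0] == 0.0
        assert c[1] == pytest.approx(0.1)
        assert c[-1] == pytest.approx(80.0)
        assert len(c) == 13
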