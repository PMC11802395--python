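import numpy as np
import pytest

from clampkit.errors import DomainError, InsufficientDataError, ValidationError
from clampkit.secretion import (
    CpepKinetics,
    beta_cell_function,
    convolution_matrix,
    deconvolve_isr,
    expected_lag1_residual_corr,
    impulse_response,
    population_kinetics,
    _second_difference,
)
from clampkit.simulate import SimNoise, SimTruth, cpeptide_from_isr, simulate_mmtt


class TestPopulationKinetics:
    def test_deterministic(self, ref_kinetics):
        again = population_kinetics(age=58, sex="male", bmi=33, diabetic=True, weight=100, height=172)
        assert again == ref_kinetics

    def test_long_halflife_increases_with_age(self):
        young = population_kinetics(age=40, sex="male", bmi=33, diabetic=True, weight=100, height=172)
        old = population_kinetics(age=70, sex="male", bmi=33, diabetic=True, weight=100, height=172)
        assert old.long_halflife > young.long_halflife
        assert old.short_halflife == young.short_halflife

    def test_reference_adult_in_class_ranges(self, ref_kinetics):
        # obese/T2D class: higher fast fraction, long half-life in the 30-45
        # min band for middle-aged adults, Vd of a few litres
        assert ref_kinetics.fraction == pytest.approx(0.78)
        assert 30 < ref_kinetics.long_halflife < 45
        assert 3.0 < ref_kinetics.vd < 7.0

    def test_lean_nondiabetic_class(self):
        k = population_kinetics(age=40, sex="female", bmi=22, diabetic=False, weight=60, height=165)
        assert k.fraction == pytest.approx(0.76)

    @pytest.mark.parametrize("kwargs", [{"age": 10}, {"bmi": 70}, {"sex": "x"}])
    def test_out_of_range(self, kwargs):
        base = dict(age=58, sex="male", bmi=33, diabetic=True, weight=100, height=172)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            population_kinetics(**base)


class TestImpulseResponse:
    def test_initial_value_and_monotone(self, ref_kinetics):
        t = np.linspace(0, 180, 500)
        h = impulse_response(ref_kinetics, t)
        assert h[0] == pytest.approx(1.0 / ref_kinetics.vd)
        assert np.all(np.diff(h) < 0)

    def test_single_exponential_limit(self):
        k = CpepKinetics(short_halflife=5.0, long_halflife=30.0, fraction=1 - 1e-12, vd=5.0)
        t = np.array([0.0, 5.0, 10.0])
        h = impulse_response(k, t)
        assert h[1] / h[0] == pytest.approx(0.5, rel=1e-6)

    def test_closed_form_integral(self, ref_kinetics):
        t = np.linspace(0, 2000, 200001)
        numeric = np.trapezoid(impulse_response(ref_kinetics, t), t)
        assert numeric == pytest.approx(ref_kinetics.kernel_integral, rel=1e-4)

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            CpepKinetics(short_halflife=30.0, long_halflife=5.0, fraction=0.7, vd=5.0)


class TestDeconvolution:
    def test_steady_state_balance(self, ref_kinetics, mmtt_grid):
        c = np.full(len(mmtt_grid), 1900.0)
        res = deconvolve_isr(c, mmtt_grid, ref_kinetics)
        expected = ref_kinetics.steady_state_isr(1900.0)
        assert np.allclose(res.isr, expected, rtol=1e-6)

    def test_all_zero(self, ref_kinetics, mmtt_grid):
        res = deconvolve_isr(np.zeros(len(mmtt_grid)), mmtt_grid, ref_kinetics)
        assert np.all(res.isr == 0.0) and res.isr_auc == 0.0

    def test_square_pulse_round_trip(self, ref_kinetics, mmtt_grid):
        isr_true = np.where((mmtt_grid >= 20) & (mmtt_grid <= 60), 800.0, 200.0)
        c = cpeptide_from_isr(mmtt_grid, isr_true, ref_kinetics, basal_isr=200.0)
        res = deconvolve_isr(c, mmtt_grid, ref_kinetics, lam=1e-6)
        rel = np.sqrt(np.mean((res.isr - isr_true) ** 2)) / np.mean(isr_true)
        assert rel < 0.05

    def test_biphasic_round_trip_default_lambda(self, ref_kinetics, mmtt_grid):
        for seed in range(5):
            truth = SimTruth(noise=SimNoise.none(), seed=seed)
            df, tdf = simulate_mmtt(truth, ref_kinetics)
            res = deconvolve_isr(df["cpeptide_pmol_l"].to_numpy(), mmtt_grid, ref_kinetics)
            rel = np.sqrt(np.mean((res.isr - tdf["isr_pmol_min"]) ** 2)) / np.mean(tdf["isr_pmol_min"])
            assert rel < 0.05
            assert np.all(res.isr >= 0)

    def test_nonnegativity_under_noise(self, ref_kinetics, mmtt_grid):
        for seed in range(10):
            df, _ = simulate_mmtt(SimTruth(seed=seed), ref_kinetics)
            res = deconvolve_isr(df["cpeptide_pmol_l"].to_numpy(), mmtt_grid, ref_kinetics)
            assert np.all(res.isr >= 0)
            # convolution of the solution must reproduce the observations
            assert np.sqrt(np.mean(res.residuals**2)) < 0.15 * np.mean(df["cpeptide_pmol_l"])

    def test_residual_whiteness_beyond_smoother(self, ref_kinetics, mmtt_grid):
        """Observed lag-1 residual correlation matches the smoother-implied value.

        Penalized-fit residuals are (I-S)eps and hence negatively
        lag-1-correlated even for white noise; excess correlation beyond
        that expectation indicates kernel misspecification.
        """
        H = convolution_matrix(ref_kinetics, mmtt_grid)
        D = _second_difference(mmtt_grid)
        excess = []
        for seed in range(20):
            df, _ = simulate_mmtt(SimTruth(seed=seed), ref_kinetics)
            res = deconvolve_isr(df["cpeptide_pmol_l"].to_numpy(), mmtt_grid, ref_kinetics)
            r = res.residuals
            obs = np.corrcoef(r[:-1], r[1:])[0, 1]
            excess.append(obs - expected_lag1_residual_corr(H, D, res.lambda_used))
        assert abs(np.mean(excess)) < 0.3

    def test_too_few_samples(self, ref_kinetics):
        with pytest.raises(InsufficientDataError):
            deconvolve_isr(np.ones(4), np.arange(4.0), ref_kinetics)

    def test_negative_cpeptide_rejected(self, ref_kinetics, mmtt_grid):
        c = np.full(len(mmtt_grid), 100.0)
        c[3] = -1.0
        with pytest.raises(DomainError):
            deconvolve_isr(c, mmtt_grid, ref_kinetics)


class TestBetaCellFunction:
    def _curves(self):
        t = np.arange(0.0, 121.0, 10.0)
        isr = 200 + 400 * np.sin(np.pi * t / 120.0)
        glucose = 7.0 + 2.0 * np.sin(np.pi * t / 120.0)
        return t, isr, glucose

    def test_linear_in_isr_excursion(self):
        t, isr, g = self._curves()
        base = beta_cell_function(t, isr, t, g, is_index=0.05)
        doubled = beta_cell_function(t, 200 + 2 * (isr - 200), t, g, is_index=0.05)
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_inverse_in_sensitivity(self):
        t, isr, g = self._curves()
        assert beta_cell_function(t, isr, t, g, 0.10) == pytest.approx(
            0.5 * beta_cell_function(t, isr, t, g, 0.05), rel=1e-9
        )

    def test_flat_glucose_missing(self):
        t, isr, _ = self._curves()
        flat = np.full(len(t), 7.0)
        assert np.isnan(beta_cell_function(t, isr, t, flat, 0.05))

    def test_nonpositive_sensitivity_rejected(self):
        t, isr, g = self._curves()
        with pytest.raises(DomainError):
            beta_cell_function(t, isr, t, g, 0.0)
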