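"""TAS construction, IRF reconvolution fitting, model comparison, and trace
utilities."""

import numpy as np
import pytest

from anapquench import (
    DataError,
    GridMismatchError,
    IRF,
    DecayTrace,
    ValidationError,
    build_tas_trace,
    compare_decay_models,
    convolve_with_irf,
    fit_reconvolution,
    residual_plateau,
    savitzky_golay,
    subtract_background_trace,
)
from anapquench.simulate import TASSim, TRPLSim, simulate_irf, simulate_tas, simulate_trpl
from anapquench.time_resolved import savitzky_golay_variance_gain

GRID = 0.4 * np.arange(256)


def _trace(signal, **kw):
    return DecayTrace(GRID, np.asarray(signal, dtype=float), **kw)


def _delta_irf():
    resp = np.zeros(GRID.size)
    resp[0] = 1.0
    return IRF(GRID, resp)


class TestBuildTAS:
    def test_null_transient(self):
        unpumped = _trace(np.full(GRID.size, 2.0))
        fluor = _trace(np.full(GRID.size, 0.5))
        pumped = _trace(unpumped.signal + fluor.signal)
        dod = build_tas_trace(pumped, unpumped, fluor)
        np.testing.assert_allclose(dod.signal, 0.0, atol=1e-15)

    @pytest.mark.parametrize("ratio, expected", [(0.5, 0.30103), (2.0, -0.30103)])
    def test_log_ratio_sign_convention(self, ratio, expected):
        unpumped = _trace(np.ones(GRID.size))
        fluor = _trace(np.zeros(GRID.size))
        sig = np.ones(GRID.size)
        sig[100] = ratio
        dod = build_tas_trace(_trace(sig), unpumped, fluor)
        assert dod.signal[100] == pytest.approx(expected, abs=1e-5)

    def test_nonpositive_numerator_masked_and_counted(self):
        unpumped = _trace(np.ones(GRID.size))
        fluor = _trace(np.full(GRID.size, 0.5))
        sig = np.ones(GRID.size)
        sig[:3] = 0.2  # below fluorescence -> masked
        dod = build_tas_trace(_trace(sig), unpumped, fluor)
        assert dod.meta["n_masked"] == 3
        assert np.isnan(dod.signal[:3]).all()

    def test_inverse_transform_round_trip(self):
        rng = np.random.default_rng(0)
        unpumped = _trace(np.full(GRID.size, 1.5))
        fluor = _trace(0.1 * rng.random(GRID.size))
        pumped = _trace(fluor.signal + 1.5 * (0.5 + 0.5 * rng.random(GRID.size)))
        dod = build_tas_trace(pumped, unpumped, fluor)
        ratio = (pumped.signal - fluor.signal) / unpumped.signal
        np.testing.assert_allclose(10.0 ** (-dod.signal), ratio, rtol=1e-12)

    def test_nonpositive_unpumped_rejected(self):
        bad = _trace(np.zeros(GRID.size))
        ones = _trace(np.ones(GRID.size))
        with pytest.raises(DataError):
            build_tas_trace(ones, bad, ones)


class TestBackgroundSubtraction:
    def test_zero_background_identity(self):
        rng = np.random.default_rng(1)
        mix = _trace(rng.random(GRID.size))
        out = subtract_background_trace(mix, _trace(np.zeros(GRID.size)))
        np.testing.assert_array_equal(out.signal, mix.signal)

    def test_self_subtraction_zeroes(self):
        mix = _trace(np.exp(-GRID / 3.0))
        np.testing.assert_array_equal(subtract_background_trace(mix, mix).signal, 0.0)

    def test_kind_mismatch_rejected(self):
        a = _trace(np.ones(GRID.size), kind="trpl")
        b = _trace(np.ones(GRID.size), kind="tas")
        with pytest.raises(GridMismatchError):
            subtract_background_trace(a, b)

    def test_isolates_fast_component_of_two_exponential_mixture(self):
        irf = simulate_irf(8.0, GRID, 16.0)
        fast = convolve_with_irf(irf, GRID, "exp1", {"amplitudes": [800.0], "lifetimes": [2.14]})
        slow = convolve_with_irf(irf, GRID, "exp1", {"amplitudes": [300.0], "lifetimes": [6.0]})
        residual = subtract_background_trace(_trace(fast + slow), _trace(slow))
        fit = fit_reconvolution(residual, irf, model="exp1")
        assert fit.lifetimes[0] == pytest.approx(2.14, rel=1e-6)


class TestConvolution:
    def test_delta_irf_identity(self):
        out = convolve_with_irf(
            _delta_irf(), GRID, "exp1", {"amplitudes": [3.0], "lifetimes": [2.0]}
        )
        np.testing.assert_allclose(out, 3.0 * np.exp(-GRID / 2.0), rtol=1e-12)

    def test_unit_area_kernel_preserves_constant(self):
        irf = simulate_irf(8.0, GRID, 16.0)
        out = convolve_with_irf(irf, GRID, "second_order", {"amplitude": 5.0, "rate": 0.0})
        # interior points (after the IRF has fully entered the window)
        assert np.allclose(out[150:], 5.0, rtol=1e-6)

    def test_integral_preserved_for_gaussian_irf(self):
        irf = simulate_irf(8.0, GRID, 16.0)
        h = 1.0 * np.exp(-GRID / 2.776)
        out = convolve_with_irf(irf, GRID, "exp1", {"amplitudes": [1.0], "lifetimes": [2.776]})
        assert out.sum() == pytest.approx(h.sum(), rel=1e-3)

    def test_linear_in_amplitudes(self):
        irf = simulate_irf(8.0, GRID, 16.0)
        one = convolve_with_irf(irf, GRID, "exp1", {"amplitudes": [1.0], "lifetimes": [2.0]})
        two = convolve_with_irf(irf, GRID, "exp1", {"amplitudes": [1.0], "lifetimes": [7.0]})
        both = convolve_with_irf(
            irf, GRID, "exp2", {"amplitudes": [2.0, 3.0], "lifetimes": [2.0, 7.0]}
        )
        np.testing.assert_allclose(both, 2.0 * one + 3.0 * two, atol=1e-12)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValidationError):
            convolve_with_irf(_delta_irf(), GRID, "exp1", {"amplitudes": [1.0], "lifetimes": [-1.0]})


class TestReconvolutionFit:
    def test_delta_irf_noiseless_exact(self):
        trace = _trace(5.0 * np.exp(-GRID / 2.0) + 1.0)
        fit = fit_reconvolution(trace, _delta_irf(), model="exp1")
        assert fit.lifetimes[0] == pytest.approx(2.0, rel=1e-6)
        assert fit.baseline == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("species, tau", [("anap", 2.776), ("serotonin", 2.231)])
    def test_gaussian_irf_noiseless_recovery(self, species, tau):
        trace, irf = simulate_trpl(TRPLSim().noiseless(), species, seed=1)
        fit = fit_reconvolution(trace, irf, model="exp1")
        assert fit.lifetimes[0] == pytest.approx(tau, rel=1e-3)

    def test_poisson_noise_recovery_within_bin_bound(self):
        # 64-average photon counting: the lifetime lands within the 0.4 ns
        # upper uncertainty bound set by the digitizer bin width
        trace, irf = simulate_trpl(TRPLSim(), "serotonin", seed=7)
        fit = fit_reconvolution(trace, irf, model="exp1", weighting="poisson")
        assert abs(fit.lifetimes[0] - 2.231) <= 0.4
        assert fit.stderr["lifetime"] > 0

    def test_exp2_lifetimes_sorted(self):
        irf = simulate_irf(8.0, GRID, 16.0)
        sig = convolve_with_irf(
            irf, GRID, "exp2", {"amplitudes": [500.0, 200.0], "lifetimes": [1.0, 9.0]}
        )
        fit = fit_reconvolution(_trace(sig), irf, model="exp2")
        assert fit.lifetimes[0] < fit.lifetimes[1]
        assert fit.lifetimes[0] == pytest.approx(1.0, rel=1e-3)
        assert fit.lifetimes[1] == pytest.approx(9.0, rel=1e-3)

    def test_too_few_points_rejected(self):
        trace = _trace(np.ones(GRID.size))
        with pytest.raises(DataError):
            fit_reconvolution(trace, _delta_irf(), mask=np.zeros(GRID.size, dtype=bool))


class TestModelComparison:
    def test_well_separated_biexponential_wins(self):
        irf = simulate_irf(8.0, GRID, 16.0)
        sig = convolve_with_irf(
            irf, GRID, "exp2", {"amplitudes": [600.0, 300.0], "lifetimes": [1.5, 7.5]}
        )
        rng = np.random.default_rng(5)
        noisy = np.maximum(sig + 2.0, 0)
        noisy = rng.poisson(noisy * 64) / 64
        ranked = compare_decay_models(_trace(noisy), irf, weighting="poisson")
        assert ranked[0][0] == "exp2"

    def test_pure_noise_prefers_fewest_parameters(self):
        rng = np.random.default_rng(6)
        trace = _trace(rng.normal(10.0, 0.5, GRID.size))
        ranked = compare_decay_models(trace, simulate_irf(8.0, GRID, 16.0), weighting="uniform")
        assert ranked[0][1].n_params == min(f.n_params for _, f, _ in ranked)


class TestResidualPlateau:
    def test_full_recovery_within_two_se(self):
        rng = np.random.default_rng(2)
        trace = _trace(rng.normal(0.0, 0.01, GRID.size))
        mean, se = residual_plateau(trace, (80.0, 100.0))
        assert abs(mean) <= 2 * se

    def test_constant_offset_detected(self):
        trace = _trace(np.full(GRID.size, 0.03))
        mean, se = residual_plateau(trace, (80.0, 100.0))
        assert mean == pytest.approx(0.03)

    def test_step_component_from_sum_minus_mixture(self):
        mixture = np.exp(-GRID / 3.0)
        step = np.full(GRID.size, 0.02)
        difference = _trace((mixture + step) - mixture)
        mean, _ = residual_plateau(difference, (60.0, 100.0))
        assert mean == pytest.approx(0.02)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(DataError):
            residual_plateau(_trace(np.zeros(GRID.size)), (200.0, 300.0))


class TestSavitzkyGolay:
    def test_exact_on_quadratic(self):
        trace = _trace(3.0 + 0.5 * GRID - 0.01 * GRID**2)
        out = savitzky_golay(trace, window=21, order=2)
        np.testing.assert_allclose(out.signal, trace.signal, rtol=1e-9, atol=1e-9)

    def test_constant_unchanged(self):
        out = savitzky_golay(_trace(np.full(GRID.size, 4.2)))
        np.testing.assert_allclose(out.signal, 4.2, rtol=1e-12)

    def test_white_noise_variance_reduction_matches_coefficient_norm(self):
        gain = savitzky_golay_variance_gain(21, 2)
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(200):
            noise = rng.standard_normal(GRID.size)
            sm = savitzky_golay(_trace(noise), 21, 2).signal
            ratios.append(np.var(sm[20:-20]) / np.var(noise))
        assert np.mean(ratios) == pytest.approx(gain, rel=0.2)

    def test_parameter_validation(self):
        trace = _trace(np.zeros(GRID.size))
        with pytest.raises(ValidationError):
            savitzky_golay(trace, window=20)
        with pytest.raises(ValidationError):
            savitzky_golay(trace, window=5, order=5)


class TestTASPipeline:
    def test_synthetic_product_recovery_with_emi(self):
        triple = simulate_tas(TASSim(), seed=1)
        dod = build_tas_trace(triple.pumped, triple.unpumped, triple.fluorescence)
        fit = fit_reconvolution(
            dod, triple.irf, model="exp1", weighting="uniform", mask=triple.artifact_mask
        )
        assert fit.lifetimes[0] == pytest.approx(3.18, rel=0.03)

    def test_step_term_detected_as_permanent_signal(self):
        import dataclasses

        cfg = dataclasses.replace(TASSim(), step_dod=0.02)
        triple = simulate_tas(cfg, seed=2)
        dod = build_tas_trace(triple.pumped, triple.unpumped, triple.fluorescence)
        mean, se = residual_plateau(dod, (70.0, 100.0))
        assert mean > 2 * se  # permanent increase
        recovered = simulate_tas(TASSim(), seed=2)
        dod2 = build_tas_trace(recovered.pumped, recovered.unpumped, recovered.fluorescence)
        mean2, se2 = residual_plateau(dod2, (70.0, 100.0))
        assert abs(mean2) <= 3 * se2
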