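"""Photobleach correction, response normalization, and Hill fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anapquench import (
    BleachModel,
    DataError,
    Exposure,
    ExposureSeries,
    Spectrum,
    binding_pipeline,
    bleach_correct,
    fit_bleach,
    fit_hill,
    hill_curve,
    maximal_quench,
    normalize_response,
)
from anapquench.binding import corrected_peaks, default_band
from anapquench.simulate import CellSim, simulate_cell_series

LAM = np.arange(400.0, 651.0, 1.0)


def _series(intensities, times=None, concs=None, cell_id="c0"):
    """Build a series of flat-top band spectra with given peak intensities."""
    n = len(intensities)
    times = times if times is not None else [10.0 * k for k in range(n)]
    concs = concs if concs is not None else [None] * n
    band = np.exp(-0.5 * ((LAM - 495.0) / 30.0) ** 2)
    exposures = [
        Exposure(t, c, Spectrum(LAM, i * band)) for t, c, i in zip(times, concs, intensities)
    ]
    return ExposureSeries(exposures=exposures, cell_id=cell_id)


class TestFitBleach:
    def test_constant_pre_gives_no_bleach_model(self):
        with pytest.warns(UserWarning):  # < 5 PRE exposures
            series = _series([100.0, 100.0, 100.0])
        model = fit_bleach(series)
        assert model.no_bleach and model.amplitude == 0.0
        band_scale = np.mean(np.exp(-0.5 * ((np.arange(490.0, 501.0) - 495.0) / 30.0) ** 2))
        assert model.offset == pytest.approx(100.0 * band_scale, rel=1e-9)

    def test_noiseless_exponential_recovered_exactly(self):
        a, tau, c = 40.0, 60.0, 70.0
        times = [0.0, 10.0, 20.0, 30.0, 40.0]
        series = _series([a * np.exp(-t / tau) + c for t in times], times=times)
        model = fit_bleach(series, band=(490.0, 500.0))
        scale = np.mean(np.exp(-0.5 * ((np.arange(490.0, 501.0) - 495.0) / 30.0) ** 2))
        assert model.time_constant == pytest.approx(tau, rel=1e-6)
        assert model.amplitude == pytest.approx(a * scale, rel=1e-5)
        assert model.offset == pytest.approx(c * scale, rel=1e-6)

    def test_increasing_intensity_flags_no_bleach(self):
        series = _series([100.0, 101.0, 102.0, 103.0, 104.0])
        model = fit_bleach(series)
        assert model.no_bleach and model.amplitude == 0.0

    def test_requires_three_pre_exposures(self):
        with pytest.warns(UserWarning):
            series = _series([100.0, 90.0])
        with pytest.raises(DataError):
            fit_bleach(series)


class TestBleachCorrect:
    def test_no_bleach_model_is_identity(self):
        series = _series([100.0] * 5)
        out = bleach_correct(series, BleachModel(0.0, 1e12, 100.0, 1.0, no_bleach=True))
        for e_in, e_out in zip(series.exposures, out.exposures):
            np.testing.assert_allclose(e_out.spectrum.intensity, e_in.spectrum.intensity)

    def test_pure_bleach_series_becomes_constant(self):
        a, tau, c = 40.0, 60.0, 70.0
        times = [10.0 * k for k in range(8)]
        concs = [None] * 5 + [1e-7, 1e-6, 1e-5]
        series = _series([a * np.exp(-t / tau) + c for t in times], times=times, concs=concs)
        model = fit_bleach(series, band=(490.0, 500.0))
        out = bleach_correct(series, model)
        peaks = [p for _, p in corrected_peaks(out, band=(490.0, 500.0))]
        np.testing.assert_allclose(peaks, peaks[0], rtol=1e-9)

    def test_bleach_and_quench_factorize(self):
        # generated as bleach(t) * quench(c): after correction the peaks
        # depend on concentration only
        quench = {1e-7: 0.9, 1e-6: 0.6, 1e-5: 0.4}
        times = [10.0 * k for k in range(8)]
        concs = [None] * 5 + list(quench)
        bleach = lambda t: 30.0 * np.exp(-t / 50.0) + 70.0  # noqa: E731
        series = _series(
            [bleach(t) * (quench[c] if c else 1.0) for t, c in zip(times, concs)],
            times=times,
            concs=concs,
        )
        out = bleach_correct(series, fit_bleach(series, band=(490.0, 500.0)))
        peaks = dict(corrected_peaks(out, band=(490.0, 500.0)))
        base = peaks[1e-7] / quench[1e-7]
        for c, q in quench.items():
            assert peaks[c] / base == pytest.approx(q, rel=1e-6)


class TestNormalizeResponse:
    def test_already_normalized_is_identity(self):
        pts = [(1e-8, 1.0), (1e-6, 0.5), (1e-4, 0.0)]
        out = dict(normalize_response(pts))
        assert out[1e-8] == pytest.approx(1.0)
        assert out[1e-4] == pytest.approx(0.0)
        assert out[1e-6] == pytest.approx(0.5)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        pts = [(1e-8, 1.2), (1e-7, 0.8), (1e-6, 0.5), (1e-4, 0.1)]
        base = normalize_response(pts)
        scaled = normalize_response([(c, a * f + b) for c, f in pts])
        for (_, x), (_, y) in zip(base, scaled):
            assert x == pytest.approx(y, rel=1e-9, abs=1e-9)

    def test_degenerate_range_rejected(self):
        with pytest.raises(DataError):
            normalize_response([(1e-8, 1.0), (1e-6, 1.0), (1e-4, 1.0)])

    def test_partial_ceiling_still_spans_unit_interval(self):
        conc = np.logspace(-8, -4, 9)
        occ = (hill_curve(conc[0], 594e-9, -0.46) - hill_curve(conc, 594e-9, -0.46)) / (
            hill_curve(conc[0], 594e-9, -0.46) - hill_curve(conc[-1], 594e-9, -0.46)
        )
        intensity = 1.0 - 0.66 * occ  # 66% ceiling
        out = normalize_response(list(zip(conc, intensity)))
        values = [f for _, f in out]
        assert max(values) == pytest.approx(1.0) and min(values) == pytest.approx(0.0)


class TestFitHill:
    def test_midpoint_identity(self):
        assert hill_curve(594e-9, 594e-9, -0.46) == pytest.approx(0.5)
        assert hill_curve(1e-3, 1e-3, 3.0) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "ec50, slope", [(594e-9, -0.46), (160e-9, -0.49)], ids=["whole-cell", "unroofed"]
    )
    def test_noiseless_recovery(self, ec50, slope):
        conc = np.logspace(-8.5, -4.0, 10)
        pts = list(zip(conc, hill_curve(conc, ec50, slope)))
        fit = fit_hill(pts, bootstrap=0)
        assert fit.ec50 == pytest.approx(ec50, rel=1e-6)
        assert fit.slope == pytest.approx(slope, rel=1e-6)

    def test_unit_rescale_invariance(self):
        conc = np.logspace(-8, -4, 9)
        f = hill_curve(conc, 594e-9, -0.46)
        fit_m = fit_hill(list(zip(conc, f)), bootstrap=0)
        fit_um = fit_hill(list(zip(conc * 1e6, f)), bootstrap=0)
        assert fit_um.ec50 == pytest.approx(fit_m.ec50 * 1e6, rel=1e-6)
        assert fit_um.slope == pytest.approx(fit_m.slope, rel=1e-6)

    def test_bootstrap_zero_skips_ci(self):
        conc = np.logspace(-8, -4, 9)
        fit = fit_hill(list(zip(conc, hill_curve(conc, 594e-9, -0.46))), bootstrap=0)
        assert fit.ci95 is None

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(0)
        conc = np.logspace(-8, -4, 9)
        f = hill_curve(conc, 594e-9, -0.46) + rng.normal(0, 0.03, conc.size)
        a = fit_hill(list(zip(conc, f)), bootstrap=100, seed=5)
        b = fit_hill(list(zip(conc, f)), bootstrap=100, seed=5)
        assert a.ci95 == b.ci95

    def test_too_few_points(self):
        with pytest.raises(DataError):
            fit_hill([(1e-8, 1.0), (1e-6, 0.5), (1e-4, 0.0)], bootstrap=0)


class TestMaximalQuench:
    def test_no_quench_and_full_quench(self):
        peaks = {"a": [(1e-8, 100.0), (1e-4, 100.0)], "b": [(1e-8, 100.0), (1e-4, 0.0)]}
        mean, sem, per_cell = maximal_quench(peaks)
        assert per_cell["a"] == pytest.approx(0.0)
        assert per_cell["b"] == pytest.approx(1.0)
        assert mean == pytest.approx(0.5)

    def test_single_cell_has_no_sem(self):
        mean, sem, _ = maximal_quench({"only": [(1e-8, 10.0), (1e-4, 5.0)]})
        assert mean == pytest.approx(0.5)
        assert sem is None

    def test_simulated_ceiling_recovered_within_two_sem(self):
        fractions = []
        for s in range(50):
            cells = simulate_cell_series(CellSim(), seed=s)
            res = binding_pipeline(cells, bootstrap=0)
            fractions.extend(res.per_cell_quench.values())
        fractions = np.array(fractions)
        sem = fractions.std(ddof=1) / np.sqrt(fractions.size)
        assert abs(fractions.mean() - 0.66) < 2 * sem


class TestFullPipeline:
    def test_noiseless_identity_recovery(self):
        cells = simulate_cell_series(CellSim().noiseless(), seed=1)
        res = binding_pipeline(cells, bootstrap=0)
        assert res.hill.ec50 == pytest.approx(594e-9, rel=1e-6)
        assert res.hill.slope == pytest.approx(-0.46, rel=1e-6)
        assert res.max_quench_mean == pytest.approx(0.66, rel=1e-9)

    def test_noisy_ci_contains_truth_for_reference_seed(self):
        cells = simulate_cell_series(CellSim(), seed=0)
        res = binding_pipeline(cells, bootstrap=300, seed=0)
        lo, hi = res.hill.ci95["ec50"]
        assert lo <= 594e-9 <= hi

    def test_default_band_centers_on_fluorophore_peak(self):
        cells = simulate_cell_series(CellSim().noiseless(), seed=1)
        lo, hi = default_band(cells[0])
        assert lo == pytest.approx(490.0) and hi == pytest.approx(500.0)
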