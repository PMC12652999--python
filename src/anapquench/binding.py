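"""Concentration-response analysis of receptor-bound fluorophore quenching.

A cell (or unroofed membrane sheet) is imaged repeatedly: first several
agonist-free "PRE" exposures, then one exposure per agonist concentration.
The analysis chain is

1. ``fit_bleach`` — single-exponential photobleach model
   ``A * exp(-t / tau_b) + C`` fitted to the PRE peak-band intensities,
2. ``bleach_correct`` — divide every spectrum by the predicted fractional
   intensity at its cumulative exposure time,
3. ``normalize_response`` — subtract the fluorescence at the saturating
   (highest) concentration and divide by the peak at the lowest applied
   concentration,
4. ``fit_hill`` — modified Hill equation in log10 concentration,

       F_norm = F_min + (F_max - F_min) / (1 + 10**(h * (log10 EC50 - log10 c))),

   with the slope factor ``h`` free (negative for quenching) and a seeded
   nonparametric bootstrap for 95% confidence intervals.

``maximal_quench`` reports the per-cell saturating quench fraction
``1 - F(sat) / F(lowest)`` with its mean and SEM across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm, t as t_dist

from .errors import DataError, FitError, ValidationError
from .spectra import Spectrum, band_mean, peak_wavelength

__all__ = [
    "Exposure",
    "ExposureSeries",
    "BleachModel",
    "HillFit",
    "BindingResult",
    "fit_bleach",
    "bleach_correct",
    "normalize_response",
    "hill_curve",
    "fit_hill",
    "maximal_quench",
    "default_band",
    "corrected_peaks",
    "binding_pipeline",
]


@dataclass(frozen=True)
class Exposure:
    """One spectrograph exposure: cumulative exposure time, agonist
    concentration (``None`` tags an agonist-free PRE exposure), spectrum."""

    time_s: float
    conc: float | None
    spectrum: Spectrum


@dataclass
class ExposureSeries:
    """Ordered exposures for one cell or membrane sheet."""

    exposures: list[Exposure]
    cell_id: str
    preparation: str = "cell"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [e.time_s for e in self.exposures]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"ExposureSeries {self.cell_id}: exposure times must increase")
        tags = [e.conc is None for e in self.exposures]
        if True in tags and False in tags:
            last_pre = max(i for i, is_pre in enumerate(tags) if is_pre)
            first_conc = min(i for i, is_pre in enumerate(tags) if not is_pre)
            if last_pre > first_conc:
                raise ValidationError(
                    f"ExposureSeries {self.cell_id}: PRE exposures must precede concentration steps"
                )
        if self.n_pre < 5:
            warnings.warn(
                f"ExposureSeries {self.cell_id}: only {self.n_pre} PRE exposures (5 expected)"
            )

    @property
    def pre(self) -> list[Exposure]:
        return [e for e in self.exposures if e.conc is None]

    @property
    def steps(self) -> list[Exposure]:
        return [e for e in self.exposures if e.conc is not None]

    @property
    def n_pre(self) -> int:
        return len(self.pre)


@dataclass
class BleachModel:
    """Single-exponential photobleach ``A * exp(-t / tau_b) + C``."""

    amplitude: float
    time_constant: float
    offset: float
    r_squared: float
    no_bleach: bool = False

    def __post_init__(self):
        if self.time_constant <= 0:
            raise ValidationError("BleachModel: time constant must be positive")
        if self.amplitude + self.offset <= 0:
            raise ValidationError("BleachModel: amplitude + offset must be positive")

    def predict(self, t) -> np.ndarray:
        return self.amplitude * np.exp(-np.asarray(t, dtype=float) / self.time_constant) + self.offset


def default_band(series: ExposureSeries, half_width: float = 5.0) -> tuple[float, float]:
    """10 nm band centered on the fluorophore peak of the first PRE exposure.

    A fixed narrow band near the ANAP peak (~495 nm on receptors) avoids
    contamination from the overlapping mOrange emission around 562 nm.
    """
    if not series.pre:
        raise DataError(f"default_band: series {series.cell_id} has no PRE exposures")
    peak = peak_wavelength(series.pre[0].spectrum)
    return (peak - half_width, peak + half_width)


def fit_bleach(series: ExposureSeries, band: tuple[float, float] | None = None) -> BleachModel:
    """Fit the photobleach model to the PRE peak-band intensities.

    If intensity does not decrease across the PRE exposures, a no-bleach
    model (A = 0) is returned with a flag instead of forcing a meaningless
    exponential.
    """
    pre = series.pre
    if len(pre) < 3:
        raise DataError(f"fit_bleach: need >= 3 PRE exposures, got {len(pre)}")
    if band is None:
        band = default_band(series)
    t = np.array([e.time_s for e in pre])
    y = np.array([band_mean(e.spectrum, *band) for e in pre])
    if np.any(y <= 0):
        raise DataError(f"fit_bleach: nonpositive PRE band intensity in cell {series.cell_id}")

    if y[-1] >= y[0] or np.allclose(y, y[0], rtol=1e-12, atol=0):
        return BleachModel(0.0, 1e12, float(y.mean()), 1.0, no_bleach=True)

    span = float(t[-1] - t[0])

    def residuals(p):
        a, log_tau, c = p
        return a * np.exp(-(t - t[0]) / np.exp(log_tau)) + c - y

    best = None
    # amplitude and offset bounded nonnegative: intensity is physical, and an
    # unconstrained offset can extrapolate to negative predicted fractions;
    # tau bounded to [0.1 s, 1e6 s] to keep the exponential finite
    bounds = ([0.0, np.log(0.1), 0.0], [np.inf, np.log(1e6), np.inf])
    for tau0 in (0.5 * span, 2.0 * span, 8.0 * span):
        p0 = np.array([max(y[0] - y[-1], 1e-9), np.log(tau0), max(y[-1], 1e-9)])
        try:
            res = least_squares(residuals, p0, bounds=bounds, x_scale="jac", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError(f"fit_bleach: divergence in cell {series.cell_id}", last_fit=best)
    a, log_tau, c = best.x
    tau = float(np.exp(log_tau))
    # the fit is anchored at the first PRE time; shift back to absolute time
    a_abs = float(a * np.exp(t[0] / tau))
    ss_res = float(2 * best.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BleachModel(a_abs, tau, float(c), r2)


def bleach_correct(series: ExposureSeries, model: BleachModel) -> ExposureSeries:
    """Divide each spectrum by the bleach model's predicted fractional
    intensity (prediction normalized to 1 at the first PRE exposure)."""
    t0 = series.exposures[0].time_s
    ref = float(model.predict(t0))
    corrected = []
    for e in series.exposures:
        frac = float(model.predict(e.time_s)) / ref
        if frac <= 0:
            raise DataError(f"bleach_correct: predicted fraction {frac:g} <= 0 at t={e.time_s:g} s")
        corrected.append(
            Exposure(e.time_s, e.conc, e.spectrum.with_intensity(e.spectrum.intensity / frac))
        )
    return replace(series, exposures=corrected, meta={**series.meta, "bleach_corrected": True})


def corrected_peaks(series: ExposureSeries, band: tuple[float, float] | None = None):
    """Band intensity per concentration of a (bleach-corrected) series.

    Replicate exposures at the same concentration are averaged into one
    point per concentration.
    """
    if band is None:
        band = default_band(series)
    by_conc: dict[float, list[float]] = {}
    for e in series.steps:
        by_conc.setdefault(float(e.conc), []).append(band_mean(e.spectrum, *band))
    return [(c, float(np.mean(vals))) for c, vals in sorted(by_conc.items())]


def normalize_response(corrected_peaks_list) -> list[tuple[float, float]]:
    """Normalize corrected peak intensities to the protocol anchors.

    ``F_norm(c) = (F(c) - F_min) / (F_lowest - F_min)`` with ``F_min`` the
    intensity at the highest (saturating) concentration and ``F_lowest`` the
    intensity at the lowest applied nonzero concentration.  The output is
    invariant to any affine transform of the input intensities.
    """
    pts = sorted((float(c), float(f)) for c, f in corrected_peaks_list)
    if len(pts) < 3:
        raise DataError("normalize_response: need >= 3 concentrations")
    if any(c <= 0 for c, _ in pts):
        raise DataError("normalize_response: concentrations must be positive")
    span = pts[-1][0] / pts[0][0]
    if span < 100:
        warnings.warn(
            f"normalize_response: concentrations span only {span:.3g}x (< 2 orders of magnitude)"
        )
    f_min = pts[-1][1]
    f_lowest = pts[0][1]
    if f_lowest == f_min:
        raise DataError("normalize_response: degenerate range (F_lowest == F_min)")
    return [(c, (f - f_min) / (f_lowest - f_min)) for c, f in pts]


def hill_curve(conc, ec50: float, slope: float, fmax: float = 1.0, fmin: float = 0.0):
    """Modified Hill equation in log10 concentration.

    At ``conc == ec50`` the logistic term is exactly 1/2 for any slope.
    A negative slope factor describes a response that falls with
    concentration (quenching).
    """
    conc = np.asarray(conc, dtype=float)
    logistic = 1.0 / (1.0 + 10.0 ** (slope * (np.log10(ec50) - np.log10(conc))))
    return fmin + (fmax - fmin) * logistic


@dataclass
class HillFit:
    """Modified Hill fit with bootstrap confidence intervals."""

    ec50: float
    slope: float
    fmax: float
    fmin: float
    ci95: dict | None
    preparation: str = "cell"
    n_points: int = 0
    n_cells: int | None = None
    boundary_flag: bool = False
    residual_ss: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "ec50_M": self.ec50,
            "slope": self.slope,
            "fmax": self.fmax,
            "fmin": self.fmin,
            "ci95": self.ci95,
            "preparation": self.preparation,
            "n_points": self.n_points,
            "n_cells": self.n_cells,
            "boundary_flag": self.boundary_flag,
        }


def _hill_point_fit(logc: np.ndarray, f: np.ndarray, p0: np.ndarray | None = None):
    def model(p):
        log_ec50, h, fmax, fmin = p
        return fmin + (fmax - fmin) / (1.0 + 10.0 ** (h * (log_ec50 - logc)))

    def residuals(p):
        return model(p) - f

    # standard dose-response constraints: the midpoint may sit at most two
    # decades outside the applied range, the slope magnitude is bounded, and
    # the asymptotes stay near the normalized scale
    lo = np.array([logc.min() - 2.0, -6.0, -1.0, -1.0])
    hi = np.array([logc.max() + 2.0, 6.0, 2.0, 2.0])

    if p0 is None:
        decreasing = f[np.argmax(logc)] < f[np.argmin(logc)]
        h0 = -0.5 if decreasing else 0.5
        starts = [
            np.array([np.median(logc), h0, float(f.max()), float(f.min())]),
            np.array([np.median(logc), 3 * h0, float(f.max()), float(f.min())]),
            np.array([np.median(logc), -h0, float(f.max()), float(f.min())]),
        ]
    else:
        starts = [np.asarray(p0, dtype=float)]
    best = None
    for start in starts:
        start = np.clip(start, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(residuals, start, bounds=(lo, hi), x_scale="jac", max_nfev=3000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("fit_hill: optimizer failed to converge", last_fit=best)
    # the parameterization is exactly symmetric under (h, fmax, fmin) ->
    # (-h, fmin, fmax); canonicalize so fmax >= fmin and the slope sign
    # reflects the response direction
    if best.x[2] < best.x[3]:
        best.x[1] = -best.x[1]
        best.x[2], best.x[3] = best.x[3], best.x[2]
    return best


def fit_hill(
    points,
    bootstrap: int = 1000,
    seed: int | None = None,
    cells: list | None = None,
    preparation: str = "cell",
) -> HillFit:
    """Least-squares modified-Hill fit of normalized response points.

    ``points`` are (concentration M, normalized F) pairs, pooled across cells
    when ``cells`` labels are given.  The asymptotes ``fmax``/``fmin`` are
    fitted rather than pinned at 1/0 so the normalization convention does not
    bias EC50 or slope.  The 95% CI is a seeded nonparametric bootstrap:
    plain resampling over points, or — when cell labels are provided — a
    two-stage cluster bootstrap (resample cells with replacement, then points
    within each chosen cell), which keeps interval widths stable when the
    number of cells is small.  Percentile levels carry the expanded-
    percentile small-sample correction (Hesterberg 2015) based on the number
    of resampling units.  ``bootstrap=0`` skips the CI.
    """
    pts = np.asarray([(c, f) for c, f in points], dtype=float)
    if pts.shape[0] < 4:
        raise DataError(f"fit_hill: need >= 4 points, got {pts.shape[0]}")
    if np.any(pts[:, 0] <= 0):
        raise DataError("fit_hill: concentrations must be positive")
    logc, f = np.log10(pts[:, 0]), pts[:, 1]

    best = _hill_point_fit(logc, f)
    log_ec50, h, fmax, fmin = best.x
    ec50 = float(10.0**log_ec50)
    boundary = not (pts[:, 0].min() <= ec50 <= pts[:, 0].max())
    if boundary:
        warnings.warn(f"fit_hill: EC50 {ec50:g} M outside the applied concentration range")

    ci95 = None
    if bootstrap and bootstrap > 0:
        rng = np.random.default_rng(seed)
        labels = None
        if cells is not None:
            labels = np.asarray(cells)
            if labels.size != pts.shape[0]:
                raise ValidationError("fit_hill: cells labels must match points")
            unique = np.unique(labels)
            idx_by_cell = {c: np.flatnonzero(labels == c) for c in unique}
        samples = {"ec50": [], "slope": [], "fmax": [], "fmin": []}
        n = pts.shape[0]
        for _ in range(int(bootstrap)):
            if labels is None:
                idx = rng.integers(0, n, size=n)
            else:
                chosen = rng.choice(unique, size=unique.size, replace=True)
                idx = np.concatenate(
                    [rng.choice(idx_by_cell[c], idx_by_cell[c].size, replace=True) for c in chosen]
                )
            try:
                res = _hill_point_fit(logc[idx], f[idx], p0=best.x)
            except FitError:
                continue
            b_log_ec50, b_h, b_fmax, b_fmin = res.x
            samples["ec50"].append(10.0**b_log_ec50)
            samples["slope"].append(b_h)
            samples["fmax"].append(b_fmax)
            samples["fmin"].append(b_fmin)
        if len(samples["ec50"]) >= max(10, bootstrap // 10):
            # expanded percentile levels (Hesterberg 2015): the plain
            # percentile interval is systematically narrow when the number of
            # resampling units is small (here often 6 cells), so the nominal
            # 2.5/97.5 levels are widened via the t distribution on n-1 df
            n_units = int(unique.size) if labels is not None else int(n)
            if n_units > 2:
                z_exp = np.sqrt(n_units / (n_units - 1)) * t_dist.ppf(0.975, n_units - 1)
                lo_level = 100.0 * float(norm.cdf(-z_exp))
            else:
                lo_level = 2.5
            hi_level = 100.0 - lo_level
            ci95 = {
                key: [float(np.percentile(vals, lo_level)), float(np.percentile(vals, hi_level))]
                for key, vals in samples.items()
            }
        else:
            warnings.warn("fit_hill: too few successful bootstrap resamples; CI omitted")

    return HillFit(
        ec50=ec50,
        slope=float(h),
        fmax=float(fmax),
        fmin=float(fmin),
        ci95=ci95,
        preparation=preparation,
        n_points=int(pts.shape[0]),
        n_cells=None if cells is None else int(np.unique(np.asarray(cells)).size),
        boundary_flag=bool(boundary),
        residual_ss=float(2 * best.cost),
    )


def maximal_quench(per_cell_peaks: dict) -> tuple[float, float | None, dict]:
    """Saturating quench fraction per cell: ``1 - F(sat) / F(lowest)``.

    ``per_cell_peaks`` maps cell id to its (conc, corrected intensity) list.
    Returns (mean, SEM across cells, per-cell fractions); SEM is ``None``
    for a single cell.
    """
    fractions = {}
    for cell_id, peaks in per_cell_peaks.items():
        pts = sorted((float(c), float(f)) for c, f in peaks)
        if len(pts) < 2:
            raise DataError(f"maximal_quench: cell {cell_id} needs lowest and saturating points")
        f_low, f_sat = pts[0][1], pts[-1][1]
        if f_low <= 0:
            raise DataError(f"maximal_quench: nonpositive lowest-concentration intensity in {cell_id}")
        fractions[cell_id] = 1.0 - f_sat / f_low
    values = np.array(list(fractions.values()))
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else None
    return mean, sem, fractions


@dataclass
class BindingResult:
    """Output of the full binding pipeline."""

    hill: HillFit
    max_quench_mean: float
    max_quench_sem: float | None
    per_cell_quench: dict
    bleach_models: dict
    points: list
    cells: list


def binding_pipeline(
    series_list: list[ExposureSeries],
    band: tuple[float, float] | None = None,
    bootstrap: int = 1000,
    seed: int | None = None,
    resample: str = "cells",
) -> BindingResult:
    """Bleach-correct, normalize, and pool cells into one Hill fit.

    Each cell is normalized independently; the pooled points share a single
    fit.  ``resample`` chooses the bootstrap unit ('cells' or 'points').
    """
    if not series_list:
        raise ValidationError("binding_pipeline: no exposure series given")
    if resample not in ("cells", "points"):
        raise ValidationError(f"binding_pipeline: unknown resample unit {resample!r}")
    points: list[tuple[float, float]] = []
    cell_labels: list[str] = []
    per_cell_peaks = {}
    bleach_models = {}
    for series in series_list:
        cell_band = band if band is not None else default_band(series)
        model = fit_bleach(series, band=cell_band)
        corrected = bleach_correct(series, model)
        peaks = corrected_peaks(corrected, band=cell_band)
        per_cell_peaks[series.cell_id] = peaks
        bleach_models[series.cell_id] = model
        for c, f in normalize_response(peaks):
            points.append((c, f))
            cell_labels.append(series.cell_id)
    preparation = series_list[0].preparation
    hill = fit_hill(
        points,
        bootstrap=bootstrap,
        seed=seed,
        cells=cell_labels if (len(series_list) > 1 and resample == "cells") else None,
        preparation=preparation,
    )
    mq_mean, mq_sem, per_cell = maximal_quench(per_cell_peaks)
    return BindingResult(
        hill=hill,
        max_quench_mean=mq_mean,
        max_quench_sem=mq_sem,
        per_cell_quench=per_cell,
        bleach_models=bleach_models,
        points=points,
        cells=cell_labels,
    )
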