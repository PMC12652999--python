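"""Time-resolved photoluminescence (TRPL) and transient absorption (TAS)
analysis by iterative IRF reconvolution.

Measured decays are modeled as the discrete causal convolution of the
normalized instrument response function (IRF) with a molecular decay law
``h(t)`` — a single exponential, a biexponential, or second-order kinetics
``a / (1 + k t)`` — plus a constant baseline, with an adjustable time-zero
shift of the IRF.  Fitting the convolved model ("reconvolution") rather than
deconvolving the data allows lifetimes shorter than the excitation pulse
width to be recovered.

TAS traces are constructed from raw pump-probe intensities as

    dOD(t) = -log10( (I_pumped(t) - I_fluorescence(t)) / I_unpumped(t) ),

so a positive dOD is an absorbing photoproduct and a negative dOD a
ground-state bleach.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_coeffs, savgol_filter

from .errors import DataError, FitError, GridMismatchError, ValidationError

__all__ = [
    "DecayTrace",
    "IRF",
    "ReconvolutionFit",
    "build_tas_trace",
    "subtract_background_trace",
    "convolve_with_irf",
    "fit_reconvolution",
    "compare_decay_models",
    "residual_plateau",
    "savitzky_golay",
]

MODELS = ("exp1", "exp2", "second_order")
_N_DECAY_PARAMS = {"exp1": 2, "exp2": 4, "second_order": 2}


@dataclass(frozen=True)
class DecayTrace:
    """Uniform-grid time-resolved signal (counts for TRPL, dOD for TAS).

    Masked points (e.g. nonpositive TAS numerators) are NaN and are excluded
    from every downstream statistic and fit.
    """

    time: np.ndarray
    signal: np.ndarray
    kind: str = "trpl"
    averages: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        t = self.time
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("DecayTrace: need at least two time points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("DecayTrace: time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * dt[0] + 1e-12:
            raise ValidationError("DecayTrace: time grid must be uniform")
        if self.signal.shape != t.shape:
            raise ValidationError("DecayTrace: signal and time lengths differ")
        if self.kind not in ("trpl", "tas"):
            raise ValidationError(f"DecayTrace: unknown kind {self.kind!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def with_signal(self, signal: np.ndarray, **meta) -> "DecayTrace":
        return DecayTrace(self.time, signal, self.kind, self.averages, {**self.meta, **meta})


@dataclass(frozen=True)
class IRF:
    """Instrument response on a uniform time grid, normalized to unit sum."""

    time: np.ndarray
    response: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        resp = np.asarray(self.response, dtype=float)
        if resp.shape != self.time.shape:
            raise ValidationError("IRF: response and time lengths differ")
        if np.any(resp < 0):
            raise ValidationError("IRF: response must be nonnegative")
        total = resp.sum()
        if total <= 0:
            raise ValidationError("IRF: response sums to zero")
        if abs(total - 1.0) > 1e-12:
            resp = resp / total
        object.__setattr__(self, "response", resp)

    @property
    def peak_time(self) -> float:
        return float(self.time[int(np.argmax(self.response))])


def _require_same_time_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape or not np.allclose(a, b, rtol=0, atol=1e-9):
        raise GridMismatchError(f"{what}: time grids differ")


def build_tas_trace(pumped: DecayTrace, unpumped: DecayTrace, fluorescence: DecayTrace) -> DecayTrace:
    """Construct the dOD trace from pumped/unpumped/fluorescence intensities.

    Points where ``I_pumped - I_fluorescence <= 0`` (detector overload near
    peak irradiance, noise at vanishing intensity) are masked as NaN and
    counted in the metadata.
    """
    _require_same_time_grid(pumped.time, unpumped.time, "build_tas_trace")
    _require_same_time_grid(pumped.time, fluorescence.time, "build_tas_trace")
    if np.any(unpumped.signal <= 0):
        raise DataError("build_tas_trace: unpumped intensity must be positive everywhere")
    numerator = pumped.signal - fluorescence.signal
    bad = numerator <= 0
    if np.all(bad):
        raise DataError("build_tas_trace: every point has nonpositive numerator")
    dod = np.full_like(numerator, np.nan)
    ok = ~bad
    dod[ok] = -np.log10(numerator[ok] / unpumped.signal[ok])
    return DecayTrace(
        pumped.time,
        dod,
        kind="tas",
        averages=pumped.averages,
        meta={**pumped.meta, "n_masked": int(bad.sum())},
    )


def subtract_background_trace(mixture: DecayTrace, background: DecayTrace) -> DecayTrace:
    """Pointwise subtraction of a separately measured background trace.

    The background is subtracted as measured (scale 1.0).  Grids and kinds
    must match; the mixture's shot-average metadata is propagated.
    """
    _require_same_time_grid(mixture.time, background.time, "subtract_background_trace")
    if mixture.kind != background.kind:
        raise GridMismatchError(
            f"subtract_background_trace: kind mismatch {mixture.kind!r} vs {background.kind!r}"
        )
    return mixture.with_signal(
        mixture.signal - background.signal,
        background_subtracted=True,
    )


def _decay_law(model: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    if model == "exp1":
        a, tau = theta
        return a * np.exp(-t / tau)
    if model == "exp2":
        a1, tau1, a2, tau2 = theta
        return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    if model == "second_order":
        a, k = theta
        return a / (1.0 + k * t)
    raise ValidationError(f"unknown decay model {model!r}")


def _shifted_irf(irf: IRF, t0: float) -> np.ndarray:
    resp = np.interp(irf.time - t0, irf.time, irf.response, left=0.0, right=0.0)
    total = resp.sum()
    if total <= 0:
        return resp
    return resp / total


def convolve_with_irf(irf: IRF, grid: np.ndarray, model: str, params, t0: float = 0.0) -> np.ndarray:
    """Causal discrete convolution of the (sum-normalized) IRF with a decay law.

    ``params`` is a dict: ``{"amplitudes": [...], "lifetimes": [...]}`` for
    exponential models or ``{"amplitude": a, "rate": k}`` for second-order
    kinetics.  The decay law is evaluated from the start of the grid; because
    the discrete IRF has unit sum, the convolution preserves the discrete
    integral of the decay away from the grid edges.
    """
    grid = np.asarray(grid, dtype=float)
    if model in ("exp1", "exp2"):
        amps = np.atleast_1d(np.asarray(params["amplitudes"], dtype=float))
        taus = np.atleast_1d(np.asarray(params["lifetimes"], dtype=float))
        if np.any(taus <= 0):
            raise ValidationError("convolve_with_irf: lifetimes must be positive")
        theta = np.ravel(np.column_stack([amps, taus]))
        model_key = "exp1" if taus.size == 1 else "exp2"
    elif model == "second_order":
        theta = np.array([params["amplitude"], params["rate"]], dtype=float)
        model_key = model
    else:
        raise ValidationError(f"convolve_with_irf: unknown model {model!r}")
    h = _decay_law(model_key, theta, grid - grid[0])
    resp = _shifted_irf(irf, t0)
    return np.convolve(resp, h)[: grid.size]


@dataclass
class ReconvolutionFit:
    """Result of a weighted reconvolution fit."""

    model: str
    lifetimes: tuple  # ns, increasing order for exp2; empty for second_order
    amplitudes: tuple
    rate: float | None  # 1/ns, second-order kinetics only
    t0_shift: float
    baseline: float
    reduced_chi_sq: float
    stderr: dict
    aicc: float
    n_points: int
    n_params: int
    success: bool
    boundary_flag: bool

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "lifetimes_ns": list(self.lifetimes),
            "amplitudes": list(self.amplitudes),
            "rate_per_ns": self.rate,
            "t0_ns": self.t0_shift,
            "baseline": self.baseline,
            "reduced_chi_sq": self.reduced_chi_sq,
            "aicc": self.aicc,
            "stderr": self.stderr,
            "n_points": self.n_points,
            "boundary_flag": self.boundary_flag,
        }


_PARAM_NAMES = {
    "exp1": ["amplitude", "lifetime", "t0", "baseline"],
    "exp2": ["amplitude_1", "lifetime_1", "amplitude_2", "lifetime_2", "t0", "baseline"],
    "second_order": ["amplitude", "rate", "t0", "baseline"],
}

_TAU_STARTS = (0.5, 2.0, 8.0)
_TAU_BOUNDS = (1e-3, 1e4)
_RATE_BOUNDS = (1e-6, 1e4)


def _starts_for(model: str, amp_scale: float):
    if model == "exp1":
        return [np.array([amp_scale, tau]) for tau in _TAU_STARTS]
    if model == "exp2":
        pairs = [(0.5, 2.0), (2.0, 8.0), (0.5, 8.0)]
        return [np.array([amp_scale / 2, t1, amp_scale / 2, t2]) for t1, t2 in pairs]
    return [np.array([amp_scale, 1.0 / tau]) for tau in _TAU_STARTS]


def fit_reconvolution(
    trace: DecayTrace,
    irf: IRF,
    model: str = "exp1",
    weighting: str = "poisson",
    mask: np.ndarray | None = None,
    fit_start: float | None = None,
    t0_bound: float = 5.0,
    max_nfev: int = 5000,
) -> ReconvolutionFit:
    """Weighted least-squares reconvolution fit of a decay trace.

    ``weighting='poisson'`` uses ``var = max(signal, 1)`` (count data);
    ``weighting='uniform'`` uses unit weights (dOD data, where EMI
    oscillations are fitted through rather than filtered out).  ``mask`` is a
    boolean include-array; ``fit_start`` drops all points before a time (used
    to exclude the TAS overload artifact).  The time-zero shift is bounded to
    +/- ``t0_bound`` ns around the measured IRF position to prevent the
    lifetime/shift degeneracy when lifetimes are shorter than the pulse.
    Three lifetime starts (0.5, 2, 8 ns) guard against local minima.
    """
    if model not in MODELS:
        raise ValidationError(f"fit_reconvolution: unknown model {model!r}")
    if weighting not in ("poisson", "uniform"):
        raise ValidationError(f"fit_reconvolution: unknown weighting {weighting!r}")

    t = trace.time
    sig = trace.signal
    include = np.isfinite(sig)
    if mask is not None:
        include &= np.asarray(mask, dtype=bool)
    if fit_start is not None:
        include &= t >= fit_start
    n = int(include.sum())
    n_decay = _N_DECAY_PARAMS[model]
    n_par = n_decay + 2
    if n < max(10, n_par + 2):
        raise DataError(f"fit_reconvolution: only {n} usable points")

    y = sig[include]
    if weighting == "poisson":
        sigma = np.sqrt(np.maximum(np.abs(y), 1.0))
    else:
        sigma = np.ones_like(y)

    baseline0 = float(np.percentile(y, 10))
    amp_scale = max(float(np.max(y) - baseline0), 1e-12)
    t_rel = t - t[0]

    def model_signal(p: np.ndarray) -> np.ndarray:
        theta, t0, base = p[:n_decay], p[n_decay], p[n_decay + 1]
        h = _decay_law(model, theta, t_rel)
        resp = _shifted_irf(irf, t0)
        return np.convolve(resp, h)[: t.size] + base

    def residuals(p: np.ndarray) -> np.ndarray:
        return (model_signal(p)[include] - y) / sigma

    lo = np.full(n_par, -np.inf)
    hi = np.full(n_par, np.inf)
    if model in ("exp1", "exp2"):
        for j in range(1, n_decay, 2):
            lo[j], hi[j] = _TAU_BOUNDS
    else:
        lo[1], hi[1] = _RATE_BOUNDS
    lo[n_decay], hi[n_decay] = -t0_bound, t0_bound

    best = None
    for start_decay in _starts_for(model, amp_scale):
        p0 = np.concatenate([start_decay, [0.0, baseline0]])
        # rescale the amplitude guess so the convolved peak matches the data
        trial = model_signal(p0) - baseline0
        peak = float(np.max(np.abs(trial)))
        if peak > 0:
            for j in range(0, n_decay, 2):
                p0[j] *= amp_scale / peak
        p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                residuals, p0, bounds=(lo, hi), x_scale="jac", max_nfev=max_nfev
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError(f"fit_reconvolution: no start converged for model {model!r}", last_fit=best)

    p = best.x
    chi2 = float(2.0 * best.cost)
    dof = max(n - n_par, 1)
    red_chi2 = chi2 / dof
    jac = best.jac
    try:
        cov = np.linalg.pinv(jac.T @ jac) * red_chi2
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(n_par, np.nan)

    names = list(_PARAM_NAMES[model])
    theta = p[:n_decay].copy()
    errs = perr.copy()
    if model == "exp2" and theta[1] > theta[3]:
        theta = theta[[2, 3, 0, 1]]
        errs[:4] = errs[[2, 3, 0, 1]]
    if model in ("exp1", "exp2"):
        lifetimes = tuple(float(theta[j]) for j in range(1, n_decay, 2))
        amplitudes = tuple(float(theta[j]) for j in range(0, n_decay, 2))
        rate = None
        boundary = any(
            tau <= _TAU_BOUNDS[0] * (1 + 1e-6) or tau >= _TAU_BOUNDS[1] * (1 - 1e-6)
            for tau in lifetimes
        )
    else:
        lifetimes = ()
        amplitudes = (float(theta[0]),)
        rate = float(theta[1])
        boundary = rate <= _RATE_BOUNDS[0] * (1 + 1e-6) or rate >= _RATE_BOUNDS[1] * (1 - 1e-6)
    boundary = boundary or abs(p[n_decay]) >= t0_bound * (1 - 1e-6)
    if boundary:
        warnings.warn(f"fit_reconvolution: {model} parameters at bounds")

    # small-sample-corrected AIC on the weighted Gaussian likelihood
    aic = n * math.log(max(chi2 / n, 1e-300)) + 2 * n_par
    aicc = aic + (2 * n_par * (n_par + 1)) / (n - n_par - 1) if n - n_par - 1 > 0 else math.inf

    return ReconvolutionFit(
        model=model,
        lifetimes=lifetimes,
        amplitudes=amplitudes,
        rate=rate,
        t0_shift=float(p[n_decay]),
        baseline=float(p[n_decay + 1]),
        reduced_chi_sq=red_chi2,
        stderr={name: float(e) for name, e in zip(names, errs)},
        aicc=float(aicc),
        n_points=n,
        n_params=n_par,
        success=bool(best.success),
        boundary_flag=bool(boundary),
    )


def compare_decay_models(
    trace: DecayTrace,
    irf: IRF,
    weighting: str = "poisson",
    mask: np.ndarray | None = None,
    fit_start: float | None = None,
) -> list[tuple[str, ReconvolutionFit, float]]:
    """Fit exp1, exp2, and second-order kinetics; rank by AICc.

    Models whose AICc lies within 2 of the best are treated as statistically
    indistinguishable (the usual information-criterion convention) and the
    tie is broken toward fewer parameters, so a needless biexponential never
    outranks a single exponential it cannot beat.
    """
    fits: dict[str, ReconvolutionFit] = {}
    failures: dict[str, str] = {}
    for model in MODELS:
        try:
            fits[model] = fit_reconvolution(
                trace, irf, model=model, weighting=weighting, mask=mask, fit_start=fit_start
            )
        except (FitError, DataError) as exc:  # recorded per model
            failures[model] = str(exc)
    if not fits:
        raise FitError(f"compare_decay_models: every model failed: {failures}")

    remaining = dict(fits)
    ranked: list[tuple[str, ReconvolutionFit, float]] = []
    while remaining:
        best_aicc = min(f.aicc for f in remaining.values())
        tied = [m for m, f in remaining.items() if f.aicc <= best_aicc + 2.0]
        winner = min(tied, key=lambda m: (remaining[m].n_params, remaining[m].aicc))
        ranked.append((winner, remaining[winner], remaining[winner].aicc))
        del remaining[winner]
    return ranked


def residual_plateau(trace: DecayTrace, window: tuple[float, float]) -> tuple[float, float]:
    """Mean and standard error of the signal over a late-time window.

    A trace that has fully recovered has a plateau mean within two standard
    errors of zero; a permanent photoproduct shows up as a positive offset.
    """
    lo, hi = window
    if lo >= hi or hi < trace.time[0] or lo > trace.time[-1]:
        raise DataError(f"residual_plateau: window [{lo:g}, {hi:g}] ns outside the trace grid")
    sel = (trace.time >= lo) & (trace.time <= hi) & np.isfinite(trace.signal)
    n = int(sel.sum())
    if n < 5:
        raise DataError(f"residual_plateau: only {n} points in window (need >= 5)")
    values = trace.signal[sel]
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(n))


def savitzky_golay(trace: DecayTrace, window: int = 21, order: int = 2) -> DecayTrace:
    """Savitzky-Golay smoothing on the unchanged time grid.

    Endpoints are handled by the polynomial fit on truncated windows
    (scipy's ``mode='interp'``).  Exact on polynomials up to ``order``.
    """
    if window % 2 == 0:
        raise ValidationError(f"savitzky_golay: window must be odd, got {window}")
    if order >= window:
        raise ValidationError(f"savitzky_golay: order {order} must be < window {window}")
    smoothed = savgol_filter(trace.signal, window_length=window, polyorder=order, mode="interp")
    return trace.with_signal(smoothed, savgol_window=window, savgol_order=order)


def savitzky_golay_variance_gain(window: int = 21, order: int = 2) -> float:
    """White-noise variance reduction factor of the central SG filter."""
    c = savgol_coeffs(window, order)
    return float(np.sum(c**2))
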