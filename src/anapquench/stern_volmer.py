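"""Stern-Volmer analysis of collisional quenching titrations.

For a collisional quencher at concentration ``[Q]`` the ratio of unquenched
to quenched fluorescence follows a straight line,

    F0 / F = F_intercept + K_sv * [Q],

whose slope ``K_sv`` (per molar) measures quenching efficiency and whose
intercept is expected near one.  ``F`` is the mean peak fluorescence over a
fixed band (default 445-455 nm) of each blank-subtracted spectrum, optionally
corrected for the inner-filter effect; ``F0`` comes from the zero-quencher
spectrum of the same replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, FitError, ValidationError
from .spectra import AbsorbanceSpectrum, Spectrum, band_mean, inner_filter_correct

__all__ = [
    "TitrationSeries",
    "SternVolmerFit",
    "stern_volmer_ratios",
    "fit_stern_volmer",
    "quench_fraction",
    "average_fits",
]


@dataclass
class TitrationSeries:
    """Quencher-concentration-labeled spectra for one replicate.

    ``conc`` is molar, strictly increasing, and must contain 0 (defines F0).
    ``spectra`` are blank-subtracted emission spectra, one per concentration.
    ``absorbances`` (optional, needed for inner-filter correction) are the
    measured OD spectra of the corresponding solutions.
    """

    conc: np.ndarray
    spectra: list[Spectrum]
    absorbances: list[AbsorbanceSpectrum] | None = None
    quencher: str = "5-HT"
    excitation_nm: float = 370.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.ndim != 1 or self.conc.size < 2:
            raise ValidationError("TitrationSeries: need at least two concentrations")
        if np.any(np.diff(self.conc) <= 0):
            raise ValidationError("TitrationSeries: concentrations must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValidationError("TitrationSeries: concentrations must be >= 0")
        if self.conc[0] != 0.0:
            raise ValidationError("TitrationSeries: concentration 0 (F0 reference) must be present")
        if len(self.spectra) != self.conc.size:
            raise ValidationError("TitrationSeries: one spectrum per concentration required")
        if self.absorbances is not None and len(self.absorbances) != self.conc.size:
            raise ValidationError("TitrationSeries: one absorbance per concentration required")


@dataclass
class SternVolmerFit:
    """Ordinary-least-squares line through (concentration, F0/F) points."""

    ksv: float
    intercept: float
    r_squared: float
    ksv_stderr: float
    intercept_stderr: float
    corrected: bool = False
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "ksv_per_M": self.ksv,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "ksv_stderr": self.ksv_stderr,
            "intercept_stderr": self.intercept_stderr,
            "corrected": self.corrected,
            "n_points": self.n_points,
        }


def stern_volmer_ratios(
    series: TitrationSeries,
    band: tuple[float, float] = (445.0, 455.0),
    apply_inner_filter: bool = False,
) -> list[tuple[float, float]]:
    """F0/F per quencher concentration (the zero concentration is excluded).

    With ``apply_inner_filter`` each spectrum is first corrected using its
    solution's absorbance spectrum; OD at the excitation wavelength is read
    off the same absorbance spectrum.
    """
    if apply_inner_filter and series.absorbances is None:
        raise ValidationError(
            "stern_volmer_ratios: inner-filter correction requested but the series "
            "has no absorbance spectra"
        )
    values = []
    for i, c in enumerate(series.conc):
        spec = series.spectra[i]
        if apply_inner_filter:
            absorbance = series.absorbances[i]
            od_ex = absorbance.od_at(series.excitation_nm)
            spec = inner_filter_correct(spec, od_ex, absorbance)
        f = band_mean(spec, *band)
        if f <= 0:
            raise DataError(
                f"stern_volmer_ratios: nonpositive band fluorescence ({f:g}) at "
                f"{c:g} M {series.quencher}"
            )
        values.append(f)
    f0 = values[0]
    return [(float(c), f0 / f) for c, f in zip(series.conc[1:], values[1:])]


def fit_stern_volmer(points, corrected: bool = False) -> SternVolmerFit:
    """Unweighted OLS of F0/F on concentration (slope = K_sv)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise FitError("fit_stern_volmer: need at least two (conc, ratio) points")
    conc, ratio = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise FitError("fit_stern_volmer: all concentrations are equal")
    res = stats.linregress(conc, ratio)
    return SternVolmerFit(
        ksv=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ksv_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
        corrected=corrected,
        n_points=int(conc.size),
    )


def quench_fraction(f0_over_f: float) -> float:
    """Quenched fraction ``1 - 1/(F0/F)``.

    Ratios below one (apparent enhancement, e.g. a solvatochromic intensity
    increase at low quencher) yield a negative fraction and a warning rather
    than an error.
    """
    if f0_over_f <= 0:
        raise DataError(f"quench_fraction: F0/F must be positive, got {f0_over_f:g}")
    if f0_over_f < 1:
        warnings.warn(
            f"quench_fraction: F0/F = {f0_over_f:g} < 1 (fluorescence enhancement); "
            "returning a negative fraction"
        )
    return 1.0 - 1.0 / f0_over_f


def average_fits(fits: list[SternVolmerFit]) -> dict:
    """Mean and SEM of K_sv and intercept across replicate fits."""
    if not fits:
        raise ValidationError("average_fits: no fits given")
    ksv = np.array([f.ksv for f in fits])
    inter = np.array([f.intercept for f in fits])
    n = len(fits)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else None  # noqa: E731
    return {
        "n_replicates": n,
        "ksv_per_M_mean": float(ksv.mean()),
        "ksv_per_M_sem": sem(ksv),
        "intercept_mean": float(inter.mean()),
        "intercept_sem": sem(inter),
    }
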