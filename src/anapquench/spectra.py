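"""Steady-state emission and absorbance spectra with the corrections applied
before any quenching analysis.

A :class:`Spectrum` is a wavelength-indexed emission intensity (arbitrary
units); an :class:`AbsorbanceSpectrum` is a wavelength-indexed optical
density.  The operations here implement the standard steady-state
pre-processing chain for a quenching titration:

1. blank subtraction (removes quencher autofluorescence),
2. local-kernel smoothing of the absorbance spectra,
3. multiplicative inner-filter correction,
   ``F = F_obs * 10**((g * OD_ex + OD_em(lam)) / 2)``,
   where ``g`` is a geometric factor for the short excitation path of a
   low-volume cuvette (default 0.2),
4. band statistics (mean intensity over a fixed wavelength window, peak
   wavelength for solvatochromic-shift reporting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, DataError, GridMismatchError, ValidationError

__all__ = [
    "Spectrum",
    "AbsorbanceSpectrum",
    "subtract_blank",
    "smooth_spectrum",
    "inner_filter_correct",
    "band_mean",
    "peak_wavelength",
]


def _validate_grid(wavelength: np.ndarray, what: str) -> None:
    if wavelength.ndim != 1 or wavelength.size == 0:
        raise ValidationError(f"{what}: wavelength grid must be a nonempty 1-d array")
    if not np.all(np.isfinite(wavelength)):
        raise ValidationError(f"{what}: wavelength grid contains non-finite values")
    if np.any(np.diff(wavelength) <= 0):
        raise ValidationError(f"{what}: wavelength grid must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """Emission spectrum: intensity (a.u.) on a strictly increasing nm grid.

    Negative intensities are permitted only on blank-subtracted spectra
    (``meta['blank_subtracted']``); they are retained, not clipped, because
    clipping would bias band means.
    """

    wavelength: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "wavelength", np.asarray(self.wavelength, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        _validate_grid(self.wavelength, "Spectrum")
        if self.intensity.shape != self.wavelength.shape:
            raise ValidationError("Spectrum: intensity and wavelength lengths differ")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("Spectrum: intensity contains non-finite values")

    def with_intensity(self, intensity: np.ndarray, **meta) -> "Spectrum":
        return Spectrum(self.wavelength, intensity, {**self.meta, **meta})


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Optical density (dimensionless) on a strictly increasing nm grid."""

    wavelength: np.ndarray
    od: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "wavelength", np.asarray(self.wavelength, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        _validate_grid(self.wavelength, "AbsorbanceSpectrum")
        if self.od.shape != self.wavelength.shape:
            raise ValidationError("AbsorbanceSpectrum: od and wavelength lengths differ")
        if not np.all(np.isfinite(self.od)):
            raise ValidationError("AbsorbanceSpectrum: od contains non-finite values")

    def od_at(self, wavelength_nm: float) -> float:
        """OD at a single wavelength (linear interpolation, no extrapolation)."""
        lam = self.wavelength
        if not (lam[0] <= wavelength_nm <= lam[-1]):
            raise CoverageError(
                f"absorbance spectrum [{lam[0]:g}, {lam[-1]:g}] nm does not cover "
                f"{wavelength_nm:g} nm"
            )
        return float(np.interp(wavelength_nm, lam, self.od))


def _require_same_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape or not np.array_equal(a, b):
        if a.shape == b.shape:
            i = int(np.argmax(a != b))
            raise GridMismatchError(
                f"{what}: grids differ first at index {i} "
                f"({a[i]:.6g} nm vs {b[i]:.6g} nm)"
            )
        raise GridMismatchError(f"{what}: grids have different lengths {a.size} vs {b.size}")


def subtract_blank(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Pointwise blank subtraction of a quencher-only emission spectrum.

    Requires identical wavelength grids.  The result keeps the sample's
    metadata, records the blank id, and flags any negative points (retained,
    not clipped).
    """
    _require_same_grid(sample.wavelength, blank.wavelength, "subtract_blank")
    intensity = sample.intensity - blank.intensity
    n_negative = int(np.sum(intensity < 0))
    return sample.with_intensity(
        intensity,
        blank_subtracted=True,
        blank_id=blank.meta.get("sample_id", "blank"),
        n_negative_points=n_negative,
    )


def smooth_spectrum(spec: AbsorbanceSpectrum, bandwidth: float = 0.25) -> AbsorbanceSpectrum:
    """Local Gaussian-kernel smoothing of an absorbance spectrum.

    The kernel has sigma equal to ``bandwidth`` (nm), is truncated at
    +/- 4 sigma, and is renormalized at the grid edges so that constants are
    preserved everywhere (no boundary droop).  The grid is unchanged.
    """
    if not bandwidth > 0:
        raise ValidationError(f"smooth_spectrum: bandwidth must be > 0, got {bandwidth}")
    lam = spec.wavelength
    # pairwise distances; grids are short (hundreds of points) so the dense
    # matrix is cheap and handles non-uniform grids for free
    d = lam[:, None] - lam[None, :]
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    w[np.abs(d) > 4.0 * bandwidth] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    od = w @ spec.od
    return AbsorbanceSpectrum(lam, od, {**spec.meta, "smoothed_bandwidth_nm": bandwidth})


def inner_filter_correct(
    spec: Spectrum,
    od_ex: float,
    absorbance: AbsorbanceSpectrum,
    excitation_path_factor: float = 0.2,
) -> Spectrum:
    """Correct an emission spectrum for the inner-filter effect.

    ``F(lam) = F_obs(lam) * 10**((g*OD_ex + OD_em(lam)) / 2)`` where ``OD_ex``
    is the optical density at the excitation wavelength, ``OD_em`` the optical
    density at each emission wavelength, and ``g`` the excitation-path
    geometric factor (0.2 for a low-volume cuvette with a short, 0.2 cm path
    toward the excitation light).  The absorbance spectrum must cover the full
    emission range: no silent extrapolation.
    """
    if not np.isfinite(od_ex):
        raise ValidationError("inner_filter_correct: od_ex must be finite")
    lam = spec.wavelength
    alam = absorbance.wavelength
    if lam[0] < alam[0] or lam[-1] > alam[-1]:
        raise CoverageError(
            f"absorbance range [{alam[0]:g}, {alam[-1]:g}] nm does not cover the "
            f"emission range [{lam[0]:g}, {lam[-1]:g}] nm"
        )
    od_em = np.interp(lam, alam, absorbance.od)
    factor = 10.0 ** ((excitation_path_factor * od_ex + od_em) / 2.0)
    return spec.with_intensity(
        spec.intensity * factor,
        inner_filter_corrected=True,
        inner_filter={
            "od_ex": float(od_ex),
            "excitation_path_factor": float(excitation_path_factor),
            "factor_min": float(factor.min()),
            "factor_max": float(factor.max()),
        },
    )


def band_mean(spec: Spectrum, lo: float = 445.0, hi: float = 455.0) -> float:
    """Mean intensity over grid points with ``lo <= lam <= hi`` (inclusive).

    Band endpoints are interpreted on the measured grid, with no
    interpolation, for reproducibility.
    """
    if not lo < hi:
        raise ValidationError(f"band_mean: need lo < hi, got [{lo}, {hi}]")
    sel = (spec.wavelength >= lo) & (spec.wavelength <= hi)
    if not np.any(sel):
        raise DataError(
            f"band_mean: no grid points in [{lo:g}, {hi:g}] nm "
            f"(grid spans [{spec.wavelength[0]:g}, {spec.wavelength[-1]:g}] nm)"
        )
    return float(spec.intensity[sel].mean())


def peak_wavelength(spec: Spectrum) -> float:
    """Wavelength of maximum intensity; ties break toward shorter wavelength.

    An all-equal spectrum raises a warning and returns the shortest
    wavelength.
    """
    if spec.wavelength.size == 0:
        raise ValidationError("peak_wavelength: empty spectrum")
    if np.all(spec.intensity == spec.intensity[0]):
        warnings.warn("peak_wavelength: spectrum is constant; returning shortest wavelength")
    return float(spec.wavelength[int(np.argmax(spec.intensity))])
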