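"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator emulates one acquisition of the assay with a known ground
truth, so the analysis chain can be verified end-to-end by parameter
recovery without any external data:

* ``simulate_titration`` — solution quenching titration: asymmetric
  fluorophore emission band, concentration-proportional quencher
  autofluorescence (matched blanks), optional Beer-Lambert inner-filter
  attenuation, and intensities constructed so the measured F0/F ratios lie
  exactly on the configured Stern-Volmer line before noise.
* ``simulate_trpl`` / ``simulate_mixture_trpl`` — photon-counting decays as
  the convolution of a Gaussian IRF (8 ns FWHM on 0.4 ns bins) with a single
  exponential, with Poisson noise scaled by the number of averaged shots.
* ``simulate_tas`` — the pumped/unpumped/fluorescence intensity triple of a
  pump-probe experiment whose reconstructed dOD trace is an IRF-convolved
  exponential photoproduct decay, plus a detector-overload artifact near
  peak irradiance and damped-sinusoid electromagnetic interference.
* ``simulate_cell_series`` — cell exposure series: fluorophore band (~495 nm)
  with an overlapping mOrange band (~562 nm), exponential photobleaching,
  and concentration steps whose quench follows the modified Hill equation
  between the protocol anchors (no quench at the lowest applied
  concentration, the full ceiling at the saturating one).

All randomness flows from one master seed through named substreams, so a
given configuration is bit-reproducible at the text-serialization level.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding import Exposure, ExposureSeries
from .errors import CoverageError, ValidationError
from .spectra import AbsorbanceSpectrum, Spectrum, subtract_blank
from .time_resolved import IRF, DecayTrace, convolve_with_irf

__all__ = [
    "TitrationSim",
    "TRPLSim",
    "TASSim",
    "CellSim",
    "SimConfig",
    "simulate_emission_spectrum",
    "simulate_titration",
    "simulate_irf",
    "simulate_trpl",
    "simulate_mixture_trpl",
    "simulate_tas",
    "simulate_cell_series",
    "SimulatedTitration",
    "TASTriple",
    "write_dataset",
    "config_from_json",
]


def stream_rng(seed: int, *tags: str) -> np.random.Generator:
    """Named, platform-stable substream of the master seed."""
    keys = [zlib.crc32(t.encode("utf-8")) & 0x7FFFFFFF for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TitrationSim:
    """Solution-quenching titration ground truth.

    The default Stern-Volmer constant and intercept are the serotonin values
    in DMSO; ``for_dopamine``/``for_corrected`` switch to the weaker
    dopamine quencher or to the intrinsic constant observed after
    inner-filter correction.
    """

    ksv_true: float = 13.3  # 1/M
    intercept_true: float = 0.98
    quencher: str = "5-HT"
    peak_nm: float = 451.0
    band_fwhm_nm: float = 60.0
    asymmetry: float = 0.4
    peak_shift_per_M: float = -40.0  # -4 nm at 100 mM quencher
    amplitude: float = 1000.0
    blank_fraction_at_ref: float = 0.152  # of total signal at the fluorophore peak
    ref_conc_M: float = 0.1
    blank_peak_nm: float = 430.0
    blank_fwhm_nm: float = 80.0
    inner_filter: bool = False
    od_ex_per_M: float = 8.0  # quencher OD at the excitation wavelength
    od_em_decay_nm: float = 40.0  # exponential tail of quencher absorbance
    excitation_nm: float = 370.0
    concentrations: tuple = (0.0, 0.005, 0.01, 0.025, 0.05, 0.1)
    band_nm: tuple = (445.0, 455.0)  # analysis band on which the truth is defined
    noise_sigma: float = 0.01  # additive Gaussian, relative to amplitude
    replicates: int = 3
    grid_nm: tuple = (380.0, 600.0, 1.0)

    def noiseless(self) -> "TitrationSim":
        return dataclasses.replace(self, noise_sigma=0.0)


@dataclass
class TRPLSim:
    """Photon-counting decay ground truth (lifetimes in ns)."""

    lifetimes_ns: dict = field(
        default_factory=lambda: {"anap": 2.776, "serotonin": 2.231, "anap_quenched": 2.14}
    )
    amplitudes: dict = field(
        default_factory=lambda: {"anap": 1000.0, "serotonin": 300.0, "anap_quenched": 1000.0}
    )
    irf_fwhm_ns: float = 8.0
    bin_ns: float = 0.4
    n_bins: int = 256
    irf_center_ns: float = 16.0
    background: float = 2.0  # dark counts per bin
    averages: int = 64
    noise_mode: str | None = "poisson"  # 'poisson' | 'gaussian' | None

    def noiseless(self) -> "TRPLSim":
        return dataclasses.replace(self, noise_mode=None)


@dataclass
class TASSim:
    """Pump-probe photoproduct ground truth."""

    product_tau_ns: float = 3.18
    product_amplitude_dod: float = 0.1  # peak dOD of the bare decay law
    fluor_tau_ns: float = 2.776
    fluor_amplitude: float = 0.2
    unpumped_level: float = 1.0
    artifact_window_ns: tuple = (13.0, 19.0)  # detector overload near peak irradiance
    artifact_amplitude: float = 3.0
    emi_freq_ghz: float = 0.25
    emi_amplitude: float = 0.002  # coherent pickup, relative to the probe level
    emi_damping_ns: float = 20.0
    emi_phase: float = 0.6
    step_dod: float = 0.0  # long-lived photoproduct; 0 = complete recovery
    irf_fwhm_ns: float = 8.0
    bin_ns: float = 0.4
    n_bins: int = 256
    irf_center_ns: float = 16.0
    averages: int = 500
    noise_sigma: float = 0.01  # per-shot relative probe-intensity noise

    def noiseless(self) -> "TASSim":
        return dataclasses.replace(self, noise_sigma=0.0, emi_amplitude=0.0)


@dataclass
class CellSim:
    """Cell / unroofed-membrane exposure-series ground truth.

    EC50 and slope default to the whole-cell concentration-response values;
    ``unroofed()`` switches to the membrane-sheet parameter set.
    """

    ec50_M: float = 594e-9
    slope: float = -0.46
    max_quench: float = 0.66
    quench_sd: float = 0.07  # cell-to-cell spread of the saturating quench
    bleach_amplitude: float = 0.1  # fraction of initial intensity
    bleach_tau_s: float = 150.0
    bleach_offset: float = 0.9
    anap_peak_nm: float = 495.0
    anap_fwhm_nm: float = 70.0
    morange_peak_nm: float = 562.0
    morange_fwhm_nm: float = 45.0
    morange_amplitude: float = 0.5  # relative to the fluorophore band
    amplitude: float = 1000.0
    cell_amplitude_sd: float = 0.2  # lognormal sigma of per-cell brightness
    n_cells: int = 6
    n_pre: int = 5
    step_replicates: int = 1  # consecutive exposures per concentration
    exposure_s: float = 10.0
    concentrations: tuple = (1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5, 3e-5, 1e-4)
    noise_sigma: float = 0.03  # multiplicative, per exposure
    preparation: str = "cell"
    grid_nm: tuple = (400.0, 650.0, 1.0)

    def noiseless(self) -> "CellSim":
        return dataclasses.replace(self, noise_sigma=0.0, quench_sd=0.0, cell_amplitude_sd=0.0)

    def unroofed(self) -> "CellSim":
        return dataclasses.replace(self, ec50_M=160e-9, slope=-0.49, preparation="unroofed")


@dataclass
class SimConfig:
    """Complete seeded ground-truth parameter set for one synthetic study."""

    seed: int | None = None
    titration: TitrationSim = field(default_factory=TitrationSim)
    trpl: TRPLSim = field(default_factory=TRPLSim)
    tas: TASSim = field(default_factory=TASSim)
    cells: CellSim = field(default_factory=CellSim)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValidationError("SimConfig: a seed is mandatory for simulation")
        return int(self.seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def config_from_json(text: str) -> SimConfig:
    raw = json.loads(text)
    unknown = set(raw) - {"seed", "titration", "trpl", "tas", "cells"}
    if unknown:
        raise ValidationError(f"SimConfig: unknown fields {sorted(unknown)}")

    def build(cls, data):
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - names
        if bad:
            raise ValidationError(f"{cls.__name__}: unknown fields {sorted(bad)}")
        data = {
            k: tuple(v) if isinstance(v, list) and not isinstance(getattr(cls, k, None), dict) else v
            for k, v in data.items()
        }
        return cls(**data)

    return SimConfig(
        seed=raw.get("seed"),
        titration=build(TitrationSim, raw.get("titration", {})),
        trpl=build(TRPLSim, raw.get("trpl", {})),
        tas=build(TASSim, raw.get("tas", {})),
        cells=build(CellSim, raw.get("cells", {})),
    )


# ---------------------------------------------------------------------------
# spectra


def _band_profile(lam: np.ndarray, peak: float, fwhm: float, asym: float) -> np.ndarray:
    """Log-normal (Siano-Metzler) emission band: unit height, peak at
    ``peak``, red-tailed for positive asymmetry, zero where undefined."""
    if asym == 0:
        return np.exp(-4.0 * np.log(2.0) * ((lam - peak) / fwhm) ** 2)
    arg = 1.0 + 2.0 * asym * (lam - peak) / fwhm
    out = np.zeros_like(lam)
    ok = arg > 0
    out[ok] = np.exp(-np.log(2.0) * (np.log(arg[ok]) / asym) ** 2)
    return out


def simulate_emission_spectrum(
    peak_nm: float,
    width_nm: float,
    amplitude: float,
    grid: np.ndarray,
    asymmetry: float = 0.4,
    meta: dict | None = None,
) -> Spectrum:
    """Asymmetric (log-normal in wavelength) emission band.

    The grid must cover ``peak +/- width`` so the band maximum and both
    flanks are representable.
    """
    if width_nm <= 0:
        raise ValidationError("simulate_emission_spectrum: width must be positive")
    grid = np.asarray(grid, dtype=float)
    if grid[0] > peak_nm - width_nm or grid[-1] < peak_nm + width_nm:
        raise CoverageError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] nm does not cover the band "
            f"{peak_nm:g} +/- {width_nm:g} nm"
        )
    return Spectrum(grid, amplitude * _band_profile(grid, peak_nm, width_nm, asymmetry), meta or {})


def _nm_grid(spec_grid: tuple) -> np.ndarray:
    lo, hi, step = spec_grid
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass
class SimulatedTitration:
    """Raw spectra, matched quencher blanks, and absorbance spectra for each
    replicate of a synthetic titration, plus the generating configuration."""

    config: TitrationSim
    seed: int
    conc: np.ndarray
    raw: list  # raw[replicate][i_conc] -> Spectrum
    blanks: list  # blanks[replicate][i_conc] -> Spectrum
    absorbances: list  # absorbances[i_conc] -> AbsorbanceSpectrum

    def series(self, replicate: int = 0):
        """Blank-subtracted TitrationSeries for one replicate."""
        from .stern_volmer import TitrationSeries

        spectra = [
            subtract_blank(s, b) for s, b in zip(self.raw[replicate], self.blanks[replicate])
        ]
        return TitrationSeries(
            conc=self.conc,
            spectra=spectra,
            absorbances=self.absorbances,
            quencher=self.config.quencher,
            excitation_nm=self.config.excitation_nm,
            meta={"seed": self.seed, "replicate": replicate},
        )


def simulate_titration(cfg: TitrationSim, seed: int) -> SimulatedTitration:
    """Generate a quenching titration whose measured F0/F ratios lie exactly
    on the configured Stern-Volmer line before noise.

    The ground truth is defined on the analysis band: the zero-quencher
    spectrum has band-mean fluorescence F0, and each quenched spectrum is
    scaled so its band mean is ``F0 / (intercept + K_sv * c)``, giving
    ``F0 / F(c) = intercept + K_sv * c`` exactly for every c > 0 even when
    the solvatochromic peak shift deforms the band (an intercept below one
    encodes the slight brightening seen at low quencher).
    Quencher autofluorescence grows linearly with concentration, anchored to
    the configured fraction of total peak signal at the reference
    concentration, and is emitted as a matched blank.  With ``inner_filter``
    on, both sample and blank are attenuated by the Beer-Lambert factor
    ``10**(-(0.2*OD_ex + OD_em)/2)`` and the corresponding absorbance
    spectra are emitted.
    """
    conc = np.asarray(cfg.concentrations, dtype=float)
    if conc.size < 2 or conc[0] != 0.0 or np.any(np.diff(conc) <= 0):
        raise ValidationError(
            "simulate_titration: concentrations must be strictly increasing and include 0"
        )
    if not 0 < cfg.blank_fraction_at_ref < 1:
        raise ValidationError("simulate_titration: blank_fraction_at_ref must be in (0, 1)")
    lam = _nm_grid(cfg.grid_nm)
    abs_lam = np.arange(360.0, cfg.grid_nm[1] + cfg.grid_nm[2], cfg.grid_nm[2])

    # quencher autofluorescence amplitude anchored at the reference concentration
    anap_peak_ref = cfg.amplitude / (cfg.intercept_true + cfg.ksv_true * cfg.ref_conc_M)
    frac = cfg.blank_fraction_at_ref
    blank_amp_ref = frac / (1.0 - frac) * anap_peak_ref

    absorbances = []
    for c in conc:
        od = c * cfg.od_ex_per_M * np.exp(-(abs_lam - cfg.excitation_nm) / cfg.od_em_decay_nm)
        absorbances.append(
            AbsorbanceSpectrum(abs_lam, od if cfg.inner_filter else np.zeros_like(abs_lam))
        )

    raw, blanks = [], []
    for rep in range(cfg.replicates):
        rng = stream_rng(seed, "titration", cfg.quencher, f"rep{rep}")
        raw_r, blank_r = [], []
        band_sel = (lam >= cfg.band_nm[0]) & (lam <= cfg.band_nm[1])
        profile0 = _band_profile(lam, cfg.peak_nm, cfg.band_fwhm_nm, cfg.asymmetry)
        f0_band = cfg.amplitude * float(profile0[band_sel].mean())
        for i, c in enumerate(conc):
            peak = cfg.peak_nm + cfg.peak_shift_per_M * c
            profile = simulate_emission_spectrum(
                peak, cfg.band_fwhm_nm, 1.0, lam, cfg.asymmetry
            ).intensity
            target = f0_band if c == 0.0 else f0_band / (cfg.intercept_true + cfg.ksv_true * c)
            anap = (target / float(profile[band_sel].mean())) * profile
            blank = (c / cfg.ref_conc_M) * blank_amp_ref * _band_profile(
                lam, cfg.blank_peak_nm, cfg.blank_fwhm_nm, cfg.asymmetry
            )
            if cfg.inner_filter:
                od_ex = c * cfg.od_ex_per_M
                od_em = np.interp(lam, abs_lam, absorbances[i].od)
                atten = 10.0 ** (-(0.2 * od_ex + od_em) / 2.0)
                anap = anap * atten
                blank = blank * atten
            sigma = cfg.noise_sigma * cfg.amplitude
            total = anap + blank
            if sigma > 0:
                total = total + rng.normal(0.0, sigma, size=lam.size)
                blank_measured = blank + rng.normal(0.0, sigma, size=lam.size)
            else:
                blank_measured = blank
            meta = {"seed": seed, "replicate": rep, "conc_M": float(c), "quencher": cfg.quencher}
            raw_r.append(Spectrum(lam, total, {**meta, "sample_id": f"{cfg.quencher}_c{i}_r{rep}"}))
            blank_r.append(
                Spectrum(lam, blank_measured, {**meta, "sample_id": f"blank_c{i}_r{rep}"})
            )
        raw.append(raw_r)
        blanks.append(blank_r)
    return SimulatedTitration(
        config=cfg, seed=seed, conc=conc, raw=raw, blanks=blanks, absorbances=absorbances
    )


# ---------------------------------------------------------------------------
# time-resolved


def simulate_irf(fwhm_ns: float, grid: np.ndarray, center_ns: float | None = None) -> IRF:
    """Gaussian instrument response, sum-normalized on the grid."""
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    if fwhm_ns < 2 * dt:
        raise ValidationError(
            f"simulate_irf: FWHM {fwhm_ns:g} ns below grid resolution (2 bins = {2 * dt:g} ns)"
        )
    if center_ns is None:
        center_ns = grid[0] + 2.0 * fwhm_ns
    sigma = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    resp = np.exp(-0.5 * ((grid - center_ns) / sigma) ** 2)
    return IRF(grid, resp / resp.sum(), {"fwhm_ns": fwhm_ns, "center_ns": center_ns})


def _trpl_grid(cfg: TRPLSim) -> np.ndarray:
    return cfg.bin_ns * np.arange(cfg.n_bins)


def _apply_count_noise(mu: np.ndarray, cfg: TRPLSim, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_mode is None:
        return mu
    if cfg.noise_mode == "poisson":
        return rng.poisson(np.maximum(mu, 0.0) * cfg.averages) / cfg.averages
    if cfg.noise_mode == "gaussian":
        return mu + rng.normal(0.0, np.sqrt(np.maximum(mu, 0.0) / cfg.averages))
    raise ValidationError(f"simulate_trpl: unknown noise mode {cfg.noise_mode!r}")


def simulate_trpl(cfg: TRPLSim, species: str, seed: int) -> tuple[DecayTrace, IRF]:
    """One photon-counting decay: IRF-convolved exponential plus dark counts."""
    if species not in cfg.lifetimes_ns:
        raise ValidationError(
            f"simulate_trpl: unknown species {species!r}; configured: {sorted(cfg.lifetimes_ns)}"
        )
    grid = _trpl_grid(cfg)
    irf = simulate_irf(cfg.irf_fwhm_ns, grid, cfg.irf_center_ns)
    mu = (
        convolve_with_irf(
            irf,
            grid,
            "exp1",
            {"amplitudes": [cfg.amplitudes[species]], "lifetimes": [cfg.lifetimes_ns[species]]},
        )
        + cfg.background
    )
    rng = stream_rng(seed, "trpl", species)
    signal = _apply_count_noise(mu, cfg, rng)
    trace = DecayTrace(
        grid,
        signal,
        kind="trpl",
        averages=cfg.averages,
        meta={"seed": seed, "species": species, "tau_true_ns": cfg.lifetimes_ns[species]},
    )
    return trace, irf


def simulate_mixture_trpl(cfg: TRPLSim, seed: int) -> tuple[DecayTrace, DecayTrace, IRF]:
    """Fluorophore/quencher mixture plus the separately measured quencher-only
    background trace (each with independent noise).

    The mixture is the sum of a quenched-fluorophore component
    (``anap_quenched`` lifetime) and a quencher emission component
    (``serotonin`` lifetime); subtracting the background isolates the
    quenched fluorophore.
    """
    grid = _trpl_grid(cfg)
    irf = simulate_irf(cfg.irf_fwhm_ns, grid, cfg.irf_center_ns)

    def component(species):
        return convolve_with_irf(
            irf,
            grid,
            "exp1",
            {"amplitudes": [cfg.amplitudes[species]], "lifetimes": [cfg.lifetimes_ns[species]]},
        )

    mu_mix = component("anap_quenched") + component("serotonin") + cfg.background
    mu_bg = component("serotonin") + cfg.background
    mixture = DecayTrace(
        grid,
        _apply_count_noise(mu_mix, cfg, stream_rng(seed, "trpl", "mixture")),
        kind="trpl",
        averages=cfg.averages,
        meta={"seed": seed, "species": "mixture", "tau_true_ns": cfg.lifetimes_ns["anap_quenched"]},
    )
    background = DecayTrace(
        grid,
        _apply_count_noise(mu_bg, cfg, stream_rng(seed, "trpl", "background")),
        kind="trpl",
        averages=cfg.averages,
        meta={"seed": seed, "species": "background"},
    )
    return mixture, background, irf


@dataclass
class TASTriple:
    """Raw intensity traces of one pump-probe acquisition."""

    pumped: DecayTrace
    unpumped: DecayTrace
    fluorescence: DecayTrace
    irf: IRF
    config: TASSim

    @property
    def artifact_mask(self) -> np.ndarray:
        """Include-mask that drops the configured overload window."""
        lo, hi = self.config.artifact_window_ns
        t = self.pumped.time
        return ~((t >= lo) & (t <= hi))


def simulate_tas(cfg: TASSim, seed: int) -> TASTriple:
    """Pump-probe intensity triple whose reconstructed dOD trace is an
    IRF-convolved exponential photoproduct decay.

    The pumped channel carries a saturating overload artifact inside the
    configured window, damped-sinusoid EMI, and shot noise scaled by
    1/sqrt(averages); a ``step_dod`` above zero adds a long-lived
    (non-recovering) product for sum-versus-mixture comparisons.
    """
    if cfg.product_tau_ns <= 0:
        raise ValidationError("simulate_tas: product lifetime must be positive")
    lo, hi = cfg.artifact_window_ns
    t_max = cfg.bin_ns * (cfg.n_bins - 1)
    if lo >= hi or lo < 0 or hi > t_max:
        raise ValidationError(f"simulate_tas: artifact window [{lo}, {hi}] ns outside the grid")
    grid = cfg.bin_ns * np.arange(cfg.n_bins)
    irf = simulate_irf(cfg.irf_fwhm_ns, grid, cfg.irf_center_ns)

    dod = convolve_with_irf(
        irf,
        grid,
        "exp1",
        {"amplitudes": [cfg.product_amplitude_dod], "lifetimes": [cfg.product_tau_ns]},
    )
    if cfg.step_dod:
        dod = dod + cfg.step_dod * np.cumsum(irf.response)
    fluor = convolve_with_irf(
        irf,
        grid,
        "exp1",
        {"amplitudes": [cfg.fluor_amplitude], "lifetimes": [cfg.fluor_tau_ns]},
    )
    pumped = cfg.unpumped_level * 10.0 ** (-dod) + fluor
    in_window = (grid >= lo) & (grid <= hi)
    pumped = pumped + cfg.artifact_amplitude * cfg.unpumped_level * in_window
    if cfg.emi_amplitude:
        pumped = pumped + (
            cfg.emi_amplitude
            * cfg.unpumped_level
            * np.exp(-grid / cfg.emi_damping_ns)
            * np.sin(2.0 * np.pi * cfg.emi_freq_ghz * grid + cfg.emi_phase)
        )
    unpumped = np.full_like(grid, cfg.unpumped_level)
    if cfg.noise_sigma > 0:
        rng = stream_rng(seed, "tas")
        sig = cfg.noise_sigma * cfg.unpumped_level / np.sqrt(cfg.averages)
        pumped = pumped + rng.normal(0.0, sig, grid.size)
        unpumped = unpumped + rng.normal(0.0, sig, grid.size)
        fluor = fluor + rng.normal(0.0, sig, grid.size)

    meta = {"seed": seed, "tau_true_ns": cfg.product_tau_ns}
    make = lambda s, name: DecayTrace(  # noqa: E731
        grid, s, kind="trpl", averages=cfg.averages, meta={**meta, "channel": name}
    )
    return TASTriple(
        pumped=make(pumped, "pumped"),
        unpumped=make(unpumped, "unpumped"),
        fluorescence=make(fluor, "fluorescence"),
        irf=irf,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# cells


def _hill_logistic(conc: np.ndarray, ec50: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (slope * (np.log10(ec50) - np.log10(conc))))


def simulate_cell_series(cfg: CellSim, seed: int) -> list[ExposureSeries]:
    """Per-cell exposure series with photobleaching and Hill-shaped quench.

    Receptor occupancy follows the modified Hill equation between the
    protocol anchors: zero at the lowest applied concentration (where no
    appreciable quenching is seen) and one at the saturating (highest)
    concentration, mirroring how the experimental normalization defines its
    endpoints.  The quenchable fraction ceiling varies across cells with SD
    ``quench_sd``; per-exposure multiplicative noise has SD ``noise_sigma``.
    """
    if cfg.n_cells < 1:
        raise ValidationError("simulate_cell_series: need at least one cell")
    if not 0 < cfg.max_quench <= 1:
        raise ValidationError("simulate_cell_series: max_quench must be in (0, 1]")
    if cfg.ec50_M <= 0 or cfg.bleach_tau_s <= 0:
        raise ValidationError("simulate_cell_series: EC50 and bleach tau must be positive")
    conc = np.asarray(cfg.concentrations, dtype=float)
    if conc.size < 3 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValidationError(
            "simulate_cell_series: concentrations must be positive and strictly increasing"
        )
    lam = _nm_grid(cfg.grid_nm)
    anap = _band_profile(lam, cfg.anap_peak_nm, cfg.anap_fwhm_nm, 0.4)
    morange = cfg.morange_amplitude * _band_profile(lam, cfg.morange_peak_nm, cfg.morange_fwhm_nm, 0.4)

    logistic = _hill_logistic(conc, cfg.ec50_M, cfg.slope)
    occ_raw = 1.0 - logistic
    denom = occ_raw[-1] - occ_raw[0]
    if denom <= 0:
        raise ValidationError("simulate_cell_series: Hill curve is not quenching over the range")
    occupancy = (occ_raw - occ_raw[0]) / denom

    series = []
    for j in range(cfg.n_cells):
        rng = stream_rng(seed, "cells", cfg.preparation, f"cell{j}")
        amp = cfg.amplitude * (
            np.exp(rng.normal(0.0, cfg.cell_amplitude_sd)) if cfg.cell_amplitude_sd > 0 else 1.0
        )
        ceiling = cfg.max_quench
        if cfg.quench_sd > 0:
            ceiling = float(np.clip(rng.normal(cfg.max_quench, cfg.quench_sd), 0.05, 0.98))
        exposures = []
        k = 0
        for _ in range(cfg.n_pre):
            t = cfg.exposure_s * k
            bleach = cfg.bleach_amplitude * np.exp(-t / cfg.bleach_tau_s) + cfg.bleach_offset
            noise = 1.0 + (rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 0.0)
            intensity = amp * bleach * (anap + morange) * noise
            exposures.append(Exposure(t, None, Spectrum(lam, intensity, {"cell": j, "pre": True})))
            k += 1
        for c, occ in zip(conc, occupancy):
            for _ in range(cfg.step_replicates):
                t = cfg.exposure_s * k
                bleach = cfg.bleach_amplitude * np.exp(-t / cfg.bleach_tau_s) + cfg.bleach_offset
                noise = 1.0 + (rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 0.0)
                quench = 1.0 - ceiling * occ
                intensity = amp * bleach * (quench * anap + morange) * noise
                exposures.append(
                    Exposure(t, float(c), Spectrum(lam, intensity, {"cell": j, "conc_M": float(c)}))
                )
                k += 1
        series.append(
            ExposureSeries(
                exposures=exposures,
                cell_id=f"{cfg.preparation}{j}",
                preparation=cfg.preparation,
                meta={
                    "seed": seed,
                    "stream": f"cells/{cfg.preparation}/cell{j}",
                    "ceiling": ceiling,
                    "ec50_true_M": cfg.ec50_M,
                    "slope_true": cfg.slope,
                },
            )
        )
    return series


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(cfg: SimConfig, outdir) -> dict:
    """Write a full synthetic dataset as the CSV dialects the consumers read.

    Layout: ``titration/`` (raw + blank + absorbance spectra with a manifest
    per replicate), ``trpl/``, ``tas/``, ``cells/`` (spectra plus an exposure
    manifest), and a ``config.json`` echo of the generating configuration
    including the seed.  Returns a summary of what was written.
    """
    from .io import write_absorbance, write_irf, write_spectrum, write_trace

    seed = cfg.require_seed()
    out = Path(outdir)
    written: dict = {"outdir": str(out)}

    tdir = out / "titration"
    tdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_titration(cfg.titration, seed)
    for i in range(sim.conc.size):
        write_absorbance(sim.absorbances[i], tdir / f"abs_c{i}.csv")
    manifests = []
    for rep in range(cfg.titration.replicates):
        rows = ["conc_M,spectrum_path,absorbance_path,blank_path"]
        for i, c in enumerate(sim.conc):
            write_spectrum(sim.raw[rep][i], tdir / f"raw_c{i}_r{rep}.csv")
            write_spectrum(sim.blanks[rep][i], tdir / f"blank_c{i}_r{rep}.csv")
            rows.append(f"{float(c)!r},raw_c{i}_r{rep}.csv,abs_c{i}.csv,blank_c{i}_r{rep}.csv")
        manifest = tdir / f"manifest_r{rep}.csv"
        manifest.write_text("\n".join(rows) + "\n", encoding="utf-8")
        manifests.append(str(manifest))
    written["titration_manifests"] = manifests

    ldir = out / "trpl"
    ldir.mkdir(exist_ok=True)
    for species in cfg.trpl.lifetimes_ns:
        trace, irf = simulate_trpl(cfg.trpl, species, seed)
        write_trace(trace, ldir / f"{species}.csv")
    mixture, background, irf = simulate_mixture_trpl(cfg.trpl, seed)
    write_trace(mixture, ldir / "mixture.csv")
    write_trace(background, ldir / "background.csv")
    write_irf(irf, ldir / "irf.csv")
    written["trpl_dir"] = str(ldir)

    adir = out / "tas"
    adir.mkdir(exist_ok=True)
    triple = simulate_tas(cfg.tas, seed)
    write_trace(triple.pumped, adir / "pumped.csv")
    write_trace(triple.unpumped, adir / "unpumped.csv")
    write_trace(triple.fluorescence, adir / "fluorescence.csv")
    write_irf(triple.irf, adir / "irf.csv")
    written["tas_dir"] = str(adir)

    cdir = out / "cells"
    cdir.mkdir(exist_ok=True)
    rows = ["cell_id,cum_exposure_s,conc_M_or_PRE,spectrum_path,preparation"]
    for series in simulate_cell_series(cfg.cells, seed):
        for k, e in enumerate(series.exposures):
            name = f"{series.cell_id}_exp{k}.csv"
            write_spectrum(e.spectrum, cdir / name)
            tag = "PRE" if e.conc is None else repr(float(e.conc))
            rows.append(f"{series.cell_id},{float(e.time_s)!r},{tag},{name},{series.preparation}")
    (cdir / "manifest.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    written["cells_manifest"] = str(cdir / "manifest.csv")

    (out / "config.json").write_text(cfg.to_json() + "\n", encoding="utf-8")
    written["config"] = str(out / "config.json")
    return written
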