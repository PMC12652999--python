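# Methods

This note records the models implemented by `anapquench`, the assumptions
behind them, the defaults of the synthetic-data generators, and the places
where a design choice had to be made. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Steady-state quenching

Emission spectra are wavelength-indexed intensities on a strictly
increasing nm grid. The processing order is fixed: quencher-only blanks are
subtracted first (pointwise, identical grids required), absorbance spectra
are smoothed before any correction, and the inner-filter correction is
applied to the blank-subtracted emission. Negative intensities after blank
subtraction are retained and counted, never clipped, because clipping
biases band means.

**Smoothing.** Local Gaussian-kernel smoothing with σ equal to the
bandwidth (default 0.25 nm), truncated at ±4σ and renormalized at the grid
edges. Renormalization makes the filter exact on constants everywhere,
including the boundary; on a linear ramp it is exact on interior points
and slightly biased within 4σ of the edges.

**Inner-filter correction.** `F = F_obs·10^((g·OD_ex + OD_em(λ))/2)` with
`g = 0.2` for the short excitation path of a low-volume cuvette. The
formula divides the summed optical densities by 2 even though the
excitation path already carries the geometric factor; it is implemented
exactly as used in this assay, without "fixing" the geometry. The
absorbance spectrum must cover the emission range — out-of-range requests
raise rather than extrapolate.

**Band statistics.** The Stern–Volmer fluorescence `F` is the mean
intensity over grid points inside the inclusive 445–455 nm band; endpoints
are interpreted on the measured grid with no interpolation, trading a
half-bin of band-placement accuracy for exact reproducibility. Peak
wavelengths break ties toward the shorter wavelength.

**Stern–Volmer fit.** Unweighted ordinary least squares of F₀/F on
concentration (molar). F₀ comes from the zero-concentration spectrum of
the same replicate; replicate fits are averaged afterwards, which keeps
replicates statistically independent. Points with apparent enhancement
(F₀/F < 1, a solvatochromic effect at low quencher) are included by
default; `quench_fraction` flags them with a warning.

## Time-resolved analysis

Measured decays are modeled as `conv(IRF, h)(t) + baseline` where the
discrete IRF is normalized to unit sum (so convolution preserves the
discrete integral of `h`) and `h` is one of: single exponential,
biexponential, or second-order kinetics `a/(1+kt)`. A time-zero shift of
the IRF, implemented by linear interpolation and bounded to ±5 ns, absorbs
trigger jitter while preventing the lifetime/shift degeneracy that appears
when lifetimes are shorter than the 8 ns pulse. Fits are
derivative-based weighted least squares with three lifetime starts
(0.5, 2, 8 ns); Poisson weighting uses `var = max(signal, 1)` for count
data, uniform weighting is used for ΔOD data, where electromagnetic
interference is fitted through rather than notch-filtered. Parameter
standard errors come from the covariance at the optimum scaled by the
reduced χ².

**TAS construction.** `ΔOD(t) = −log₁₀((I_pumped − I_fluorescence)/I_unpumped)`;
points with nonpositive numerator are masked (NaN) and counted. The
detector-overload artifact near peak irradiance is excluded via an
explicit mask window rather than a hard-coded rule; the simulator's
default window is the 6 ns centered on the pulse peak. Model comparison
ranks AICc computed on the weighted residuals, with models within
ΔAICc ≤ 2 treated as indistinguishable and the tie broken toward fewer
parameters — the standard information-criterion convention, which keeps a
needless biexponential from outranking a single exponential it cannot
beat.

**Plateau detection.** Late-window mean ± standard error; "complete
recovery" means the mean lies within two standard errors of zero. This is
the sum-versus-mixture comparison used to distinguish a reversible
charge-transfer product from a permanent photoproduct.

**Savitzky–Golay smoothing** (display/denoising only, never before
fitting): default 21-point window, order 2, polynomial edge handling.

## Cell binding

Each cell contributes an exposure series: five agonist-free PRE exposures
(10 s each of cumulative illumination) followed by one exposure per
agonist concentration, ascending. The analysis band is the 10 nm window
centered on the fluorophore peak detected in the first PRE exposure
(~495 nm on receptors), which avoids the overlapping mOrange emission near
562 nm without spectral unmixing.

**Photobleach correction.** `A·exp(−t/τ_b) + C` fitted to the PRE band
intensities with A and C bounded nonnegative (an unconstrained offset can
extrapolate to negative predicted intensities over a long protocol) and
τ_b in [0.1 s, 10⁶ s]. Non-decreasing PRE intensities yield a flagged
no-bleach model rather than a forced exponential. Every spectrum is then
divided by the model's predicted fraction relative to the first exposure.

**Normalization.** `(F − F_min)/(F_lowest − F_min)` with `F_min` the
corrected intensity at the saturating (highest) concentration and
`F_lowest` at the lowest applied concentration. The output is invariant to
affine transforms of the input intensities.

**Hill fit.** `F_norm = fmin + (fmax − fmin)/(1 + 10^(h(log₁₀EC₅₀ − log₁₀c)))`
by bounded least squares in log concentration, with the asymptotes fitted
rather than pinned at 1/0 — the normalization anchors are themselves noisy
single measurements, and pinning them would bias EC₅₀ and the slope.
Bounds follow standard dose–response practice: the midpoint within two
decades of the applied range, |h| ≤ 6, asymptotes in [−1, 2]. The
parameterization is exactly symmetric under `(h, fmax, fmin) →
(−h, fmin, fmax)`; fits are canonicalized to `fmax ≥ fmin` so the slope
sign always reflects the response direction (negative for quenching).
Cells are normalized independently and their points pooled into a single
fit.

**Confidence intervals.** Seeded nonparametric bootstrap, 1000 resamples
by default. With cell labels the resampling is a two-stage cluster
bootstrap — cells with replacement, then points within each chosen cell —
which keeps interval widths stable when only ~6 cells are available; plain
point resampling is used otherwise. Percentile levels carry the
expanded-percentile small-sample correction (Hesterberg 2015, *Am. Stat.*
69:371), i.e. the nominal 2.5/97.5 levels are widened through the t
distribution on (units − 1) degrees of freedom. Plain percentile intervals
over six cells are systematically narrow; the combination above restores
near-nominal coverage in the pipeline's own simulation checks (the
acceptance suite measures this directly).

**Maximal quench.** Per cell, `1 − F(saturating)/F(lowest)` on corrected
band intensities; reported as mean ± SEM across cells (SEM absent for a
single cell).

## Synthetic-data generators

One master seed feeds named, platform-stable substreams (CRC32 of the
stream name) so each output is independently and reproducibly noisy; the
same configuration serializes to bit-identical CSV text across runs.

**Emission bands** are log-normal in wavelength (Siano–Metzler form): unit
height at the stated peak, configurable FWHM, red-tailed asymmetry 0.4 —
the characteristic shape of a broad charge-transfer emission band.

**Titrations.** The ground truth is defined on the 445–455 nm analysis
band: the zero-quencher spectrum has band-mean F₀ and each quenched
spectrum is scaled so its band mean equals `F₀/(intercept + K_sv·c)`,
which makes the measured ratios reproduce the Stern–Volmer line exactly
before noise even when the solvatochromic peak shift (−40 nm·M⁻¹,
i.e. −4 nm at 100 mM) deforms the band. An intercept below one encodes the
slight brightening seen at low quencher concentrations. Quencher
autofluorescence grows linearly with concentration, anchored to 15.2% of
total peak signal at the 100 mM reference, and is emitted as a matched
blank. With the inner filter enabled, sample and blank are attenuated by
the Beer–Lambert factor implied by the emitted absorbance spectra
(exponential tail from the excitation wavelength), so the downstream
correction is its exact inverse. Defaults: concentrations 0–100 mM,
additive noise 1% of the reference amplitude, 3 replicates.

**TRPL.** Decays are IRF-convolved single exponentials (defaults: ANAP
2.776 ns, serotonin 2.231 ns, quenched mixture component 2.14 ns) on
0.4 ns bins with an 8 ns FWHM Gaussian IRF and a 2-count dark background.
Poisson noise is applied at the photon level and divided by the number of
averaged shots (64 by default); a Gaussian mode approximates analog
averaging. The mixture generator emits the mixture and the quencher-only
background as independently noisy traces, so background subtraction is
tested under realistic double-counting of noise. Steady-state and lifetime
quenching are parameterized independently: the assay's steady-state
constant and its lifetime shortening are not linked by τ₀/τ = 1 + K_sv[Q]
here, and the generator does not impose a relation the data do not obey.

**TAS.** The pumped channel is constructed so the reconstructed ΔOD trace
is an IRF-convolved exponential photoproduct decay (default lifetime
3.18 ns, bare-decay amplitude 0.1 OD), plus a saturating overload artifact
inside the 13–19 ns window, coherent damped-sinusoid EMI (0.25 GHz, 0.2%
of the probe level, 20 ns damping) added to the pumped intensity only, and
per-point Gaussian noise of 1%/√500 of the probe level — about 3×10⁻⁴ OD,
the scale consistent with the sub-3% lifetime fit uncertainties this kind
of averaging produces. An optional step term generates the non-recovering
photoproduct used in sum-versus-mixture comparisons.

**Cells.** Six cells by default, each with five PRE exposures and one
exposure per concentration (10 nM – 100 µM, nine log-spaced steps);
per-cell brightness is lognormal (σ = 0.2) and the saturating quench
ceiling is normal (0.66 ± 0.07 across cells, the across-cell variability
the assay reports). Receptor occupancy follows the modified Hill curve
*anchored at the protocol endpoints*: zero at the lowest applied
concentration (where no appreciable quenching is observed) and one at the
saturating concentration. This anchoring reflects how the experimental
normalization defines its endpoints: with a slope factor near −0.46 the
Hill curve approaches its mathematical asymptotes only over ~12 decades of
concentration, far beyond any applicable range, yet the measured protocol
still exhibits an unquenched baseline and a saturating plateau. The
anchored curve is an exact affine image of the Hill logistic, so the
noiseless pipeline recovers EC₅₀ and slope exactly and the saturating
quench equals the configured ceiling. Photobleaching is mild
(`0.1·exp(−t/150 s) + 0.9`), consistent with a photostable fluorophore
under LED illumination; per-exposure multiplicative noise is 3%. Cell
noise magnitudes are artifact choices — the assay does not publish them —
selected once so that the saturating-quench variability across cells is of
the reported ±7% scale.

### What the generators do not emulate

Real spectra carry wavelength-correlated detector noise, cosmic-ray
spikes, and baseline drift; real cells desensitize, move, and defocus;
real TAS pump scatter is structured, not a clean window; mOrange bleaches
at its own rate (here it shares the ANAP bleach factor, which the
band choice makes irrelevant to the analysis). Passing the recovery suite
therefore demonstrates the correctness and statistical calibration of the
analysis chain under its stated model, not robustness to every artifact of
real instruments.

## Numerical choices and degenerate inputs

- Grids must match exactly (spectra) or within 10⁻⁹ relative (time) —
  mismatches raise structured errors naming the first offending point.
- CSV serialization uses shortest-round-trip decimal text (`repr`), so
  write/read cycles are bit-exact.
- Reconvolution lifetime bounds are [10⁻³, 10⁴] ns; parameters landing on
  a bound set a boundary flag and a warning rather than failing silently.
- All-equal spectra return the shortest wavelength as "peak" with a
  warning; empty band intersections and all-masked TAS traces are errors.
- Problem sizes used by the verification suites: 256-bin traces, 100-seed
  replicate studies for the stochastic checks, 1000 bootstrap resamples
  for CI coverage (500 in exploratory studies), 200 repeated 6-cell
  simulations for the saturating-quench summary.

## Known limitations

- The bleach model is the same single exponential the generator uses; on
  real data a bi-exponential bleach would leave a residual tilt that the
  concentration–time confound can turn into an EC₅₀ bias (the pipeline's
  own simulations show a ~3% low bias at 10% bleach and 3% exposure
  noise).
- The expanded-percentile cluster bootstrap is mildly conservative for
  the EC₅₀ with six cells (measured coverage above nominal in simulation);
  with many cells it converges to the plain percentile interval.
- Model comparison is calibrated for the simulated SNR regimes; at much
  lower SNR the AICc tie convention increasingly favors the single
  exponential by construction.
- The inner-filter correction assumes the printed two-path geometry; other
  cuvette geometries require a different excitation path factor.
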