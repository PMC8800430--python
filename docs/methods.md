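# Methods

This note records the models, conventions and numerical choices behind
`cellugel`, what the synthetic generators do and do not emulate, and the
known limits of each estimator.

## Two-level unified SAXS model

The model is the standard unified (Beaucage) description of hierarchical
scatterers: per level a Guinier exponential `G exp(−Q²Rg²/3)` and a power
law `B (1/Q*)^P` whose low-Q divergence is suppressed by the
error-function-rescaled vector `Q* = Q [erf(Q·Rg/√6)]⁻³`. Two levels are
used, ordered `Rg₁ > Rg₂`, and the level-2 power law carries no high-Q
cutoff (`Rg₃ ≡ 0`, exposed as a module constant, not a parameter — the
published parameter tables list no third radius, and this is the standard
convention for the innermost level). At Q → 0, `Q* ∝ Q⁻²` diverges, so
`I → bkg + G₁ + G₂` exactly.

Evaluation notes:

- the power-law factor is computed in log space
  (`exp(log B − Q²Rg²/3 − P·log Q*)`) so the `Q⁻²`-divergent `Q*` cannot
  overflow before its exponential damping;
- the evaluator agrees with a 40-digit mpmath transcription to ≥ 10
  significant digits on randomized parameter/Q draws (tested).

### Fitting

`fit_unified_model` minimizes weighted residuals with a bounded
trust-region least-squares minimizer (lmfit/`least_squares`):

- **weighting** — `(I_obs − I_model)/σ` when uncertainties are present,
  otherwise unweighted residuals of `log I`. The log form keeps the five
  decades of intensity from being dominated by the low-Q points.
- **ordering** — `Rg₁ > Rg₂` is enforced by parametrizing
  `Rg₁ = Rg₂ + gap` with `gap > 0`; all prefactors are bounded ≥ 0 and the
  exponents to (0, 8].
- **restarts** — up to five deterministic re-starts from jittered initial
  values when the optimizer reports failure; lowest chi²/point wins.
- **uncertainties** — 1-σ values from the covariance at the optimum;
  `chi2_per_point = Σ residuals²/N`.

### Identifiability of Rg₁ at the measured window

With data on 0.07–2.5 nm⁻¹ the level-1 Guinier knee (`√3/Rg₁ ≈ 0.05 nm⁻¹`
for `Rg₁ ≈ 34 nm`) lies below the lowest measured Q, so Rg₁ is constrained
only by residual curvature at the window edge and is strongly correlated
with G₁. Under 2% fractional noise the covariance-based standard error of
Rg₁ at the optimum is ≈ 6–7%, so point estimates scatter at that level
(right-skewed: the Rg₁↑/G₁↑ direction is soft) no matter the optimizer —
fits routinely reach chi² below the chi² of the generating truth. Rg₂, whose
knee sits inside the window, recovers with ≈ 3–4% scatter. Conclusions that
rest on Rg₂ (the lamellar scale) are therefore robust at these conditions;
conclusions about Rg₁'s exact value are not, and the package reports its
per-fit standard error so users can see this directly.

### Transforms and summaries

- Kratky transform: `I → Q²I`, σ propagated as `Q²σ`.
- Positional residuals: exact-grid subtraction only (no silent
  interpolation); σ combined in quadrature.
- Local power-law slope: least-squares line of log I vs log Q in a stated
  window, reported as the positive exponent of `I ∝ Q⁻ᵖ`.
- Position averages: mean ± SEM with the sample (n−1) standard deviation;
  reporting precision is a caller choice (`ndigits`).

## WAXS quantification

The solvent-dominated profiles rise smoothly and monotonically over
5–16 nm⁻¹; crystalline reflections sit on top. The background is a
polynomial of degree ≤ 4 least-squares fitted to the points outside the
declared peak windows (defaults: ±0.8 nm⁻¹ around the three cellulose II
positions at 8.69, 14.1 and 15.6 nm⁻¹), with its derivative constrained to
a single sign over the full grid (SLSQP refit triggered only when the
unconstrained fit violates monotonicity). At least 30% of the points must
lie outside the windows.

Peaks are Gaussians fitted per window on the background-subtracted
profile; `area = amplitude · FWHM · √(π/4 ln 2)`. The Gaussian shape is a
choice — the profile function of the original analysis is not recorded —
and suffices for recovery testing; a pseudo-Voigt would change areas at
the percent level at most for these narrow peaks. A window whose fitted
amplitude is non-positive (or at numerical-noise level) is reported with
area 0 and flagged absent. Area uncertainty is first-order propagation of
the amplitude and FWHM errors.

Conversions: `d[Å] = 2π/Q[nm⁻¹] × 10`; `2θ = 2 asin(Qλ/4π)` with the
0.92 Å beamline wavelength as default; FWHM in degrees 2θ is the
difference of the converted half-maximum endpoints, not a small-angle
approximation. Reflection assignment takes the nearest reference spacing
within a 2% relative tolerance, one-to-one with closest-wins and ties
broken toward the smaller spacing. The reference table (7.23 / 4.45 /
4.03 Å) is the published one; note 2π/14.1 nm⁻¹ is 4.456 Å, which the
source rounds to 4.45 — the table is a lookup, not a computation.

## MALDI DP estimation

Cellodextrin peaks sit on the comb `m_n = unit_mass·n + adduct_mass`. The
residue mass defaults to the 162.14 Da average anhydroglucose mass (the
quoted "162 Da" spacing treated as rounded). The adduct mass defaults to
41.0 Da = H₂O (18.0) + Na (23.0): sodiated free oligosaccharides are the
common MALDI species, and this offset maps both published MW/DP pairs
(1160 → 6.90 vs printed 6.89; 1072 → 6.36 vs 6.35) to within 0.03 DP. The
original convention is not recorded, so this is an inference; both masses
are parameters.

Peak picking takes local maxima above a robust floor (median + 5·MAD of
the whole spectrum), matches them to the comb within a tolerance (default
2 Da; the highest match per n wins), and keeps the longest consecutive
run of n. Runs shorter than 3 are flagged unreliable. Faint noise maxima
adjacent to the comb can extend a run at its ends; their near-zero
heights have negligible leverage on the envelope.

The envelope is a Gaussian least-squares fit through the (m/z, height)
peak tops — fitted in mass, not DP index, because the headline quantity
is the mean molecular weight; mean DP follows from the adduct relation. A
perfectly flat envelope is degenerate (any center fits); by symmetry the
series midpoint is returned with infinite width. Fewer than 4 peaks is an
error.

## Ribbon-width morphometry

Fibers are segmented by Otsu (or fixed) thresholding with small-object
removal and hole filling (both at 20 px), skeletonised, and the local
diameter is sampled at each retained skeleton pixel from the Euclidean
distance transform, treating ribbons as locally cylindrical.

**Boundary correction.** The EDT measures pixel-centre to pixel-centre.
When the nearest background pixel lies along a lattice axis, the digitised
boundary sits half a pixel beyond the last foreground centre on each side,
so `2·EDT − 1` is exact (an 11-px straight ribbon reads exactly 11). For
oblique boundaries the lattice samples the boundary densely and the
nearest background centre abuts it, making `2·EDT` the unbiased choice; a
constant −1 there would be a ~20% error at the 5-px widths of interest.
The estimator therefore subtracts the half-pixel per side only when the
EDT nearest-background offset vector is axis-aligned. Validated per angle
on constructed ribbons (residual |bias| ≲ 0.2 px at generic angles,
≲ 0.5 px at exact diagonals).

Skeleton pixels within one local radius of an endpoint or junction are
excluded (the EDT there reflects branch geometry, not width); the exact
exclusion rule of the original plugin-based analysis is unpublished, so
this estimator is validated against constructed fixtures, not against the
published table. Samples are per skeleton pixel, i.e. length-weighted;
with widths drawn independently of lengths this matches the per-ribbon
moments in expectation.

Statistics: mean, sample SD, median, min, max directly; the mode is the
centre of the most populated histogram bin (default 0.05 µm — a
continuous sample has no unique mode and the original binning is not
stated); skewness is Fisher g₁ and kurtosis is **excess** kurtosis g₂.
The excess convention is forced by coherence: the published space-side
pair (skewness 1.31, kurtosis 2.70) violates the raw-kurtosis bound
k ≥ s² + 1 (2.70 < 2.72) but is admissible as excess kurtosis. All-equal
samples report SD 0 and skewness/kurtosis 0 by convention.

## Synthetic generators

The generators define the validation conditions; their defaults mirror
the study where it states values.

- **SAXS** — forward unified-model curves on 0.07–2.5 nm⁻¹ (200 points
  log-spaced by default) with multiplicative Gaussian noise of constant
  fractional level (count-dominated synchrotron regime at moderate
  intensity); σ is reported as noise × model. Draws are truncated at ±5σ
  if any point would otherwise go negative (flagged); fractional noise
  ≥ 20% cannot be made positivity-safe this way and errors out. Not
  emulated: instrument smearing, q-dependent counting statistics,
  detector artefacts, buffer-subtraction residuals.
- **WAXS** — monotone polynomial water background (default 20 + 6q +
  0.2q² on 5–16 nm⁻¹) plus Gaussian peaks, additive noise scaled to the
  profile median. Peak pairs closer than 0.2× their mean FWHM are flagged
  unresolvable. Not emulated: amorphous halo shape, preferred
  orientation, Lorentz-polarization effects.
- **MALDI** — comb peaks with a Gaussian envelope in DP, rendered as
  narrow m/z Gaussians (σ 1.5 Da) on a 0.25 Da grid over 500–2000 Da,
  plus zero-mean baseline noise clipped at the detector floor. The
  envelope spread defaults to 1.2 DP units, which keeps the weighted mean
  of the discrete, 4–11-truncated envelope within 0.01 DP of its centre.
  Not emulated: isotope patterns, matrix peaks, detector saturation,
  mass-dependent ionisation efficiency.
- **Ribbons** — straight, constant-width segments (lognormal widths,
  default mean 0.254 µm / SD 0.128 µm at 0.05 µm/px; uniform orientation
  and length 5–15 µm), foreground 200 on background 20, optional light
  blur. A requested width (fixed value or distribution mean) below 3 px
  errors as unmeasurable; individual random draws below 3 px are rendered
  as drawn and recorded, since rejecting them would shift the drawn-sample
  mean ~13% above the configured one. Not emulated: curvature, tapering,
  out-of-plane tilt, SEM texture/charging, depth-of-field.

Because the generators are idealized, passing recovery tests demonstrates
estimator correctness under the stated noise models — not robustness to
the instrument effects listed above.

## Validation problem sizes

Recovery checks run at: 300-point SAXS curves, 20 replicates at 2% noise;
50 WAXS profiles at 1% noise; 20 MALDI spectra at 5% noise with mean DP
drawn in [5, 9]; one 2048² px ribbon image with 300 ribbons (~7% area
coverage, so junction exclusion is exercised). The residual ~5–7%
negative bias of the ribbon mean comes mostly from the sub-3-px lognormal
tail at the quantisation floor.

## Pipeline

`run_pipeline` validates its YAML config against an explicit key schema
(unknown keys are named in the error), derives every stage seed from the
run seed via SHA-256 (all seeds are logged), fails fast on missing input
files, and writes plain CSV tables; reruns of the same config are
byte-identical. Comparative quantities (area ratio, FWHM contrast,
Rg₂ mean ± SEM, B₂ max/min uniformity) are recomputed from stage outputs
on every access, never cached.

## Known limitations

- The published parameter tables cannot be re-derived from data (the raw
  curves, spectra and micrographs are not deposited); the package
  reproduces the arithmetic on the printed values and validates its
  estimators on synthetic truth instead.
- Rg₁ at the measured SAXS window is identifiable only to ~6–7% (above).
- The diameter estimator assumes locally straight, constant-width,
  in-plane ribbons; curvature-aware tracing is out of scope.
- The MW→DP adduct convention is inferred, not documented by the source.
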