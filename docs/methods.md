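# Methods

## Scope and model

`leafspec` implements a leaf-spectroscopy trait-modelling workflow for
aquatic macrophytes: trait derivation from raw measurements, an exhaustive
two-band NDSI proxy search, PLSR reflectance-trait models with
leave-one-out cross-validation and VIP diagnostics, species-level
variability statistics, and projection of trait-linked indices onto
hyperspectral imagery.  Because the workflow is validated on synthetic
data, this note documents both the analysis methods and the generative
model, and is explicit about what the synthetic results do and do not show.

## Light-response model

ETR–PAR curves are fitted with the saturating-exponential (Webb-type)
form

    ETR(PAR) = ETR_max · (1 − exp(−α·PAR/ETR_max)),

with α the dimensionless initial slope (quantum-yield proxy), ETR_max
(µmol electrons m⁻² s⁻¹) the saturation rate, and I_k = ETR_max/α
(µmol photons m⁻² s⁻¹) the derived saturation irradiance.  The form has no
photoinhibition term — it supplies exactly the three parameters reported
(α, ETR_max, I_k) and behaves well at the 11-step PAR ladder
(5–787 µmol m⁻² s⁻¹) used for data collection.  Fitting is trust-region
nonlinear least squares with α₀ from the through-origin slope of the first
three points and ETR_max₀ = max(ETR); relative tolerance 1e-8, 500
iteration budget, non-convergence flagged rather than raised.  I_k is
returned as the exact ratio of the fitted parameters.  ETR uses leaf
absorptance 0.84 and PSII excitation fraction 0.5 (the usual PAM
convention); both are arguments, not constants, because instruments and
protocols differ.

## Pigment and structural assays

Pigments follow the Lichtenthaler equations for 80 % acetone extracts read
at 663.2, 646.8 and 470 nm, converted to a leaf-area basis (µg cm⁻²) by
extract volume over disc area.  Degraded extracts can yield negative
carotenoid estimates; these are reported unclamped with `negative_flag`
set, so screening decisions stay with the analyst.  DMC is dry/fresh mass
(g g⁻¹) and LMA dry mass per area (g m⁻²).

## NDSI search

For P retained bands all P(P−1)/2 unordered pairs are evaluated; pairs are
keyed (shorter λ, longer λ) and the signed Pearson r is reported for that
orientation (NDSI is antisymmetric under pair swap, so orientation is a
presentation choice).  Two-sided p-values come from the t transform of r
with n−2 degrees of freedom and are Bonferroni-adjusted over the pairs
tested *for that one trait* — per-trait maps are the reporting unit, so the
per-trait family is the honest multiplicity.  Samples missing the trait are
dropped for that map (maximal data use); constant index columns produce
NaN entries which the pair selection skips.  The search is vectorised over
one band index (987 bands × 300 samples ≈ 2 s on one CPU).  Spearman
correlation is available behind a method flag (rank transform of trait and
index columns); Pearson on raw traits is the default analysis.

## PLSR, component selection and VIP

Single-response PLSR uses the NIPALS deflation scheme on mean-centered,
unscaled X and y — with one response the weight vector of each component
is the normalised covariance X'y of the deflated data, so the algorithm is
exactly deterministic with no inner iteration.  Mean-centering without
variance scaling is the chemometrics default for spectra on a common
physical scale.  At full rank and k = P components the fit coincides with
ordinary least squares, which the tests exploit as an oracle; the
implementation is also cross-checked against an independent PLS
implementation (scikit-learn, test-only dependency).

LooCV refits the model N times; each left-out sample is predicted at every
component count 1..K (K = min(30, N−2, P)) in a single pass, giving the
RMSEP curve.  The selected component count is the curve's minimum with
ties broken toward fewer components (parsimony).  Reported diagnostics:
RMSEP at the selected k, R²_CV (squared Pearson correlation of measured
vs LooCV-predicted) and nRMSE = RMSEP/(max−min of measured) × 100 %.

VIP_j = sqrt(P · Σ_a SS_a w²_aj / Σ_a SS_a) with SS_a = q_a²·t_a't_a the
response variance captured by component a and w_a the unit-norm weight
vectors; mean squared VIP over bands is 1 by construction, which every fit
asserts.

Trait candidacy before modelling: a trait qualifies when its best
Bonferroni-significant NDSI pair exceeds R²_cal = 0.15; mutually
correlated traits (|r| > 0.5) are pruned greedily in decreasing order of
that best score, so the more spectrally tractable member of each
correlated pair survives.

## Variability statistics

CVs use the sample standard deviation (n−1) over the mean, computed per
species on the peak-of-growth subset (month filter, default July).
Between-species differences use Kruskal–Wallis (tie-corrected H,
chi-square p) and Dunn's pairwise z tests with pooled-rank variance, tie
correction and Benjamini–Hochberg adjustment over the k(k−1)/2 pairs.
Average ranks and the standard tie-correction factor are used throughout.

## Image pipeline

Pixel spectra are divided by their Euclidean norm (vector normalization),
which cancels per-pixel brightness scaling exactly — NDSI maps computed
after normalization are provably invariant to any positive per-pixel
scale factor, the property that motivates normalizing before canopy-scale
index mapping.  Pixels with LAI strictly below 0.67 m² m⁻² are masked.
Requested proxy wavelengths are matched to the nearest band center within
±5 nm (conventional airborne-sensor tolerance; configurable).  RGB
composites stretch each channel between its 2nd and 98th percentile over
unmasked pixels (constant channels render at 0.5 with a warning).  Stand
statistics use pixel-center polygon containment and Tukey box-plot
summaries (median, quartiles, 1.5×IQR whisker extremes).  ENVI I/O covers
BSQ float32 with an ASCII header; geometry is a simple axis-aligned grid
(origin + pixel size), since georeferencing is out of scope.

## Synthetic data generator

The generator emulates the statistical structure of a six-species
macrophyte leaf dataset, not any particular instrument:

- **Trait marginals.**  Positive traits (Chl-a, Car, LMA, α, ETR_max) are
  log-normal with species mean and CV matched exactly; bounded traits
  (DMC, F_v/F_m, qP, qN) are logit-normal with (µ, σ) moment-matched
  numerically (Gauss–Hermite quadrature + root finding) so configured
  means and CVs are honoured exactly there too.  Chl-b is derived from
  Chl-a through a per-sample Ca/Cb ratio drawn around the species ratio;
  I_k is the exact ratio ETR_max/α.  Per-species CVs follow the pattern
  observed in these communities at peak of growth (ETR_max and I_k most
  variable; F_v/F_m least; structural traits most variable in water
  chestnut); species trait means are literature-plausible values for these
  taxa, not reconstructions of any particular dataset.
- **Coupling structure.**  Carotenoids share a latent factor with the
  chlorophyll pool (loading 0.5).  The photophysiological traits load on
  the chlorophyll factor with the species' `photophysiology_coupling`
  (default 0.3) plus independent noise — photophysiology is physiologically
  real but only weakly expressed in reflectance, so reflectance models
  should, and do, recover it poorly.
- **Reflectance forward model.**  R(λ) = P(λ)·exp(−A_pig−A_wat−A_dm)·(1+ε),
  clipped to [0.001, 0.999].  P(λ) is a smooth structural baseline with a
  red-edge step to a NIR plateau and a gentle SWIR decline, modulated per
  leaf by a random spectral tilt (sd 0.05) representing internal-scattering
  differences independent of the measured traits — without it the NIR
  plateau would be an unrealistically noise-free reference band.  A_pig
  sums Gaussian features for Chl-a (430, 665 nm, a long-wavelength wing at
  710 nm that moves the red edge with chlorophyll, and a broad visible
  continuum standing in for the package effect and overlapping electronic
  transitions), Chl-b (460, 645 nm) and Car (480 nm), each scaled linearly
  by content.  A_wat has features at 1200/1450/1940 nm scaled by water
  mass per area LMA·(1/DMC − 1) (fresh minus dry mass per area); A_dm has
  features at 1720/2100/2300 nm scaled by LMA.  ε is i.i.d. multiplicative
  Gaussian noise, default sd 0.01 (typical contact-probe repeatability).
  The default grid is 987 uniformly spaced bands over 400–2500 nm; the
  instrument grid it stands in for is non-uniform, so the spacing is
  configurable.
- **Scenes.**  98 uniformly spaced bands over 425–905 nm, dark water-like
  background at low LAI, per-pixel independent trait draws inside each
  stand polygon, stand LAI ~2 with 5 % jitter.
- **Determinism.**  All draws flow through one seeded generator per
  config; identical configs reproduce outputs bit-for-bit.

### What the synthetic results do and do not show

The generator plants exactly the band–trait physics the analysis assumes
(pigments → visible/red edge; water and dry matter → SWIR), with
near-linear index–trait relations and noise far below field conditions.
Passing tests therefore demonstrate that the *machinery* is correct —
oracle-exact statistics, recovered planted signals, correct masking and
ranking — not that field data would yield comparable accuracies: real
leaf datasets carry phenological drift, site effects, sensor artefacts and
radiative-transfer nonlinearities that this generator deliberately omits
(no PROSPECT-class radiative transfer, no canopy BRDF, no atmosphere).
Synthetic cross-validated scores (e.g. nRMSE ≈ 1–6 % for pigments and
structure) are accordingly far better than what field campaigns report;
the qualitative ordering — structure ≈ pigments ≫ photophysiology — is the
property the generator is designed to reproduce.

## Numerical choices and degenerate inputs

Problem sizes used throughout the analysis and checks: 150-sample
libraries (6 species × 25) at 987 bands for the leaf-scale stages, 300
samples for the full-grid timing run, 200 curves for light-curve recovery,
and 60×60-pixel scenes at 98 bands — each comfortably larger than the
minimum needed for the statistics involved while keeping any single stage
in the seconds-to-a-couple-of-minutes range.  Other choices: component
selection ties go to fewer components; NDSI pairs with zero-sum
denominators or constant columns are NaN and excluded from selection;
zero-variance responses give degenerate PLSR models that predict the mean;
Dunn z is 0 with p = 1 when the pooled variance vanishes; CV is undefined
(error) at zero mean; whisker statistics use the Tukey 1.5×IQR rule.

## Known limitations

- The Webb light-response form cannot represent photoinhibition; curves
  with a declining tail will fit with biased ETR_max.
- PLSR prediction intervals are not provided; LooCV residuals are the only
  uncertainty measure.
- The image pipeline treats leaf-scale proxies as canopy proxies; the
  observation-scale mismatch (leaf vs 5 m pixels) is inherent to the
  approach and is documented, not solved.
- qP and qN are accepted as instrument-derived inputs; no re-derivation
  from raw fluorescence pulse traces is attempted.
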