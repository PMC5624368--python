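# Methods

## The model

`gamutkit` treats an RGB image as a large sample of three-bin spectra and
analyzes the sample in three layers.

**Colorimetry.** An illuminant attenuated by every reflectance function with
values in [0, 1] produces a convex, centrally symmetric region of
tristimulus space — the object-color solid. On a wavelength grid it is the
zonotope of the per-interval tristimulus increments v_i of the illuminant,
and its volume is the standard triple sum Σ_{i<j<k} |det(v_i, v_j, v_k)|.
Two cuts split the spectrum into three bands whose tristimulus vectors span
a parallelepiped inscribed in the solid; the cuts are chosen to maximize
|det| of the band matrix. Because both volumes transform with the same
determinant under a linear recoding of color space, the maximized volume
*fraction* is colorimetrically invariant and the optimum is well defined.
With the vendored CIE D65 and CIE 1964 tables the optimum falls at
(482.74, 565.43) nm and the spanned cube covers 0.629 of the solid (the
fraction is a value computed by this package, recorded as a regression
fixture, not an externally reported constant). Re-expressing the
colour-matching functions in the band basis gives functions whose negative
lobes carry 11.3 % of the total absolute area — predominantly nonnegative,
which is what makes an approximately physical three-filter sensor possible.

**Homomorphic opponent statistics.** Observation values live on (0, 1);
the physics that generates them (products of cross-sections, exposures)
is additive on a log-like scale. The logistic pair Ω(x) = (1 + tanh x)/2,
Ω⁻¹(y) = atanh(2y − 1) carries data to the "physical" domain, where channel
histograms are near normal. Any sigmoid would do; the tanh form is fixed
here for speed and reproducibility. The Kubelka–Munk reflectance of an
infinitely thick turbid layer, R∞ = 1 + ξ − sqrt(ξ² + 2ξ) with ξ = K/S, is
implemented as the canonical physical example, and `km_histogram` shows how
a log-normal prior on ξ produces the skewed and bimodal reflectance
histograms seen in real channel data. On physical triples (ρ, χ, β) the
fixed opponent transform T = (1/12)[[4,4,4],[6,0,−6],[−3,6,−3]] yields
(Λ, Θ, Ξ): mean, first difference (spectral slope) and second difference
(spectral curvature) of the three-bin spectrum. T⁻¹ is the exact matrix
inverse (1/3)[[3,3,−2],[3,0,4],[3,−3,−2]].

**Covariance model and Z.** In a narrow, statistically
translation-invariant spectral window, channel covariance should take the
unit-diagonal form with off-diagonals 1 − ε₁, 1 − ε₂, 1 − ε₃, where ε grows
with spectral separation (ε₁ ≈ ε₃, ε₂ larger). In the symmetric case
ε₁ = ε₃ = ε, ε₂ = 2ε, the vector (1, 0, −1)/√2 is an exact eigenvector with
eigenvalue exactly 2ε, the eigenvalues approach the ratio 1 : 2ε/3 : 2ε/9,
and the dominance statistic Z = λ₁/(λ₂ + λ₃) → 9/(8ε). `summarize` computes
the empirical analogue (unbiased covariance, eigenvalues sorted descending,
eigenvectors sign-fixed so the largest-magnitude component is positive);
Z is computed from physical-domain covariance by default, with the raw-RGB
domain available through the CLI flag, since the two differ and both are of
interest. Eigendirections are compared against the fiducial opponent axes
by stereographic projection from the antipode of the achromatic pole
(1,1,1)/√3: the pole maps to the origin, equatorial directions map onto the
unit circle. Directions are axes (sign-free); the convention flips each
into the hemisphere facing the pole, and exactly equatorial directions to a
nonnegative first coordinate — under which the green–purple axis
(−1, 2, −1)/√6 images to (0, −1).

## The generator

`sample_gamut` draws (λ, θ, ξ) from independent normals with the six
signature parameters, applies T⁻¹ and Ω. Units: all six parameters are in
the physical (log-like) domain; μ_Λ sets overall level, σ_Λ monochrome
contrast, (σ_Θ, σ_Ξ) the red–blue and green–purple spreads. The `sublunar`
preset uses the median spreads observed across natural corpora,
(σ_Λ, σ_Θ, σ_Ξ) = (1.07, 0.47, 0.13), zero means (automatic white balance).
The `alien` preset uses equal spreads s\* = π/√(12·23/9) ≈ 0.567: equal
opponent deviates of variance s² give physical channel variances
(22/9, 25/9, 22/9)s² through the non-orthogonal T⁻¹, and matching the mean
channel variance to π²/12 — the variance of the logistic distribution whose
CDF is Ω — flattens the RGB histograms. A residual red–blue correlation of
about 0.18 is structural under equal spreads and cannot be removed without
abandoning the equal-spread definition.

`psi_regression` fits ln σ_Ξ = ln Ψ + p · ln σ_Θ across a collection of
gamut signatures by ordinary least squares and reports both the power-law
prefactor Ψ = exp(intercept) and the alternative through-origin linear
slope, since the two parametrizations coincide only when the fitted power
is exactly 1.

**Distortion robustness.** The experiment draws Gaussian physical triples
with a reference natural-scene covariance, squashes them to "true" RGB, and
for each of 1,000 seeded draws applies per-channel gain A ~ U(0.5, 1.5) and
gamma γ ~ U(0.5, 1.5) as (A·v)^γ clipped to the ingestion interval. Each
draw contributes the Pearson correlation between distorted and true values
*within* each channel; the pooled coefficients have median ≈ 0.993 with
interquartile range ≈ (0.985, 0.998). Per-channel correlation is the right
operationalization because each channel suffers its own monotone transform;
pooling the raw values across channels instead would conflate the channel
gains with the quantity being tested.

## The toy spectral model

Random reflectance spectra are Ω(shift + scale·g) where g is a stationary
Gaussian articulation process on the visible range (length normalized to 1)
with Lorentzian power spectrum S(f) ∝ 1/(f² + f_c²), f_c = 1/(2πτ), so the
articulation power falls off as 1/f² over the resolved band and the
autocorrelation length is τ. Synthesis is spectral: complex-normal Fourier
coefficients with amplitude √S on a 4× oversampled periodic domain, cropped
to the unit range (removing the periodicity), with an exact (not
per-realization) standardization to unit variance. A smoothness cutoff
f_max = 8 cycles per range truncates the spectrum: measured reflectance
spectra carry no articulation at very fine spectral scales, and the cutoff
keeps realizations smooth between the 96 grid samples. Defaults (grid 96,
oversample 4, f_max 8) were fixed once against the model's own diagnostics:
sample autocorrelation e⁻¹ at lag τ, periodogram slope −2 over f ∈ [2, 7],
and the ensemble covariance shape below.

Binning spectra into equal thirds (unweighted: the model describes
articulation envelopes, not illuminant-weighted radiances) and summarizing
the physical-domain triples reproduces, at τ = bin width, the expected
structure: correlation decreasing with bin separation with ε₁ ≈ ε₃ < ε₂,
Z > 1, and minor eigenvectors within a few degrees of the opponent axes.

**Telegraph-wave limit.** With zero shift and large amplitude the squashed
spectra become effectively binary, and binned samples should populate only
the six cube edges reachable by a single 0/1 spectral transition — the
boundary colors black–red, red–yellow, yellow–white, white–cyan, cyan–blue,
blue–black, with the green/magenta edges empty. This limit requires the
articulation to vary *slowly compared with the visible window*: by Rice's
formula, any stationary Gaussian process whose correlation falls to 1/e
within one bin crosses zero more than once per window on average, and
multi-transition spectra land inside the cube rather than on its edges (the
single-transition fraction then saturates near 0.65 regardless of cutoff or
amplitude). The `telegraph_params()` preset therefore uses a correlation
length of ten window widths and amplitude 50; with it ≈ 93 % of binned
samples lie within 0.05 of the six single-transition edges and under 1 %
occupy the other six. Edge occupancy is attributed with one care: six cube
corners lie on the single-transition hexagon, so samples near those corners
are also geometrically close to green/magenta edges; the occupancy of the
other six edges counts only samples *not* within tolerance of any
single-transition edge, keeping the "green/magenta edges unpopulated" claim
falsifiable.

## Numerical and design choices

- **CIE tables.** Vendored at the published 5 nm sampling, linearly
  interpolated onto a 1 nm working grid over 380–700 nm. Band integrals are
  trapezoidal, with cuts between grid nodes handled by linearly splitting
  the straddling interval, so the objective is smooth in the cut positions.
  The cut search is an exhaustive vectorized scan over all node pairs
  (via cumulative integrals) followed by coordinate-wise golden-section
  refinement to 0.01 nm — fully deterministic, bit-identical across runs,
  with lexicographic tie-breaking in the coarse scan.
- **Zonotope volume.** Exact O(m³) triple sum; an optional `coarsen` step
  merges runs of consecutive (nearly parallel) generators for fine grids,
  off by default.
- **Clamps.** Byte pixels ingest as (v + 0.5)/256, so image values always
  lie in [1/512, 511/512] and Ω⁻¹ is finite. Float fields from the
  generators are guarded at 1e-15 instead: winsorizing genuine tails at
  1/512 would bias estimated spreads of high-contrast gamuts by about 1 %,
  which exceeds their sampling error at n = 10⁵. Degenerate inputs (zero
  variance, n < 4, cuts outside the grid, non-PSD covariances) raise typed
  errors rather than returning NaNs.
- **Randomness.** Every stochastic operation takes a seed and uses its own
  `numpy` Generator; fixtures seed per image as `default_rng([seed, i])` so
  any single image regenerates bit-identically. CLI reports embed all
  effective parameters and seeds.
- **Problem sizes.** Tests and the acceptance script use 10⁴–10⁶ samples:
  large enough that Monte-Carlo error is well below every asserted
  tolerance, small enough to run in seconds.

## What the synthetic data does and does not show

The fixture generator emulates the *marginal and covariance* structure of
natural imagery — six-parameter opponent signatures, optional two-region
(ground/sky) banding, optional physical-domain spatial smoothing, 8-bit
quantization. It does not emulate spatial power spectra, JPEG artifacts,
saturation/flare, or object-level segmentation; passing tests therefore
validate the estimators and generators against their own model class, not
against any external image corpus. Quantities that depend on real corpora
(the empirical Ψ ≈ 0.114 proportionality between σ_Ξ and σ_Θ, corpus Z
quartiles, per-database means) are exercised here only as parameter-recovery
properties on synthetic signatures generated with those published values.

## Known limitations

- The colorimetry covers exactly what the optimization needs: no
  chromaticity diagrams, color-appearance models, or observers beyond the
  supplied table files.
- The Kubelka–Munk layer is the infinite-thickness limit only.
- The toy spectral model's construction (Gaussian synthesis, hard f_max,
  equal-thirds binning) is one concrete realization of a 1/f² articulation
  model; its constants are package choices, documented above, not measured
  quantities.
- `psi_regression` assumes independent signatures; no uncertainty is
  propagated from the per-image estimates into the fit.
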