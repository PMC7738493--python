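# Methods

## Model equations and conventions

The scale-invariant (SI) family and its pooled extension are implemented in
`poolsi.core` exactly as closed forms (see README for the equations). All
angles are degrees at public interfaces (radians internally), spatial
frequencies cyc/°, spatial widths degrees of visual angle, and every width
is 1σ of a Gaussian. The "61% half-width" bandwidth convention used by the
tuning fits equals 1σ to within 1%: exp(−x²/2σ²) = 0.61 at
x = σ·sqrt(2 ln(1/0.61)) ≈ 0.994σ.

Two numerical points worth noting:

* The constant log-SF bandwidth of the SI family, log₂(1 + α/2π), evaluates
  to log₂(1.5) ≈ 0.585 octaves at α = π. A value near 0.71 oct sometimes
  quoted for this expression is not what the formula gives; the
  implementation returns the expression's value.
* The F1/F0 Gaussian has SD (σ_h(x)·2π·D)⁻¹; at σ_h(x) = 0.24° and D = 1
  this is 0.66 cyc/° (`f1f0_gaussian_sd`).

## Generative simulations as oracles

`poolsi.simulate` rebuilds the pooled predictions constructively — shifted,
Gaussian-weighted SI envelopes (spatial), half-wave-rectified phase-shifted
inputs (phase), and 2D spectral Gaussian blobs under an isotropic pooling
window (spectral) — on numerical grids, and the test suite requires them to
agree with the closed forms within 2–5%. These tolerances were set by
grid-convergence runs (default 0.01° spatial step, ±5σ extents, inputs on a
±4σ pooling grid), not taken from any reported value. In the spectral
simulation all input blobs share the radial width σ_f,si(f_o) of the pooled
cell's preferred SF — the same approximation the closed forms make — so the
superposition separates into independent radial and tangential 1D profiles.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed and the
tests and acceptance runs use them as-is.

* **Cortical sheet** (`synth.sheet`): the preferred-SF map is band-pass
  filtered Gaussian noise (annular Gaussian band centred on 1/750 µm⁻¹,
  relative bandwidth 0.25), standardized and exponentiated so the log₂(f_o)
  marginals match the measured population exactly (mean-log₂ 0.95, SD-log₂
  0.64). The orientation map is the half-angle of an identically filtered
  complex field, which produces pinwheels. Retinotopy is a linear gradient
  at 2.0 mm/° magnification; the absolute-phase map advances at
  D·360·f_o degrees per degree of retinotopy. Map synthesis by filtered
  noise is a modelling choice made for controllability of the period and
  marginals — the real maps' higher-order structure is not emulated.
* **Populations** (`synth.population`): each neuron's true tuning follows
  the pooled equations at its map-inherited f_o. Measurement targets carry
  multiplicative log-normal scatter on widths with SD 0.2 in log₂ units
  (the analysis domain; no noise model is prescribed by the data source)
  and additive truncated-Gaussian noise (SD 0.15, clipped to [0, π]) on
  F1/F0. RF centres get isotropic jitter with total radial SD 0.05°
  (0.05/√2 per component). ON–OFF separation is tied to phase selectivity
  (0.5·F1F0/π), a generator convention.
* **Kernels** (`synth.kernels`): grating responses are separable — axial
  Gaussian in orientation, Gaussian in linear SF, and a phase curve that
  mixes a rectified cosine with a flat component so its fundamental
  peak-to-peak over mean equals the target F1/F0 exactly. Bar responses are
  line-weighting Gaussians (projections of the anisotropic 2D envelope,
  length/width = 2) analytically convolved with the 0.2° boxcar bar
  profile; bar length is fixed at 3°. The temporal profile is a
  double-exponential calcium impulse response (rise 50 ms, decay 400 ms,
  config-exposed; indicator kinetics are not prescribed). Kernel noise is
  additive Gaussian with SD expressed as a fraction of the peak response
  (default 0.05–0.1 across the pipeline).
* **Movies/sessions** (`synth.movie`): stimulus sequences flash one
  condition per 133 ms update in 20–40 s blocks with 5 s gray gaps; each
  condition is treated as a static flash. Movies paint Gaussian puncta
  (σ = 3 µm) with a static baseline brightness plus the session traces,
  shared additive sinusoids at the breathing/heartbeat frequencies
  (defaults 0.4 and 1.5 Hz), white noise, and optional integer-pixel drift.
  No optics/PSF, photon shot noise, or axial motion is modelled, so
  passing end-to-end tests demonstrates correctness of the analysis chain,
  not robustness to every real-data artifact.

## Imaging pipeline

Alignment is translation-only, via the cross-correlation peak against the
mean frame (integer-pixel by default). Cell detection scores each pixel
with the local cross-correlation image — the summed product of its
(mean-subtracted) time course with the DoG-filtered frame, centre σ = 3 µm
and surround σ = 20 µm, each integral-normalized — then replaces manual
point-and-click with a deterministic rule: local maxima above 4 robust SDs
seed region growing at 50% of the seed value, claimed in seed-strength
order so ROIs never overlap. A mask-import path preserves the manual
workflow.

The artifact notch filter detects up to two resonant lines in a 0.2–3 Hz
search band on a Welch-averaged log-spectrum; a candidate must exceed the
local median floor by 3 robust SDs *and* stand at least 6 dB above it.
The prominence requirement keeps broadband noise fluctuations (which can
exceed 3 SD by chance across many bins) from triggering spurious notches,
while genuine sinusoidal artifacts clear both by a wide margin. Removal is
zero-phase spectral interpolation of the affected full-resolution FFT
bins, avoiding phase distortion of triggered averages; the operation is
idempotent. Traces are Z-scored per trial block, and stimulus-triggered
averages span 1 s (15 frames) after onset with per-condition counts
reported and never-shown conditions flagged.

## Tuning fits

Kernels are smoothed along time (Gaussian, σ = 50 ms) and sliced at the
peak frame (ties to the earliest). Orientation: 4-parameter Gaussian after
circularly centring the peak, on the SF-weighted 1D curve (weights are the
mean response along the other axis, clipped at zero and renormalized);
σ_θ is the fitted σ, falling back to the numerical 61% half-width capped at
90° for very broad fits. SF: 5-parameter difference-of-Gaussians on the
linear axis; f_o is the argmax of the fitted curve, bandwidth is
(f_hi − f_low)/2 at 61% of the peak with f_low falling back to the lowest
sampled SF; a fitted peak at the minimum SF flags the cell low-pass. Phase:
fixed single-cycle sine fit over the four phases; F1 is the fundamental's
peak-to-peak, F0 the mean (non-positive F0 excludes the cell). Note that
four-point sampling of a half-wave-rectified cosine biases F1/F0 between
2.83 and 4 depending on phase alignment (π is the continuous value).

Bar kernels are 2×-binned in orientation and position before fitting. The
RF width is the Gaussian σ of the luminance-averaged line-weighting
function at the optimal orientation; ON and OFF are fit separately for
|μ_ON − μ_OFF|/(σ_ON + σ_OFF). The RF centre comes from a 2D (rotated)
Gaussian fit to the ramp-filtered back-projection of the position
responses; projections are normalized to equal area first — orientation
tuning modulates the projection amplitudes, which violates the Radon
consistency conditions, and the normalizer is floored at 25% of the
maximum so orientations carrying mostly noise are not amplified. Inclusion
requires 70% variance explained (orientation+SF fits for grating analyses,
the 2D envelope fit for bar analyses; joint analyses intersect), and
low-pass cells are excluded from statistics but kept for plotting. The
optional bar-width correction removes the boxcar variance w²/12 (≈2% of
the width at w = 0.2°, σ = 0.3°); it is off by default to match the
headline fits. Fit initialization is by small grid search over width seeds
with bounded local least squares; none of this is prescribed upstream.

## Estimation and model comparison

The root-median estimators use signed squared differences; a non-positive
median is an explicit failure, since the pooled construction presumes
measured widths exceed the SI prediction. D is fit by bounded scalar least
squares after σ_h(x) is constrained from RF widths (the sequential
procedure). LOOCV refits the left-out model per cell (brute force — at the
n of interest this is cheap and exact) and compares squared log₂ errors
with a paired t-test (Wilcoxon available). Flexible-α scale invariance has
the closed-form log-space solution (geometric mean of implied per-cell
coefficients).

Magnification: the zero-intercept line through the pairwise (cortical mm,
RF °) scatter is fit with the RF separation — the noise-laden variable —
as the response, then inverted. A direct mm-on-deg regression suffers
errors-in-variables attenuation of ~5% at the default RF-centre jitter;
the inverted fit halves it (~2.5%, characterized by Monte-Carlo in the
tests). Per-ROI estimates are available via a grouping column; the
headline estimates always pool all included cells.

## Clustering statistics

All unordered pairs are binned by cortical distance into half-open 75-µm
bins (bins with <3 pairs are flagged untested). Non-circular parameters use
the Pearson correlation of the paired values with each pair entered in both
orders (making the statistic symmetric); orientation uses
r = ⟨cos 2(ori_i − ori_j)⟩, which is +1 for identical preferences and −1
for orthogonal ones (90° apart; the factor-2 formula is implemented as
defined). Parametric Pearson p is the default for non-circular parameters;
orientation uses a 1000-fold position-shuffle permutation with add-one
smoothing (minimum attainable p = 1/1001); either method is available for
any parameter.

## Problem sizes and determinism

Every generator and stochastic routine takes a seed and is bit-reproducible
(the pipeline writes a manifest with config and output checksums). The
test suite runs at reduced problem sizes chosen for convergence, not
fidelity: recovery tests use 150–200 cells and 100 seeded replicates,
end-to-end movie tests use two cells on a 56×56-pixel field over a 20 min
session, and the demo pipeline defaults to 100–150 cells on a 0.7×1.0 mm
sheet. The acceptance script mirrors the stated recovery conditions
(n = 200/150/100 cells, 50–100 seeds) and completes in seconds.

## Known limitations

* The generator's separable grating response and analytic bar profiles are
  idealizations; nonlinearities beyond the optional static power law
  (`apply_fluorescence_nonlinearity`) are not modelled.
* Stimulus-triggered averages of rapid sequences carry overlap
  contamination from the 1 s calcium response; with the default session
  length this keeps end-to-end kernel correlations near 0.92–0.95, not 1.
* No non-rigid motion correction and no spike inference.
* No binocular disparity, color, or surround modulation.
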