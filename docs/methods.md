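# Methods

This note documents the models and procedures implemented in `matfp`, the
design choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Fingerprints and scales

A fingerprint holds 16 attribute values for one material. Two scales exist:

* `zscore` — the direct output of rating aggregation (participant-normalised
  means), unbounded;
* `unit` — per-attribute min–max rescaling of a reference corpus onto
  [−1, 1].

The similarity metric is defined only on the unit scale: its L1 term divides
the summed absolute difference by 2n, which bounds the term in [0, 1] exactly
when each |difference| ≤ 2, i.e. when values live in [−1, 1]. The rescaler
stores the reference minima/maxima so new fingerprints (model predictions,
new materials) map onto the same scale; values are clipped into [−1, 1] when
they fall outside the reference range.

Degenerate case: Pearson correlation is undefined for a constant fingerprint.
The correlation term is then defined as 0 (a neutral contribution) and a
`RuntimeWarning` is emitted. Retrieval breaks ties by ascending material id so
results are reproducible. Typicality averages the top ⌈fraction·(N−1)⌉
similarities among the *other* members — with the default 10% and N = 11 that
is exactly the single nearest neighbour.

## Rating pipeline

Z-scoring uses the sample (n−1) standard deviation within each
(participant, attribute) stratum across materials. A constant stratum carries
no ordering information; it is set to 0 and the (participant, attribute) pair
is excluded downstream with reason "zero variance".

The exclusion rule computes, per attribute, the mean rating per material over
*all* participants (including the one under test — a single pass, no
leave-one-out and no iteration) and removes participants whose correlation
with that mean is negative or undefined. An attribute rated by a single
participant is never excluded. Aggregation then averages surviving Z-scores
per (material, attribute) cell and fails loudly if any cell loses all its
ratings.

Attribute importance from free-naming data combines how often an attribute is
named (probability `ap` over participant × trial responses) and how early it
is named (mean rank `ao`): `importance = ap · (max(ao) − ao)`. An attribute
never named has `ap = 0`, undefined `ao` and importance 0.

Fleiss's kappa is implemented directly from the category-count table (it
requires a balanced design: the same number of raters per response) and is
cross-checked in the tests against `statsmodels`' implementation on seeded
tables. Raw slider responses are validated against a fixed 0–100 range.

## Image features

All three extractors are pure functions of the frame pair (non-specular frame
first); determinism is part of their contract.

**Frame conventions.** For an n-frame sweep covering 90° and ending at the
ideal specular configuration, the non-specular frame is `round(n/2)` and the
near-specular frame backs off `round(offset / step)` frames from the end
(6° by default; with 60 frames this selects frames 30 and 56). For embedding
backends, frames are resampled so the depicted sample spans
`round(sample_mm / 25.4 · 250)` pixels (250 DPI; 256 px for the canonical
26 mm sample) and centre-cropped to 224 px.

**S statistics (14 per frame).** Luminance (Rec. 709) mean, SD and skewness;
relative spectral energy in four log-spaced radial bands (DC excluded);
directionality strength (1 − circular variance of magnitude-weighted,
angle-doubled gradient orientations); bright-outlier fraction (share of
pixels > mean + 3 SD — a tail statistic that responds to sparkle speckle and
small highlights); effective number of dominant colours (exp of the Shannon
entropy of 8-means colour-cluster shares, computed on exposure-normalised
pixels, so 2.0 for an ideal two-tone checkerboard and 1.0 for a flat field);
stripe and checker scores from the orientation-binned power spectrum (stripe:
energy excess of the dominant orientation over its orthogonal; checker:
energy shared by the dominant pair and its orthogonal pair, because a square
checkerboard's fundamental peaks occupy two orthogonal orientations); mean
relative chroma (chroma/lightness, i.e. saturation, invariant to exposure);
and the log2 radial frequency of the strongest non-DC spectral peak (a direct
pattern-scale readout). Zero-variance frames yield defined values (zeros)
for every contrast-type feature, never NaN. During development two of the
originally drafted features were replaced: an orientation-histogram entropy
(nearly collinear with directionality strength, r ≈ −0.74) and a circular
hue SD (uninformative for the attributes under study) gave way to the
bright-outlier fraction and the dominant-peak scale.

**T statistics.** A complex steerable pyramid (frequency-domain raised-cosine
radial filters, cos²-law angular lobes restricted to a half-plane, dyadic
downsampling) with 3 scales and 3 orientations is built per colour channel
and frame. The statistic groups are the classical texture-synthesis set:
pixel marginals; SD/skewness/kurtosis of the low-pass image at each level;
central 7 × 7 normalised autocorrelations of the low-pass images and of the
band magnitudes; band/residual magnitude means; within-scale
cross-orientation and cross-scale (parent) magnitude correlations; phase
statistics (child real part against the real and imaginary parts of the
phase-doubled, pixel-upsampled parent); within-scale cross-orientation
real-part correlations; and high-pass marginals. The raw storage layout has
786 slots per channel, 339 of which are structural zeros (the redundant
point-symmetric half of each autocorrelation and the no-parent slots of the
coarsest scale). The zero-feature mask is fitted once over a corpus and
removes every slot that is exactly zero in all members; on any corpus of
textured images this removes precisely the structural zeros, leaving 447
statistics per channel and a 1341-dim vector over three channels. Statistics
of the two frames are averaged per channel before masking. The mask is stored
with a trained model and a length mismatch at application time is an error.

**C embeddings.** A backend maps a 224 × 224 frame to a 512-vector; the pair
representation concatenates both frames (1024 values). The default backend is
a fixed, seeded Gaussian projection of the 32 × 32 box-downsampled image —
deterministic, dependency-free, and honouring every contract of the
representation, though without the semantic content of a pretrained
vision-language encoder. A ViT-B/32 adapter is provided for environments with
the optional `clip` extra installed.

## Predictors

Features are standardised per dimension over the training set (constants
stored with the model) so that L2 distances and gradient conditioning are not
dominated by feature scale.

**kNN (2NN).** With k = 2 and distances d₁ ≤ d₂, weights are
(1/dᵢ)/Σ(1/dⱼ); a zero-distance match returns that exemplar's fingerprint
exactly. Ties in distance are broken by ascending material id. "Linear
interpolation" between two exemplars in a high-dimensional feature space is
ambiguous; inverse-distance weighting is the convention adopted here (it is
continuous away from ties and reduces to the midpoint for equidistant
neighbours).

**MLP.** Architectures are fixed per feature kind (S: 28-16-16-16,
T: 1341-256-64-32-16, C: 1024-512-512-16), ReLU hidden layers, identity
output, mean-squared-error objective (scikit-learn `MLPRegressor`). Targets
are standardised per attribute during training and the constants are stored
on the model. These networks are very small and full-batch quasi-Newton
optimisation proved far more reliable than stochastic first-order training
(which plateaued below a linear ridge baseline on the recovery experiment),
so the default regime is L-BFGS over an L2 grid {0.3, 1, 3} with 8 random
restarts; the top 5 fits by mean-squared error on a held-out 15% validation
slice of the training materials form a restart ensemble whose predictions are
averaged. Every member has exactly the architecture above; the ensemble is an
optimisation-stabilising device, not a capacity increase, and single-member
training plus an adam regime remain available through `MlpConfig`. All
training is seeded and bit-reproducible.

**Augmentation.** Image-space augmentations (random crop, rotation — never
for the rotation-invariant S statistics — scaling up to 5%, azimuth jitter up
to 2.5° realised as nearest-frame selection when a full sequence is
available) are implemented in `matfp.features.augment` and can feed extra
(feature, target) pairs into training through an augmenter callback. The
default recovery experiments do not use augmentation: at their corpus sizes
it did not improve held-out accuracy.

**Split.** Stratified by category: `round(test_fraction · n)` members per
category (at least 1 when n ≥ 2; singleton categories go to training), drawn
without replacement from a seeded generator.

## Evaluation

RD² is computed as the squared Pearson correlation per attribute (not
1 − SSres/SStot), consistent with the correlation-based RSM²; a constant
attribute yields 0 with a warning. RSM² correlates the strict upper triangles
of the two similarity matrices. Top-k overlap breaks ties by ascending
material id. The rank index selects the top-n materials *by the human
ratings* and computes the Spearman correlation between human and predicted
values within that subset (ranks taken within the subset — the only reading
that keeps the statistic in [−1, 1]). AIC uses the Gaussian-likelihood form
2k + n·ln(RSS/n) with n = materials × 16 residuals; for an MLP, k is the
trainable weight count of a single member network, and for kNN the stored
exemplar-coordinate count.

## Synthetic materials and raters

`generate_pair` composes the non-specular frame as
`brightness · colour_field · (1 + pattern)` clipped to [0, 1], where the
pattern mixes an oriented sine grating (`stripe_amp`), a two-tone
checkerboard (`checker_amp`, square-wave product along two orthogonal axes)
and a 1/f^β Gaussian noise field (`noise_amp`, amplitudes constrained to sum
≤ 1), and the colour field quantises a smooth random field into `n_palette`
regions coloured from a per-material palette. The near-specular frame adds a
smooth central gloss highlight (`gloss`) and bright sparkle speckle
(`sparkle_density`); with both at zero the frames are identical. Everything
is deterministic under the material seed; the palette uses a dedicated
sub-stream of that seed so the rendered colours always match the ground-truth
maps.

Ground-truth fingerprints are deterministic monotone maps from the
parameters. Amplitude-like attributes (stripes, checks, roughness, gloss,
sparkle, movement) go through a square-root before the affine map onto
[−1, 1] — a Stevens-type compressive magnitude function that keeps low
amplitudes discriminable on the rating scale. Attributes with no physical
generator axis use explicit surrogates: hardness inversely related to surface
noise, warmth from the base-colour hue (peaking at orange), naturalness from
noise amplitude, thickness from the noise spectral slope, value from gloss
and smoothness, pattern complexity from mixture richness and palette size.
These maps define *this generator's* truth; passing recovery tests shows the
pipeline recovers what the generator encodes, not that the surrogates are
perceptually valid for real materials.

Simulated raters apply a per-participant gain and bias to the truth, add
Gaussian noise (SD expressed on the truth scale) and clamp to the 0–100
slider; adversarial raters respond to the negated truth and are therefore
flagged by the negative-correlation exclusion rule for every non-constant
attribute. `make_corpus` stratifies draws over four pseudo-categories
(striped-fabric-like, wood-grain-like, glossy-coating-like, noisy-matte-like)
with documented parameter ranges wide enough that every generator-controlled
attribute spans at least 80% of [−1, 1] on a 200-material corpus.

## Problem sizes and numerical choices

The recovery experiments run at deliberately desk-friendly sizes chosen once:
50 materials × 10 raters for rating-pipeline recovery (response noise SD 0.2,
one adversary), and 200 materials (150 train / 50 test, 3 seeds, majority
vote) rendered at 256 px for the S-feature MLP experiment. The canonical
rendering default remains 512 px, used by the texture-statistic
dimensionality measurements. The steerable pyramid requires the image to stay
≥ 8 px after 3 dyadic downsamplings (so ≥ 64 px inputs). K-means colour
quantisation subsamples to ≤ 4096 pixels and is seeded; correlations of
zero-variance signals are defined as 0 throughout.

## Known limitations

* The default embedding backend is a random projection: it preserves coarse
  image structure but carries no semantic prior; C-feature results with it
  say nothing about pretrained vision-language embeddings.
* The generator produces stationary, fronto-parallel, clip-composited
  patterns; it does not emulate BRDF/BTF effects, anisotropy, perspective or
  white-balance variation of real captures.
* The texture-statistic layout reproduces the classical statistic families
  but is not numerically interchangeable with any specific legacy
  implementation; only its documented structure (447 informative statistics
  per channel, 1341 total) is contractual.
* Fleiss's kappa supports balanced designs only; unequal rater counts per
  response are rejected rather than approximated.
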