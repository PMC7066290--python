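# Methods

This note records the model, the conventions and the deliberately made
design choices behind `mprad`, in the order the data flows through the
package.

## Signatures and quantization

All features operate on the tissue signature S_p, the length-N vector of
intensities at voxel p across the co-registered channels.  Inputs are
assumed co-registered on a common grid; no resampling or registration is
performed, and a shape or affine mismatch (tolerance 1e-4) is a hard
error.

Gray-level quantization maps intensities to integer levels 1..G with
linear, equally spaced bins between the scope minimum and maximum,
half-open [lo, hi) with the maximum closed into level G so the top level
is never empty.  A constant channel maps wholly to level 1.  Non-finite
intensities raise immediately rather than being masked: silent NaN
handling in a texture pipeline hides registration and conversion bugs.

Two scopes are exposed because they answer different questions:

* **roi** (default for region feature values) — min/max over the region,
  maximizing intra-region dynamic range.  Note the flip side: a region of
  pure noise is stretched to full range, so a near-constant compartment
  only shows near-zero joint entropy under volume scope or with noise-free
  input.
* **volume** (default for feature maps) — min/max over the whole channel,
  fixed across sliding windows, so map values are spatially comparable.
  Per-window re-quantization would destroy spatial contrast.

Defaults: G = 8 for region-level joint features (with the small regions of
the synthetic benchmark, larger G drives every signature to a unique cell
and saturates the joint entropy at log₂ of the voxel count), G = 128 with
a 5×5 window for feature maps (the map preset), B = 128 bins for pooled
histograms, B = 32 for the per-channel baseline.  All are plain
parameters.

## TSPM

The joint distribution of quantized signatures is stored sparsely (a dict
keyed by level tuples): at most one cell per region voxel is occupied,
while a dense table would need G^N cells.  Entropy uses log base 2
(bits) with 0·log 0 := 0; uniformity is Σp².  Multivariate mutual
information is the inclusion–exclusion alternating sum of subset
entropies, Σ_{∅≠Y} (−1)^{|Y|+1} H(Y); for N = 2 this is the familiar
H₁+H₂−H₁₂ ≥ 0, for N ≥ 3 it is the interaction information, which can be
legitimately negative and is reported signed, not clipped.  Its cost is
2^N − 1 marginalizations, fine for the N ≤ 16 channel counts this package
targets.

## TSFOS

All channels' in-region intensities pool into one B-bin histogram.  Raw
pooling (global pooled min–max) suits intrinsically co-scaled series
(DWI b-values, DCE frames); normalized pooling rescales each channel to
[0, 1] over the region first and is the default in the extraction
pipeline, where channels carry arbitrary units.  Moments are computed on
bin centers weighted by bin probabilities, so every feature is strictly a
function of the histogram.  "Energy" and "uniformity" are two names for
Σp² and are reported as an alias pair.  Kurtosis is the plain
(non-excess) fourth standardized moment throughout the package, so a
Gaussian histogram scores ≈ 3.

A consequence worth stating: two channels constant at *different* values
pool, under raw mode, into two equally filled bins — 1 bit of entropy.
Zero TSFOS entropy for constant input holds per channel (normalized
pooling) or for a single common constant; the degenerate-input tests
exercise exactly those cases.

## TSCM and the 22-feature set

The between-voxel co-occurrence accumulates, for every in-region voxel
pair at offset (d, θ) *and its reverse* (symmetric accumulation, the
common GLCM practice), the per-parameter pair counts
|{r : S_i(r)=m, S_j(r)=n}|.  Angles follow the Haralick compass with the
image y-axis up: 0°→(0,d), 45°→(−d,d), 90°→(−d,0), 135°→(−d,−d); a
symmetric matrix is invariant to negating the offset.  3D fields use the
in-plane angles slice by slice; explicit axial offsets can be passed.
With N = 1 the construction is bit-identical to the classical symmetric
GLCM (verified against both a nested-loop oracle and scikit-image).  In
the extraction pipeline the features are averaged over the four in-plane
angles at d = 1; per-angle values remain available.

The feature extractor implements the 14 classical Haralick statistics
plus 8 widespread extensions (autocorrelation, cluster
prominence/shade/tendency, dissimilarity, maximum probability, inverse
difference normalized, inverse difference moment normalized), fixed as
this package's 22-feature contract.  Degenerate denominators resolve to
0: correlation when a marginal standard deviation vanishes, the
information measures of correlation when the conditioning marginal
entropy vanishes, the maximal correlation coefficient on numerical
failure (it is otherwise the square root of the second-largest eigenvalue
magnitude of the Q matrix restricted to occupied marginals).  Entropies
are in bits; the information-measure-2 exponent is converted to nats
internally so the classical formula keeps its meaning.

## TSCIN and TSRM

First-order TSCIN statistics are evaluated on the [0, 1]-normalized
signature vector independently at each voxel, so max/range/MAD are
scale-free unit-interval quantities comparable across channels.
Dispersion uses the population (1/N) convention — signatures are complete
vectors, not samples.  Signature entropy uses a fixed 8-bin histogram
over [0, 1] (signatures are short, N ≈ 4–16; more bins would be mostly
empty), hence is bounded by 3 bits.

The TSRM counts ordered level pairs at channel positions (k, k+d) within
one voxel's signature; the total count is exactly N−d.  It is kept
*ordered* (not symmetrized) because parameter sequences are directional —
reversing the channel order transposes it, and the test suite pins that
property.  Per-voxel TSRM maps for the count-expressible features
(entropy, energy, maximum probability) are computed vectorized across the
whole region; the full 22-feature set is available per signature.

## Feature maps

A map assigns to each voxel the feature of its w×w in-plane neighborhood
(odd w ≥ 3), with mirror padding so output matches input and 3D volumes
processed slice-wise (the window preset is 2D).  Quantization is
volume-scoped (see above).  Map correctness is tested pixel-for-pixel
against a naive per-window recomputation.

One algebraic fact the tests document: duplicating a channel doubles all
TSCM pair counts and therefore leaves the *normalized* matrix and its
features unchanged — the single-image GLCM map is exactly the N = 1
collapse, not merely an approximation.  A genuinely different second
channel changes the joint signature distribution and the maps.

## IsoSVM

Features are z-scored (the families live on wildly different scales),
embedded by Isomap — symmetrized k-NN graph on Euclidean distances
(k = 20 default), all-pairs shortest paths, classical MDS, top d_embed
coordinates (default 1) with a deterministic sign convention — and
classified by a linear SVM whose benign-class (label 0) cost is
multiplied by the penalty ratio.  Zero-length k-NN edges (duplicate
subjects) are clamped to 1e-12 so they survive the sparse representation;
a disconnected graph is repaired by adding the shortest Euclidean
inter-component edge until one component remains.

The grid search evaluates each ratio in {1, 1.5, 2, 2.5, 3, 3.5, 4} : 1
by leave-one-out decision scores, keeps the maximum-AUC ratio (ties to
the smaller ratio — parsimony), and reads sensitivity/specificity at the
Youden-optimal threshold of the LOOCV scores.  By default the embedding
is fit once on all subjects and only the SVM is cross-validated
(transductive); a strict mode re-embeds per fold and places the held-out
subject by nearest-neighbor geodesic extension with Gower interpolation.
The transductive and strict AUCs agree within 0.1 on the synthetic
benchmark (tested), but the transductive number remains mildly optimistic
and the caveat travels with the API.

ROC analysis: midrank Mann–Whitney AUC (ties count one half), DeLong
variance for the 95% CI.  Group statistics per feature: mean ± SEM,
Welch's two-sided unpaired t-test (robust to unequal variances), and a
univariate logistic fit whose p-value is the likelihood-ratio test —
unlike the Wald p it stays informative when the classes are perfectly
separated and the coefficient diverges.  A feature with zero variance in
both groups has no defined t statistic and is flagged rather than faked;
its AUC is still computed (0.5 under midranks).

## Synthetic phantoms: what they emulate and what they do not

Compartment textures are Gaussian random fields: white noise filtered
with a Gaussian kernel (correlation length = kernel sigma, in voxels),
then standardized *within the compartment* to the prescribed amplitude.
That standardization is load-bearing: it holds the first-order marginals
fixed while correlation length varies, so the benign/malignant contrast
lives purely in spatial heterogeneity and cross-channel structure, not in
intensity histograms.  Channels mix one shared latent field (weight =
coupling) with independent fields (weight = √(1−coupling²)), keeping
per-channel variance fixed while the coupling dials inter-channel mutual
information.

Benchmark conditions (frozen as the package's study conditions): 36×36
grid, N = 4 channels, lesion disk radius 8, glandular background with
correlation length 2 and amplitude 0.8, voxel noise sd 0.05, coupling
0.7.  Benign lesions: correlation length 3.0.  Malignant lesions at
effect size e: correlation length 3.0/(1+3e) (4:1 heterogeneity ratio at
e = 1) and lesion coupling 0.7·(1−0.4e) (larger within-voxel spread).
e = 0 makes the classes identically distributed; the glandular background
never depends on class, providing the contralateral-tissue null.  Cohorts
(default 20 + 20, mirroring a benign/malignant imbalance study at desk
scale) extract all five families plus the per-channel baseline per
subject, deterministically from one seed.

What passing tests on these phantoms show: the estimators are correct
(oracle equivalences), the information-theoretic structure behaves
(bounds, independence, monotone heterogeneity response), and the pipeline
end-to-end separates classes whose difference is joint-texture by
construction while single-channel first-order features carry little
signal.  What they do not show: performance on real lesions, where class
differences also appear in first-order statistics, lesion shape and
acquisition artifacts — none of which the generator emulates (no MR
signal physics, no pharmacokinetics, no spatially varying noise).

## Numerical and degenerate-input conventions (summary)

* log base 2 everywhere an entropy is reported; 0·log 0 := 0.
* constant region → TSPM entropy 0, uniformity 1, Haralick energy 1 /
  entropy 0 / contrast 0, TSCIN dispersion 0, zero feature maps.
* skewness/kurtosis of a zero-variance histogram or signature := 0.
* empty regions, non-finite intensities, offset with no valid pairs,
  d ≥ N for the TSRM, single-class label vectors: errors, never silent.
* all randomness flows from explicit integer seeds; equal seeds give
  byte-identical phantoms, CSVs and metrics.

## Problem sizes used by the checks

The test suite and acceptance script run at deliberately small scale,
chosen as the smallest sizes at which each property is meaningful: 8×8
images for count-exact oracle comparisons, 16×16 for pixel-exact map
verification, 10⁴ voxels for the independence bound on mutual
information, 50 seeded 20+20 cohorts for the directional class-separation
rates, and n = 100 over 50 seeds for the two-Gaussian closed-form AUC
limit Φ(1/√2) ≈ 0.760.
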