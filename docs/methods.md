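# Methods

`petseg` implements and evaluates semi-automatic segmentation of FDG-PET
lesions inside user-drawn bounding boxes.  This note records the models,
the parameters that matter, the synthetic data the package is validated on,
and the numerical choices made where the design was genuinely open.

## Problem setting

The quantity of clinical interest is the metabolic active tumor volume
(MATV): the physical volume of the segmented lesion mask, in ml.  Because
MATV changes are used to judge therapy response, the segmentation must be
*repeatable*: two scans of the same patient under the same physiological
conditions should yield nearly the same MATV.  The package therefore pairs
every segmentation method with an accuracy *and* a test-retest evaluation.

All images are handled in SUV units (activity concentration normalized by
injected dose and body weight, `SUV = C[kBq/ml] · w[g] / D[kBq]`; body-weight
SUV, no decay correction).  Grids are axis-aligned with voxel-centre
positions `(index + 0.5) · spacing`; NIfTI images with non-diagonal affines
are rejected rather than resampled.  Lesion detection is out of scope: each
lesion arrives as a 64-cube (desk scale: 32-cube) bounding box in which the
lesion is randomly placed, so that learning methods cannot memorize
position.

## Segmentation methods

**Conventional thresholds.**  `SUV2.5`, `SUV4` (fixed), `41%SUVmax`
(relative), and `50%SUVmax` with background correction.  All thresholds are
strict (`>`).  The background-corrected threshold is
`0.5·(SUVmax − BG) + BG` with BG the mean SUV in a 2-voxel-thick shell
displaced 2 voxels from the 70%-of-max core; the exact correction used in
the clinical lineage of this method is not published alongside it, so this
shell estimate is our documented, configurable choice.  `MV2`/`MV3` include
a voxel iff at least 2/3 of the four thresholds above include it.  A
connected-component policy (keep the 26-connected component with the highest
SUVmax) suppresses disconnected noise voxels inside a single-lesion box; for
majority voting it is applied only when the caller supplies the SUV volume,
because the raw vote mask is what guarantees `MV3 ⊆ MV2` and matches
per-voxel vote counting exactly.

**Textural-feature (TF) voxel classification.**  For each of the three
standard views (axial, sagittal, coronal), every voxel is the centre of a 2D
in-plane scanning window.  Nine first-order statistics (mean, SD, min, max,
median, skewness, kurtosis, energy, entropy) and four co-occurrence features
(contrast, correlation, homogeneity, dissimilarity; 32 grey levels over the
fixed SUV range [0, 20], two in-plane unit offsets, symmetric) are computed
per window, a random forest ranks them by impurity importance, the top-k
(default 8) feed a per-view random-forest voxel classifier, and the three
per-view probability maps are summed; voxels with summed probability
strictly above 1.8 form the mask.

Two TF choices deserve justification:

* *Window size.*  Default 5×5 (20 mm at 4 mm voxels).  Larger windows
  (9×9 = 36 mm) average over more than a typical lesion diameter and in our
  phantom experiments systematically over-segmented (volume ratios near 2);
  5×5 keeps the window local while still giving 40 co-occurrence pairs.
  The size is configurable.
* *Class balance.*  Training uses all tumor voxels plus an equal-count
  seeded background sample, half drawn from a 3-voxel shell around the
  lesion and half uniformly from the remaining background.  The shell is
  where classification is actually decided; uniform sampling leaves the
  blurred transition zone almost unrepresented and biases the classifier
  toward calling it tumor.

**Size-gated 3D U-Net.**  Two networks are trained, one on lesions with
ground-truth MATV ≤ 12.8 ml ("smaller"), one on the rest; at inference the
lesion is routed by an initial MV2 volume estimate (≤ 12.8 ml → small
network; an empty vote mask also routes small, since an
invisible-on-threshold lesion is most plausibly small).  The network is a
standard encoder-decoder: per level a conv block (two convolutions of kernel
5, each + ReLU), 2× max-pool, batch normalization and dropout (rate 0.2);
features double per level from 8 initial features over 3 levels; the decoder
mirrors this with nearest-neighbour up-sampling (interpolation +
convolution, not transposed convolution) and skip concatenation; a 1×1×1
convolution + sigmoid yields probabilities, binarized at 0.5 (symmetric
default, configurable).  Training minimizes the negative soft Dice loss
`−(2Σpt + s)/(Σp + Σt + s)` with smoothing `s = 1e-5` (needed for empty-mask
stability) using Adam at learning rate 0.001, batch 25, 1000 epochs.
Optional augmentation applies seeded in-plane rotations (±20°), in-plane
shifts (≤ 20 % of side length), isotropic rescaling (≤ 25 %), multiplicative
intensity stretch, and Gaussian noise; the identical spatial transform is
applied to image (linear interpolation) and mask (nearest neighbour,
re-binarized).

The network engine is written in numpy (channels-last layout, convolutions
as sums of shifted-slice GEMMs, hand-derived backpropagation, seeded
initialization/shuffling/dropout), so a single-threaded run is
bit-reproducible.

*Desk-scale profile.*  The bundled experiments run a faithful miniature:
2 levels, 4 initial features, kernel 3, 32-cube boxes, ≤ 50 epochs, batch 5,
learning rate 0.01 — same loss, optimizer family, gate and augmentation
machinery; only capacity, grid and schedule are reduced.  The kernel and
learning-rate changes follow the capacity reduction: a 5-cube kernel at
32-cube resolution is disproportionately expensive, and the short schedule
needs a larger step size with more updates per epoch.  The full-scale
profile (3/8/kernel 5/64-cube/1000 epochs) is the library default.

## Synthetic phantoms

No patient data ships with the package; all experiments run on a phantom
generator that emulates the acquisition regime of an EARL-accredited
lung-cancer PET study:

* 4 mm isotropic voxels; uniform background at SUV 1.0;
* ellipsoidal lesions with plateau uptake, tumor-to-background ratios 3-12,
  semi-axes 8-16 mm so ground-truth MATVs straddle the 12.8 ml size split;
* PSF-like Gaussian blur of 7 mm FWHM, then additive Gaussian noise
  (sd 0.2 SUV "moderate", 0.1 "high-contrast");
* optional confounder ellipsoids (heart/kidney analogs) that appear in the
  image but never in the ground truth, reproducing the
  adjacent-high-uptake failure mode;
* test-retest pairs: identical geometry with seeded per-axis centre shifts
  (sd 1 mm), lognormal uptake jitter (sd 0.05 in log), and independent noise
  realizations — emulating two whole-body scans on consecutive days.

Ground truth is the *pre-blur* geometric ellipsoid (voxel centres inside),
which makes accuracy targets analytic and masks independent of blur/noise
settings.  What the phantoms deliberately do **not** model: reconstruction
physics (no Poisson sinogram), spatially correlated noise, respiratory
motion, heterogeneous uptake, irregular lesion shapes, and expert-adjusted
reference contours.  Passing phantom tests therefore demonstrates the
internal correctness and the qualitative behaviour of the methods, not
clinical performance.

## Evaluation framework

Accuracy: Jaccard coefficient `|A∩B|/|A∪B|` (two empty masks score 1.0:
agreement on absence; empty-vs-nonempty scores 0 and is flagged), volume
ratio `MATV_seg/MATV_ref`, and barycenter distance between unweighted mask
centroids in mm (SUV-weighted variant behind a flag).

Repeatability: `TRT% = |v1 − v2| / ((v1+v2)/2) · 100` per lesion;
`RC = 1.96 · SD(TRT%)` with the sample (n−1) standard deviation; and
ICC(A,1) — the two-way, single-measure, absolute-agreement intraclass
correlation, computed from the ANOVA closed form
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` with k = 2 days.
A lesion missed (empty mask, MATV 0) by *any* method on either day is
discarded from *every* method's analysis, so all methods score the same
lesion set.

Method comparison: Friedman test on within-lesion ranks (average ranks on
ties), pairwise Nemenyi post-hoc tests via the studentized-range
approximation on mean ranks (an exact within-row permutation option exists
for tiny n and is used as the test oracle), and Benjamini-Hochberg step-up
correction at α = 0.01.

Cross-validation follows an independent-draw protocol: per fold a fresh
seeded 70/10/20 split of whole phantoms (never individual lesions, to avoid
leakage), stratified by size class so both networks see training data; a
classical rotating split is available behind a flag.

## Numerical choices and degenerate inputs

* Strict `>` at every threshold, including the 1.8 probability sum (the
  per-view probability maps are kept in float64 so the boundary is exact).
* Bounding-box regions outside the source grid are padded with the volume's
  robust background (median of non-lesion voxels), avoiding zero-cliff
  artifacts.
* Constant windows: SD/entropy/contrast 0, skewness/kurtosis defined as 0,
  co-occurrence correlation defined as 1.
* TRT% is undefined when both volumes are 0 (handled by the discard rule);
  ICC is undefined at zero total variance; volume ratio is undefined for an
  empty reference — all raise typed errors rather than returning NaN
  silently.
* Dropout uses inverted scaling; batch-norm running statistics (momentum
  0.9) are used at inference.

## Known limitations

* The numpy U-Net is CPU-bound; the full-scale profile (64-cube, 1000
  epochs) is functional but slow — the desk-scale profile exists precisely
  so the full pipeline is exercisable in minutes.
* The phantom noise level is a free parameter: the emulated study does not
  publish a quantitative noise figure, so defaults are plausible rather than
  calibrated.
* Nemenyi p-values use the asymptotic studentized-range distribution; for
  very small lesion counts prefer the exact permutation option.
* The TF feature catalogue is a compact re-implementation (13 features),
  not a full radiomics library.
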