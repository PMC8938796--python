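# Methods

`spectromics` implements, end to end, a contrast-enhanced spectral micro-CT
radiomics analysis: basis-material decomposition of photon-counting detector
(PCD) data, semantic iodine metrics, an 851-feature agnostic radiomic bank,
univariate screening with false-discovery control, and a repeated
cross-validated logistic classification harness that compares three feature
spaces (conventional energy-integrating CT, the four PCD energy bins, and
the decomposed material maps). Because raw animal images of this kind are
rarely shareable, the package ships a synthetic cohort generator whose
defaults define the study conditions under which the analysis is exercised
and tested.

## Spectral model and material decomposition

Each voxel's bin intensities are modelled as a linear mix of three basis
materials — iodine (I, mg/mL), photoelectric effect (PE) and Compton
scattering (CS), both in arbitrary basis units:

    b = A x,      A ∈ R^{4×3},  x = (c_I, c_PE, c_CS)

The four PCD bins have lower thresholds 25, 34, 50 and 60 keV; the 34 keV
bin sits just above the iodine K-edge (33.2 keV), which is why the default
sensitivity matrix's iodine column rises from the 25 keV row (20 per mg/mL)
to the 34 keV row (32) before falling (18, 10). PE falls steeply with
energy (38, 22, 10, 6) and CS slowly (9.0, 8.6, 8.0, 7.6). These entries
are documented model constants, not physical measurements: in practice A is
estimated by regressing the mean bin intensities of calibration vials of
known composition on their concentrations (per energy row, ordinary least
squares), and everything downstream uses the estimated matrix.

With four equations and three unknowns the decomposition solves the
overdetermined system per voxel by ordinary least squares (Moore–Penrose
pseudo-inverse). No non-negativity constraint is imposed; negative
concentrations from noise are handled downstream by the 1 mg/mL iodine
floor. Under additive bin noise of sd σ the voxelwise estimator covariance
is σ²(AᵀA)⁻¹, which the test suite verifies empirically.

## Semantic metrics

Within the tumor mask, iodine below 1 mg/mL is discarded (detection floor;
the comparison is `>= keep`). Five conventional metrics follow: tumor
volume, enhanced volume, enhanced percentage, accumulated iodine mass and
mean iodine concentration. Mass bookkeeping: 1 mg/mL ≡ 1 µg/mm³, so
concentration × voxel volume accumulates micrograms, reported as mg. The
mean defaults to enhanced-voxels-only (an all-tumor option exists for
sensitivity analysis); when no voxel clears the floor, mean and mass are
reported as 0 with an explicit flag.

## Agnostic feature bank

Each tumor volume yields exactly 851 features:

* 14 shape features, computed once from the mask;
* 93 intensity/texture features (18 first-order, 24 GLCM, 16 GLRLM,
  16 GLSZM, 5 NGTDM, 14 GLDM) on the original image and on each of the 8
  one-level 3D wavelet sub-bands: 14 + 9 × 93 = 851.

Names follow `transform_family_feature_source`
(e.g. `wavelet-LLH_glcm_Contrast_I`). Per subject, the EID channel gives
851 features, the four PCD bins 3404, and the three material maps 2553.

Numerical choices, all pinned and recorded in the output manifest:

* **Discretization** — fixed bin width, `level = floor((v − min)/w) + 1`.
  Default w = 25 for CT-like channels; 0.25 for material maps, whose mg/mL
  scale a CT-sized bin would collapse to a single gray level. Each
  transform image is re-discretized independently.
* **Wavelet** — orthogonal Coiflet-1, single level, periodization boundary
  on an even-padded grid. Each sub-band is reconstructed to the original
  grid by inverting with all other coefficient sets zeroed; orthogonality
  then guarantees both perfect reconstruction (the bands sum to the input)
  and an exact energy partition (Parseval), which the tests assert.
  Periodization was chosen over symmetric padding precisely to keep the
  transform orthogonal.
* **Texture aggregation** — GLCM and GLRLM matrices are built per direction
  over the 13 unique 3D offsets and the derived features averaged; GLSZM
  zones and GLDM dependences use 26-connectivity; the GLDM dependence count
  includes the voxel itself (values 1–27). NGTDM neighborhood averages use
  in-mask neighbors only; a texture-free region takes coarseness 1e6 and 0
  for the remaining features. Degenerate matrices resolve to documented
  limits rather than NaN; any non-finite feature raises.
* **Meshing** — shape features mesh the mask by marching cubes followed by
  10 Taubin smoothing passes. The raw 0.5-level mesh of a binary mask
  overestimates curved surface areas by ~8% (staircase bevels), which would
  bias sphericity down to ~0.92 for a digital ball; Taubin smoothing
  removes the staircase while preserving volumes to well under 1%.
* **Locality** — extraction crops to the mask bounding box plus a 6-voxel
  margin, which makes features exactly translation-invariant (asserted in
  tests) and keeps the wavelet transform local to the tumor.

## Univariate screening

Each feature is tested with a two-sided Wilcoxon–Mann–Whitney test (exact
null distribution for combined n ≤ 20 without ties, mid-rank/tie-corrected
normal approximation otherwise) and Benjamini–Hochberg corrected at
α = 0.05 within each feature space separately, mirroring per-group
reporting; a pooled option exists. Constant features report p = 1 with a
degeneracy flag.

## Feature selection and classification

`pca_dim` standardizes the feature table and returns the number of
principal components capturing 90% of its variance — the guide for how many
features to carry (the classification default is k = 11).

MRMR uses the MID (difference) criterion: the first feature maximizes
mutual information with the class label; each next feature maximizes
relevance minus mean redundancy against the already-selected set. MI is
estimated on equal-frequency 3-bin discretized features with
order-statistic edges, making the ranking invariant to monotone transforms;
ties break toward the earlier column for reproducibility. MIQ is available
but not default.

The harness draws 50 stratified Monte Carlo partitions into 5 validation
folds, every fold holding at least two subjects of each class. Within each
fold, MRMR ranking and feature standardization are fit on the training
subjects only, followed by an L2-regularized logistic model (C = 1;
unregularized fits diverge on separable ~20-subject training splits).
Validation predictions are pooled within each repeat, giving 50 AUC
samples; accuracy, precision and recall are evaluated at the threshold
where precision equals recall (sweep over candidate cut-points with linear
interpolation; midpoint of the crossing interval when the curves coincide;
fallback 0.5, flagged). Reported dispersions are over the 50 repeats.
Feature spaces are compared pairwise by two-sided Wilcoxon signed-rank
tests on the paired per-repeat AUC vectors (exact sign-flip distribution up
to 25 non-zero pairs, handled with mid-ranks; zeros dropped). The k-sweep
reuses one set of fold assignments across k for comparability.

## Synthetic cohort generator

The generator emulates a two-class nanoparticle contrast study: an
ellipsoidal soft-tissue tumor retains an iodinated agent inside a uniform
PE/CS background, the ground-truth material maps are pushed through the
sensitivity model (plus a separate broad-spectrum EID row), and independent
Gaussian noise is added per bin. Default grid 48³–64³ at 0.125 mm isotropic
voxels; default cohort 13 lymphocyte-present vs 12 lymphocyte-deficient
subjects.

Subject-level variability, all class-independent unless noted:

* mean intratumoral iodine: 2.5 mg/mL (negative class) vs 4.5 mg/mL
  (positive class, the leakier-vasculature effect), between-subject sd 0.6;
* iodine texture: a Gaussian random field smoothed to a per-subject
  correlation length and amplitude, clipped at zero; class means differ
  mildly (2.0 vox/0.95 mg/mL vs 1.8 vox/0.85 mg/mL) with per-subject
  jitter, so texture statistics are a noisy class cue rather than a clean
  read-out;
* a rim-enhancement factor (sd 0.6) scaling a 1-voxel peripheral shell —
  nanoparticle uptake is often rim-dominant — so tumor-boundary contrast is
  not a clean surrogate for interior concentration;
* background PE/CS levels varying between subjects (sd 0.9/0.25),
  confounding any single channel's mean intensity;
* tumor semi-axes jittered per subject.

Channel noise: sd 15 per PCD bin and 3× that for the EID channel, whose
iodine sensitivity (5 per mg/mL vs 32 in the K-edge bin) reflects the much
weaker iodine contrast of an energy-integrated spectrum. These constants
deliberately exaggerate the PCD-vs-EID iodine contrast-to-noise gap
relative to a literal 50 kVp system: at 25 subjects the qualitative
ordering (multichannel K-edge data outperforming the conventional channel)
must be statistically decidable per run, and the conventional channel in
studies of this design performs near chance anyway. The structural point
the defaults encode is that between-subject background and rim variability
leave a single energy-integrated channel without an identifiable iodine
concentration estimate, while the four-bin spectral data (and the material
maps derived from them) retain one.

What the generator does **not** emulate: projection-domain physics and
reconstruction artifacts, beam hardening, partial-volume effects at tumor
boundaries, spatially varying backgrounds/anatomy, Poisson counting noise
(additive Gaussian is used; reconstruction is out of scope), or
longitudinal kinetics. Passing tests therefore demonstrate correctness of
the analysis pipeline and the direction of the modelled effects, not
real-data effect sizes: the published-style accuracy of a real cohort
cannot be reproduced from synthetic data, and none is claimed.

## Segmentation

Tumors are segmented on the lowest-energy PCD bin by seed-based region
growing: the grown region is the connected component (26-connectivity by
default) of voxels within an absolute tolerance band around the mean of the
seed's 3×3×3 neighborhood. The pipeline wrapper smooths the image (Gaussian
σ = 1 voxel) first, auto-selects the tolerance as a fraction of seed-to-
background contrast with shrink-on-leak retries, and post-processes the
mask by morphological closing, hole filling and Gaussian surface smoothing
— the automated analogue of the interactive verification step of a
semi-automated workflow. Without that cleanup, the band-truncated intensity
distribution and the noise-roughened boundary of the raw grown mask leak
the subject's contrast level into intensity and shape features. The same
mask is applied to all co-registered channels of a subject; externally
supplied masks are accepted. On the default cohort the masks reach Dice
≈ 0.88 against ground truth.

## Problem sizes and determinism

Default analyses run on 48³ grids with ~2,500-voxel tumors, 25 subjects,
and 50×5 cross-validation — sizes chosen so a full run completes in about a
minute on one core while keeping every statistical check well-powered. All
randomness flows from a single integer seed through deterministic
sub-seeds; reruns are byte-identical, which the test suite asserts on the
persisted CSV/JSON outputs.

## Known limitations

* The texture feature definitions follow the common standardized
  formulations, but individual toolkits differ in degenerate-case
  conventions (e.g. NGTDM coarseness caps, GLDM dependence indexing); the
  conventions here are pinned above and enforced by enumeration oracles
  rather than cross-toolkit comparison.
* CV AUC estimates on 25-subject cohorts are highly dispersed; single-run
  chance levels can fall anywhere in roughly 0.3–0.7 under label
  permutation (training-fold selection anti-correlates with the held-out
  complement of a fixed cohort). Chance-level claims are therefore always
  averaged over permutations.
* The semi-automated segmentation assumes one dominant enhancing lesion
  near the seed; multi-focal or poorly enhancing tumors need external
  masks.
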