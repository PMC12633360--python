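# Methods

This note documents the models, conventions and design choices behind
`twdfc`, in the spirit of a methods appendix: what each stage computes, the
parameters that matter and their defaults, numerical edge-case behaviour,
what the synthetic phantom emulates, and known limitations.

## 1. Coordinates and tractogram I/O

Volumes live on a `VolumeGrid`: integer dimensions plus a 4×4 affine mapping
0-based voxel indices to world millimetres (the NIfTI convention).  TCK
streamline vertices are taken as scanner/world mm — the format's convention —
and are assumed to share the NIfTI world frame; no RAS/LPS re-orientation is
attempted, and a left-handed grid affine only triggers a warning.

A world point is assigned to its **nearest voxel** by rounding each
continuous index with *half-away-from-zero* ties, so a point exactly on a
voxel-face boundary deterministically belongs to the higher-index voxel.
Points mapping outside `[0, dims)` are flagged out-of-field-of-view, never
clamped.

The TCK reader validates the magic line, the `END`-terminated ASCII header,
the `file: . <offset>` field, the NaN-triplet separators and the
Inf-triplet terminator, and cross-checks the header `count` against the
body; mismatches and truncation raise integrity errors rather than being
silently repaired.  The writer emits float32 little-endian, and
read∘write is the identity on vertices at float32 precision.  Weight files
(one non-negative float per streamline, e.g. SIFT2 output) carry no header,
so their length is always validated against the tractogram.

## 2. BOLD pre-processing

Two operators are provided, applied in this order by the pipeline drivers:

* **Gaussian smoothing**, parameterised by FWHM in mm
  (σ = FWHM / (2√(2 ln 2)), converted to voxels per axis; default 6 mm).
  With a mask, smoothing is mask-renormalised — data·mask and mask are
  convolved separately and divided — so signal does not bleed across the
  mask border and border voxels are not dimmed.  Both convolutions use
  reflect padding, which keeps kernel mass inside the volume; a full mask
  therefore preserves the volume mean to machine precision.
* **Temporal bandpass** retaining `[low, high]` Hz (default 0.01–0.1 Hz).
  The default mode is an FFT hard-window filter: rFFT bins outside the band
  are zeroed (DC is removed whenever `low > 0`), giving exact band edges and
  zero phase.  An order-2 Butterworth forward–backward mode is available;
  the filter family is a documented interpretation, as resting-state
  pipelines differ on it.  Bands outside the Nyquist limit (1/(2·TR)) are
  rejected.

## 3. Seed-restricted tractogram

Streamline endpoints are the first and last polyline vertices.  Each
streamline is classified by its endpoints — none/one/both in the seed, or
out-of-FOV — and the default extraction policy keeps **only one-in-seed**
streamlines: the retained connections run between the seed and a distal
region, which is what the downstream endpoint-correlation model assumes.
Intra-seed (both-in-seed) streamlines can be included with
`policy="both"` for sensitivity analyses; how such connections should be
treated is genuinely open, and excluding them is this package's default
interpretation.  Out-of-FOV streamlines are dropped with a logged count
(no BOLD exists for them).  Endpoint tables orient each row so
`seed_voxel` is the in-seed endpoint regardless of stored vertex order,
making extraction invariant to streamline reversal.  Endpoint-density maps
count (or weight-sum) termination points per voxel; totals are conserved
exactly.

## 4. TW-dFC

* **Window**: width W timepoints (default 85; 61.2 s at TR 0.72 s) and
  stride in timepoints.  The stride is not dictated by the window width;
  the default of 1 volume gives the densest sampling, N = T − W + 1 frames,
  and frame k covers samples starting at k·stride (0-based).
* **Taper**: Hamming, w_n = 0.54 − 0.46·cos(2πn/(W−1)).  The taper enters
  the correlation itself — weighted means, variances and covariance — not
  merely frame selection; a rectangular mode reduces to the plain Pearson
  coefficient and serves as the oracle path in tests.
* **Degenerate windows**: if either endpoint series has weighted variance
  below 1e-12 inside a window, that window's value is 0 and a counter in the
  map provenance increments.  Finite values are clipped to [−1, 1].
* **Endpoint sampling** is nearest-voxel (no trilinear interpolation),
  matching the voxel resolution of the endpoint table.
* **Rasterisation**: each streamline is resampled by arc length at
  `step_mm` (default half the smallest voxel size), samples are mapped to
  voxels, out-of-FOV samples dropped, duplicates removed; both endpoint
  voxels are always included.  Sampling-based rasterisation can, for a
  segment grazing a voxel corner, miss that voxel at coarse steps — an
  inherent property of the approach; halving the step is a practical check
  of resolution sufficiency.
* **Projection**: value(v, w) = Σ_{s∋v} ω_s FC_s(w) / Σ_{s∋v} ω_s with
  ω_s = 1 by default.  Per-streamline weights (SIFT2) do **not** enter the
  average unless requested — the defining average is over tracks — and each
  streamline contributes once per voxel per window no matter how many
  samples fell inside.  Untraversed voxels are NaN.  Per-voxel sums are
  accumulated in sorted-value order, so the map is bit-identical under any
  permutation of the input streamlines.

In the limit of a single latent coupling state, the per-voxel mean over
windows converges to the static track-weighted FC (full-length endpoint
Pearson r projected the same way); at desk scale the residual is
window-sampling error, so the convergence is asserted on the mean absolute
per-voxel deviation rather than a hard per-voxel bound.

## 5. Parcellation

* **Concatenation**: subjects' 4D maps are stacked frame-wise over an
  analysis mask (voxels finite in ≥ 1 frame of ≥ 1 subject).  Each subject
  block is demeaned per voxel (nan-aware) and remaining NaNs are imputed as
  0, so every subject block has exactly zero column means.
* **Decomposition**: PCA followed by fixed-point ICA (FastICA, logcosh,
  spatial orientation: voxels are samples).  In auto mode the component
  count is the smallest n whose cumulative eigenvalue fraction reaches the
  variance threshold (default 0.98).  This PCA + FastICA pair, with
  per-component z-scoring of the spatial maps, is this package's
  interpretation of a MELODIC-style decomposition; MELODIC's residual-noise
  variance normalisation is out of scope.  All stochastic steps take
  explicit seeds; non-convergence is retried with a reseeded rotation
  before raising.
* **Thresholding**: the default mode fits a two-class Gaussian mixture to
  each component's z values by EM, initialised as a robust null class
  (median centre, MAD scale, weight 0.9) plus a broad signal class (3×
  scale, weight 0.1), and keeps voxels whose posterior probability of the
  signal class exceeds 0.5.  The signal class is the one with the larger
  second moment about the null centre, so both heavy tails and mean-shifted
  populations count as signal; on a pure-noise map the posterior never
  reaches 0.5 and essentially nothing is kept.  A plain `|z| > 1.645` mode
  is provided both as a fallback for numerically degenerate fits and as the
  alternative reading of a "p > 0.5" threshold; which of the two the
  original toolchain used is ambiguous, and both are first-class options.
  Feature vectors use the thresholded (sparsified) z-scores by default; raw
  z features are one flag away.
* **k-means**: k-means++ with n_init = 10 restarts, best inertia kept;
  labels are renumbered 1..k by descending cluster size with a
  lexicographic-centroid tie-break; k is a required input (no automatic
  model selection), with 4, 6 and 8 the documented working points.
* **Bilateral merge**: clusters are split by centroid side of the midline
  plane (default x = 0); left clusters are matched to mirrored right
  centroids by optimal one-to-one assignment, and merged ids are lettered
  A, B, C… from anterior to posterior (descending centroid y).  Unequal
  per-side counts raise unless an explicit override mapping is supplied;
  the override also reproduces a published pairing verbatim.

## 6. Group FC statistics

Cluster time series are unweighted voxel means.  Seed-based FC is the
voxel-wise Pearson correlation with the cluster series; Fisher z uses |r|
clipped to 1 − 1e-7.  Zero-variance voxels get r = 0 and a flag.

Contrasts are **paired**, one-tailed t-tests on per-subject Fisher-z
difference maps (the same subjects provide both maps of every contrast);
"one-way t-test" wording in the literature is looser, and an unpaired
analysis can be composed from the same pieces if desired.  Per voxel,
t = mean(d)/(sd(d)/√n) with df = n − 1 and p = 1 − CDF_t(t).  Voxels with
sd(d) = 0 get p = 0.5.  Each of the k·(k−1) directional contrasts carries
its own BH-FDR family over in-mask voxels; corrected q-values are converted
to z = Φ⁻¹(1 − q), capped at |z| = 8.2 to keep maps finite, and thresholded
at z ≥ 1.645 (one-tailed p = 0.05).

## 7. The synthetic phantom

The phantom provides, at desk scale, data with exactly the statistical
structure the analysis assumes:

* **Geometry** (deterministic): a 32×32×24 grid at 2 mm with the midline
  x = 0 between the two centre columns; two mirrored ellipsoidal seed
  bodies (long axis anterior–posterior) split into 3 contiguous slabs per
  side; six 3³-voxel target blocks placed laterally at the y-level of their
  wired subregion.
* **Streamlines**: 200 per subregion, drawn to targets with a connectivity
  matrix (default 0.8 on the mirror-wired primary target); each is a
  quadratic Bézier from a seed-voxel centre to a target-voxel centre with a
  6 mm-jittered midpoint, resampled at 1 mm.  Start voxels cycle through a
  shuffled list of the subregion's voxels so every seed voxel is traversed;
  every streamline has exactly one endpoint in the seed by construction.
* **BOLD**: region-level signals drawn from a multivariate normal whose
  correlation matrix depends on a latent Markov state (geometric dwell,
  mean 100 volumes), temporally smoothed with AR(1) φ = 0.3 (rescaled to
  unit marginal variance) as a cheap stand-in for BOLD autocorrelation, and
  copied to each region's voxels with iid N(0, 1) voxel noise on top.
  T = 300 volumes at TR = 0.72 s by default — a desk-scale stand-in for a
  1200-volume scan; the config scales up.  Region-level signal generation
  keeps the coupling structure exactly controllable, which is the property
  the analysis consumes.
* **Coupling defaults**: each bilateral subregion has a distinct temporal
  coupling profile to its primary target — state-1-high (0.8/0.1),
  state-2-high (0.1/0.8), and static (0.45/0.45) — in a block-2×2 structure
  that is positive definite by construction.  These three profiles are what
  make the subregions separable by a dynamic-FC analysis and *not* by a
  static one.
* **Cohorts**: subject RNG streams are spawned from a master seed; geometry
  is shared, noise/states/streamline draws are per subject.  Two special
  cohorts support the statistical checks: a *null* cohort in which all
  region pairs are equicorrelated (every cluster sees the same FC
  everywhere, so all contrasts are null), and an *effect* cohort adding a
  coupling increase of 0.35 between one bilateral subregion and its
  targets — the value that realises a subject-level effect size of about
  d = 1 on the Fisher-z difference maps after voxel-noise attenuation.

For phantom group studies, smoothing is renormalised over the tissue mask
(seed + targets) and the FC family is the tissue voxels outside the seed:
the phantom's remaining voxels are empty space a real brain mask would
exclude, and a cluster's correlation with its own voxels is trivially
positive rather than a contrast of interest.

**What the phantom does not emulate**: haemodynamic response functions,
head motion, physiological noise, spatial noise correlations, partial
voluming, tractography errors (false-positive/negative streamlines), and
realistic anatomy.  Passing tests therefore demonstrate the correctness and
statistical behaviour of the pipeline under its own model assumptions, not
robustness to the artefacts of real acquisitions.

## 8. Numerical conventions

* Degenerate-variance guard: 1e-12 (windows and FC voxels).
* Fisher-z cap: |r| ≤ 1 − 1e-7; q→z cap: |z| ≤ 8.2.
* TCK writing settles the self-referential header offset iteratively.
* All floating accumulations that must be order-independent (TW-dFC
  projection) sum in sorted-value order.
* Every stochastic step (ICA, k-means, phantom generation) takes an
  explicit seed and is bit-reproducible given it.

## 9. Problem sizes

Default test and acceptance runs use 32×32×24 grids, T = 300,
1200 streamlines/subject, cohorts of 5 (parcellation) and 20 (group
statistics) — sizes chosen so the full suite exercises every stage end to
end in minutes on one CPU while keeping every statistical margin
(ARI ≥ 0.8, ≥ 98 % variance, 95 % detection) comfortably attainable by the
planted structure rather than by chance.
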