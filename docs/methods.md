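# Methods

`coroclust` characterizes coronary artery lesions on contrast-enhanced CT
angiography without supervision.  It consumes a CT volume (Hounsfield
units) and a co-registered binary vessel mask (the product of an external
lumen segmentation) and produces typed plaque calls — calcified, soft, or
mixed — with a per-lesion geometric severity.  This note records the model,
the parameters that matter, what the synthetic phantom does and does not
emulate, and the numerical choices made where the design was open.

## Pipeline

1. **Skeletonization.**  An anisotropy-aware Euclidean distance transform
   (EDT; millimetres, voxel spacing as axis weights) locates the foreground
   voxel deepest inside the vessel (the *central point*; ties broken by
   lowest linear index).  Geodesic distances from this point are propagated
   through the mask with 26-connectivity and mm edge lengths.  Endpoints
   are geodesic local maxima whose foreground-neighbour directions fit in a
   closed half-space (tested against the 26 discrete directions) — the
   "vector-angle" test that distinguishes a vessel tip from an interior
   ridge point.  From each endpoint a path descends the geodesic field,
   preferring at each step the admissible voxel with the largest EDT so the
   path hugs the medial ridge; ties go to the lowest linear index for
   determinism.  Overlapping paths merge; merge voxels become junction
   (saddle) nodes.
   Two cleanups handle the blunt ends that voxelized tubes have and real
   arteries do not:
   * *tip trimming* — terminal points are removed while the EDT climbs
     inward faster than 0.5 mm per mm of path (the radial "climb" from an
     end-cap toward the axis; a genuinely tapering tip has a nearly flat
     EDT profile and is untouched);
   * *spur pruning* — a leaf branch is removed when the part of it
     protruding beyond the parent vessel wall (length minus the EDT at its
     attachment node) is shorter than `prune_length_mm` (default 3 mm,
     roughly one vessel diameter).  Measuring from the wall rather than the
     axis keeps the threshold meaningful across calibers and removes the
     end-cap spokes of the exact medial axis.
   Per-point radii are EDT values median-smoothed along arc length
   (window 3); per-point orthonormal frames use central-difference tangents
   with a fixed reference axis (+z, falling back to +x near parallel).
   The proximal root is the endpoint with the largest local radius
   (arteries are widest proximally); arc length is graph distance from it.

2. **Feature extraction.**  For every mask voxel, a 3×3×3 window from the
   *full* CT volume (nearest-value padding at the volume boundary; windows
   deliberately unmasked, so wall voxels see the surrounding tissue):
   mean, median, quartiles, SD (n−1), skewness and excess kurtosis
   (population moments; 0 for constant windows), central-difference
   gradients in HU/mm; and nine Haralick features from one symmetrized,
   normalized GLCM pooling the 13 unique distance-1 directions.  Pooling
   directions keeps the texture descriptors rotation-robust at this window
   scale; entropies are in bits.  HU are first quantized into 32 equal
   125-HU levels over [−1000, 3000] (clamped outside) so the co-occurrence
   matrices are insensitive to minor intensity fluctuations.  Each row also
   carries the nearest skeleton point (ownership by smallest distance to a
   point's perpendicular plane among points within 10 mm, ties to the
   nearer point), its arc length, local radius, and `radius_ratio` = local
   radius / expected healthy radius at that arc length.  `radius_ratio` is
   an explicit width feature added because the width-graded cluster
   semantics are not guaranteed by the intensity/texture features alone.

3. **Expected radius profile.**  The healthy caliber at each arc length is
   estimated by a moving 90th-percentile envelope (5 mm window) of the
   observed radii followed by isotonic, monotone-nonincreasing regression
   proximal→distal.  Fitting the upper envelope keeps focal narrowings
   from dragging the baseline down; the 5 mm window bridges focal
   stenoses while following gradual tapering.  Per-point deviation is
   `1 − observed/expected`.

4. **PCA + clustering.**  Features are z-scored (constant columns dropped)
   and projected onto the fewest principal components reaching 95%
   cumulative explained variance.  Two clusterers: plain k-means
   (k-means++, `n_init=10`, seeded) and the hybrid scheme — k-means into
   `k_pre = 50` preliminary clusters, then Ward agglomeration of the
   preliminary *centroids* with member-count weights (merge cost
   `nA·nB/(nA+nB)·‖cA−cB‖²`) down to `k_final`.  The two-stage design
   keeps Ward's quadratic cost off the raw voxels, which is its point on
   ~2·10⁵-voxel arteries; size weighting makes Ward on centroids
   equivalent to Ward on the points when `k_pre` equals the row count.

5. **Elbow selection.**  For k in [2, 10] the within-cluster sum of
   squares WCSS(k) is recorded; the selected k maximizes the discrete
   second difference of **log** WCSS (ties → smaller k).  The log scale is
   a deliberate choice: the raw second difference of a convex decreasing
   curve is always maximized at the first interior k, so it degenerates to
   "always pick k_min+1" — on planted 3-, 5- and 7-blob data it returns 3
   in every case, while the relative-curvature rule recovers the true
   count.  The pipeline default is nevertheless a *fixed* k = 5 (the
   cluster count at which coronary voxel populations resolve into four
   width grades plus calcium); `k="auto"` enables the elbow.  See
   "Limitations" for why the elbow at desk scale prefers the coarser
   3-cluster structure.

6. **Semantic ordering.**  The cluster with the highest mean raw HU is
   labelled `calcified` if that mean is ≥ 500 HU (above contrast-enhanced
   lumen at ~350 HU, below dense calcium; exact ties → lower label id);
   remaining clusters are ranked by descending mean local radius,
   `width_rank_1` (widest; green in the field's rendering convention) to
   the narrowest (red).

7. **Lesion calling.**  Calcified calls are 26-connected components of the
   calcified cluster with centerline extent ≥ 2 mm.  Soft calls are
   contiguous centerline runs (≥ 2 mm) whose cross-section majority
   cluster lies in the two narrowest width ranks, whose radius deviation
   is ≥ 0.25, and which are not majority-calcified; the run's narrow-rank
   voxels form the lesion.  A calcified and a soft candidate whose
   intervals lie within 2 mm merge into one `mixed` call.  Severity is the
   maximum deviation over the call's interval; calls with severity ≥ 0.50
   are flagged as predicted hemodynamically significant.  That geometric
   significance rule is an explicit operationalization — the clinical
   reference is invasive FFR (≤ 0.80, threshold inclusive), which imaging
   alone cannot measure.

8. **Evaluation.**  Plaque-level, type-strict, one-to-one greedy matching
   by centerline-interval overlap (≥ 1 mm; ties → more proximal).
   Plaque-level true negatives have no natural unit, so the lesion-free
   centerline is tiled into disjoint 10 mm segments and tiles containing
   no call count as TNs; the tile length is a parameter and specificity
   should be read relative to it.  Hausdorff distances are symmetric
   maxima of directed nearest-point distances between voxel-center sets in
   mm.  Algorithm comparisons use a paired two-sided t test on per-case F1
   scores with a 95% CI of the mean difference; zero-variance differences
   report t = 0 / p = 1 when the mean difference is zero, otherwise an
   infinite-t surrogate flagged degenerate.

## The phantom

The synthetic generator builds a single coronary branch crossing the
field of view (default 96×96×160 voxels at 0.43×0.43×0.5 mm): a cubic
spline centerline, a terraced monotone taper (default three plateaus from
2.0 to 1.0 mm radius, smoothstep ramps — the discrete caliber drops at
branch ostia), and cosine-tapered stenosis notches per lesion (≥ 30%
diameter reduction, the clinical inclusion threshold).  Tissue HU:
lumen 350 ± 40, background 40 ± 20, calcified 900 ± 150, soft plaque
100 ± 30, plus 10 HU global noise.  The calcified default sits at the
dense end of coronary calcium because partial-volume mixing inside 3×3×3
windows pulls calcified-window means down by ~300 HU; at lower plaque
densities the calcified cluster no longer isolates at k = 5.

The *mask* emulates a lumen segmentation: bright calcium is captured (the
calcified shell joins the mask), low-attenuation soft plaque is not — so
the segmented vessel narrows at soft lesions, which is exactly the signal
the soft-calling route uses.  Soft-plaque truth voxels are trimmed to the
annulus layer within one voxel of the mask.

Per-lesion FFR is a surrogate, `clamp(1 − 0.45·s², 0.30, 1.00) +
N(0, 0.02)` for diameter-stenosis fraction `s`, calibrated so the 0.80
significance threshold falls between 65% and 70% stenosis.  It exists to
exercise the concordance bookkeeping, not to model hemodynamics.

What the phantom does **not** emulate: bifurcating trees, motion and
beam-hardening artifacts, contrast-agent halos around plaques (the
configurable extent inflation real segmentations show), eccentric and
positively remodelled lesions, and cohort-scale heterogeneity.  Passing
tests on phantoms therefore demonstrate the machinery's correctness and
the calling logic's behaviour under idealized contrast, not clinical
performance; both clustering algorithms reach ceiling (100% F1) on the
default two-lesion battery, so their paired comparison on phantoms is
degenerate by construction.

## Numerical choices and degenerate inputs

* All randomness flows from one seed; a blake2-based hash fans it out to
  per-stage seeds below 2³¹, so stage-level reruns are reproducible.
* Ties: central point and steepest-descent by lowest linear voxel index;
  calcified-role HU ties by lower label id; elbow ties by smaller k;
  truth-matching ties by the more proximal lesion.
* Degenerate inputs: empty masks are hard errors; a single-voxel mask
  yields a single-point skeleton; an all-equidistant geodesic field yields
  a single-point skeleton; constant windows have zero skewness/kurtosis;
  a zero-variance GLCM marginal gives correlation 0; 0/0 rates are 0 with
  a degenerate flag.
* Desk-scale problem sizes: ~5,000–6,000 mask voxels per phantom,
  ~140 skeleton points, 10-case batteries — chosen so a full battery of
  pipelines runs in about a minute on one CPU.

## Limitations

* The elbow at desk scale selects k = 3, not 5, on the diseased phantoms
  regardless of the elbow rule: 3×3×3 windows straddling the vessel wall
  mix lumen and background in continuously varying proportions, so the
  feature cloud is a continuum bridged between tissue classes rather than
  five compact blobs, and the WCSS curve has exactly one genuine kink
  (relative drops ≈ 33%, 12%, then a flat ~6% tail).  This is a property
  of per-voxel window features on thin tubes, not of the selector; the
  five-cluster partition itself is well formed (k-means at k = 5 isolates
  calcium and grades the widths, which the lesion calling relies on),
  hence the fixed k = 5 default.
* Calcified severity is underestimated: the calcified shell is part of
  the mask, so the distance-map radius does not narrow at calcified
  lesions; severity (and predicted significance) is informative mainly for
  soft and mixed disease.
* Tangents at voxel-snapped skeleton points jitter by tens of degrees
  point-to-point; downstream use is limited to plane-ownership and
  ordering, which tolerate this.
* The geometric significance threshold (50% diameter) and the FFR
  surrogate's crossing (~67%) intentionally differ; concordance numbers on
  phantoms inherit that gap.
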