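# Methods

## Streamline representation and distance

Streamlines are polylines in world millimetres.  Every comparison operates
on resampled curves: 20 points placed at arc-length positions `i·L/19` by
piecewise-linear interpolation (no spline smoothing — the resampling
contract is equispacing, and linear interpolation never lengthens the
polyline).  The minimum average direct-flip (MDF) distance is the mean
point-to-point Euclidean distance, minimized over reversing one curve.  MDF
is symmetric and non-negative and vanishes for a curve against itself or its
reversal, but is not a metric (the flip minimization can break the triangle
inequality), so no triangle-type property is relied on anywhere.

All-pairs MDF matrices are assembled by accumulating one point-wise distance
matrix per sample index (direct and flipped), keeping peak memory at a few
`m×m` float matrices and making the computation a handful of BLAS-friendly
passes.

## Template clustering

Outlier pruning precedes spectral clustering: streamline *i* is discarded
when the mean of its distances to all others (diagonal excluded) exceeds the
cohort mean of those row means by two sample standard deviations (n−1
denominator).  The row-mean statistic is one reading of "distance greater
than two standard deviations from the average whole-brain streamline
distance"; it is the default and the number of SDs is configurable.

*Spectral route.*  "Kernel width" is read as σ in `w = exp(−d²/(2σ²))`; the
kernel formula is config-exposed since conventions differ.  The symmetric
normalized Laplacian `L_sym = I − D^{−1/2} W D^{−1/2}` is eigendecomposed,
the embedding on the k bottom eigenvectors is row-normalized
(Ng–Jordan–Weiss), and seeded k-means with 10 restarts partitions the rows.
Cluster ids are canonicalized by descending cluster size with ties to the
lowest member index, so labelings are comparable across permuted reruns.

*QuickBundles route.*  A single pass in input order; each streamline joins
the MDF-nearest existing centroid when that distance is below the threshold
(ties to the lowest cluster id), with the incoming streamline flipped first
when its flipped orientation is closer; the centroid is the exact running
mean of aligned member points (a sum and a count — no decaying
approximation).  At the cluster cap, streamlines join the nearest centroid
unconditionally.  The pass is deterministic in input order; order
independence is only guaranteed (and asserted in tests) when inter-bundle
separation far exceeds the threshold.

Defaults target whole-brain template tractography: 20 samples; k = 800
with 8 mm kernel/threshold; U-fiber variant k = 500 with 6 mm; a
20,000-streamline labeled subsample.  All are overridable in `RunConfig`.

## U-fiber extraction

The curvature criterion is `D < L/π`.  Length constraints of this kind are
sometimes stated on the endpoint chord D and sometimes on the streamline
length itself; the U-fiber literature bounds arc length, so the default
bounds L ∈ [20, 80] mm and `bound_on="endpoint"` switches the bounds to D
for sensitivity analyses.  The midline is the plane x = 0 of the template
world space (configurable); points exactly on the plane belong to neither
hemisphere, and a streamline crosses only when it has strictly positive and
strictly negative x.

Endpoint-to-parcel assignment orientation-aligns a tract's members first so
"end A"/"end B" are consistent, finds each endpoint's nearest non-background
parcel voxel centre within 4 mm (KD-tree over labeled voxel centres), and
takes the per-end majority over members, ties to the lowest label id.

## Label propagation

Every target streamline receives the label of the MDF-nearest template
streamline, ties to the lowest template index; no rejection distance by
default (every streamline gets a label), with an optional cutoff that marks
distant streamlines −1.  Template subsampling is uniform without replacement
(seeded); a stratified variant (proportional per cluster, minimum one) is
available when rare clusters must survive aggressive subsampling.

## Reliability metrics

*Centroids.*  A tract centroid is the per-sample-point mean over members
flipped to the orientation of the first member; the cohort-average centroid
averages subject centroids after the same alignment.  Subject-to-average
distances use MDF, so they are flip-invariant.

*Density maps and wDSC.*  Each streamline is re-interpolated so consecutive
points are closer than half the smallest voxel edge (configurable), mapped
to voxels by nearest-integer rounding of continuous voxel coordinates
(world = affine·(i,j,k,1), 0-based), and counted once per voxel touched.
Dense upsampling converges to exact segment traversal and avoids a voxel
walk.  wDSC of two empty maps is defined as 0 and logged.  "Average wDSC" is
the mean over unordered subject pairs; subject-vs-template is available.

*Along-tract ICC.*  Profiles are per-sample-index means of trilinearly
interpolated scalar values over aligned members (out-of-grid samples are
missing; columns with missing values are dropped listwise with a logged
count).  ICC(A,1) — two-way random effects, absolute agreement, single
measurement — uses subjects as rows/targets and the samples along the tract
as columns/raters:

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with the F-based 95% CI of McGraw & Wong.  The average-measure form
ICC(A,k) is config-exposed.  Degenerate inputs — zero total variance, or
zero subject effect *and* zero residual (subjects agree perfectly while the
profile still varies along the tract) — return ICC = 1 with a degenerate
flag rather than a 0/0 artifact.  Note the estimator carries a small
finite-sample downward bias (a ratio of mean squares), visible as ≈ −0.02
at 15 subjects and true intraclass correlation 0.8.

*Counts and correlations.*  CV uses the sample SD; a tract absent everywhere
reports CV as missing and is tallied in the missing-tract report, and a
tract absent in one subject is excluded from that subject's centroid,
overlap and profile computations.  Inter-metric Spearman correlations
(average-rank ties, two-sided p) are computed across tracts with streamline
counts entered log-transformed, and Benjamini–Hochberg adjustment runs over
all pairs tested; pairs with a constant column report missing rho.

The unpaired two-sample comparison between clustering methods defaults to
the pooled-variance t-test with a Welch option; both are reported, neither
is asserted, since the variant used originally is unspecified.

## Synthetic cohorts

The generator emulates the features the pipeline is sensitive to: distinct
long-range and U-shaped bundles in both hemispheres, within-bundle
dispersion (rigid per-streamline Gaussian offset plus small per-point
jitter), half the streamlines stored reversed, between-subject rigid
centroid jitter, session-varying streamline counts (multiplicative uniform
noise), and a smooth scalar volume (constant, gradient, or per-bundle
plateau) standing in for an FA map.  Within-bundle dispersion is drawn once
per bundle and shared across subjects, so a zero-jitter cohort is exactly
identical across subjects and the degenerate expectations (wDSC = 1,
distance = 0, CV = 0) hold to machine precision.  Randomness derives from
one root seed through `SeedSequence` spawn keys per bundle and subject, so
adding a bundle never perturbs existing ones.

It does **not** emulate curving anatomy with crossing fibers, partial-volume
scalar structure, registration error, or tractography false positives.
Passing tests therefore demonstrate algorithmic correctness and
self-consistency, not performance on real brains: planted-truth recovery
(ARI = 1) is expected here precisely because bundle separation is far above
dispersion, a regime real superficial white matter does not always offer.

The default demo cohort mirrors a multi-subject acquisition at desk scale:
15 subjects,
12 bundles (8 long-range, 4 U-shaped), 100–300 streamlines per bundle, 1 mm
subject jitter, 20% count jitter, a 2 mm isotropic 80×96×80 grid.  Template
builds in the demo use k = 12 and a 1,500-streamline subsample — the
full-scale defaults (k = 800, 20,000) remain the `RunConfig` defaults for
real tractograms.

## Numerical choices and limitations

- Distances are world-mm throughout; voxel-space distances are never used.
- Resampling tolerances: endpoints preserved exactly; inter-point spacing
  equal to relative 1e−6.
- k-means ties and QuickBundles assignment ties break to the lowest id;
  argmin semantics make this deterministic.
- TCK/TRK I/O round-trips to 1e−4 mm (TRK stores float32).
- The spectral eigensolver is dense (`scipy.linalg.eigh` on the bottom-k
  subspace); templates beyond a few tens of thousands of streamlines would
  need a sparse/approximate solver, which is out of scope.
- QuickBundles results depend on input order when bundles overlap within the
  threshold; this is inherent to the greedy pass and deliberately preserved.
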