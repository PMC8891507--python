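# tractreli

Template-based tractography clustering and reliability assessment.

Diffusion-MRI tractography reconstructs white-matter pathways as
*streamlines* — polylines in scanner/world millimetre coordinates.  To study
the same tract across subjects or repeated sessions, a common approach is to
cluster a reference ("template") tractogram once and transfer its cluster
labels to every analysis tractogram by streamline similarity.  `tractreli`
implements that workflow end to end for researchers evaluating how reliably
tracts — including the highly variable superficial U-fibers — are recovered
across a cohort, and ships a synthetic multi-subject cohort generator with
planted ground truth so every stage can be validated without imaging data.

## Method

**Streamline distance.**  All comparisons use the minimum average
direct-flip (MDF) distance on streamlines resampled to *n* = 20 equispaced
points (endpoints included):

    d_direct(a, b) = (1/n) Σᵢ |aᵢ − bᵢ|
    d_flip(a, b)   = (1/n) Σᵢ |aᵢ − b_{n+1−i}|
    MDF(a, b)      = min(d_direct, d_flip)

so antiparallel reconstructions of one pathway compare as identical.

**Template clustering.**  Two routes over the MDF distance matrix (after a
2-SD row-mean outlier rule):

- *Spectral*: Gaussian affinity `w = exp(−d²/2σ²)` (σ = 8 mm whole-brain,
  6 mm for U-fibers), symmetric normalized Laplacian, row-normalized
  bottom-k eigenvector embedding, seeded k-means (k = 800 whole-brain,
  500 U-fibers).
- *QuickBundles*: one greedy pass assigning each streamline to the nearest
  running-mean centroid within a distance threshold (8 mm / 6 mm), opening
  new clusters up to a cap of k.

Labels propagate from a 20,000-streamline labeled subsample to each analysis
tractogram by maximum similarity (nearest template streamline in MDF).

**U-fibers.**  Short-range superficial streamlines are extracted by
`D < L/π` (D the endpoint chord, L the arc length), 20 mm ≤ L ≤ 80 mm, and
no midline crossing; tract endpoints map to cortical parcels by nearest
labeled voxel within 4 mm with per-end majority vote.

**Reliability metrics**, per tract across subjects/sessions:

- MDF distance of each subject's tract centroid from the cohort-average
  centroid;
- weighted Dice overlap of tract density maps,
  `wDSC(A,B) = (Σ_{v′}A_{v′} + Σ_{v′}B_{v′}) / (Σ_v A_v + Σ_v B_v)` with v′
  over voxels where both per-voxel streamline fractions are positive;
- along-tract scalar (FA-like) ICC(A,1) — two-way random-effects absolute
  agreement, subjects as targets and the samples along the tract as raters —
  with an F-based 95% CI;
- streamline-count coefficient of variation, CV = sd/mean × 100%;
- Spearman correlations among the metrics with Benjamini–Hochberg FDR
  (counts log-transformed).

## Worked example

```
python examples/04_reliability_metrics.py
```

prints

```
centroid distances to average: [1.0, 1.0]
wDSC({a,b},{b,c}) = 0.5
ICC(A,1) = 0.773  95% CI [0.637, 0.896]  (generating rho = 0.8)
CV of counts (5, 10, 15): 50.0 %
```

Two subject centroids offset ±1 mm from their average each sit exactly
1 mm from it; two single-streamline tracts sharing one of two voxels
overlap with wDSC = (1+1)/(2+2) = 0.5; profiles simulated with
subject-effect variance 0.04 and residual 0.01 (intraclass correlation 0.8)
yield an ICC estimate of 0.773 with the generating value inside the CI; and
counts (5, 10, 15) have sample SD 5 over mean 10, i.e. CV = 50%.

`examples/05_full_pipeline.py` runs the whole pipeline (both clustering
methods) on a 5-subject synthetic cohort of 12 planted bundles and prints
the per-tract reliability table; `examples/01–03` demonstrate the U-fiber
geometry, template clustering, and label propagation individually.  A thin
CLI wraps the same functions:

```
tractreli generate cohort/ --seed 0
tractreli run-all run.yaml --cohort-dir cohort/ --outdir out/
```

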