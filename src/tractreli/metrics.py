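"""Reliability metrics for template-labeled tracts.

Given corresponding tracts across subjects (or sessions), this module
computes the reliability suite:

* distance of each subject's tract centroid from the cohort-average centroid
  (MDF distance between centroid curves);
* voxel-wise spatial overlap via the weighted Dice similarity coefficient,

      wDSC(A, B) = (sum_{v'} A_{v'} + sum_{v'} B_{v'})
                   / (sum_v A_v + sum_v B_v),

  where A_v, B_v are the fractions of each tract's streamlines traversing
  voxel v and v' runs over voxels where both fractions are positive — dense
  tract cores dominate, stray periphery is down-weighted;
* along-tract scalar (e.g. FA) profiles and their across-subject agreement as
  the two-way random-effects absolute-agreement single-measure intraclass
  correlation ICC(A,1), with subjects as targets and the samples along the
  tract as raters;
* streamline-count coefficient of variation, CV = sd/mean * 100 %;
* Spearman rank correlations among the per-tract metrics with
  Benjamini-Hochberg false-discovery-rate adjustment (streamline counts enter
  log-transformed).

Endpoint connectivity of superficial tracts against an integer cortical
parcellation is resolved by nearest labeled voxel within a radius (4 mm
default), with per-end majority vote over streamlines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .clustering import align_to_reference

__all__ = [
    "TractDensityMap",
    "tract_centroid",
    "average_centroid",
    "centroid_distance",
    "density_map",
    "wdsc",
    "pairwise_wdsc_mean",
    "map_scalar_along",
    "tract_profile",
    "icc_absolute",
    "streamline_cv",
    "metric_correlations",
    "assign_endpoints_to_parcels",
]

logger = logging.getLogger(__name__)

PARCEL_RADIUS_MM = 4.0


# ---------------------------------------------------------------------------
# centroids


def tract_centroid(streamlines: np.ndarray) -> np.ndarray:
    """Per-point mean curve over orientation-aligned member streamlines."""
    A = np.asarray(streamlines, dtype=float)
    if A.ndim != 3 or A.shape[0] == 0:
        raise ValueError("tract has no streamlines")
    return align_to_reference(A, A[0]).mean(axis=0)


def average_centroid(centroids) -> np.ndarray:
    """Cohort-average centroid: per-point mean across subject centroids.

    Subject centroids are orientation-aligned to the first before averaging.
    """
    C = np.asarray(centroids, dtype=float)
    if C.ndim != 3 or C.shape[0] == 0:
        raise ValueError("need at least one centroid")
    return align_to_reference(C, C[0]).mean(axis=0)


def centroid_distance(c: np.ndarray, avg: np.ndarray) -> float:
    """MDF distance between a subject centroid and the average centroid (mm)."""
    from .geometry import mdf_distance

    return mdf_distance(c, avg)


# ---------------------------------------------------------------------------
# density maps and overlap


@dataclass
class TractDensityMap:
    """Sparse per-voxel streamline fractions for one tract on one grid.

    ``indices`` are flat (raveled) voxel indices with a positive fraction;
    ``fractions`` the corresponding values in (0, 1].
    """

    shape: tuple
    affine: np.ndarray
    indices: np.ndarray
    fractions: np.ndarray
    n_streamlines: int

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.shape)
        out.ravel()[self.indices] = self.fractions
        return out

    def same_grid(self, other: "TractDensityMap") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


def _upsample(points: np.ndarray, max_step: float) -> np.ndarray:
    """Interpolate along the polyline so consecutive spacing is < ``max_step`` mm.

    Arc-length re-parameterization keeping the original vertices' positions
    covered: sampling is dense enough that every traversed voxel is hit.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0 or np.all(seg < max_step):
        return points
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = int(np.ceil(total / (0.9 * max_step))) + 1
    targets = np.linspace(0.0, total, n_out)
    # include original vertex positions so corners are never cut
    targets = np.union1d(targets, cum)
    out = np.empty((targets.size, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, points[:, d])
    return out


def density_map(
    streamlines,
    shape,
    affine,
    step_fraction: float = 0.5,
) -> TractDensityMap:
    """Fraction of a tract's streamlines traversing each voxel.

    Each streamline is densely upsampled (spacing below ``step_fraction`` of
    the smallest voxel edge), mapped to voxel indices by nearest-integer
    rounding of continuous voxel coordinates, and counted once per voxel it
    touches; fractions divide by the total streamline count.  Points outside
    the grid are dropped with a warning.
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    voxel_edges = np.linalg.norm(affine[:3, :3], axis=0)
    max_step = step_fraction * voxel_edges.min()
    shape = tuple(int(d) for d in shape)
    touched = []
    n = 0
    n_outside = 0
    for s in streamlines:
        n += 1
        pts = _upsample(np.asarray(s, dtype=float), max_step)
        vox = (pts @ inv[:3, :3].T) + inv[:3, 3]
        ijk = np.rint(vox).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
        n_outside += int((~inside).sum())
        ijk = ijk[inside]
        if ijk.size:
            touched.append(np.unique(np.ravel_multi_index(ijk.T, shape)))
    if n == 0:
        raise ValueError("tract has no streamlines")
    if n_outside:
        logger.warning("density_map: %d upsampled points fell outside the grid", n_outside)
    if touched:
        allv = np.concatenate(touched)
        idx, cnt = np.unique(allv, return_counts=True)
        frac = cnt.astype(float) / n
    else:
        idx = np.empty(0, dtype=int)
        frac = np.empty(0)
    return TractDensityMap(shape, affine, idx, frac, n)


def wdsc(A: TractDensityMap, B: TractDensityMap) -> float:
    """Weighted Dice similarity coefficient between two density maps.

    Sums each map's fractions over the voxels where both are positive,
    normalized by the total fraction mass of both maps.  Two empty maps give
    0 (logged).
    """
    if not A.same_grid(B):
        raise ValueError("density maps are on different grids")
    denom = A.fractions.sum() + B.fractions.sum()
    if denom == 0:
        logger.warning("wdsc: both density maps are empty; returning 0")
        return 0.0
    common, ia, ib = np.intersect1d(A.indices, B.indices, return_indices=True)
    if common.size == 0:
        return 0.0
    return float((A.fractions[ia].sum() + B.fractions[ib].sum()) / denom)


def pairwise_wdsc_mean(maps) -> float:
    """Mean wDSC over all unordered subject pairs for one tract."""
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    vals = [wdsc(a, b) for a, b in combinations(maps, 2)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# along-tract scalar profiles


def map_scalar_along(points: np.ndarray, volume: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a scalar volume at world-space points.

    Out-of-grid points come back as NaN.
    """
    volume = np.asarray(volume, dtype=float)
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    pts = np.asarray(points, dtype=float)
    vox = (pts @ inv[:3, :3].T) + inv[:3, 3]
    out = np.full(len(vox), np.nan)
    shape = np.asarray(volume.shape)
    base = np.floor(vox).astype(int)
    frac = vox - base
    ok = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    base_c = np.minimum(base[ok], shape - 2)  # clamp so corner i+1 exists
    frac_c = vox[ok] - base_c
    acc = np.zeros(base_c.shape[0])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac_c[:, 0] if dx else 1 - frac_c[:, 0])
                    * (frac_c[:, 1] if dy else 1 - frac_c[:, 1])
                    * (frac_c[:, 2] if dz else 1 - frac_c[:, 2])
                )
                acc += w * volume[base_c[:, 0] + dx, base_c[:, 1] + dy, base_c[:, 2] + dz]
    out[ok] = acc
    return out


def tract_profile(streamlines: np.ndarray, volume: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Mean scalar value at each sample index over aligned member streamlines.

    Members are orientation-aligned first so sample i means the same position
    along the tract for every member; NaNs (out-of-grid) are ignored in the
    mean.
    """
    A = np.asarray(streamlines, dtype=float)
    if A.ndim != 3 or A.shape[0] == 0:
        raise ValueError("tract has no streamlines")
    aligned = align_to_reference(A, A[0])
    vals = np.stack([map_scalar_along(s, volume, affine) for s in aligned])
    with np.errstate(invalid="ignore"):
        return np.nanmean(vals, axis=0)


# ---------------------------------------------------------------------------
# ICC


def icc_absolute(profiles: np.ndarray, form: str = "single") -> tuple[float, tuple[float, float], bool]:
    """Two-way random-effects absolute-agreement intraclass correlation.

    ``profiles`` is a subjects x samples matrix (targets x raters).  The
    single-measure form is

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with n subjects, k samples, and MSR/MSC/MSE the row, column and residual
    mean squares of the two-way ANOVA.  ``form="average"`` returns ICC(A,k).
    The 95% confidence interval follows the standard F-based construction
    (McGraw & Wong).  Columns containing missing values are dropped listwise
    (logged).  A matrix with zero total variance returns ICC = 1 flagged
    degenerate.

    Returns (icc, (lo, hi), degenerate_flag).
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 samples")
    keep = ~np.any(np.isnan(X), axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("icc_absolute: dropped %d columns with missing values", dropped)
    X = X[:, keep]
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("too few complete columns for ICC")
    if np.allclose(X, X.flat[0]):
        return 1.0, (1.0, 1.0), True
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((X - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    # perfect inter-subject agreement: no subject effect and no residual
    # (profiles may still vary along the tract) -> degenerate, ICC = 1
    scale = max(X.var(), 1.0)
    if msr <= 1e-12 * scale and mse <= 1e-12 * scale:
        return 1.0, (1.0, 1.0), True
    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom_single == 0:
        return 1.0, (1.0, 1.0), True
    if form == "single":
        icc = (msr - mse) / denom_single
    elif form == "average":
        denom = msr + (msc - mse) / n
        icc = (msr - mse) / denom if denom != 0 else 1.0
    else:
        raise ValueError("form must be 'single' or 'average'")
    lo, hi = _icc_a1_ci(msr, msc, mse, n, k)
    if form == "average":
        # Spearman-Brown style step-up of the single-measure bounds
        def up(r):
            return k * r / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else 1.0

        lo, hi = up(lo), up(hi)
    return float(icc), (float(lo), float(hi)), False


def _icc_a1_ci(msr, msc, mse, n, k, alpha=0.05):
    """F-based 95% CI for ICC(A,1) (McGraw & Wong 1996)."""
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else 1.0
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_lo * mse) / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_hi * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    return lo, hi


# ---------------------------------------------------------------------------
# counts and correlations


def streamline_cv(counts) -> float:
    """Coefficient of variation of per-subject streamline counts, in percent.

    Sample SD (n-1) over the mean, times 100.  Returns NaN when the mean is
    zero (the tract is absent everywhere).
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need counts from at least 2 subjects")
    mu = c.mean()
    if mu == 0:
        logger.warning("streamline_cv: zero mean count; CV undefined")
        return float("nan")
    return float(c.std(ddof=1) / mu * 100.0)


def metric_correlations(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    log_count_col: str = "mean_streamline_count",
) -> pd.DataFrame:
    """Spearman correlations between reliability metrics across tracts.

    ``table`` has one row per tract with metric columns.  Streamline counts
    enter log-transformed.  Every unordered metric pair is tested (two-sided,
    average-rank ties) and p-values are Benjamini-Hochberg adjusted across
    the pairs.  Pairs with a constant column are reported with NaN rho.

    Returns a DataFrame with columns metric_i, metric_j, rho, p, q.
    """
    df = table.copy()
    if log_count_col in df.columns:
        df[log_count_col] = np.log(df[log_count_col].astype(float))
        df = df.rename(columns={log_count_col: f"log_{log_count_col}"})
    if metrics is None:
        metrics = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    df = df[metrics].dropna()
    if len(df) < 4:
        raise ValueError("need >= 4 complete tracts for correlations")
    rows = []
    for a, b in combinations(metrics, 2):
        x, y = df[a].to_numpy(float), df[b].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append((a, b, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((a, b, rho, p))
    out = pd.DataFrame(rows, columns=["metric_i", "metric_j", "rho", "p"])
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# endpoint-to-parcel connectivity


def assign_endpoints_to_parcels(
    streamlines: np.ndarray,
    label_volume: np.ndarray,
    affine: np.ndarray,
    radius: float = PARCEL_RADIUS_MM,
):
    """Resolve a tract's two endpoint parcels against an integer parcellation.

    Member streamlines are orientation-aligned so "end A"/"end B" are
    consistent across members.  Each endpoint's candidate parcel is the label
    of the nearest non-background (non-zero) voxel center within ``radius``
    mm; per end, the parcel collecting the most endpoints wins (ties to the
    lowest label id).  An end with no candidate for any member is None.

    Returns (parcel_A, parcel_B), each an int or None.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    A = np.asarray(streamlines, dtype=float)
    if A.ndim != 3 or A.shape[0] == 0:
        raise ValueError("tract has no streamlines")
    aligned = align_to_reference(A, A[0])
    lab = np.asarray(label_volume)
    affine = np.asarray(affine, dtype=float)
    nz = np.argwhere(lab != 0)
    if nz.size == 0:
        return None, None
    centers = nz @ affine[:3, :3].T + affine[:3, 3]
    tree = cKDTree(centers)
    labels_nz = lab[nz[:, 0], nz[:, 1], nz[:, 2]]

    def vote(points):
        d, j = tree.query(points, distance_upper_bound=radius)
        hit = np.isfinite(d)
        if not hit.any():
            return None
        cand = labels_nz[j[hit]]
        ids, cnt = np.unique(cand, return_counts=True)
        return int(ids[np.argmax(cnt)])  # unique is sorted: ties -> lowest id

    return vote(aligned[:, 0, :]), vote(aligned[:, -1, :])
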