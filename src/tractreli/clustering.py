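"""Bundle clustering of template tractograms.

Two clustering routes operate on MDF distances between resampled
streamlines:

* **Spectral clustering** — distances become similarities through a Gaussian
  kernel w_ij = exp(-d_ij^2 / (2 sigma^2)); the normalized symmetric graph
  Laplacian L_sym = I - Deg^{-1/2} W Deg^{-1/2} is eigendecomposed, the
  embedding on the k bottom eigenvectors is row-normalized, and k-means (fixed
  seed, 10 restarts) partitions the embedded points.  Before the kernel, a
  row-mean outlier rule discards streamlines whose mean distance to all others
  exceeds the cohort mean by two (sample) standard deviations.
* **QuickBundles** — a single greedy pass: each streamline joins the nearest
  existing centroid when the MDF distance is below a threshold (updating the
  centroid as the running mean over orientation-aligned members), otherwise
  seeds a new cluster; once an optional cluster cap is hit, streamlines are
  assigned to the nearest centroid regardless of threshold.

Defaults target whole-brain template tractography, the setting this package
was built for: k = 800 clusters with an 8 mm kernel width; the superficial
U-fiber variant uses k = 500 and 6 mm.

Cluster ids are canonical: spectral clusters are renumbered by descending
size (ties by lowest member index); QuickBundles ids follow first appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .geometry import mdf_distance

__all__ = [
    "ClusterLabeling",
    "remove_outliers",
    "gaussian_affinity",
    "spectral_cluster",
    "quickbundles",
    "cluster_centroid",
    "align_to_reference",
]

OUTLIER_SENTINEL = -1
WHOLE_BRAIN_K = 800
WHOLE_BRAIN_SIGMA_MM = 8.0
USHAPE_K = 500
USHAPE_SIGMA_MM = 6.0


@dataclass
class ClusterLabeling:
    """Per-streamline integer labels in {0..k-1}, sentinel -1 for outliers."""

    labels: np.ndarray
    k: int
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        valid = self.labels[self.labels != OUTLIER_SENTINEL]
        if valid.size and valid.max() >= self.k:
            raise ValueError("label exceeds k")

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != OUTLIER_SENTINEL]


def remove_outliers(dm: np.ndarray, n_sd: float = 2.0) -> np.ndarray:
    """Indices retained after the two-standard-deviation row-mean rule.

    For each streamline i, m_i is the mean of its distances to all other
    streamlines (diagonal excluded); i is discarded when
    m_i > mean(m) + n_sd * sd(m), with the sample SD (n-1 denominator).
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 streamlines")
    m = (dm.sum(axis=1) - np.diag(dm)) / (n - 1)
    thresh = m.mean() + n_sd * m.std(ddof=1)
    keep = np.flatnonzero(m <= thresh)
    if keep.size == 0:
        raise ValueError("outlier rule discarded every streamline")
    return keep


def gaussian_affinity(dm: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel affinity w_ij = exp(-d_ij^2 / (2 sigma^2)), unit diagonal."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    dm = np.asarray(dm, dtype=float)
    aff = np.exp(-(dm**2) / (2.0 * sigma**2))
    np.fill_diagonal(aff, 1.0)
    return aff


def _canonical_relabel(raw: np.ndarray, k: int) -> np.ndarray:
    """Renumber labels by descending cluster size, ties by lowest member index."""
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in raw], dtype=int)


def spectral_cluster(
    aff: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterLabeling:
    """Normalized spectral clustering of an affinity matrix into k clusters.

    Uses the symmetric normalized Laplacian with a row-normalized bottom-k
    eigenvector embedding and seeded k-means.  Deterministic given
    (aff, k, seed).
    """
    aff = np.asarray(aff, dtype=float)
    n = aff.shape[0]
    if aff.shape != (n, n) or not np.allclose(aff, aff.T, atol=1e-10):
        raise ValueError("affinity matrix must be square and symmetric")
    if k > n:
        raise ValueError(f"k={k} exceeds number of streamlines {n}")
    if k == 1:
        return ClusterLabeling(np.zeros(n, dtype=int), 1, "spectral", {"seed": seed})
    deg = aff.sum(axis=1)
    bad = np.flatnonzero(deg <= 0)
    if bad.size:
        raise ValueError(f"zero-degree row(s) in affinity matrix: {bad[:5].tolist()}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - inv_sqrt[:, None] * aff * inv_sqrt[None, :]
    lap = 0.5 * (lap + lap.T)
    _, vecs = eigh(lap, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vecs / norms
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(emb)
    labels = _canonical_relabel(raw, k)
    return ClusterLabeling(labels, k, "spectral", {"seed": seed, "n_init": n_init})


def _aligned(s: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Flip ``s`` when its reversed orientation is MDF-closer to ``ref``."""
    d_dir = np.linalg.norm(s - ref, axis=1).mean()
    d_flip = np.linalg.norm(s[::-1] - ref, axis=1).mean()
    return s[::-1] if d_flip < d_dir else s


def align_to_reference(streamlines: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Orientation-align a (m, n, 3) stack to a reference curve."""
    return np.stack([_aligned(s, ref) for s in streamlines])


def quickbundles(
    streamlines: np.ndarray,
    threshold: float,
    max_clusters: int | None = None,
) -> tuple[ClusterLabeling, list[np.ndarray]]:
    """Single-pass greedy MDF clustering with running-mean centroids.

    Returns the labeling and the final centroid curve of each cluster, in
    cluster-id order (first appearance).  Deterministic given the input order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    A = np.asarray(streamlines, dtype=float)
    if A.ndim != 3 or A.shape[0] == 0:
        raise ValueError("need a non-empty (m, n, 3) stack")
    sums: list[np.ndarray] = []  # running point sums of aligned members
    counts: list[int] = []
    labels = np.empty(A.shape[0], dtype=int)
    for i, s in enumerate(A):
        if sums:
            cents = np.stack([sm / c for sm, c in zip(sums, counts)])
            diff = cents - s[None]
            d_dir = np.sqrt((diff**2).sum(-1)).mean(-1)
            diff_f = cents - s[None, ::-1]
            d_flip = np.sqrt((diff_f**2).sum(-1)).mean(-1)
            d = np.minimum(d_dir, d_flip)
            j = int(np.argmin(d))  # argmin takes the lowest id on ties
            capped = max_clusters is not None and len(sums) >= max_clusters
            if d[j] < threshold or capped:
                member = s[::-1] if d_flip[j] < d_dir[j] else s
                sums[j] = sums[j] + member
                counts[j] += 1
                labels[i] = j
                continue
        sums.append(s.copy())
        counts.append(1)
        labels[i] = len(sums) - 1
    centroids = [sm / c for sm, c in zip(sums, counts)]
    labeling = ClusterLabeling(
        labels,
        len(sums),
        "quickbundles",
        {"threshold": threshold, "max_clusters": max_clusters},
    )
    return labeling, centroids


def cluster_centroid(
    streamlines: np.ndarray, labeling: ClusterLabeling, cluster_id: int
) -> np.ndarray:
    """Per-point mean curve of a cluster after orientation alignment.

    Members are flipped to the orientation of the first member (lowest index)
    whenever the flipped MDF distance to it is smaller, then averaged
    point-wise.
    """
    idx = labeling.members(cluster_id)
    if idx.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    A = np.asarray(streamlines, dtype=float)[idx]
    return align_to_reference(A, A[0]).mean(axis=0)
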