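"""Streamline geometry primitives.

A *streamline* is an ordered polyline of 3D points in world coordinates
(millimetres).  All bundle comparisons in this package run on streamlines
resampled to a fixed number of equispaced-by-arc-length points (20 by
default, endpoints included), compared with the minimum average direct-flip
(MDF) distance: the mean point-to-point Euclidean distance between two
equally sampled curves, minimised over reversing one curve's point order so
that antiparallel reconstructions of the same pathway compare as identical.

Short-range superficial ("U"-shaped) fibers are selected by the classical
chord-to-arc criterion: with L the arc length and D the Euclidean distance
between the two terminal points, a streamline is U-shaped when D < L/pi
(the chord of a semicircle sits exactly at D = 2L/pi, so this admits curves
bent further than a semicircle) together with length bounds, 20-80 mm by
default.  Streamlines crossing the inter-hemispheric midline plane are
excluded from the superficial set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tractogram",
    "as_streamline",
    "arc_length",
    "endpoint_distance",
    "resample_streamline",
    "resample_all",
    "mdf_distance",
    "pairwise_distance_matrix",
    "cross_distance_matrix",
    "is_u_shaped",
    "crosses_midline",
    "filter_u_shaped",
]

DEFAULT_N_SAMPLES = 20
U_MIN_LENGTH_MM = 20.0
U_MAX_LENGTH_MM = 80.0


def as_streamline(points) -> np.ndarray:
    """Validate and return a streamline as a float (N, 3) array.

    Requires at least 2 points, finite coordinates and positive arc length.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (N, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    if arc_length(pts) <= 0.0:
        raise ValueError("streamline has zero arc length")
    return pts


@dataclass
class Tractogram:
    """A collection of streamlines sharing one spatial reference.

    ``shape`` is the voxel grid extent and ``affine`` the 4x4 voxel-to-world
    matrix of that reference; streamline coordinates are world mm.
    """

    streamlines: list = field(default_factory=list)
    shape: tuple = (1, 1, 1)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def arc_length(s) -> float:
    """Polyline arc length L = sum of consecutive inter-point distances (mm)."""
    pts = np.asarray(s, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def endpoint_distance(s) -> float:
    """Euclidean distance D between the first and last point (mm)."""
    pts = np.asarray(s, dtype=float)
    return float(np.linalg.norm(pts[-1] - pts[0]))


def resample_streamline(s, n: int = DEFAULT_N_SAMPLES, index: int | None = None) -> np.ndarray:
    """Resample a streamline to ``n`` equispaced-by-arc-length points.

    Points sit at arc-length positions ``i * L / (n - 1)`` and are obtained by
    linear interpolation along the polyline; both endpoints are preserved.

    Parameters
    ----------
    s : array-like, (N, 3)
        Input polyline, at least 2 points, positive length.
    n : int
        Number of output samples (>= 2); 20 by default.
    index : int, optional
        Identifier used in error messages when validation fails.

    Returns
    -------
    (n, 3) float array.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    pts = np.asarray(s, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError(f"streamline {index if index is not None else ''} is degenerate")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        where = f" (index {index})" if index is not None else ""
        raise ValueError(f"cannot resample zero-length streamline{where}")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, pts[:, d])
    # guard against interp round-off at the ends
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def resample_all(streamlines, n: int = DEFAULT_N_SAMPLES) -> np.ndarray:
    """Resample every streamline; returns a (M, n, 3) stack."""
    return np.stack(
        [resample_streamline(s, n, index=i) for i, s in enumerate(streamlines)]
    )


def mdf_distance(a, b) -> float:
    """Minimum average direct-flip distance between two resampled streamlines.

    d_direct = mean_i |a_i - b_i|, d_flip = mean_i |a_i - b_{n-1-i}|;
    returns min of the two.  Symmetric; zero for identical curves and for a
    curve against its own reversal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point counts differ: {a.shape} vs {b.shape}")
    d_direct = np.linalg.norm(a - b, axis=1).mean()
    d_flip = np.linalg.norm(a - b[::-1], axis=1).mean()
    return float(min(d_direct, d_flip))


def cross_distance_matrix(A, B) -> np.ndarray:
    """MDF distances between every streamline of stack A and every one of B.

    Both stacks must share the sample count n.  Accumulates one point-wise
    Euclidean distance matrix per sample index (direct and flipped), so peak
    memory is a few (|A|, |B|) float matrices.
    """
    from scipy.spatial.distance import cdist

    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 3 or B.ndim != 3 or A.shape[1:] != B.shape[1:]:
        raise ValueError("stacks must be (m, n, 3) with matching n")
    n = A.shape[1]
    d_dir = np.zeros((A.shape[0], B.shape[0]))
    d_flip = np.zeros_like(d_dir)
    for k in range(n):
        d_dir += cdist(A[:, k, :], B[:, k, :])
        d_flip += cdist(A[:, k, :], B[:, n - 1 - k, :])
    d_dir /= n
    d_flip /= n
    return np.minimum(d_dir, d_flip)


def pairwise_distance_matrix(streamlines) -> np.ndarray:
    """Symmetric MDF distance matrix over a stack of resampled streamlines."""
    A = np.asarray(streamlines, dtype=float)
    if A.ndim != 3 or A.shape[0] < 1:
        raise ValueError("need a non-empty (m, n, 3) stack")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 streamlines")
    dm = cross_distance_matrix(A, A)
    dm = 0.5 * (dm + dm.T)  # kill float asymmetry
    np.fill_diagonal(dm, 0.0)
    return dm


def is_u_shaped(
    s,
    min_len: float = U_MIN_LENGTH_MM,
    max_len: float = U_MAX_LENGTH_MM,
    bound_on: str = "arc",
) -> bool:
    """True when a streamline satisfies the U-fiber geometry criteria.

    The curvature criterion is D < L/pi.  Length bounds apply to the arc
    length L by default (``bound_on="arc"``); ``bound_on="endpoint"`` bounds
    the chord D instead.
    """
    if not 0 < min_len < max_len:
        raise ValueError("require 0 < min_len < max_len")
    if bound_on not in ("arc", "endpoint"):
        raise ValueError("bound_on must be 'arc' or 'endpoint'")
    L = arc_length(s)
    D = endpoint_distance(s)
    bounded = L if bound_on == "arc" else D
    return bool(D < L / np.pi and min_len <= bounded <= max_len)


def crosses_midline(s, midline_x: float = 0.0) -> bool:
    """True when any two points lie strictly on opposite sides of x = midline_x.

    Points exactly on the plane belong to neither hemisphere.
    """
    x = np.asarray(s, dtype=float)[:, 0] - midline_x
    return bool(np.any(x > 0) and np.any(x < 0))


def filter_u_shaped(
    t: Tractogram,
    midline_x: float = 0.0,
    min_len: float = U_MIN_LENGTH_MM,
    max_len: float = U_MAX_LENGTH_MM,
    bound_on: str = "arc",
) -> tuple[Tractogram, np.ndarray]:
    """Extract superficial U-shaped streamlines from a tractogram.

    Keeps streamlines that pass :func:`is_u_shaped` and do not cross the
    midline.  Returns the filtered tractogram and the original indices of the
    survivors.
    """
    if len(t) == 0:
        raise ValueError("empty tractogram")
    keep = [
        i
        for i, s in enumerate(t.streamlines)
        if is_u_shaped(s, min_len, max_len, bound_on) and not crosses_midline(s, midline_x)
    ]
    kept = Tractogram([t.streamlines[i] for i in keep], t.shape, t.affine)
    return kept, np.asarray(keep, dtype=int)
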