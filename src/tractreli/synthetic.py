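"""Synthetic multi-subject tractography cohorts with planted ground truth.

The generator stands in for real multi-subject tractography: each *bundle*
is a parametric centroid curve (straight line, circular arc with an arc
fraction, or cubic Bezier) replicated into streamlines by a per-streamline
rigid Gaussian offset plus optional per-point jitter, half of them emitted
with reversed point order to exercise orientation handling.  A *cohort*
replicates the bundles across subjects with a per-subject rigid translation
(centroid jitter), multiplicative streamline-count noise, and a smooth
scalar volume (constant, linear gradient, or per-bundle plateau) standing in
for an FA map.

What this emulates: distinct long-range and U-shaped bundles per hemisphere,
between-subject anatomical jitter, and session-varying streamline counts in
a shared template space.  What it does not: curving anatomy with crossing
fibers, partial-volume FA structure, registration error, or tractography
false positives — results on this data bound algorithmic correctness, not
performance on real brains.

Randomness: one root seed; per-subject and per-bundle generators are derived
with ``np.random.SeedSequence(root, spawn_key)`` counter offsets, so adding a
bundle never perturbs the streamlines of existing ones.

The default demo cohort mirrors a realistic multi-subject design at toy scale: 15 subjects,
12 bundles (8 long-range, 4 U-shaped) of 100-300 streamlines each on a 2 mm
isotropic 80x96x80 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import Tractogram, arc_length, endpoint_distance, is_u_shaped

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "line_curve",
    "arc_curve",
    "bezier_curve",
    "make_bundle",
    "make_u_bundle",
    "make_cohort",
    "demo_cohort_spec",
]

CURVE_POINTS = 60  # dense sampling of each generated streamline (>= 50)


def line_curve(start, end, n: int = CURVE_POINTS) -> np.ndarray:
    """Straight centroid curve from start to end."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(start, float) + t * (np.asarray(end, float) - np.asarray(start, float))


def arc_curve(
    radius: float,
    arc_fraction: float,
    center,
    plane: Literal["xy", "xz", "yz"] = "xz",
    n: int = CURVE_POINTS,
) -> np.ndarray:
    """Circular arc of ``arc_fraction`` of a full circle, radius in mm.

    The arc is symmetric about the plane's second axis and lies in the given
    coordinate plane through ``center``.
    """
    if not 0 < arc_fraction <= 1:
        raise ValueError("arc_fraction must be in (0, 1]")
    half = np.pi * arc_fraction
    theta = np.linspace(-half, half, n)
    u = radius * np.sin(theta)
    v = radius * np.cos(theta)
    out = np.tile(np.asarray(center, float), (n, 1))
    ax = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    out[:, ax[0]] += u
    out[:, ax[1]] += v
    return out


def bezier_curve(p0, p1, p2, p3, n: int = CURVE_POINTS) -> np.ndarray:
    """Cubic Bezier centroid curve from 4 control points."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


@dataclass
class BundleSpec:
    """One planted bundle: a centroid curve plus dispersion parameters."""

    curve: np.ndarray  # dense (>=50, 3) centroid polyline, mm
    n_streamlines: int = 200
    dispersion_sd: float = 1.0  # mm, rigid per-streamline offset
    point_jitter_sd: float = 0.1  # mm, independent per-point noise
    hemisphere: Literal["left", "right", "crossing"] = "left"
    name: str = "bundle"

    def __post_init__(self):
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 2 or self.curve.shape[0] < 2:
            raise ValueError("curve must be a (N, 3) polyline")
        L = arc_length(self.curve)
        if not 0 < L <= 300:
            raise ValueError(f"curve length {L:.1f} mm outside (0, 300]")
        if self.dispersion_sd < 0 or self.point_jitter_sd < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_streamlines < 1:
            raise ValueError("need n_streamlines >= 1")


@dataclass
class CohortSpec:
    """A multi-subject cohort of planted bundles.

    ``subject_jitter_sd`` translates each bundle's centroid rigidly per
    subject (between-subject anatomical variability); ``count_jitter`` is the
    half-width of the multiplicative uniform noise on per-subject streamline
    counts.  ``scalar_field`` selects the synthetic scalar volume: a constant,
    a linear gradient along x, or per-bundle plateaus on a background.
    """

    bundles: list
    n_subjects: int = 15
    subject_jitter_sd: float = 1.0
    count_jitter: float = 0.2
    seed: int = 0
    shape: tuple = (80, 96, 80)
    affine: np.ndarray = field(
        default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0])
        @ np.array(
            [[1, 0, 0, -40], [0, 1, 0, -48], [0, 0, 1, -40], [0, 0, 0, 1]], dtype=float
        )
    )
    scalar_field: Literal["constant", "gradient", "plateau"] = "plateau"
    scalar_constant: float = 0.5

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need n_subjects >= 1")
        self.affine = np.asarray(self.affine, dtype=float)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def make_bundle(spec: BundleSpec, seed: int, offset_override: np.ndarray | None = None):
    """Generate one bundle's streamlines; returns (list of arrays, name).

    Each streamline is the centroid curve shifted by a draw from
    N(0, dispersion_sd^2 I) with independent N(0, point_jitter_sd^2) noise on
    every point; every other streamline is emitted point-reversed.
    """
    rng = _rng(seed, 0)
    streams = []
    for i in range(spec.n_streamlines):
        shift = rng.normal(0.0, spec.dispersion_sd, size=3) if spec.dispersion_sd > 0 else np.zeros(3)
        s = spec.curve + shift
        if spec.point_jitter_sd > 0:
            s = s + rng.normal(0.0, spec.point_jitter_sd, size=s.shape)
        if offset_override is not None:
            s = s + offset_override
        if i % 2 == 1:
            s = s[::-1]
        streams.append(s)
    return streams, spec.name


def make_u_bundle(
    radius: float,
    arc_fraction: float,
    center,
    plane: Literal["xy", "xz", "yz"] = "xz",
    n_streamlines: int = 200,
    dispersion_sd: float = 1.0,
    point_jitter_sd: float = 0.1,
    hemisphere: Literal["left", "right"] = "left",
    name: str = "u_bundle",
) -> BundleSpec:
    """A circular-arc bundle whose centroid passes the U-fiber filter.

    Fails fast when the arc violates D < L/pi or the 20-80 mm length bounds,
    or when the arc touches the midline plane x = 0.
    """
    curve = arc_curve(radius, arc_fraction, center, plane)
    if not is_u_shaped(curve):
        L, D = arc_length(curve), endpoint_distance(curve)
        raise ValueError(
            f"arc violates U constraints: L={L:.1f} mm, D={D:.1f} mm, L/pi={L/np.pi:.1f}"
        )
    x = curve[:, 0]
    reach = dispersion_sd * 4 + point_jitter_sd * 4
    if x.min() - reach < 0 < x.max() + reach:
        raise ValueError("U-bundle too close to the midline x=0 for its dispersion")
    return BundleSpec(
        curve, n_streamlines, dispersion_sd, point_jitter_sd, hemisphere, name
    )


def _render_scalar(spec: CohortSpec, bundle_curves) -> np.ndarray:
    """Synthetic scalar volume on the cohort grid."""
    if spec.scalar_field == "constant":
        return np.full(spec.shape, spec.scalar_constant)
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in spec.shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    world = vox @ spec.affine.T
    if spec.scalar_field == "gradient":
        x = world[..., 0]
        lo, hi = x.min(), x.max()
        return 0.2 + 0.6 * (x - lo) / (hi - lo)
    # plateau: smooth per-bundle bumps on a 0.2 background
    from scipy.spatial import cKDTree

    vol = np.full(spec.shape, 0.2)
    pts = world[..., :3].reshape(-1, 3)
    flat = vol.ravel()
    for b, curve in enumerate(bundle_curves):
        level = 0.3 + 0.4 * (b % 5) / 4.0
        sub = curve[:: max(1, len(curve) // 20)]
        d, _ = cKDTree(sub).query(pts)
        d2 = d**2
        bump = level * np.exp(-d2 / (2 * 6.0**2)) + 0.2 * np.exp(-d2 / 800)
        np.maximum(flat, bump, out=flat)
    return np.clip(flat.reshape(spec.shape), 0.0, 1.0)


def make_cohort(spec: CohortSpec):
    """Generate the cohort: per-subject tractograms, labels, scalar volumes.

    Returns a dict with keys ``subjects`` (list of Tractogram), ``labels``
    (list of int arrays, planted bundle index per streamline), ``scalar``
    (per-subject scalar volume, identical across subjects unless jitter moves
    bundles), ``bundle_names``, ``shape``, ``affine``.  Fully deterministic
    given ``spec.seed``.
    """
    subjects, labels = [], []
    bundle_curves = [b.curve for b in spec.bundles]
    scalar = _render_scalar(spec, bundle_curves)
    # Within-bundle dispersion is a bundle property shared by all subjects:
    # pre-generate each bundle at the maximum per-subject count, then give
    # every subject a prefix of those streamlines plus its own rigid offset.
    # With zero subject jitter and zero count jitter all subjects coincide.
    base: list[list[np.ndarray]] = []
    for b, bspec in enumerate(spec.bundles):
        n_max = max(1, int(np.ceil(bspec.n_streamlines * (1.0 + spec.count_jitter))))
        full_spec = BundleSpec(
            bspec.curve,
            n_max,
            bspec.dispersion_sd,
            bspec.point_jitter_sd,
            bspec.hemisphere,
            bspec.name,
        )
        seed_b = int(
            np.random.SeedSequence(spec.seed, spawn_key=(2, b)).generate_state(1)[0]
            % (2**31)
        )
        streams_b, _ = make_bundle(full_spec, seed_b)
        base.append(streams_b)
    for subj in range(spec.n_subjects):
        streams, labs = [], []
        for b, bspec in enumerate(spec.bundles):
            rng = _rng(spec.seed, 1, subj, b)
            offset = (
                rng.normal(0.0, spec.subject_jitter_sd, size=3)
                if spec.subject_jitter_sd > 0
                else np.zeros(3)
            )
            if spec.count_jitter > 0:
                factor = 1.0 + rng.uniform(-spec.count_jitter, spec.count_jitter)
                n = max(1, min(len(base[b]), int(round(bspec.n_streamlines * factor))))
            else:
                n = bspec.n_streamlines
            streams.extend(s + offset for s in base[b][:n])
            labs.extend([b] * n)
        subjects.append(Tractogram(streams, spec.shape, spec.affine))
        labels.append(np.asarray(labs, dtype=int))
    return {
        "subjects": subjects,
        "labels": labels,
        "scalar": scalar,
        "bundle_names": [b.name for b in spec.bundles],
        "shape": spec.shape,
        "affine": spec.affine,
    }


def demo_cohort_spec(
    seed: int = 0,
    n_subjects: int = 15,
    n_streamlines: int | None = None,
    subject_jitter_sd: float = 1.0,
    count_jitter: float = 0.2,
    dispersion_sd: float = 1.0,
) -> CohortSpec:
    """The default demo cohort: 12 well-separated bundles, 8 long + 4 U-shaped.

    Bundles sit in both hemispheres with inter-centroid MDF separation far
    above their dispersion, so clustering recovery is well-posed.  Streamline
    counts per bundle span 100-300 unless ``n_streamlines`` fixes them.
    """
    bundles = []
    counts = [100, 140, 180, 220, 260, 300, 120, 200]
    # 8 long-range bundles: straight/bezier tracks, 4 per hemisphere
    long_defs = [
        (line_curve((-55, -60, -20), (-55, 60, 10)), "left"),
        (line_curve((-30, -70, 20), (-35, 50, 25)), "left"),
        (bezier_curve((-50, 0, -30), (-60, 10, 0), (-50, 20, 20), (-40, 0, 35)), "left"),
        (line_curve((-20, -40, -35), (-25, 55, -30)), "left"),
        (line_curve((55, -60, -20), (55, 60, 10)), "right"),
        (line_curve((30, -70, 20), (35, 50, 25)), "right"),
        (bezier_curve((50, 0, -30), (60, 10, 0), (50, 20, 20), (40, 0, 35)), "right"),
        (line_curve((20, -40, -35), (25, 55, -30)), "right"),
    ]
    for i, (curve, hemi) in enumerate(long_defs):
        n = n_streamlines or counts[i]
        bundles.append(
            BundleSpec(curve, n, dispersion_sd, 0.1, hemi, f"long_{i}")
        )
    # 4 U-shaped arc bundles, 2 per hemisphere
    u_defs = [
        (10.0, 0.75, (-40, -20, 45), "xz", "left"),
        (12.0, 0.80, (-45, 35, -45), "yz", "left"),
        (10.0, 0.75, (40, -20, 45), "xz", "right"),
        (12.0, 0.80, (45, 35, -45), "yz", "right"),
    ]
    u_counts = [150, 250, 110, 190]
    for i, (r, f, c, plane, hemi) in enumerate(u_defs):
        n = n_streamlines or u_counts[i]
        bundles.append(
            make_u_bundle(
                r, f, c, plane, n, dispersion_sd, 0.1, hemi, name=f"u_{i}"
            )
        )
    return CohortSpec(
        bundles=bundles,
        n_subjects=n_subjects,
        subject_jitter_sd=subject_jitter_sd,
        count_jitter=count_jitter,
        seed=seed,
    )
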