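"""Labeled-template subsampling and label propagation.

A clustered template tractogram is reduced to a labeled subsample (20,000
streamlines at whole-brain scale) and its cluster labels are transferred to each
analysis tractogram by maximum similarity: every target streamline receives
the label of the MDF-nearest template streamline.  No rejection distance is
applied by default; an optional cutoff marks distant streamlines with the
sentinel -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import OUTLIER_SENTINEL, ClusterLabeling
from .geometry import cross_distance_matrix

__all__ = ["LabeledTemplate", "subsample_template", "propagate_labels"]

DEFAULT_SUBSAMPLE = 20_000


@dataclass
class LabeledTemplate:
    """Resampled template streamlines with per-streamline cluster labels."""

    streamlines: np.ndarray  # (m, n, 3)
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.streamlines = np.asarray(self.streamlines, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.streamlines.shape[0] != self.labels.shape[0]:
            raise ValueError("labels and streamlines differ in cardinality")
        if np.any(self.labels == OUTLIER_SENTINEL):
            raise ValueError("template may not contain sentinel labels")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


def subsample_template(
    template: LabeledTemplate,
    n_keep: int,
    seed: int,
    stratified: bool = False,
) -> LabeledTemplate:
    """Seeded random subsample of a labeled template, labels preserved.

    Uniform without replacement by default.  ``stratified=True`` draws
    proportionally per cluster with a minimum of one streamline each, for
    robustness when rare clusters must survive subsampling.
    """
    m = len(template)
    if n_keep > m:
        raise ValueError(f"n_keep={n_keep} exceeds available {m}")
    rng = np.random.default_rng(seed)
    if not stratified:
        idx = np.sort(rng.choice(m, size=n_keep, replace=False))
    else:
        ids, counts = np.unique(template.labels, return_counts=True)
        quota = np.maximum(1, np.round(counts * n_keep / m)).astype(int)
        # trim largest quotas until the total matches n_keep
        while quota.sum() > n_keep:
            quota[np.argmax(quota)] -= 1
        while quota.sum() < n_keep:
            j = np.argmax(counts - quota)
            quota[j] += 1
        picks = []
        for cid, q in zip(ids, quota):
            members = np.flatnonzero(template.labels == cid)
            picks.append(rng.choice(members, size=min(q, members.size), replace=False))
        idx = np.sort(np.concatenate(picks))
    prov = dict(template.provenance)
    prov.update({"subsample_seed": int(seed), "n_keep": int(n_keep), "stratified": stratified})
    return LabeledTemplate(template.streamlines[idx], template.labels[idx], prov)


def propagate_labels(
    template: LabeledTemplate,
    target: np.ndarray,
    max_distance: float | None = None,
) -> tuple[ClusterLabeling, np.ndarray]:
    """Assign each target streamline the label of its MDF-nearest template one.

    ``target`` is a (m, n, 3) stack resampled to the template's sample count.
    Ties go to the lowest template index.  When ``max_distance`` is set,
    streamlines farther than it from every template streamline get the
    sentinel label -1.  Returns the labeling and the nearest distances.
    """
    T = np.asarray(target, dtype=float)
    if T.ndim != 3 or T.shape[0] == 0:
        raise ValueError("target must be a non-empty (m, n, 3) stack")
    if len(template) == 0:
        raise ValueError("template is empty")
    dm = cross_distance_matrix(T, template.streamlines)
    nearest = dm.argmin(axis=1)  # argmin -> lowest template index on ties
    dists = dm[np.arange(T.shape[0]), nearest]
    labels = template.labels[nearest].copy()
    if max_distance is not None:
        labels[dists > max_distance] = OUTLIER_SENTINEL
    k = int(template.labels.max()) + 1
    labeling = ClusterLabeling(
        labels, k, "propagated", {"max_distance": max_distance}
    )
    return labeling, dists
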