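"""Shared fixtures: analytic curves and small planted-bundle stacks."""

import numpy as np
import pytest

from tractreli.geometry import resample_all


def dense_arc(radius, angle_span, n=2000, center=(0.0, 0.0, 0.0), plane="xy"):
    """Dense circular-arc polyline spanning ``angle_span`` radians."""
    theta = np.linspace(-angle_span / 2, angle_span / 2, n)
    u = radius * np.sin(theta)
    v = radius * np.cos(theta)
    out = np.tile(np.asarray(center, float), (n, 1))
    ax = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    out[:, ax[0]] += u
    out[:, ax[1]] += v
    return out


@pytest.fixture
def semicircle():
    """Dense semicircle, radius 15 mm: L = 15*pi, D = 30."""
    return dense_arc(15.0, np.pi)


@pytest.fixture
def three_quarter_arc():
    """Dense 3/4 circle, radius 10 mm: L = 15*pi ~ 47.1, D = 10*sqrt(2)."""
    return dense_arc(10.0, 1.5 * np.pi)


def planted_bundles(n_bundles=4, n_per=30, sep=40.0, dispersion=1.0, n_samples=20, seed=0):
    """Well-separated parallel straight bundles; returns (stack, labels).

    Inter-centroid MDF equals ``sep``; within-bundle MDF is of order
    ``dispersion``; every other streamline is reversed.
    """
    rng = np.random.default_rng(seed)
    streams, labels = [], []
    for b in range(n_bundles):
        base = np.stack(
            [np.linspace(0, 60, 50), np.full(50, b * sep), np.zeros(50)], axis=1
        )
        for i in range(n_per):
            s = base + rng.normal(0, dispersion, size=3)
            if i % 2:
                s = s[::-1]
            streams.append(s)
            labels.append(b)
    return resample_all(streams, n_samples), np.array(labels)


@pytest.fixture
def bundles4():
    return planted_bundles()
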