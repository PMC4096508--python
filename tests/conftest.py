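"""Shared fixtures and synthetic helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nucleidetect.image_io import Volume


def make_sphere_volume(
    radius: float,
    n: int = 48,
    center=None,
    soft: bool = False,
    edge: float = 2.0,
    background: float = 0.0,
    peak: float = 100.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[Volume, tuple[float, float, float]]:
    """Isotropic cube containing one bright sphere; returns (volume, center)."""
    if center is None:
        center = (n / 2.0, n / 2.0, n / 2.0)
    g = np.arange(n)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    d = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    if soft:
        s = np.clip((radius - d) / edge + 0.5, 0.0, 1.0)
        data = background + peak * (s * s * (3.0 - 2.0 * s))
    else:
        data = np.where(d <= radius, background + peak, background)
    if noise > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise * peak, data.shape)
    return Volume(np.clip(data, 0.0, None)), center


def make_multi_sphere_volume(
    centers,
    radii,
    n: int = 64,
    background: float = 10.0,
    peak: float = 150.0,
    soft: bool = True,
) -> Volume:
    """Isotropic cube with several bright spheres."""
    g = np.arange(n)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    data = np.full((n, n, n), float(background))
    for c, r in zip(centers, radii):
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        if soft:
            s = np.clip((r - d) / 2.0 + 0.5, 0.0, 1.0)
            blob = peak * (s * s * (3.0 - 2.0 * s))
        else:
            blob = np.where(d <= r, float(peak), 0.0)
        data = np.maximum(data, background + blob)
    return Volume(data)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
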