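"""Shared fixtures: small synthetic trees and aligned scan triples.

Heavy simulations are session-scoped so several tests can share them.
Fixture trees use a coarser 5 mm sampling than the generator's 3 mm
default to keep the suite fast; tests that depend on the sampling density
(the 4×d differencing chain) build their own full-density inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from shootdelta import PointCloud, TreeSpec, generate_tree


@pytest.fixture(scope="session")
def small_tree():
    """One deterministic labeled tree at coarse sampling."""
    spec = TreeSpec(seed=42, n_shoots=15, point_spacing=0.005)
    cloud, truth = generate_tree(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def separated_tree():
    """A tree whose shoots are mutually separated by > DBSCAN eps."""
    spec = TreeSpec(seed=7, n_shoots=12, point_spacing=0.005,
                    curvature=0.0, min_shoot_clearance=0.04)
    cloud, truth = generate_tree(spec)
    return spec, cloud, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cloud(rng: np.random.Generator, n: int, scale: float = 1.0) -> PointCloud:
    return PointCloud(points=rng.uniform(-scale, scale, (n, 3)))
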