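"""Shared fixtures: one full-scale tuned phantom and calibrated beams.

The full default phantom (3000 CVT points, 100^3 grid, supersampling 4)
takes a couple of minutes to build, so it is session-scoped and shared
by the density, transport and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from vorolung import (
    BeamSpec,
    PhantomSpec,
    assign_radii,
    build_voronoi_edges,
    calibrate_sigma_to_dfw,
    cast_rays,
    lloyd_relax,
    pristine_pdd,
    sample_poisson_disk,
)
from vorolung.io_cli import build_phantom

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_phantom():
    """Tuned default phantom (network, voxel grid) at the study conditions."""
    spec = PhantomSpec(seed=DEFAULT_SEED)
    net, phantom = build_phantom(spec)
    return spec, net, phantom


@pytest.fixture(scope="session")
def default_wepl(default_phantom):
    _, _, phantom = default_phantom
    return cast_rays(phantom, jitter_seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def beam_155():
    return calibrate_sigma_to_dfw(0.24, BeamSpec.for_energy(155.0))


@pytest.fixture(scope="session")
def beam_200():
    return calibrate_sigma_to_dfw(0.36, BeamSpec.for_energy(200.0))


@pytest.fixture(scope="session")
def pristine_155(beam_155):
    return pristine_pdd(beam_155)


@pytest.fixture(scope="session")
def pristine_200(beam_200):
    return pristine_pdd(beam_200)


@pytest.fixture(scope="session")
def small_network():
    """A light CVT network (150 points) for geometry/voxelizer tests."""
    spec = PhantomSpec(n_points=150, seed=3)
    pts = lloyd_relax(sample_poisson_disk(spec), iterations=10)
    net = build_voronoi_edges(pts, spec)
    return spec, assign_radii(net, spec, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
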