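"""Shared fixtures.

The session-scoped ``scaled_suite`` runs the whole scaled study once
(60 phantoms, five frequencies, forward simulation on the refined grid,
100 CSI iterations each) and is shared by the evaluation and acceptance
tests; everything else is cheap and local.
"""

from __future__ import annotations

import numpy as np
import pytest

from mwi3d import (PhantomSpec, ProbeArray, RunConfig, VoxelGrid,
                   make_fixture_suite, sample_phantom)
from mwi3d.forward import ring_probes

SUITE_SEED = 1


@pytest.fixture(scope="session")
def grid2d() -> VoxelGrid:
    return VoxelGrid((32, 32), spacing=3.3e-3)


@pytest.fixture(scope="session")
def probes2d() -> ProbeArray:
    return ProbeArray(ring_probes(24, 0.06, ndim=2))


@pytest.fixture(scope="session")
def phantom2d(grid2d):
    """One deterministic single-tumor phantom on the 2-D test grid."""
    return sample_phantom(PhantomSpec(grid=grid2d, n_tumors=1, rng_seed=7))


@pytest.fixture(scope="session")
def scaled_suite():
    """The scaled study: 60 phantoms, simulated, inverted at 5 frequencies."""
    return make_fixture_suite(RunConfig(profile="scaled", scenario="baseline",
                                        seed=SUITE_SEED))
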