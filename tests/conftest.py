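"""Shared fixtures.

The two expensive end-to-end simulations (the multi-patient study and the
reference recovery phantom) are session-scoped so every test that needs
them shares one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from bonespect.grid import VoxelGrid
from bonespect.projector import Geometry
from bonespect.study import run_recovery_phantom, run_study

STUDY_SEED = 7   # fixed for the whole suite


@pytest.fixture(scope="session")
def study_result():
    """Full simulated comparative study: 5 patients x 4 lesions, 6 conditions."""
    return run_study(seed=STUDY_SEED, n_phantoms=5)


@pytest.fixture(scope="session")
def recovery_result():
    """Reference thorax (fixed lesions incl. one >= 30 mm) under CTAC."""
    return run_recovery_phantom(seed=STUDY_SEED)


@pytest.fixture
def small_geometry():
    return Geometry(n_views=12, t_view_s=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(data, spacing=(6.0, 6.0, 6.0), kind="activity"):
    return VoxelGrid(np.asarray(data, dtype=float), spacing, kind)
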