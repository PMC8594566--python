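"""Shared fixtures.

The expensive twin-experiment artifacts (ground-truth runs, observation
extraction) are session-scoped so several tests can share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from voxelda.cases import (
    channel_case,
    channel_initial_state,
    cylinder_case,
    extract_observations,
    run_spin_up,
    shedding_period,
)
from voxelda.ensemble import PhaseSchedule
from voxelda.grids import StaggeredGrid, VelocityField
from voxelda.observation import build_mapping
from voxelda.solver import advance_to


@pytest.fixture
def periodic_grid():
    n = 16
    return StaggeredGrid((n, n, 1), (2 * np.pi / n, 2 * np.pi / n, 1.0), (True, True, True))


@pytest.fixture
def wall_grid():
    return StaggeredGrid((8, 8, 1), (0.5, 0.25, 1.0), (True, False, True))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cylinder_twin():
    """Reduced confined-cylinder twin experiment: spin-up, measured
    shedding period, and 50 pulses of full-domain voxel observations."""
    bundle = cylinder_case("reduced")
    bundle.spin_up = 150.0
    state = run_spin_up(bundle)
    period, state = shedding_period(bundle, state, n_cycles=25)
    schedule = PhaseSchedule.uniform(period, 20)
    voxels = bundle.window_voxels("full")
    obs, truth_moments, state = extract_observations(
        bundle, state, voxels, n_pulses=50, schedule=schedule
    )
    mapping = build_mapping(bundle.grid, voxels)
    return {
        "bundle": bundle,
        "period": period,
        "schedule": schedule,
        "obs": obs,
        "truth_moments": truth_moments,
        "mapping": mapping,
    }


@pytest.fixture(scope="session")
def channel_truth():
    """Reduced turbulent-channel ground truth after its transient."""
    bundle = channel_case("reduced")
    state = channel_initial_state(bundle)
    state = advance_to(state, bundle.grid, bundle.solver, (), bundle.spin_up)
    return {"bundle": bundle, "state": state}
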