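"""Shared fixtures: a fast unit-test world and the full-scale study setting.

Session-scoped fixtures hold the expensive artefacts (the standard 8.12 m
environment, its zero-pitch memory bank and the pitch sweep) so every test
that needs them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from antcompass import (ExperimentConfig, RetinaSpec, WorldParams,
                        build_environment, build_memory_bank, generate_route,
                        generate_world, sample_pitch_trace)
from antcompass.experiments import run_pitch_sweep
from antcompass.world import PitchDistribution


@pytest.fixture(scope="session")
def small_world():
    """A sparse world that renders fast in unit tests."""
    return generate_world(WorldParams(n_tussocks=12, blades_per_tussock=12,
                                      seed=42))


@pytest.fixture(scope="session")
def small_route(small_world):
    return generate_route(small_world, 1.0, 0.01, seed=3)


@pytest.fixture(scope="session")
def env_std():
    """The full-scale study setting: seeded world, 8.12 m route, 81 test
    locations on the 10 cm grid."""
    return build_environment(ExperimentConfig(master_seed=1))


@pytest.fixture(scope="session")
def zero_bank_std(env_std):
    """Zero-pitch 812-entry memory bank on the standard route."""
    route = env_std.route
    n = len(route.storage_indices(0.01))
    trace = sample_pitch_trace(PitchDistribution.from_kind("zero"), n, seed=0)
    return build_memory_bank(env_std.world, route, trace,
                             env_std.config.retina)


@pytest.fixture(scope="session")
def sweep_std(env_std):
    """Pitch-sweep rows over the 81 standard locations at the levels the
    compass-degradation checks need."""
    rows, summary = run_pitch_sweep(env_std.config, env_std,
                                    pitch_levels=[-5, 0, 5, 10, 20, 40])
    return rows, summary
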