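"""Shared fixtures: geometries and the (expensive) wild-type equilibrium."""

import numpy as np
import pytest

import samsim as s


@pytest.fixture(scope="session")
def params():
    return s.load_parameters()


@pytest.fixture(scope="session")
def geometry():
    return s.build_dome_geometry(seed=0)


@pytest.fixture(scope="session")
def toy():
    return s.fixtures.toy_dome()


@pytest.fixture(scope="session")
def wt_noise(geometry, params):
    return s.sample_anchoring_noise(geometry, params.noise_amplitude, 1)


@pytest.fixture(scope="session")
def wt_stage1(geometry, params, wt_noise):
    """Wild-type stage-1 trajectory from the canonical initial condition."""
    wt = s.scenario_preset("wild_type")
    return s.run_stage(s.initial_state(geometry), s.STAGE1_DURATION,
                       s.DEFAULT_DT, params, wt, geometry, wt_noise,
                       stage="stage1")


@pytest.fixture(scope="session")
def wt_state(wt_stage1):
    return wt_stage1.final_state


@pytest.fixture(scope="session")
def wt_label(wt_state, geometry):
    return s.label_domains(wt_state, wt_state, geometry=geometry)
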