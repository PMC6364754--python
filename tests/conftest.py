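"""Shared fixtures: reusable simulated sessions and helper builders."""

import logging

import numpy as np
import pytest
from hypothesis import settings

import gazeperim as gp

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")

logging.getLogger("gazeperim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def screen():
    return gp.ScreenModel()


@pytest.fixture(scope="session")
def engine_cfg():
    return gp.EngineConfig()


def make_gaze(positions, t0=0.0, dt=20.0, distance=50.0, valid=None):
    """Build a gaze stream from a list of (x, y) positions."""
    valid = valid or [True] * len(positions)
    return [gp.GazeSample(t0 + i * dt, x, y, distance, v)
            for i, ((x, y), v) in enumerate(zip(positions, valid))]


@pytest.fixture(scope="session")
def perfect_params():
    """An observer that always sees and saccades accurately."""
    return gp.ObserverParams(
        psychometric_slope_db=1e-6, lapse_rate=0.0, false_saccade_rate=0.0,
        landing_sigma_deg=0.2, saccade_undershoot_frac=0.0,
        tracker_noise_sigma_deg=0.1, drift_sigma_deg=0.2)


@pytest.fixture(scope="session")
def perfect_session(perfect_params):
    field = gp.TrueField(baseline_center_db=30.0, eccentricity_slope_db_per_deg=0.0)
    return gp.simulate_session(field, perfect_params, seed=7)


@pytest.fixture(scope="session")
def blind_session():
    params = gp.ObserverParams(recenter_rate=0.0, false_saccade_rate=0.0)
    return gp.simulate_session(gp.TrueField(baseline_center_db=0.0), params, seed=7)


@pytest.fixture(scope="session")
def healthy_session():
    return gp.simulate_session(gp.TrueField(), seed=11)


@pytest.fixture(scope="session")
def hemifield_field():
    return gp.TrueField(scotomas=(gp.Scotoma("hemifield", (0.0, -1.0),
                                             depth_db=28.0),))


@pytest.fixture(scope="session")
def cohort_run():
    """The 20-eye synthetic cohort, shared across acceptance-style tests."""
    table, reports = gp.evaluate_cohort(seed=1)
    return table, reports


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (keeps tests order-independent)."""
    return np.random.default_rng(12345)
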