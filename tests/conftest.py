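"""Shared fixtures: small synthetic sessions at a desk-scale 100 Hz grid."""

import numpy as np
import pytest

from striatophot import (PipelineConfig, SimParams, normalize_gcamp,
                         segment_treadmill, simulate_locomotion,
                         simulate_photometry)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def patch_session():
    """A patch-like treadmill session: velocity, photometry, ground truth."""
    params = SimParams(duration_s=240.0, sampling_rate=100.0,
                       coupling_profile="patch_like")
    velocity, loco_truth = simulate_locomotion(params, seed=11)
    session, truth = simulate_photometry(params, velocity=velocity, seed=11,
                                         true_bouts=loco_truth.true_bouts)
    return {"params": params, "velocity": velocity, "session": session,
            "truth": truth}


@pytest.fixture(scope="session")
def patch_norm(patch_session):
    return normalize_gcamp(patch_session["session"])


@pytest.fixture(scope="session")
def patch_bouts(patch_session):
    return segment_treadmill(patch_session["velocity"])


def make_velocity(values, fs=100.0):
    """Build a VelocityTrace from raw values (helper used across tests)."""
    from striatophot import VelocityTrace

    values = np.asarray(values, dtype=float)
    return VelocityTrace(time=np.arange(values.size) / fs, velocity=values,
                         sampling_rate=fs)
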