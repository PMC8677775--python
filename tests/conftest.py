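"""Shared fixtures: scenes, rollouts and one session-scoped calibration run."""

from __future__ import annotations

import numpy as np
import pytest

from errpirl.ds import ModulationParams, SceneSpec, integrate_trajectory
from errpirl.loop import RunConfig, run_calibration
from errpirl.synthetic import UserModel, make_exp1_scene, scene_start


@pytest.fixture(scope="session")
def scene() -> SceneSpec:
    return make_exp1_scene("lr")


@pytest.fixture(scope="session")
def start(scene):
    return scene_start(scene)


@pytest.fixture(scope="session")
def rollout(scene, start):
    def _rollout(rho: float, eta: float, **kw):
        return integrate_trajectory(start, scene, ModulationParams(rho, eta), **kw)

    return _rollout


@pytest.fixture(scope="session")
def calibration_run():
    """One 300-trial calibration + decoder fit, shared across decoder tests.

    Default study conditions: random modulation parameters, ~25% erroneous
    trials, synthetic ErrP at the default amplitude.
    """
    config = RunConfig(seed=7, n_calibration_trials=300, n_folds=10,
                       user=UserModel())
    return run_calibration(config)
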