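"""Shared fixtures: one small mixed-population session reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from socialca1 import behavior, preprocess, synthgen
from socialca1.task import TaskSpec


@pytest.fixture(scope="session")
def task() -> TaskSpec:
    return TaskSpec()


@pytest.fixture(scope="session")
def small_truth() -> synthgen.GroundTruth:
    return synthgen.GroundTruth.build(
        n_reward=5, n_no_reward=3, n_identity=4, n_none=20, seed=0
    )


@pytest.fixture(scope="session")
def session(task, small_truth) -> synthgen.SessionRecord:
    """A 32-neuron, 300-trial session with planted classes (well-trained agent)."""
    return synthgen.generate_session(task, small_truth, n_trials=300, seed=1)


@pytest.fixture(scope="session")
def events(session) -> preprocess.EventTrace:
    return preprocess.preprocess_session(session)


@pytest.fixture(scope="session")
def analysis_mask(session) -> np.ndarray:
    return behavior.analysis_trial_mask(session.trials)
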