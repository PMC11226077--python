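import numpy as np
import pytest

from commloop import toy_config
from commloop.curation import TrainingExample
from commloop.fixtures import make_toy_loop_task
from commloop.model import CommunityModel


@pytest.fixture(scope="session")
def toy_task_truth():
    """A loop_len=6 toy task with its hidden ground truth."""
    return make_toy_loop_task(6, seed=0)


@pytest.fixture(scope="session")
def toy_example(toy_task_truth):
    task, truth = toy_task_truth
    return TrainingExample(task=task, ground_truth=truth)


@pytest.fixture(scope="session")
def toy_model():
    """Untrained desk-scale model (parameters seeded, deterministic)."""
    return CommunityModel(toy_config())


@pytest.fixture(scope="session")
def toy_state(toy_model, toy_task_truth):
    task, _ = toy_task_truth
    state, traj = toy_model.run_cycles(task, seed=7, n_members=4)
    return state, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def antibody_example():
    from commloop.fixtures import make_toy_antibody_example

    return make_toy_antibody_example()
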