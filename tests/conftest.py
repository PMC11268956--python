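import numpy as np
import pytest

from loopforge.fixtures import make_loop_task
from loopforge.model import ModelConfig, prepare_task


@pytest.fixture(scope="session")
def loop_task_raw():
    """One helix-loop-helix fixture: (structure, spec, truth loop coords)."""
    return make_loop_task(8, 6, 8, seed=7)


@pytest.fixture(scope="session")
def prepared_task(loop_task_raw):
    structure, spec, truth = loop_task_raw
    return prepare_task(structure, spec, truth_loop_coords=truth, task_id="fixture7")


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig.small(seed=11)


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=seed).as_matrix()
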