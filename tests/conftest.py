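import numpy as np
import pytest

from taskconn import alignment, parcellation, synthetic


@pytest.fixture(scope="session")
def gordon():
    return parcellation.gordon_schema()


@pytest.fixture(scope="session")
def toy_schema():
    """3 ROIs: network a = rows 0,1; network b = row 2."""
    return parcellation.ParcellationSchema(
        roi_ids=(1, 2, 3), network_of={1: "a", 2: "a", 3: "b"})


@pytest.fixture(scope="session")
def ten_region_schema():
    return parcellation.ParcellationSchema(
        roi_ids=tuple(range(1, 11)),
        network_of={r: "X" for r in range(1, 11)})


@pytest.fixture(scope="session")
def default_design():
    return synthetic.TaskDesign()


@pytest.fixture(scope="session")
def quiet_session(default_design):
    """One participant with the default planted ground truth, low seed."""
    gt = synthetic.default_ground_truth(seed=0, amplitude=0.8)
    return synthetic.simulate_session(default_design, gt, seed=7)


def make_stack(data, condition=(1, "word")):
    return alignment.FrameStack(condition=condition, data=np.asarray(data, float))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
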