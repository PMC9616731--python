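import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from winshift.ram import VisitSequence

logging.getLogger("winshift").setLevel(logging.WARNING)
warnings.filterwarnings("ignore", message=".*convergence.*", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20220722)


def make_bout(arms, bee_id="b1", bout_index=1, bout_type="test", n_arms=4, timestamps=None):
    return VisitSequence(
        bee_id=bee_id,
        bout_index=bout_index,
        bout_type=bout_type,
        arms=tuple(arms),
        n_arms=n_arms,
        timestamps=timestamps,
    )


@pytest.fixture
def uniform_no_self_matrix():
    """4-arm matrix moving uniformly to any other arm (the chance-mover null)."""
    from winshift.nullmodels import TransitionMatrix

    P = (np.ones((4, 4)) - np.eye(4)) / 3.0
    return TransitionMatrix(
        bee_id="uniform",
        n_arms=4,
        P=P,
        counts=np.zeros((4, 4)),
        start_dist=np.full(4, 0.25),
    )


@pytest.fixture
def small_covariates():
    return pd.DataFrame(
        {
            "bee_id": [f"b{i}" for i in range(5)],
            "size_mm": [4.2, 4.5, 4.8, 4.4, 4.6],
            "age_at_release": [5, 7, 9, 6, 8],
            "n_bouts": [3, 3, 3, 3, 3],
        }
    )
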