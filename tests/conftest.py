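import numpy as np
import pandas as pd
import pytest

from dihsmm.model import ModelSample, generate_task_schedule, simulate_dataset
from dihsmm.trial_features import build_design


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_table():
    """Two sessions, five trials, all choice types represented."""
    return pd.DataFrame(
        {
            "session": [1, 1, 1, 2, 2],
            "trial": [1, 2, 3, 1, 2],
            "contrast_left": [1.0, 0.0, 0.0, 0.5, 0.0],
            "contrast_right": [0.0, 0.5, 0.0, 0.0, 0.25],
            "choice": ["L", "R", "timeout", "L", "R"],
            "rewarded_side": ["L", "R", "L", "L", "R"],
        }
    )


def three_state_model(n_sessions: int) -> ModelSample:
    """Well-separated flat / one-sided / fully tuned states."""
    ws = np.array(
        [
            [0.0, 0.0, 0.5, -1.5],
            [-1.0, 5.0, 0.5, 1.0],
            [-5.0, 5.0, 0.5, 0.0],
        ]
    )
    w = np.repeat(ws[:, None, :], n_sessions, axis=1)
    return ModelSample(
        beta=np.full(3, 1 / 3),
        pi0=np.array([0.6, 0.3, 0.1]),
        pi=np.full((3, 3), 1 / 3),
        alpha=1.0,
        gamma=1.0,
        r=np.array([60, 60, 60]),
        p=np.array([0.25, 0.25, 0.25]),
        w=w,
    )


@pytest.fixture(scope="session")
def planted_fit():
    """A small 3-state dataset with its design matrix (no fitting)."""
    rng = np.random.default_rng(7)
    model = three_state_model(8)
    schedule = generate_task_schedule(8, 150, rng)
    table, model = simulate_dataset(model, schedule, rng, timeout_prob=0.01)
    design = build_design(table)
    return table, design, model
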