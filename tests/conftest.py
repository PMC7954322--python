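import numpy as np
import pandas as pd
import pytest

from hale.cohort import SimulationConfig, generate_cohort
from hale.intensities import GompertzIntensityParams
from hale.panel import PanelDataset


@pytest.fixture
def toy_q_params():
    """Time-homogeneous toy generator: q12=.1, q13=.02, q21=.05, q23=.1."""
    return GompertzIntensityParams.from_rates(
        rates={(1, 2): 0.1, (1, 3): 0.02, (2, 1): 0.05, (2, 3): 0.1})


@pytest.fixture
def toy_q_matrix():
    return np.array([[-0.12, 0.1, 0.02], [0.05, -0.15, 0.1], [0.0, 0.0, 0.0]])


@pytest.fixture
def small_panel():
    """Two subjects, two waves each, one death."""
    obs = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b"],
        "age": [61.0, 63.5, 70.0, 71.2],
        "state": [1, 2, 2, 3],
    })
    cov = pd.DataFrame({"sex": [0.0, 1.0], "part": [1.0, 0.0]},
                       index=pd.Index(["a", "b"], name="subject_id"))
    return PanelDataset.from_frames(obs, cov)


@pytest.fixture
def sim_panel():
    """Small simulated cohort under the default study conditions."""
    cfg = SimulationConfig(n_subjects=400, seed=2024,
                           covariate_prevalences={"part": 0.32})
    dataset, trajectories = generate_cohort(cfg)
    return dataset, trajectories, cfg
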