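import numpy as np
import pytest

from psbart.data import TrialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_trial():
    """Hand-built 8-row, 4-cluster dataset covering all four observation
    patterns and both arms."""
    return TrialDataset(
        cluster=[0, 0, 1, 1, 2, 2, 3, 3],
        z=[1, 1, 1, 1, 0, 0, 0, 0],
        x=np.array([[0.5, 1.0], [-0.3, 0.0], [1.2, 1.0], [0.1, 0.0],
                    [-0.6, 1.0], [0.9, 0.0], [0.0, 1.0], [-1.1, 0.0]]),
        covariate_names=["x1", "x2"],
        s_obs=[1, 1, 0, np.nan, 1, 1, 0, np.nan],
        r_s=[1, 1, 1, 0, 1, 1, 1, 0],
        r_y=[1, 0, 0, 0, 1, 0, 0, 0],
        y_obs=[1.4, np.nan, np.nan, np.nan, -0.2, np.nan, np.nan, np.nan],
        truncated=[False, False, True, False, False, False, True, False],
    )


@pytest.fixture
def small_sim():
    """A small simulated replicate with ground truth (40 clusters x 4)."""
    from psbart.simulate import DgpConfig, generate_dataset
    return generate_dataset(DgpConfig(n_clusters=40, cluster_size=4, seed=7))
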