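import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but complete two-cohort dataset for structural tests."""
    from amsa import simulate as sim

    cfg = sim.default_config(seed=11, n_hc=6, n_ms=7, voxels_per_roi=80)
    voxels, subjects, truth = sim.generate_cohort_dataset(cfg)
    return cfg, voxels, subjects, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def single_subject_voxels():
    """Noiseless voxels on a known cos^2 curve for one subject."""
    theta = np.linspace(5.0, 85.0, 100)
    chi = 21.0 * np.cos(np.deg2rad(theta)) ** 2 + (-35.0)
    return pd.DataFrame(
        {
            "subject_id": "S1",
            "cohort": "HC",
            "roi": "OR",
            "theta_deg": theta,
            "chi_app_ppb": chi,
            "fa": 0.8,
            "pq": 0.1,
        }
    )
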