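import numpy as np
import pandas as pd
import pytest

from immunophen import simdata


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample, 240-gene cohort with balanced module proportions."""
    cfg = simdata.SimConfig(
        n_samples=60,
        n_genes=240,
        module_sizes={
            "cytotoxic": 36,
            "antigen_presentation": 20,
            "tgfb_stroma": 20,
            "desert_program": 8,
            "housekeeping": 8,
            "noise": None,
        },
        seed=101,
    )
    return simdata.generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """150-sample, 800-gene cohort used for recovery-style tests."""
    cfg = simdata.SimConfig(
        n_samples=150,
        n_genes=800,
        module_sizes={
            "cytotoxic": 120,
            "antigen_presentation": 70,
            "tgfb_stroma": 70,
            "desert_program": 30,
            "housekeeping": 20,
            "noise": None,
        },
        seed=202,
    )
    return simdata.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_image():
    spec = simdata.IHCImageSpec(seed=5)
    image, mask, truth = simdata.generate_ihc_image(spec)
    return spec, image, mask, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_densities():
    return pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d"],
            "cd8_tumour_density": [3.0, 10.0, 0.0, 0.0],
            "cd8_stroma_density": [4.0, 0.0, 7.0, 0.0],
        }
    )
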