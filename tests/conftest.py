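import numpy as np
import pytest

from biofilmq import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small two-cohort synthetic dataset shared by pipeline-level tests."""
    root = tmp_path_factory.mktemp("dataset")
    presets = {
        "LB": synthetic.lb_preset(image_size=(256, 256), outer_radius_day1=55.0, core_radius_day1=45.0),
        "LBGM": synthetic.lbgm_preset(image_size=(256, 256), outer_radius_day1=55.0, core_radius_day1=45.0),
    }
    synthetic.generate_cohorts(root, n_lb=3, n_lbgm=3, presets=presets, seed=11)
    return root
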