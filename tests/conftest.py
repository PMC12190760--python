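import numpy as np
import pytest

from lumiquant import SimConfig, simulate_cohort, simulate_mouse_image


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=5, n_mice=10)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, sim_config):
    """A small synthetic cohort directory (grayscale dialect), written once."""
    d = tmp_path_factory.mktemp("cohort")
    truth = simulate_cohort(sim_config, d)
    return d, truth


@pytest.fixture()
def phantom_factory(sim_config):
    """Render a single phantom mouse with ground truth."""

    def make(mean_radiance=5e5, *, seed=1, raw_height=100, tail=None,
             tail_angle=0.0, region_weights=None):
        return simulate_mouse_image(
            sim_config, "m0", 7.0, mean_radiance,
            rng=np.random.default_rng(seed), raw_height=raw_height,
            tail=tail, tail_angle=tail_angle, region_weights=region_weights,
        )

    return make
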