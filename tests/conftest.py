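import numpy as np
import pytest

from ppgbp.config import BackboneConfig, MHCAConfig, RenderSpec, SimConfig
from ppgbp.preprocess import SegmentWindow, make_windows
from ppgbp.simulate import simulate_record


@pytest.fixture(scope="session")
def clean_sim_config():
    """Noise-free, wander-free simulator config for deterministic checks."""
    return SimConfig(
        n_records=4,
        record_duration=40.0,
        noise_sd=0.0,
        wander_amplitude=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def sim_record(clean_sim_config):
    return simulate_record(clean_sim_config, 0)


@pytest.fixture(scope="session")
def sim_windows(sim_record):
    return make_windows(sim_record)


@pytest.fixture(scope="session")
def small_render_spec():
    return RenderSpec(height=64, width=64, margin=4, line_thickness=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_model_kwargs():
    """A model small enough for finite-difference and determinism tests."""
    return dict(
        backbone_config=BackboneConfig(kind="tiny"),
        mhca_config=MHCAConfig(d_model=16, n_heads=2),
        render_spec=RenderSpec(height=32, width=32, margin=4),
        seed=5,
    )
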