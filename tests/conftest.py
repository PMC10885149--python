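import numpy as np
import pytest

from plaquemap import pipeline

# A compact but fully featured simulation used by several test modules:
# 48x48 grid, 6 plaques, the full species panel, default noise and gain.
SMALL_SIM = {
    "grid_size": (48, 48),
    "n_plaques": 6,
    "radius_range": (2.0, 4.0),
    "n_background_peaks": 30,
}

SMALL_OVERRIDES = {
    "seed": 11,
    "simulate": SMALL_SIM,
    "segmentation": {"min_area": 4, "max_area": 120},
}


@pytest.fixture(scope="session")
def small_run():
    """One full in-memory pipeline run on the small simulation."""
    cfg = pipeline.load_config(overrides=SMALL_OVERRIDES)
    return pipeline.run_in_memory(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
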