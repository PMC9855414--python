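import numpy as np
import pytest

from glyecg import PipelineConfig
from glyecg.synthetic_data import (
    EUGLYCEMIA,
    GlycemicEffect,
    simulate_state_run,
    simulate_subject,
)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cfg() -> PipelineConfig:
    """Reduced-scale protocol for fast end-to-end tests: 1-min strips and
    a 2/1/1 split instead of 10-min strips and 10/5/5."""
    return PipelineConfig(
        bg_corr_window_s=60.0,
        n_train_eu=2,
        n_val_eu=1,
        n_val_dys=1,
        min_bg_records=4,
        min_dys_records=1,
        min_train_beats=50,
    )


@pytest.fixture(scope="session")
def eu_run(cfg):
    """A 400-beat euglycemic run at default jitter with its ground truth."""
    return simulate_state_run(EUGLYCEMIA, 400, seed=1001, cfg=cfg)


@pytest.fixture(scope="session")
def small_subject(small_cfg):
    """One reduced-scale synthetic subject (6 one-minute strips)."""
    return simulate_subject(None, GlycemicEffect(), n_bg=6, seed=77,
                            cfg=small_cfg)


@pytest.fixture(scope="session")
def clean_strip_signal(cfg):
    """60 s of noise-free euglycemic signal plus its designed truth."""
    rec, truth = simulate_state_run(
        EUGLYCEMIA, 70, seed=5, cfg=cfg, noise_sd_mv=0.0, jitter_scale=0.0)
    return rec, truth
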