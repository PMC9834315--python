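"""Shared fixtures: small grids, synthetic stimulus sets, simulated sessions.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import logging

import pytest

from cfsdecode.ensemble import EnsembleConfig
from cfsdecode.grid import build_grid
from cfsdecode.spectra import extract_features
from cfsdecode.synth import (
    ResponseModel,
    WedgeEnergySpec,
    calibrate_beta,
    make_stimulus_set,
    make_trial_table,
    simulate_responses,
)

logging.getLogger("cfsdecode").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_grid():
    """6 x 4 wedges on 32 px images: fast, every band populated."""
    return build_grid(n_sf=6, n_ori=4, image_side=32)


@pytest.fixture(scope="session")
def default_grid():
    """The full 24 x 16 grid on 128 px images (384 wedges)."""
    return build_grid()


@pytest.fixture(scope="session")
def flat_spec():
    return WedgeEnergySpec(base_energy=1.0, class_deltas={}, identity_sd=0.2)


@pytest.fixture(scope="session")
def small_images(flat_spec, small_grid):
    return make_stimulus_set(flat_spec, n_per_class=6, side=32, seed=11,
                             grid=small_grid)


@pytest.fixture(scope="session")
def small_features(small_images, small_grid):
    return {im.image_id: extract_features(im, small_grid)
            for im in small_images}


@pytest.fixture(scope="session")
def small_session(small_images, small_features, small_grid):
    """A responded 6 x 48 session driven by horizontal-axis energy."""
    driver = tuple(int(i) for i in small_grid.axis_wedges("horizontal"))
    beta = calibrate_beta(small_features, driver, target_logit_sd=2.0)
    model = ResponseModel(driver_wedges=driver, beta=beta, lapse=0.05)
    trials = make_trial_table(small_images, trials_per_condition=48, seed=13)
    return simulate_responses(trials, small_features, model, seed=17)


@pytest.fixture(scope="session")
def tiny_ensemble_config():
    """Reduced engine settings used throughout the unit tests."""
    return EnsembleConfig(
        k_folds=4, n_models_per_method=4, n_control_reps=6,
        wrapper_cap=3, wrapper_pool=6, wrapper_inner_folds=2,
    )
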