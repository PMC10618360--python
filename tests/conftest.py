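"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

import scchoice as sc


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_one_target():
    """A small one-target session (8 cells x 24 trials) for pipeline tests."""
    cfg = sc.RunConfig.defaults_for(
        "one-target", seed=11, n_cells=8, trials_per_cell=24
    ).model_copy(update={"write_figures": False})
    return sc.make_session(cfg)


@pytest.fixture(scope="session")
def small_one_target_results(small_one_target):
    return sc.EyeChoiceModel(small_one_target).fit()


@pytest.fixture(scope="session")
def noiseless_one_target():
    """One-target session with zero measurement noise and zero drift."""
    cfg = sc.RunConfig.defaults_for(
        "one-target", seed=5, n_cells=6, trials_per_cell=30
    )
    cfg = cfg.model_copy(
        update={
            "geometry": cfg.geometry.model_copy(
                update={"noise_sd": 0.0, "drift_sd": 0.0}
            ),
            "write_figures": False,
        }
    )
    return sc.make_session(cfg)
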