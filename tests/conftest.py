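import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dartdose.chamber_model import load_stopping_tables
from dartdose.decay_chain import load_default_chain
from dartdose.study_pipeline import StudyConfig, run_full_study


@pytest.fixture(scope="session")
def chain():
    return load_default_chain()


@pytest.fixture(scope="session")
def tables():
    return load_stopping_tables()


@pytest.fixture(scope="session")
def full_study():
    """The complete study at production resolution (shared across tests).

    1e6 cascade histories per depth, 50 µm / 15 min DL solves for both
    diffusion scenarios, 4e5 chamber histories per emission line.
    """
    cfg = StudyConfig(rng_seed=42)
    with warnings.catch_warnings():
        # The low-diffusion scenario runs at dr = L_Pb/2 by design; the
        # solver warns that sub-L/4 structure is smoothed.
        warnings.simplefilter("ignore", UserWarning)
        return run_full_study(cfg)


@pytest.fixture(scope="session")
def coarse_study():
    """A fast, low-resolution study for structural/determinism tests."""
    cfg = StudyConfig(
        n_histories=50_000,
        chamber_histories=50_000,
        dr_um=100.0,
        dz_um=100.0,
        dt_pb_minutes=90.0,
        treatment_days=6.0,
        diffusion_scenarios=("high",),
        rng_seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_full_study(cfg)
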