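import numpy as np
import pandas as pd
import pytest

import stroopdelta as sd
from stroopdelta.synth import ExGaussian, SimConfig


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A small three-target cohort with realistic pruning rates."""
    cfg = SimConfig(
        n_studies=3, participants_per_study=8, trials_per_cell=30, seed=7
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_single_target_cohort() -> pd.DataFrame:
    """One face-target cohort with no errors/non-responses/contamination
    and a linear delta profile delta(p) = 40 - 80 p."""
    base = ExGaussian(450.0, 50.0, 120.0)
    prof = sd.make_delta_profile(40.0, -80.0, baseline=base)
    cfg = SimConfig(
        n_studies=3,
        participants_per_study=10,
        trials_per_cell=80,
        target_types=("face",),
        baselines={"face": base},
        profiles={"face": prof},
        study_sd=20.0,
        participant_sd=30.0,
        error_rate=0.0,
        nonresponse_rate=0.0,
        contamination=(0.0, 100.0, 2000.0),
        seed=21,
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
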