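import dataclasses

import numpy as np
import pandas as pd
import pytest

from periprior.fitting import DISPARITIES_MM, ConditionData, FitConfig
from periprior.model import CouplingPriorParams, SensoryNoise, predict_mean_estimates
from periprior.pipeline import run_full_pipeline
from periprior.simulate import (
    CohortDesign,
    ConditionParams,
    default_generative_params,
    make_cohort,
)


@pytest.fixture
def visible_noise():
    """Hand-visible unisensory dispersions (mm)."""
    return SensoryNoise(sigma_v=6.8, sigma_p=22.9)


@pytest.fixture
def small_design():
    """A reduced session: 24+24 unisensory reaches, 2 presentations/cell."""
    return CohortDesign(n_participants=2, n_uni_visual=24, n_uni_proprio=24,
                        n_multi_presentations=36)


@pytest.fixture
def small_cohort(small_design):
    trials, truth = make_cohort(small_design, master_seed=11)
    return trials, truth


@pytest.fixture
def homogeneous_params():
    """Generative defaults with zero between-participant spread."""
    zero = ConditionParams(0.0, 0.0, 0.0, 0.0)
    return dataclasses.replace(default_generative_params(),
                               visible_sd=zero, invisible_sd=zero)


def condition_data_from_model(params: CouplingPriorParams,
                              noise: SensoryNoise,
                              participant: str = "p1",
                              visibility: str = "visible") -> ConditionData:
    """Noiseless per-condition means generated by the model itself."""
    d = np.array(DISPARITIES_MM)
    pred = predict_mean_estimates(d, noise, params)
    means = pd.DataFrame({
        "mean_visual_mm": pred["v_hat_mm"].to_numpy(),
        "mean_proprio_mm": pred["p_hat_mm"].to_numpy(),
        "n_visual": 12,
        "n_proprio": 12,
    }, index=d)
    return ConditionData(participant=participant, visibility=visibility,
                         noise=noise, means=means)


@pytest.fixture(scope="session")
def recovery_run():
    """Full 20-participant recovery at the study conditions (shared)."""
    seed = 1
    trials, truth = make_cohort(master_seed=seed)
    report = run_full_pipeline(
        trials, FitConfig(n_starts_stage1=50, n_carry_stage2=50,
                          master_seed=seed))
    return trials, truth, report
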