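import math

import numpy as np
import pandas as pd
import pytest

from healthspan import IllnessDeathSpec, IntensityParameters, SimulationConfig


@pytest.fixture
def const_params():
    """Age-constant rates q12=0.1, q13=0.05, q23=0.2 per year."""
    return IntensityParameters(
        beta0={"12": math.log(0.1), "13": math.log(0.05), "23": math.log(0.2)}
    )


@pytest.fixture
def gompertz_params():
    """Age-varying (Gompertz-type) intensities typical of an oldest-old cohort."""
    return IntensityParameters(
        beta0={"12": -3.0, "13": -3.2, "23": -2.0},
        beta_age={"12": 0.08, "13": 0.09, "23": 0.07},
        ref_age=80.0,
    )


@pytest.fixture
def const_spec():
    return IllnessDeathSpec(covariates={}, age_effect=False, ref_age=80.0)


@pytest.fixture
def small_cohort_config(const_params):
    return SimulationConfig(
        n_subjects=200,
        true_params=const_params,
        seed=11,
        wave_offsets=(0.0, 3.0, 6.0, 9.0),
    )


def panel_frame(rows, **covariates):
    """Build a panel DataFrame from (subject_id, age, state, is_death) tuples."""
    df = pd.DataFrame(rows, columns=["subject_id", "age", "state", "is_death_record"])
    df["state"] = df["state"].astype(float)
    for name, value in covariates.items():
        df[name] = value
    return df


@pytest.fixture
def panel_builder():
    return panel_frame


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
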