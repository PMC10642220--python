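import numpy as np
import pytest
from scipy.special import logit

from ncdprev.synthetic import (
    BmiTrend,
    IndicatorTrend,
    NonresponseModel,
    ScenarioConfig,
    default_nonresponse,
)

WAVES = (1997, 2002, 2007, 2012, 2017)


def flat_bmi(normal=0.5, overweight=0.3, obese=0.2):
    """Time-constant BMI category distribution."""
    return BmiTrend(
        overweight=(float(np.log(overweight / normal)), 0.0, 0.0, 0.0),
        obese=(float(np.log(obese / normal)), 0.0, 0.0, 0.0),
    )


def make_scenario(n_per_sex=1000, waves=WAVES, smoking=(0.30, 0.0),
                  seed=0, nonresponse=None, obesity_to_diabetes=0.0,
                  **trend_overrides) -> ScenarioConfig:
    """Small test scenario: flat indicators unless overridden; smoking
    gets (baseline prevalence, logit slope per year)."""
    trends = {
        "smoking": IndicatorTrend(float(logit(smoking[0])), smoking[1]),
        "sedentary": IndicatorTrend(float(logit(0.25))),
        "hypertension": IndicatorTrend(float(logit(0.40))),
        "elevated_tc": IndicatorTrend(float(logit(0.55))),
    }
    trends.update(trend_overrides)
    return ScenarioConfig(
        wave_years=tuple(waves),
        invited_n={s: {y: n_per_sex for y in waves} for s in (0, 1)},
        trend_params=trends,
        bmi_params=flat_bmi(),
        diabetes_params=IndicatorTrend(float(logit(0.05)),
                                       obesity_coef=obesity_to_diabetes),
        nonresponse=nonresponse,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    return make_scenario(n_per_sex=500, seed=11)
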