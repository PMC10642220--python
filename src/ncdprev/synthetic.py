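"""Synthetic multi-wave health-examination survey data with known ground
truth.

The generator emulates the structure of the Finnish risk-factor
monitoring series: five cross-sectional waves (1997-2017, every five
years), invited samples of the published sizes, ages 25-64 in five study
areas, six risk-factor indicators with secular logit-scale trends, unit
and item non-response, and glycated-haemoglobin (HbA1c) measurements that
are structurally absent in the 1997 and 2007 waves.

Binary indicators are drawn from Bernoulli distributions whose logit is
linear in calendar time with optional sex, age and obesity terms; the
body-mass-index (BMI) category is drawn from a three-category
multinomial logit.  Diabetes is emitted as its raw components -- a
medication flag and an HbA1c value -- so the downstream derivation
(medication and/or HbA1c >= 48 mmol/mol) and the structural missingness
of HbA1c are exercised end to end.

Default trends are calibrated so the population prevalences at the first
and last waves match the published Finnish series; everything is
overridable through :class:`ScenarioConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import datasets
from .datasets import MEN, WOMEN

DEMOGRAPHIC_COLS = ["year", "sex", "age", "area"]
#: survey-derived columns: missing for unit non-respondents.
SURVEY_COLS = [
    "marital",
    "education",
    "smoking",
    "sedentary",
    "hypertension",
    "elevated_tc",
    "bmi_cat",
    "diabetes_med",
    "hba1c",
]
FRAME_COLS = DEMOGRAPHIC_COLS + SURVEY_COLS + ["participation"]

BINARY_INDICATORS = ("smoking", "sedentary", "hypertension", "elevated_tc")

# substream labels so that adding a wave or switching one mechanism off
# never perturbs the draws of another
_STAGE_FRAME, _STAGE_INDICATORS, _STAGE_NONRESPONSE, _STAGE_PROJECTION = range(4)


def _rng(seed: int, year: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(year), stage)))


@dataclass(frozen=True)
class IndicatorTrend:
    """Logit-linear secular trend for one binary indicator.

    logit p = intercept + slope*(year-1997) + sex_coef*[woman]
              + sex_slope*[woman]*(year-1997) + age_coef*(age-45)
              + obesity_coef*[obese]
    """

    intercept: float
    slope: float = 0.0
    sex_coef: float = 0.0
    sex_slope: float = 0.0
    age_coef: float = 0.0
    obesity_coef: float = 0.0

    def linpred(self, t: np.ndarray, sex: np.ndarray, age: np.ndarray,
                obese: np.ndarray | float = 0.0) -> np.ndarray:
        w = (np.asarray(sex) == WOMEN).astype(float)
        return (
            self.intercept
            + self.slope * t
            + self.sex_coef * w
            + self.sex_slope * w * t
            + self.age_coef * (np.asarray(age, dtype=float) - 45.0)
            + self.obesity_coef * np.asarray(obese, dtype=float)
        )


@dataclass(frozen=True)
class BmiTrend:
    """Three-category multinomial-logit trend for the BMI category.

    Utilities relative to normal weight (category 0):
    ``u_c = intercept_c + slope_c*t + sex_coef_c*[woman] + sex_slope_c*[woman]*t``
    for overweight (category 1) and obese (category 2).
    """

    overweight: tuple[float, float, float, float]  # intercept, slope, sex_coef, sex_slope
    obese: tuple[float, float, float, float]

    def probs(self, t: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """(n, 3) category probabilities: normal, overweight, obese."""
        t = np.asarray(t, dtype=float)
        w = (np.asarray(sex) == WOMEN).astype(float)
        u_ow = self.overweight[0] + self.overweight[1] * t + self.overweight[2] * w + self.overweight[3] * w * t
        u_ob = self.obese[0] + self.obese[1] * t + self.obese[2] * w + self.obese[3] * w * t
        e_ow, e_ob = np.exp(u_ow), np.exp(u_ob)
        denom = 1.0 + e_ow + e_ob
        return np.column_stack([1.0 / denom, e_ow / denom, e_ob / denom])


@dataclass(frozen=True)
class NonresponseModel:
    """Unit non-response (whole survey skipped) and item non-response.

    Unit response is Bernoulli with
    ``logit P(respond) = unit_intercepts[sex][year] + unit_age_coef*(age-45)``;
    with ``unit_age_coef = 0`` the realised rate equals
    ``expit(intercept)`` in expectation.  Item non-response strikes each
    survey column independently among respondents (missing completely at
    random by default; an age/sex-dependent mechanism -- what multiple
    imputation actually assumes -- via ``item_age_coef``/``item_sex_coef``
    acting on the per-item missingness logit).
    """

    unit_intercepts: Mapping[int, Mapping[int, float]]
    unit_age_coef: float = 0.0
    item_rates: Mapping[str, float] = field(default_factory=dict)
    item_age_coef: float = 0.0
    item_sex_coef: float = 0.0

    def unit_response_prob(self, year: int, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
        icpt = np.array([self.unit_intercepts[int(s)][int(year)] for s in np.asarray(sex)])
        return expit(icpt + self.unit_age_coef * (np.asarray(age, dtype=float) - 45.0))

    def item_missing_prob(self, col: str, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
        rate = float(self.item_rates.get(col, 0.0))
        sex = np.asarray(sex)
        if rate <= 0.0:
            return np.zeros(sex.shape)
        if self.item_age_coef == 0.0 and self.item_sex_coef == 0.0:
            return np.full(sex.shape, rate)
        eta = (
            logit(rate)
            + self.item_age_coef * (np.asarray(age, dtype=float) - 45.0)
            + self.item_sex_coef * (sex == WOMEN).astype(float)
        )
        return expit(eta)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study scenario."""

    wave_years: tuple[int, ...] = datasets.WAVE_YEARS
    invited_n: Mapping[int, Mapping[int, int]] = field(
        default_factory=lambda: {s: dict(d) for s, d in datasets.INVITED_N.items()}
    )
    age_range: tuple[int, int] = (25, 64)
    n_areas: int = 5
    trend_params: Mapping[str, IndicatorTrend] = field(default_factory=dict)
    bmi_params: BmiTrend | None = None
    diabetes_params: IndicatorTrend | None = None
    med_given_diabetes: float = 0.8  # share of diabetics on medication
    marital_p: float = 0.55
    education_probs: tuple[float, float, float] = (0.30, 0.40, 0.30)
    nonresponse: NonresponseModel | None = None
    structural_missing: frozenset[tuple[int, str]] = frozenset(
        {(1997, "hba1c"), (2007, "hba1c")}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.wave_years) != sorted(set(self.wave_years)):
            raise ValueError("wave_years must be strictly increasing")
        for sex in (MEN, WOMEN):
            for y in self.wave_years:
                if self.invited_n[sex][y] < 0:
                    raise ValueError("invited_n must be nonnegative")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be a nondecreasing interval")


# ---------------------------------------------------------------------------
# default-scenario calibration

def _mean_prevalence(trend: IndicatorTrend, bmi: BmiTrend, t: float, sex: int,
                     ages: np.ndarray) -> float:
    """Population prevalence implied by a trend at time *t*: mean over the
    uniform age distribution and the obesity mixture."""
    p_ob = bmi.probs(np.full(ages.shape, t), np.full(ages.shape, sex))[:, 2]
    eta = trend.linpred(np.full(ages.shape, t), np.full(ages.shape, sex), ages, 0.0)
    p = (1.0 - p_ob) * expit(eta) + p_ob * expit(eta + trend.obesity_coef)
    return float(p.mean())


def calibrate_trend(p_start: Mapping[int, float], p_end: Mapping[int, float],
                    span: float, bmi: BmiTrend, age_coef: float = 0.0,
                    obesity_coef: float = 0.0,
                    age_range: tuple[int, int] = (25, 64)) -> IndicatorTrend:
    """Solve the logit-linear trend whose population prevalence hits the
    given per-sex endpoints at t=0 and t=span, accounting for the age
    spread and the obesity dependence."""
    ages = np.arange(age_range[0], age_range[1] + 1, dtype=float)
    eta: dict[tuple[int, float], float] = {}
    for sex, t, target in ((MEN, 0.0, p_start[MEN]), (MEN, span, p_end[MEN]),
                           (WOMEN, 0.0, p_start[WOMEN]), (WOMEN, span, p_end[WOMEN])):
        base = IndicatorTrend(0.0, age_coef=age_coef, obesity_coef=obesity_coef)

        def gap(icpt: float) -> float:
            tr = replace(base, intercept=icpt)
            return _mean_prevalence(tr, bmi, t, sex, ages) - target

        eta[(sex, t)] = brentq(gap, -20.0, 20.0)
    slope_m = (eta[(MEN, span)] - eta[(MEN, 0.0)]) / span
    slope_w = (eta[(WOMEN, span)] - eta[(WOMEN, 0.0)]) / span
    return IndicatorTrend(
        intercept=eta[(MEN, 0.0)],
        slope=slope_m,
        sex_coef=eta[(WOMEN, 0.0)] - eta[(MEN, 0.0)],
        sex_slope=slope_w - slope_m,
        age_coef=age_coef,
        obesity_coef=obesity_coef,
    )


def calibrate_bmi(shares_start: Mapping[int, tuple[float, float, float]],
                  shares_end: Mapping[int, tuple[float, float, float]],
                  span: float) -> BmiTrend:
    """Multinomial-logit BMI trend through the given per-sex category
    shares (normal, overweight, obese) at t=0 and t=span."""
    u = {}
    for sex, shares, t in ((MEN, shares_start[MEN], 0.0), (MEN, shares_end[MEN], span),
                           (WOMEN, shares_start[WOMEN], 0.0), (WOMEN, shares_end[WOMEN], span)):
        norm, ow, ob = shares
        u[(sex, t, "ow")] = np.log(ow / norm)
        u[(sex, t, "ob")] = np.log(ob / norm)
    params = {}
    for cat in ("ow", "ob"):
        sm = (u[(MEN, span, cat)] - u[(MEN, 0.0, cat)]) / span
        sw = (u[(WOMEN, span, cat)] - u[(WOMEN, 0.0, cat)]) / span
        params[cat] = (
            u[(MEN, 0.0, cat)],
            sm,
            u[(WOMEN, 0.0, cat)] - u[(MEN, 0.0, cat)],
            sw - sm,
        )
    return BmiTrend(overweight=params["ow"], obese=params["ob"])


#: mild age gradients on the logit scale (per year of age), reflecting
#: the usual epidemiology of these indicators
DEFAULT_AGE_COEFS = {
    "smoking": -0.010,
    "sedentary": 0.010,
    "hypertension": 0.060,
    "elevated_tc": 0.050,
    "diabetes": 0.070,
}

#: log-odds-ratio of diabetes / hypertension for obese vs non-obese
DEFAULT_OBESITY_COEFS = {"diabetes": 1.0, "hypertension": 0.5}


def default_nonresponse(wave_years: Sequence[int] = datasets.WAVE_YEARS,
                        item_rate: float = 0.02) -> NonresponseModel:
    """Unit non-response calibrated to the published questionnaire
    response rates; a flat per-item missingness rate among respondents
    (per-variable rates were not published)."""
    icpt = {
        sex: {y: float(logit(datasets.QUESTIONNAIRE_RESPONSE_PCT[sex][y] / 100.0))
              for y in wave_years}
        for sex in (MEN, WOMEN)
    }
    rates = {c: item_rate for c in SURVEY_COLS}
    return NonresponseModel(unit_intercepts=icpt, item_rates=rates)


def default_scenario(seed: int = 0, item_rate: float = 0.02) -> ScenarioConfig:
    """The study conditions: five waves with the published invited sizes
    and response rates, indicator trends calibrated to the published
    1997/2017 prevalences, obesity feeding diabetes and hypertension,
    HbA1c structurally missing in 1997 and 2007."""
    ep = datasets.endpoint_prevalence().set_index(["indicator", "sex"])

    def p(ind: str, col: str) -> dict[int, float]:
        return {MEN: float(ep.loc[(ind, "men"), col]),
                WOMEN: float(ep.loc[(ind, "women"), col])}

    def shares(col: str) -> dict[int, tuple[float, float, float]]:
        out = {}
        for sex, lab in ((MEN, "men"), (WOMEN, "women")):
            ow = float(ep.loc[("overweight", lab), col])
            ob = float(ep.loc[("obesity", lab), col])
            out[sex] = (1.0 - ow - ob, ow, ob)
        return out

    bmi = calibrate_bmi(shares("p_1997"), shares("p_2017"), span=20.0)
    trends = {}
    for ind in BINARY_INDICATORS:
        trends[ind] = calibrate_trend(
            p(ind, "p_1997"), p(ind, "p_2017"), 20.0, bmi,
            age_coef=DEFAULT_AGE_COEFS[ind],
            obesity_coef=DEFAULT_OBESITY_COEFS.get(ind, 0.0),
        )
    diabetes = calibrate_trend(
        p("diabetes", "p_1997"), p("diabetes", "p_2017"), 20.0, bmi,
        age_coef=DEFAULT_AGE_COEFS["diabetes"],
        obesity_coef=DEFAULT_OBESITY_COEFS["diabetes"],
    )
    return ScenarioConfig(
        trend_params=trends,
        bmi_params=bmi,
        diabetes_params=diabetes,
        nonresponse=default_nonresponse(item_rate=item_rate),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation operations

def generate_population_frame(config: ScenarioConfig, year: int) -> pd.DataFrame:
    """Sampling-frame rows for one wave: demographics filled from the
    population register, every survey-derived column empty."""
    if year not in config.wave_years:
        raise ValueError(f"year {year} is not a wave year {config.wave_years}")
    rng = _rng(config.seed, year, _STAGE_FRAME)
    parts = []
    for sex in (MEN, WOMEN):
        n = int(config.invited_n[sex][year])
        lo, hi = config.age_range
        parts.append(pd.DataFrame({
            "year": np.full(n, year, dtype=int),
            "sex": np.full(n, sex, dtype=int),
            "age": rng.integers(lo, hi + 1, size=n),
            "area": rng.integers(0, config.n_areas, size=n),
        }))
    frame = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    for col in SURVEY_COLS + ["participation"]:
        frame[col] = np.nan
    return frame[FRAME_COLS]


def simulate_indicators(frame: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Draw the survey-derived variables for every invited person.

    BMI category is drawn first so the configured obesity coefficients can
    feed diabetes and hypertension.  Diabetes status is latent: the frame
    records the medication flag and the HbA1c value that the indicator
    derivation recombines.
    """
    for col in DEMOGRAPHIC_COLS:
        if frame[col].isna().any():
            raise ValueError(f"demographic column {col!r} has missing values")
    out = frame.copy()
    year = int(out["year"].iloc[0]) if len(out) else 0
    rng = _rng(config.seed, year, _STAGE_INDICATORS)
    n = len(out)
    if n == 0:
        return out
    t = out["year"].to_numpy(dtype=float) - 1997.0
    sex = out["sex"].to_numpy()
    age = out["age"].to_numpy(dtype=float)

    out["marital"] = (rng.random(n) < config.marital_p).astype(float)
    out["education"] = rng.choice(3, size=n, p=np.asarray(config.education_probs, float)).astype(float)

    bmi = config.bmi_params
    if bmi is None:
        raise ValueError("ScenarioConfig.bmi_params is not set")
    pcat = bmi.probs(t, sex)
    u = rng.random(n)
    cum = np.cumsum(pcat, axis=1)
    out["bmi_cat"] = (u[:, None] > cum).sum(axis=1).astype(float)
    obese = (out["bmi_cat"].to_numpy() == 2).astype(float)

    for ind in BINARY_INDICATORS:
        tr = config.trend_params[ind]
        p = expit(tr.linpred(t, sex, age, obese))
        out[ind] = (rng.random(n) < p).astype(float)

    dtr = config.diabetes_params
    if dtr is None:
        raise ValueError("ScenarioConfig.diabetes_params is not set")
    p_diab = expit(dtr.linpred(t, sex, age, obese))
    diab = rng.random(n) < p_diab
    med = diab & (rng.random(n) < config.med_given_diabetes)
    out["diabetes_med"] = med.astype(float)
    hba1c = np.where(
        diab,
        48.0 + rng.exponential(8.0, size=n),
        np.minimum(rng.normal(37.0, 4.0, size=n), 47.5),
    )
    out["hba1c"] = hba1c
    out["participation"] = np.nan
    return out


def apply_nonresponse(frame: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Overlay unit non-response, item non-response and structural
    missingness.  Demographics come from the sampling frame and are never
    blanked; a boolean ``participation`` column records unit response."""
    out = frame.copy()
    n = len(out)
    if n == 0:
        return out
    year = int(out["year"].iloc[0])
    rng = _rng(config.seed, year, _STAGE_NONRESPONSE)
    sex = out["sex"].to_numpy()
    age = out["age"].to_numpy(dtype=float)
    nr = config.nonresponse
    if nr is None:
        out["participation"] = 1.0
    else:
        p_resp = nr.unit_response_prob(year, sex, age)
        respond = rng.random(n) < p_resp
        out["participation"] = respond.astype(float)
        out.loc[~respond, SURVEY_COLS] = np.nan
        for col in SURVEY_COLS:
            p_miss = nr.item_missing_prob(col, sex, age)
            drop = respond & (rng.random(n) < p_miss)
            out.loc[drop, col] = np.nan
    for (y, col) in config.structural_missing:
        if y == year and col in out.columns:
            out[col] = np.nan
    return out


def simulate_wave(config: ScenarioConfig, year: int) -> pd.DataFrame:
    """Frame -> indicators -> non-response for one wave."""
    return apply_nonresponse(
        simulate_indicators(generate_population_frame(config, year), config), config
    )


def generate_survey_data(config: ScenarioConfig) -> pd.DataFrame:
    """All waves of the scenario, concatenated."""
    waves = [simulate_wave(config, y) for y in config.wave_years]
    return pd.concat(waves, ignore_index=True)


def generate_population_projection(config: ScenarioConfig, years: Iterable[int],
                                   ageing_drift: float = 0.0) -> pd.DataFrame:
    """Per-year age x sex weight table standing in for a national
    population projection.

    With ``ageing_drift = 0`` the age distribution is uniform; a positive
    drift tilts weight towards older ages linearly in (age, elapsed
    years), emulating population ageing.  Weights are normalised to sum
    to one within each year (sexes share the year equally).
    """
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    lo, hi = config.age_range
    ages = np.arange(lo, hi + 1)
    base_year = years[0]
    rows = []
    for y in years:
        tilt = 1.0 + ageing_drift * (y - base_year) * (ages - ages.mean()) / (hi - lo + 1)
        w = np.maximum(tilt, 0.0)
        w = w / w.sum() / 2.0
        for sex in (MEN, WOMEN):
            rows.append(pd.DataFrame({"year": y, "sex": sex, "age": ages, "weight": w}))
    return pd.concat(rows, ignore_index=True)
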