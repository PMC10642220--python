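"""End-to-end prevalence projection.

The projection treats future survey waves as missing data: for each
projection year a pseudo-sample is created whose age and sex
distribution matches a population-projection table, with every
survey-derived column missing.  The pseudo-samples are appended to the
full invited samples of the observed waves, the chained-equations engine
completes the combined frame ``m`` times, and prevalences are pooled
across imputations per indicator, sex and year.  Wilson score intervals
at the pseudo-sample size serve as prediction intervals;
between-imputation variance is reported alongside, never silently
merged into the band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mice import CompletedSet, ImputationSpec, MiceConfig, run_chain
from .synthetic import FRAME_COLS, SURVEY_COLS

logger = logging.getLogger("ncdprev")

#: indicator name -> (frame column, category value for categorical ones)
INDICATOR_COLUMNS = {
    "smoking": ("smoking", None),
    "sedentary": ("sedentary", None),
    "hypertension": ("hypertension", None),
    "elevated_tc": ("elevated_tc", None),
    "diabetes": ("diabetes", None),
    "normal_weight": ("bmi_cat", 0),
    "overweight": ("bmi_cat", 1),
    "obesity": ("bmi_cat", 2),
}


@dataclass(frozen=True)
class FutureSampleSpec:
    """Pseudo-samples to append for the projection years."""

    years: tuple[int, ...]
    projection: pd.DataFrame  # columns: year, sex, age, weight
    n_per_year: int = 10_000
    mode: str = "allocate"  # "allocate" (largest remainder) | "sample"

    def __post_init__(self) -> None:
        if self.n_per_year < 1:
            raise ValueError("n_per_year must be >= 1")
        if self.mode not in ("allocate", "sample"):
            raise ValueError(f"unknown demographics mode {self.mode!r}")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts proportional to weights, summing exactly to total."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return base


def build_future_samples(spec: FutureSampleSpec,
                         rng: np.random.Generator | None = None,
                         age_range: tuple[int, int] = (25, 64),
                         columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pseudo-sample rows for each projection year with sex and age
    matched to the projection table restricted to the analysis ages;
    every survey-derived column missing."""
    proj = spec.projection
    frames = []
    for year in spec.years:
        sub = proj[(proj["year"] == year)
                   & proj["age"].between(age_range[0], age_range[1])]
        if sub.empty:
            raise ValueError(f"projection table has no rows for year {year}")
        for a in range(age_range[0], age_range[1] + 1):
            if not (sub["age"] == a).any():
                raise ValueError(f"projection table missing age {a} in year {year}")
        w = sub["weight"].to_numpy(dtype=float)
        if (w < 0).any():
            raise ValueError("projection weights must be nonnegative")
        if spec.mode == "allocate":
            counts = _largest_remainder(w, spec.n_per_year)
        else:
            if rng is None:
                raise ValueError("sampling mode needs an rng")
            counts = rng.multinomial(spec.n_per_year, w / w.sum())
        rep = np.repeat(np.arange(len(sub)), counts)
        frames.append(pd.DataFrame({
            "year": year,
            "sex": sub["sex"].to_numpy()[rep],
            "age": sub["age"].to_numpy()[rep],
        }))
    out = pd.concat(frames, ignore_index=True)
    schema = list(columns) if columns is not None else FRAME_COLS
    for col in [c for c in schema if c not in out.columns]:
        out[col] = np.nan
    return out[schema]


def assemble_joint_frame(observed: pd.DataFrame, future: pd.DataFrame) -> pd.DataFrame:
    """Concatenate observed invited samples and future pseudo-samples,
    tagging the origin of each row in a ``source`` column."""
    obs_cols = [c for c in observed.columns if c != "source"]
    fut_cols = [c for c in future.columns if c != "source"]
    if set(obs_cols) != set(fut_cols):
        diff = sorted(set(obs_cols) ^ set(fut_cols))
        raise ValueError(f"column schemas differ: {diff}")
    observed = observed[obs_cols].copy()
    future = future[obs_cols].copy()
    observed["source"] = "observed"
    future["source"] = "future"
    return pd.concat([observed, future], ignore_index=True)


def wilson_interval(p: float, n: float, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    centre = (p + z^2/2n) / (1 + z^2/n);
    half-width = z * sqrt(p(1-p)/n + z^2/(4n^2)) / (1 + z^2/n).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = norm.ppf((1.0 + level) / 2.0)
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # the score interval is bounded by [0, 1]; clamp rounding spill
    return float(max(centre - half, 0.0)), float(min(centre + half, 1.0))


def pool_prevalence(completed: CompletedSet, indicator: str,
                    level: float = 0.95,
                    last_observed_year: int | None = None) -> pd.DataFrame:
    """Pool one indicator's prevalence over the ``m`` completed frames.

    Per (sex, year) stratum the point estimate is the mean over
    imputations of the within-imputation proportion; the stratum row
    count enters the Wilson interval; the between-imputation variance of
    the proportions is reported alongside.
    """
    col, category = INDICATOR_COLUMNS[indicator]
    if col not in completed.frames[0].columns:
        raise ValueError(f"column {col!r} absent from the completed frames")
    per_imp = []
    for f in completed.frames:
        vals = f[col].to_numpy(dtype=float)
        hit = (vals == category) if category is not None else (vals == 1.0)
        g = pd.DataFrame({"sex": f["sex"], "year": f["year"], "hit": hit.astype(float)})
        per_imp.append(g.groupby(["sex", "year"])["hit"].agg(["mean", "size"]))
    stacked = pd.concat(per_imp, keys=range(len(per_imp)), names=["imputation"])
    pooled = stacked.groupby(["sex", "year"]).agg(
        prevalence=("mean", "mean"),
        between_var=("mean", "var"),
        n_eff=("size", "first"),
    ).reset_index()
    lows, highs = zip(*(wilson_interval(p, n, level)
                        for p, n in zip(pooled["prevalence"], pooled["n_eff"])))
    pooled["interval_low"] = lows
    pooled["interval_high"] = highs
    pooled["indicator"] = indicator
    if last_observed_year is not None:
        pooled["source"] = np.where(pooled["year"] <= last_observed_year,
                                    "observed-imputed", "projected")
    else:
        pooled["source"] = "observed-imputed"
    cols = ["indicator", "sex", "year", "prevalence", "interval_low",
            "interval_high", "n_eff", "between_var", "source"]
    return pooled[cols]


def pool_all(completed: CompletedSet, indicators: Sequence[str],
             level: float = 0.95,
             last_observed_year: int | None = None) -> pd.DataFrame:
    series = [pool_prevalence(completed, ind, level, last_observed_year)
              for ind in indicators]
    return pd.concat(series, ignore_index=True)


def run_projection(observed: pd.DataFrame, specs: Sequence[ImputationSpec],
                   future_spec: FutureSampleSpec, mice_config: MiceConfig,
                   indicators: Sequence[str] | None = None,
                   level: float = 0.95) -> tuple[pd.DataFrame, CompletedSet]:
    """Assemble -> impute -> pool -> Wilson intervals.

    Returns the prevalence series (observed-imputed and projected years)
    and the completed set for diagnostics.
    """
    last_obs = int(observed["year"].max())
    for y in future_spec.years:
        if y <= last_obs:
            raise ValueError(f"projection year {y} not after last observed wave {last_obs}")
    rng = np.random.default_rng(np.random.SeedSequence(mice_config.seed,
                                                       spawn_key=(99,)))
    future = build_future_samples(
        future_spec, rng, columns=[c for c in observed.columns if c != "source"])
    joint = assemble_joint_frame(observed, future)
    logger.info("joint frame: %d observed + %d future rows", len(observed), len(future))
    completed = run_chain(joint, specs, mice_config)
    if indicators is None:
        targets = {s.target for s in specs}
        indicators = [name for name, (col, _) in INDICATOR_COLUMNS.items()
                      if col in targets]
    series = pool_all(completed, indicators, level, last_observed_year=last_obs)
    return series, completed
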