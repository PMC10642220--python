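"""Design-matrix construction shared by the imputation engine and model
selection: dummy coding of categorical covariates, linear or restricted
cubic spline handling of the survey-year term, and the spline basis
itself.

The restricted (natural) cubic spline basis follows the standard
truncated-power construction: ``k`` knots give ``k - 1`` columns, the
first of which is the untransformed variable, and every column is exactly
linear beyond the boundary knots.  Linearity in the tails is what makes
the basis safe for extrapolating secular trends beyond the observed
survey years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: categorical variables and their category counts; everything else is
#: treated as numeric (binary indicators enter as 0/1).
CATEGORICAL_LEVELS = {"area": 5, "education": 3, "bmi_cat": 3}

YEAR_ORIGIN = 1997.0
YEAR_SCALE = 10.0  # year enters models as (year - origin) / scale


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis.

    Parameters
    ----------
    x
        Values at which to evaluate the basis.
    knots
        At least three strictly increasing knot locations.

    Returns
    -------
    (len(x), len(knots) - 1) array whose first column is ``x`` itself.
    """
    t = np.asarray(knots, dtype=float)
    if t.size < 3:
        raise ValueError("restricted cubic spline needs at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    x = np.asarray(x, dtype=float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2

    def plus3(v: np.ndarray, knot: float) -> np.ndarray:
        return np.maximum(v - knot, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        cj = (
            plus3(x, t[j])
            - plus3(x, t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x, t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / scale
        cols.append(cj)
    return np.column_stack(cols)


@dataclass(frozen=True)
class YearTerm:
    """How the survey-year covariate enters a model."""

    form: str = "linear"  # "linear" | "spline"
    knots: tuple[float, ...] = ()  # calendar years; required for "spline"

    def __post_init__(self) -> None:
        if self.form not in ("linear", "spline"):
            raise ValueError(f"unknown year form {self.form!r}")
        if self.form == "spline" and len(self.knots) < 3:
            raise ValueError("spline year form needs >= 3 knots")

    def n_columns(self) -> int:
        return 1 if self.form == "linear" else len(self.knots) - 1


def default_year_knots(years: Sequence[float]) -> tuple[float, ...]:
    """Three knots at the 10th/50th/90th percentiles of the observed
    survey years (for five equally spaced waves: the first, middle and
    last wave)."""
    y = np.asarray(sorted(set(float(v) for v in years)))
    q = np.quantile(y, [0.10, 0.50, 0.90])
    return tuple(float(v) for v in q)


@dataclass
class DesignInfo:
    names: list[str]
    matrix: np.ndarray


def _scaled_year(year: np.ndarray) -> np.ndarray:
    return (np.asarray(year, dtype=float) - YEAR_ORIGIN) / YEAR_SCALE


def build_design(
    frame: pd.DataFrame,
    predictors: Sequence[str],
    year_term: YearTerm | None = None,
) -> DesignInfo:
    """Assemble an intercept-first design matrix from named predictors.

    ``"year"`` in *predictors* is expanded according to *year_term*
    (default linear); categorical predictors are dummy coded against
    their first level; all other predictors enter as numeric columns.
    Rows with missing predictor values yield NaNs, which callers mask.
    """
    year_term = year_term or YearTerm()
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for p in predictors:
        if p == "year":
            ys = _scaled_year(frame["year"].to_numpy())
            if year_term.form == "linear":
                cols.append(ys)
                names.append("year")
            else:
                knots = tuple(_scaled_year(np.asarray(year_term.knots)))
                basis = rcs_basis(ys, knots)
                for j in range(basis.shape[1]):
                    cols.append(basis[:, j])
                    names.append("year" if j == 0 else f"year_rcs{j}")
        elif p in CATEGORICAL_LEVELS:
            vals = frame[p].to_numpy(dtype=float)
            for level in range(1, CATEGORICAL_LEVELS[p]):
                col = np.where(np.isnan(vals), np.nan, (vals == level).astype(float))
                cols.append(col)
                names.append(f"{p}[{level}]")
        elif p == "age":
            cols.append((frame["age"].to_numpy(dtype=float) - 45.0) / 10.0)
            names.append("age")
        else:
            cols.append(frame[p].to_numpy(dtype=float))
            names.append(p)
    return DesignInfo(names=names, matrix=np.column_stack(cols))
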