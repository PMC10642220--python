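"""Choice of imputation models by the Bayesian information criterion.

For each risk-factor target, candidate models combine a mandatory core
(age, sex, survey year) with optional predictors (area, marital status,
education, the other risk factors).  Candidates are fitted on the
complete cases of the observed waves and scored by
``BIC = k ln(n) - 2 ln(L)``; the minimum-BIC predictor set wins, and the
functional form of the year effect -- linear versus restricted cubic
spline -- is then chosen by a second BIC comparison within the winning
set.  Scoring contains no randomness, so selection is deterministic
given the data; ties (within 1e-9) go to the smaller model, then to
lexicographic predictor order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .formula import CATEGORICAL_LEVELS, YearTerm, build_design, default_year_knots
from .mice import BinaryFit, ImputationSpec, PolytomousFit, fit_binary_model, fit_polytomous_model

logger = logging.getLogger("ncdprev")

BIC_TIE_TOL = 1e-9


@dataclass(frozen=True)
class CandidateSpace:
    """Search space for one target's imputation model."""

    target: str
    mandatory: tuple[str, ...] = ("age", "sex", "year")
    optional: tuple[str, ...] = ()
    spline_knots: int = 3

    def __post_init__(self) -> None:
        if self.target in self.optional or self.target in self.mandatory:
            raise ValueError(f"target {self.target!r} cannot be its own predictor")
        if self.spline_knots < 3:
            raise ValueError("restricted cubic spline needs >= 3 knots")


def bic(fit: BinaryFit | PolytomousFit) -> float:
    """Bayesian information criterion, k ln(n) - 2 ln(L)."""
    if fit.n <= 0:
        raise ValueError("sample size must be positive")
    return fit.k * np.log(fit.n) - 2.0 * fit.llf


def _fit(target: str, data: pd.DataFrame, predictors: Sequence[str],
         year_term: YearTerm):
    design = build_design(data, predictors, year_term)
    y = data[target].to_numpy(dtype=float)
    if target in CATEGORICAL_LEVELS:
        return fit_polytomous_model(y, design.matrix, design.names,
                                    CATEGORICAL_LEVELS[target])
    return fit_binary_model(y, design.matrix, design.names)


def select_spec(target: str, space: CandidateSpace, data: pd.DataFrame,
                exhaustive: bool = True) -> tuple[ImputationSpec, pd.DataFrame]:
    """Minimum-BIC imputation spec for *target* on complete-case data
    from the observed waves.

    Returns the chosen spec and the full BIC table.  The default search
    is exhaustive over optional-predictor subsets (at most 2^8 here,
    cheap and path-independent); a forward-stepwise search is available
    for larger optional sets.
    """
    cc = data.dropna(subset=[target, *space.mandatory, *space.optional])
    largest_k = 1 + len(space.mandatory) + sum(
        CATEGORICAL_LEVELS.get(p, 2) - 1 for p in space.optional)
    if len(cc) <= 10 * largest_k:
        raise ValueError(
            f"only {len(cc)} complete cases for up to {largest_k} parameters")
    linear = YearTerm("linear")
    records = []

    def score(opts: tuple[str, ...], year_term: YearTerm) -> float:
        preds = tuple(space.mandatory) + opts
        fit = _fit(target, cc, preds, year_term)
        val = bic(fit)
        records.append({"target": target, "optional": ",".join(opts),
                        "year_form": year_term.form, "bic": val,
                        "k": fit.k, "n": fit.n})
        return val

    if exhaustive:
        subsets = [tuple(sorted(c)) for r in range(len(space.optional) + 1)
                   for c in itertools.combinations(sorted(space.optional), r)]
        scores = {opts: score(opts, linear) for opts in subsets}
        # tie-break: smaller model, then lexicographic predictor order
        best_val = min(scores.values())
        tied = [o for o, v in scores.items() if v <= best_val + BIC_TIE_TOL]
        best_opts = min(tied, key=lambda o: (len(o), o))
    else:
        best_opts: tuple[str, ...] = ()
        best_val = score(best_opts, linear)
        improved = True
        while improved:
            improved = False
            for cand in sorted(set(space.optional) - set(best_opts)):
                trial = tuple(sorted(best_opts + (cand,)))
                val = score(trial, linear)
                if val < best_val - BIC_TIE_TOL:
                    best_opts, best_val = trial, val
                    improved = True

    knots = default_year_knots(cc["year"].unique())
    if space.spline_knots != 3:
        qs = np.linspace(0.05, 0.95, space.spline_knots)
        knots = tuple(float(v) for v in np.quantile(sorted(cc["year"].unique()), qs))
    spline = YearTerm("spline", knots)
    lin_bic = _fit_score(records, target, cc, space.mandatory, best_opts, linear)
    spl_bic = _fit_score(records, target, cc, space.mandatory, best_opts, spline)
    year_term = spline if spl_bic < lin_bic - BIC_TIE_TOL else linear
    logger.info("selected for %s: optional=%s year=%s (BIC linear %.2f, spline %.2f)",
                target, best_opts, year_term.form, lin_bic, spl_bic)
    spec = ImputationSpec(
        target=target,
        sampler="polytomous" if target in CATEGORICAL_LEVELS else "logistic",
        predictors=tuple(space.mandatory) + best_opts,
        year_term=year_term,
    )
    return spec, pd.DataFrame(records)


def _fit_score(records: list, target: str, cc: pd.DataFrame,
               mandatory: Sequence[str], opts: tuple[str, ...],
               year_term: YearTerm) -> float:
    fit = _fit(target, cc, tuple(mandatory) + opts, year_term)
    val = bic(fit)
    records.append({"target": target, "optional": ",".join(opts),
                    "year_form": year_term.form, "bic": val,
                    "k": fit.k, "n": fit.n})
    return val


def select_all_specs(data: pd.DataFrame, targets: Sequence[str],
                     covariates: Sequence[str] = ("area", "marital", "education"),
                     exhaustive: bool = True) -> tuple[list[ImputationSpec], pd.DataFrame]:
    """Run model selection for every risk-factor target: the optional
    set for each target is the covariates plus the other targets."""
    specs, tables = [], []
    for tgt in targets:
        optional = tuple(c for c in covariates if c in data.columns) + tuple(
            t for t in targets if t != tgt)
        space = CandidateSpace(target=tgt, optional=optional)
        spec, table = select_spec(tgt, space, data, exhaustive=exhaustive)
        specs.append(spec)
        tables.append(table)
    return specs, pd.concat(tables, ignore_index=True)
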