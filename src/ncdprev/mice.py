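"""Fully-conditional-specification (chained equations) multiple
imputation with logistic and polytomous-logistic samplers.

This is the computational core of the package.  A frame with missing
binary/categorical cells -- item non-response, unit non-response, and
entire future pseudo-samples -- is completed ``m`` times.  Each
imputation stream initialises missing cells by resampling observed
values (within sex stratum), then cycles ``iterations`` times through
the incomplete variables in visit order; on each visit the conditional
model is refitted on the originally-observed rows given the current
state of the other variables, a parameter vector is drawn to propagate
estimation uncertainty (proper imputation), and the missing cells are
redrawn from the resulting predictive distribution.

Maximum-likelihood fits are delegated to statsmodels (Logit / MNLogit);
separation or rank deficiency -- likely once sparse future pseudo-cells
enter -- triggers a logged ridge-penalised refit instead of an abort.
The year covariate enters every model as a continuous term (linear or
restricted cubic spline), so fits on the observed waves extrapolate to
projection years; the spline basis is linear beyond its boundary knots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .formula import CATEGORICAL_LEVELS, YearTerm, build_design

logger = logging.getLogger("ncdprev")

RIDGE_SCALE = 1e-4  # ridge penalty per observation when the MLE fails


@dataclass(frozen=True)
class ImputationSpec:
    """Conditional model for one incomplete variable."""

    target: str
    sampler: str  # "logistic" | "polytomous"
    predictors: tuple[str, ...]
    year_term: YearTerm = YearTerm()
    visit_rank: int | None = None  # None -> ordered by missingness

    def __post_init__(self) -> None:
        if self.sampler not in ("logistic", "polytomous"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if self.target in self.predictors:
            raise ValueError(f"{self.target!r} cannot predict itself")
        if self.sampler == "logistic" and self.target in CATEGORICAL_LEVELS:
            raise ValueError(f"{self.target!r} is categorical; use the polytomous sampler")
        if self.sampler == "polytomous" and self.target not in CATEGORICAL_LEVELS:
            raise ValueError(f"{self.target!r} is binary; use the logistic sampler")


@dataclass(frozen=True)
class MiceConfig:
    """Run-level settings for one multiple-imputation run."""

    m: int = 100
    iterations: int = 10
    seed: int = 0
    binary_draw: str = "posterior"  # "posterior" | "bootstrap"
    polytomous_draw: str = "bootstrap"

    def __post_init__(self) -> None:
        if self.m < 1 or self.iterations < 1:
            raise ValueError("m and iterations must be >= 1")
        for mode in (self.binary_draw, self.polytomous_draw):
            if mode not in ("posterior", "bootstrap"):
                raise ValueError(f"unknown parameter-draw mode {mode!r}")


@dataclass
class BinaryFit:
    """Logit fit summary sufficient for BIC scoring and posterior draws."""

    params: np.ndarray
    cov: np.ndarray
    llf: float
    k: int
    n: int
    names: list[str]
    separation: bool = False
    ridge: float = 0.0


@dataclass
class PolytomousFit:
    """Multinomial-logit fit (reference category 0); params has shape
    (n_features, n_categories - 1)."""

    params: np.ndarray
    cov: np.ndarray | None
    llf: float
    k: int
    n: int
    names: list[str]
    n_categories: int
    separation: bool = False
    ridge: float = 0.0


# ---------------------------------------------------------------------------
# binary (logistic) sampler

def _ridge_logit(y: np.ndarray, X: np.ndarray, lam: float,
                 max_iter: int = 100, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Newton solver for an L2-penalised logit (intercept unpenalised).

    Returns (params, covariance = inverse penalised information).
    """
    n, p = X.shape
    pen = np.full(p, lam)
    pen[0] = 0.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    hess = (X * w[:, None]).T @ X + np.diag(pen)
    return beta, np.linalg.inv(hess)


def _bernoulli_llf(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_binary_model(y: np.ndarray, X: np.ndarray,
                     names: Sequence[str] | None = None) -> BinaryFit:
    """Maximum-likelihood logistic fit on the rows where the outcome and
    all predictors are observed; covariance is the inverse observed
    information.  Separation or rank deficiency is flagged and resolved
    by a logged ridge refit rather than an abort."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    yo, Xo = y[mask], X[mask]
    n, p = Xo.shape
    if n == 0:
        raise ValueError("no complete cases to fit on")
    degenerate = (yo.min() == yo.max()) or np.linalg.matrix_rank(Xo) < p
    fit_params = cov = None
    separation = False
    if not degenerate:
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation is handled below
                res = sm.Logit(yo, Xo).fit(disp=0, method="newton", maxiter=50)
            if res.mle_retvals.get("converged", False) and np.max(np.abs(res.params)) < 50:
                fit_params = np.asarray(res.params)
                cov = np.asarray(res.cov_params())
            else:
                separation = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
    ridge = 0.0
    if fit_params is None:
        separation = True
        ridge = RIDGE_SCALE * n
        logger.info("logit fit degenerate (n=%d, k=%d): ridge fallback lambda=%.3g",
                    n, p, ridge)
        fit_params, cov = _ridge_logit(yo, Xo, ridge)
    llf = _bernoulli_llf(yo, Xo @ fit_params)
    return BinaryFit(params=fit_params, cov=cov, llf=llf, k=p, n=n,
                     names=names, separation=separation, ridge=ridge)


def _nearest_pd_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor of cov, repairing non-positive-definiteness by
    clipping eigenvalues (logged)."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        logger.info("covariance not positive definite; eigenvalue clip applied")
        vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
        vals = np.clip(vals, 1e-12, None)
        return np.linalg.cholesky(vecs @ np.diag(vals) @ vecs.T)


def draw_parameters(fit: BinaryFit, rng: np.random.Generator,
                    mode: str = "posterior",
                    refit: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """One proper-imputation parameter draw.

    ``posterior``: multivariate normal centred at the MLE with the fit's
    covariance.  ``bootstrap``: coefficients refitted on a resample of
    the complete cases (*refit* supplies (y, X) of the complete cases).
    """
    if mode == "posterior":
        if np.allclose(fit.cov, 0.0):
            return fit.params.copy()
        L = _nearest_pd_cholesky(fit.cov)
        return fit.params + L @ rng.standard_normal(fit.params.shape[0])
    if mode == "bootstrap":
        if refit is None:
            raise ValueError("bootstrap draw needs the complete-case (y, X)")
        y, X = refit
        idx = rng.integers(0, len(y), size=len(y))
        return fit_binary_model(y[idx], X[idx], fit.names).params
    raise ValueError(f"unknown draw mode {mode!r}")


def impute_binary(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Fill the missing cells of a binary vector by Bernoulli draws at
    the drawn parameters; observed cells untouched."""
    y = np.asarray(y, dtype=float).copy()
    missing = np.isnan(y)
    if missing.any():
        p = expit(X[missing] @ beta)
        y[missing] = (rng.random(missing.sum()) < p).astype(float)
    return y


# ---------------------------------------------------------------------------
# polytomous (multinomial-logit) sampler

def fit_polytomous_model(y: np.ndarray, X: np.ndarray,
                         names: Sequence[str] | None = None,
                         n_categories: int | None = None) -> PolytomousFit:
    """Multinomial-logit fit on complete cases, category 0 as reference
    (its log-odds are identically zero)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    yo, Xo = y[mask].astype(int), X[mask]
    n, p = Xo.shape
    if n == 0:
        raise ValueError("no complete cases to fit on")
    J = int(n_categories if n_categories is not None else yo.max() + 1)
    counts = np.bincount(yo, minlength=J)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise ValueError(f"category {empty[0]} has no complete cases")
    separation = False
    ridge = 0.0
    try:
        res = sm.MNLogit(yo, Xo).fit(disp=0, method="newton", maxiter=50)
        converged = res.mle_retvals.get("converged", False)
        params = np.asarray(res.params)  # (p, J-1)
        if not converged or np.max(np.abs(params)) >= 50:
            raise PerfectSeparationError
        cov = np.asarray(res.cov_params())
        llf = float(res.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        separation = True
        ridge = RIDGE_SCALE * n
        logger.info("multinomial fit degenerate (n=%d): one-vs-reference ridge fallback", n)
        params = np.column_stack([
            _ridge_logit((yo == j).astype(float)[np.isin(yo, [0, j])],
                         Xo[np.isin(yo, [0, j])], ridge)[0]
            for j in range(1, J)
        ])
        cov = None
        llf = _multinomial_llf(yo, Xo, params)
    return PolytomousFit(params=params, cov=cov, llf=llf, k=p * (J - 1), n=n,
                         names=names, n_categories=J, separation=separation,
                         ridge=ridge)


def _category_probs(X: np.ndarray, params: np.ndarray) -> np.ndarray:
    """(n, J) softmax probabilities with reference-category utility 0."""
    util = np.hstack([np.zeros((X.shape[0], 1)), X @ params])
    util -= util.max(axis=1, keepdims=True)
    e = np.exp(util)
    return e / e.sum(axis=1, keepdims=True)


def _multinomial_llf(y: np.ndarray, X: np.ndarray, params: np.ndarray) -> float:
    pr = _category_probs(X, params)
    return float(np.sum(np.log(np.maximum(pr[np.arange(len(y)), y], 1e-300))))


def draw_polytomous_parameters(fit: PolytomousFit, rng: np.random.Generator,
                               mode: str = "bootstrap",
                               refit: tuple[np.ndarray, np.ndarray] | None = None
                               ) -> np.ndarray:
    """Parameter draw for the multinomial sampler: bootstrap-refit
    (default) or multivariate normal around the MLE."""
    if mode == "bootstrap":
        if refit is None:
            raise ValueError("bootstrap draw needs the complete-case (y, X)")
        y, X = refit
        idx = rng.integers(0, len(y), size=len(y))
        # resample until every category appears (rare failure at small n)
        for _ in range(100):
            if np.isin(np.arange(fit.n_categories), y[idx]).all():
                break
            idx = rng.integers(0, len(y), size=len(y))
        return fit_polytomous_model(y[idx], X[idx], fit.names,
                                    fit.n_categories).params
    if mode == "posterior":
        if fit.cov is None:
            return fit.params.copy()
        flat = fit.params.flatten(order="F")
        L = _nearest_pd_cholesky(fit.cov)
        draw = flat + L @ rng.standard_normal(flat.shape[0])
        return draw.reshape(fit.params.shape, order="F")
    raise ValueError(f"unknown draw mode {mode!r}")


def impute_polytomous(y: np.ndarray, X: np.ndarray, params: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Fill missing cells of a categorical vector from the predicted
    category distribution at the drawn parameters."""
    y = np.asarray(y, dtype=float).copy()
    missing = np.isnan(y)
    if missing.any():
        pr = _category_probs(X[missing], params)
        u = rng.random((missing.sum(), 1))
        y[missing] = (u > np.cumsum(pr, axis=1)).sum(axis=1).astype(float)
    return y


# ---------------------------------------------------------------------------
# the chain

@dataclass
class CompletedSet:
    """The ``m`` completed copies of the frame plus run metadata."""

    frames: list[pd.DataFrame]
    specs: list[ImputationSpec]
    config: MiceConfig
    chain_stats: pd.DataFrame  # columns: imputation, iteration, target, imputed_mean

    @property
    def m(self) -> int:
        return len(self.frames)

    def imputed_cell_means(self, target: str) -> np.ndarray:
        """Per-imputation mean of the cells that were originally missing
        (diagnostic for between-imputation variability)."""
        last = self.chain_stats[self.chain_stats["target"] == target]
        last = last[last["iteration"] == last["iteration"].max()]
        return last.sort_values("imputation")["imputed_mean"].to_numpy()


def _visit_order(specs: Sequence[ImputationSpec], frame: pd.DataFrame) -> list[ImputationSpec]:
    frac = {s.target: float(frame[s.target].isna().mean()) for s in specs}
    return sorted(specs, key=lambda s: (s.visit_rank if s.visit_rank is not None else 10**6,
                                        frac[s.target], s.target))


def _validate_specs(frame: pd.DataFrame, specs: Sequence[ImputationSpec]) -> None:
    targets = {s.target for s in specs}
    for s in specs:
        if s.target not in frame.columns:
            raise ValueError(f"target {s.target!r} not in frame")
        for p in s.predictors:
            if p == "year":
                continue
            if p not in frame.columns:
                raise ValueError(f"predictor {p!r} of {s.target!r} not in frame")
            if frame[p].isna().any() and p not in targets:
                raise ValueError(
                    f"predictor {p!r} of {s.target!r} has missing values but no spec")


def _initial_fill(col: np.ndarray, sex: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Start the chain by resampling observed values within sex stratum."""
    out = col.copy()
    missing = np.isnan(col)
    for s in np.unique(sex):
        sel = (sex == s) & missing
        pool = col[(sex == s) & ~missing]
        if pool.size == 0:
            pool = col[~missing]
        if pool.size == 0:
            raise ValueError("variable has no observed values at all")
        out[sel] = rng.choice(pool, size=sel.sum(), replace=True)
    return out


def run_chain(frame: pd.DataFrame, specs: Sequence[ImputationSpec],
              config: MiceConfig) -> CompletedSet:
    """Run the chained-equations imputation and return the ``m``
    completed datasets.

    Observed cells are never modified; only originally-missing cells
    differ between the returned copies.  Per-iteration means of the
    imputed cells are recorded for convergence diagnostics.
    """
    specs = list(specs)
    _validate_specs(frame, specs)
    order = _visit_order(specs, frame)
    miss_mask = {s.target: frame[s.target].isna().to_numpy() for s in specs}
    sex = frame["sex"].to_numpy()
    base_cols = {s.target: frame[s.target].to_numpy(dtype=float) for s in specs}
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.m)

    frames: list[pd.DataFrame] = []
    stats: list[tuple[int, int, str, float]] = []
    for mi in range(config.m):
        rng = np.random.default_rng(streams[mi])
        work = frame.copy()
        for s in order:
            work[s.target] = _initial_fill(base_cols[s.target], sex, rng)
        for it in range(config.iterations):
            for s in order:
                y_obs_mask = ~miss_mask[s.target]
                design = build_design(work, s.predictors, s.year_term)
                X = design.matrix
                y_for_fit = np.where(y_obs_mask, base_cols[s.target], np.nan)
                if s.sampler == "logistic":
                    fit = fit_binary_model(y_for_fit, X, design.names)
                    cc = ~np.isnan(y_for_fit) & ~np.isnan(X).any(axis=1)
                    beta = draw_parameters(fit, rng, config.binary_draw,
                                           refit=(y_for_fit[cc], X[cc]))
                    filled = impute_binary(y_for_fit, X, beta, rng)
                else:
                    J = CATEGORICAL_LEVELS[s.target]
                    fit = fit_polytomous_model(y_for_fit, X, design.names, J)
                    cc = ~np.isnan(y_for_fit) & ~np.isnan(X).any(axis=1)
                    params = draw_polytomous_parameters(
                        fit, rng, config.polytomous_draw,
                        refit=(y_for_fit[cc].astype(int), X[cc]))
                    filled = impute_polytomous(y_for_fit, X, params, rng)
                work[s.target] = filled
                if miss_mask[s.target].any():
                    stats.append((mi, it, s.target,
                                  float(filled[miss_mask[s.target]].mean())))
        frames.append(work)
    chain_stats = pd.DataFrame(stats, columns=["imputation", "iteration",
                                               "target", "imputed_mean"])
    return CompletedSet(frames=frames, specs=specs, config=config,
                        chain_stats=chain_stats)
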