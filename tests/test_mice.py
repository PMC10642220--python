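"""The chained-equations engine: samplers, parameter draws, and the
chain's statistical guarantees (observed-cell immutability, MCAR
neutrality, proper between-imputation variability, stable chains)."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ncdprev.mice import (
    ImputationSpec,
    MiceConfig,
    _category_probs,
    draw_parameters,
    draw_polytomous_parameters,
    fit_binary_model,
    fit_polytomous_model,
    impute_binary,
    impute_polytomous,
    run_chain,
)


class TestBinaryFit:
    def test_intercept_only_closed_form(self):
        y = np.repeat([1.0, 0.0], [30, 70])
        fit = fit_binary_model(y, np.ones((100, 1)))
        assert fit.params[0] == pytest.approx(logit(0.3), abs=1e-6)
        assert fit.n == 100 and fit.k == 1
        assert not fit.separation

    def test_recovers_known_coefficients(self, rng):
        n = 5000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([-0.5, 1.2])
        y = (rng.random(n) < expit(X @ beta)).astype(float)
        fit = fit_binary_model(y, X)
        se = np.sqrt(np.diag(fit.cov))
        assert np.all(np.abs(fit.params - beta) < 3 * se)

    def test_perfect_separation_flagged_and_resolved(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = (x > 0).astype(float)  # perfectly separable
        fit = fit_binary_model(y, np.column_stack([np.ones(n), x]))
        assert fit.separation
        assert fit.ridge > 0
        assert np.isfinite(fit.params).all()

    def test_complete_case_masking(self, rng):
        y = np.array([1.0, 0.0, np.nan, 1.0])
        X = np.ones((4, 1))
        fit = fit_binary_model(y, X)
        assert fit.n == 3


class TestDrawParameters:
    def test_degenerate_covariance_returns_mle(self, rng):
        fit = fit_binary_model(np.repeat([1.0, 0.0], [30, 70]), np.ones((100, 1)))
        fit.cov = np.zeros((1, 1))
        np.testing.assert_array_equal(draw_parameters(fit, rng), fit.params)

    def test_draws_match_fit_moments(self):
        rng = np.random.default_rng(77)
        y = np.repeat([1.0, 0.0], [300, 700])
        X = np.ones((1000, 1))
        fit = fit_binary_model(y, X)
        draws = np.array([draw_parameters(fit, rng)[0] for _ in range(10_000)])
        se = np.sqrt(fit.cov[0, 0])
        assert abs(draws.mean() - fit.params[0]) < 3 * se / np.sqrt(10_000) * 1.1
        assert draws.var() == pytest.approx(fit.cov[0, 0], rel=0.1)

    def test_seeded_draw_reproducible(self):
        y = np.repeat([1.0, 0.0], [40, 60])
        fit = fit_binary_model(y, np.ones((100, 1)))
        a = draw_parameters(fit, np.random.default_rng(5))
        b = draw_parameters(fit, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_bootstrap_mode(self, rng):
        y = np.repeat([1.0, 0.0], [40, 60])
        X = np.ones((100, 1))
        fit = fit_binary_model(y, X)
        d = draw_parameters(fit, rng, mode="bootstrap", refit=(y, X))
        assert np.isfinite(d).all()


class TestImputeBinary:
    def test_saturating_intercept_gives_all_ones(self, rng):
        y = np.full(50, np.nan)
        X = np.ones((50, 1))
        out = impute_binary(y, X, np.array([30.0]), rng)
        assert (out == 1.0).all()

    def test_fair_coin_rate(self):
        rng = np.random.default_rng(3)
        y = np.full(10_000, np.nan)
        out = impute_binary(y, np.ones((10_000, 1)), np.array([0.0]), rng)
        assert 0.485 <= out.mean() <= 0.515

    def test_no_missing_is_identity(self, rng):
        y = np.array([0.0, 1.0, 1.0])
        out = impute_binary(y, np.ones((3, 1)), np.array([5.0]), rng)
        np.testing.assert_array_equal(out, y)


class TestPolytomous:
    def test_uniform_model_imputes_uniform_shares(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([np.tile([0.0, 1.0, 2.0], 400),
                            np.full(6000, np.nan)])
        X = np.ones((len(y), 1))
        fit = fit_polytomous_model(y, X, n_categories=3)
        out = impute_polytomous(y, X, fit.params, rng)
        shares = np.bincount(out[-6000:].astype(int), minlength=3) / 6000
        assert np.all(np.abs(shares - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 6000))

    def test_probabilities_normalised(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        params = rng.standard_normal((2, 2))
        pr = _category_probs(X, params)
        np.testing.assert_allclose(pr.sum(axis=1), 1.0, atol=1e-12)

    def test_reference_category_parameterisation(self):
        # utilities are measured against category 0: params has J-1 columns
        y = np.tile([0.0, 1.0, 2.0], 100)
        fit = fit_polytomous_model(y, np.ones((300, 1)), n_categories=3)
        assert fit.params.shape == (1, 2)

    def test_empty_category_named_in_error(self):
        y = np.tile([0.0, 2.0], 50)
        with pytest.raises(ValueError, match="category 1"):
            fit_polytomous_model(y, np.ones((100, 1)), n_categories=3)

    def test_bootstrap_draw_finite(self, rng):
        y = np.tile([0.0, 1.0, 2.0], 60).astype(float)
        X = np.ones((180, 1))
        fit = fit_polytomous_model(y, X, n_categories=3)
        d = draw_polytomous_parameters(fit, rng, refit=(y.astype(int), X))
        assert d.shape == fit.params.shape and np.isfinite(d).all()


def _mcar_frame(rng, n=2000, waves=(1997, 2002, 2007, 2012, 2017),
                p=0.3, miss=0.3):
    frames = []
    for y in waves:
        frames.append(pd.DataFrame({
            "year": y,
            "sex": rng.integers(0, 2, n),
            "age": rng.integers(25, 65, n),
            "smoking": (rng.random(n) < p).astype(float),
        }))
    frame = pd.concat(frames, ignore_index=True)
    truth = frame["smoking"].copy()
    mask = rng.random(len(frame)) < miss
    frame.loc[mask, "smoking"] = np.nan
    return frame, truth


class TestRunChain:
    SPEC = ImputationSpec("smoking", "logistic", ("age", "sex", "year"))

    def test_zero_missing_returns_identical_copies(self, rng):
        frame, _ = _mcar_frame(rng, n=200, miss=0.0)
        out = run_chain(frame, [self.SPEC], MiceConfig(m=3, iterations=2, seed=1))
        for f in out.frames:
            pd.testing.assert_frame_equal(f, frame)

    def test_observed_cells_never_modified(self, rng):
        frame, _ = _mcar_frame(rng, n=500)
        observed = frame["smoking"].notna()
        out = run_chain(frame, [self.SPEC], MiceConfig(m=3, iterations=3, seed=2))
        for f in out.frames:
            np.testing.assert_array_equal(
                f.loc[observed, "smoking"].to_numpy(),
                frame.loc[observed, "smoking"].to_numpy())
            assert f["smoking"].notna().all()

    def test_same_seed_reproducible_different_seed_differs_only_in_missing(self, rng):
        frame, _ = _mcar_frame(rng, n=400)
        cfg = MiceConfig(m=2, iterations=3, seed=5)
        a = run_chain(frame, [self.SPEC], cfg)
        b = run_chain(frame, [self.SPEC], cfg)
        for fa, fb in zip(a.frames, b.frames):
            pd.testing.assert_frame_equal(fa, fb)
        c = run_chain(frame, [self.SPEC], MiceConfig(m=2, iterations=3, seed=6))
        missing = frame["smoking"].isna()
        for fa, fc in zip(a.frames, c.frames):
            np.testing.assert_array_equal(
                fa.loc[~missing, "smoking"].to_numpy(),
                fc.loc[~missing, "smoking"].to_numpy())
            assert (fa.loc[missing, "smoking"] != fc.loc[missing, "smoking"]).any()

    def test_between_imputation_variance_positive(self, rng):
        frame, _ = _mcar_frame(rng, n=800)
        out = run_chain(frame, [self.SPEC], MiceConfig(m=5, iterations=3, seed=7))
        means = out.imputed_cell_means("smoking")
        assert len(means) == 5
        assert means.var() > 0

    def test_chain_means_do_not_drift(self, rng):
        """In a null scenario the imputed-cell means show no monotone
        drift over the last half of the iterations."""
        frame, _ = _mcar_frame(rng, n=1500)
        out = run_chain(frame, [self.SPEC], MiceConfig(m=6, iterations=10, seed=8))
        stats = out.chain_stats
        late = stats[stats["iteration"] >= 5]
        x = late["iteration"].to_numpy(dtype=float)
        y = late["imputed_mean"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        se = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
        assert abs(slope) < 3 * se

    def test_spec_validation(self, rng):
        frame, _ = _mcar_frame(rng, n=100)
        with pytest.raises(ValueError, match="cannot predict itself"):
            ImputationSpec("smoking", "logistic", ("smoking",))
        with pytest.raises(ValueError, match="not in frame"):
            run_chain(frame, [ImputationSpec("sedentary", "logistic", ("age",))],
                      MiceConfig(m=1, iterations=1))
        frame["marital"] = np.nan
        with pytest.raises(ValueError, match="missing values but no spec"):
            run_chain(frame,
                      [ImputationSpec("smoking", "logistic", ("age", "marital"))],
                      MiceConfig(m=1, iterations=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MiceConfig(m=0)
        with pytest.raises(ValueError):
            MiceConfig(binary_draw="jackknife")
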