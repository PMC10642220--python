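"""Future pseudo-samples, prevalence pooling, Wilson intervals, and the
end-to-end projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from ncdprev.mice import CompletedSet, ImputationSpec, MiceConfig
from ncdprev.projection import (
    FutureSampleSpec,
    assemble_joint_frame,
    build_future_samples,
    pool_prevalence,
    run_projection,
    wilson_interval,
)
from ncdprev.synthetic import generate_population_projection

from conftest import make_scenario


def _uniform_projection(years):
    return generate_population_projection(make_scenario(), years)


class TestWilsonInterval:
    def test_closed_form_half(self):
        low, high = wilson_interval(0.5, 100, 0.95)
        assert low == pytest.approx(0.4038, abs=1e-4)
        assert high == pytest.approx(0.5962, abs=1e-4)

    def test_zero_proportion_boundary(self):
        low, _ = wilson_interval(0.0, 50)
        assert low == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for p, n in ((0.3, 200), (0.05, 1000), (0.97, 64)):
            ref = proportion_confint(round(p * n), n, alpha=0.05, method="wilson")
            got = wilson_interval(round(p * n) / n, n, 0.95)
            assert got == pytest.approx(ref, abs=1e-10)

    @settings(max_examples=300, derandomize=True)
    @given(p=st.floats(0.0, 1.0), n=st.integers(1, 10**6),
           level=st.floats(0.5, 0.999))
    def test_interval_within_unit_range_and_ordered(self, p, n, level):
        low, high = wilson_interval(p, n, level)
        assert 0.0 <= low <= high <= 1.0
        assert low <= p <= high or min(abs(p - low), abs(high - p)) < 1e-12

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            wilson_interval(0.5, 10, 1.5)


class TestBuildFutureSamples:
    YEARS = (2020, 2025, 2030, 2035, 2040)

    def test_row_count_arithmetic(self):
        spec = FutureSampleSpec(self.YEARS, _uniform_projection(self.YEARS),
                                n_per_year=10_000)
        out = build_future_samples(spec)
        assert len(out) == 50_000

    def test_allocation_mode_exact_counts(self):
        spec = FutureSampleSpec((2020,), _uniform_projection((2020,)),
                                n_per_year=4000, mode="allocate")
        out = build_future_samples(spec)
        counts = out.groupby(["sex", "age"]).size()
        assert counts.min() >= 4000 // 80 and counts.max() <= 4000 // 80 + 1

    def test_sampling_mode_matches_projection(self, rng):
        spec = FutureSampleSpec((2020,), _uniform_projection((2020,)),
                                n_per_year=8000, mode="sample")
        out = build_future_samples(spec, rng)
        observed = out.groupby("age").size().reindex(range(25, 65), fill_value=0)
        stat, p = chisquare(observed)
        assert p > 0.001

    def test_survey_columns_all_missing(self):
        spec = FutureSampleSpec((2020,), _uniform_projection((2020,)), n_per_year=100)
        out = build_future_samples(spec)
        assert out["smoking"].isna().all() and out["bmi_cat"].isna().all()
        assert out[["year", "sex", "age"]].notna().all().all()

    def test_missing_year_named_in_error(self):
        spec = FutureSampleSpec((2020, 2025), _uniform_projection((2020,)),
                                n_per_year=100)
        with pytest.raises(ValueError, match="2025"):
            build_future_samples(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FutureSampleSpec((2020,), _uniform_projection((2020,)), n_per_year=0)


class TestAssembleJointFrame:
    def test_row_counts_additive_and_flagged(self):
        obs = pd.DataFrame({"year": [1997] * 3, "sex": [0, 1, 0],
                            "age": [30, 40, 50], "smoking": [1.0, 0.0, np.nan]})
        fut = pd.DataFrame({"year": [2020] * 2, "sex": [0, 1],
                            "age": [35, 45], "smoking": [np.nan, np.nan]})
        joint = assemble_joint_frame(obs, fut)
        assert len(joint) == 5
        assert (joint.loc[joint["source"] == "future", "smoking"].isna()).all()

    def test_schema_mismatch_lists_columns(self):
        obs = pd.DataFrame({"year": [1997], "sex": [0], "age": [30],
                            "smoking": [1.0]})
        fut = pd.DataFrame({"year": [2020], "sex": [0], "age": [30]})
        with pytest.raises(ValueError, match="smoking"):
            assemble_joint_frame(obs, fut)

    def test_roundtrip_serialisation(self, tmp_path):
        from ncdprev.io import read_frame, write_frame

        obs = pd.DataFrame({"year": [1997, 2002], "sex": [0, 1],
                            "age": [30, 40], "area": [1.0, 2.0],
                            "smoking": [1.0, np.nan]})
        path = write_frame(obs, tmp_path / "frame.csv")
        back = read_frame(path)
        pd.testing.assert_frame_equal(back, obs)


def _completed_from_columns(cols, base):
    frames = []
    for c in cols:
        f = base.copy()
        f["smoking"] = c
        frames.append(f)
    cfg = MiceConfig(m=len(frames), iterations=1)
    spec = ImputationSpec("smoking", "logistic", ("age",))
    return CompletedSet(frames=frames, specs=[spec], config=cfg,
                        chain_stats=pd.DataFrame(columns=["imputation", "iteration",
                                                          "target", "imputed_mean"]))


class TestPooling:
    BASE = pd.DataFrame({"sex": [0] * 10, "year": [2020] * 10,
                         "age": np.arange(30, 40)})

    def test_identical_copies_equal_single_frame_proportion(self):
        col = [1.0] * 3 + [0.0] * 7
        completed = _completed_from_columns([col, col], self.BASE)
        out = pool_prevalence(completed, "smoking")
        assert out["prevalence"].iloc[0] == pytest.approx(0.3)
        assert out["n_eff"].iloc[0] == 10

    def test_pooled_mean_of_two_imputations(self):
        a = [1.0] * 2 + [0.0] * 8  # 0.2
        b = [1.0] * 4 + [0.0] * 6  # 0.4
        completed = _completed_from_columns([a, b], self.BASE)
        out = pool_prevalence(completed, "smoking")
        assert out["prevalence"].iloc[0] == pytest.approx(0.3)
        assert out["between_var"].iloc[0] > 0

    def test_bmi_categories_sum_to_one(self, rng):
        base = pd.DataFrame({"sex": rng.integers(0, 2, 300),
                             "year": rng.choice([1997, 2020], 300),
                             "age": rng.integers(25, 65, 300)})
        frames = []
        for _ in range(3):
            f = base.copy()
            f["bmi_cat"] = rng.integers(0, 3, 300).astype(float)
            frames.append(f)
        completed = CompletedSet(
            frames=frames,
            specs=[ImputationSpec("bmi_cat", "polytomous", ("age",))],
            config=MiceConfig(m=3, iterations=1),
            chain_stats=pd.DataFrame())
        parts = [pool_prevalence(completed, ind)
                 for ind in ("normal_weight", "overweight", "obesity")]
        total = sum(p.set_index(["sex", "year"])["prevalence"] for p in parts)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_interval_order_invariant(self):
        completed = _completed_from_columns([[1.0] * 5 + [0.0] * 5], self.BASE)
        out = pool_prevalence(completed, "smoking")
        row = out.iloc[0]
        assert 0 <= row["interval_low"] <= row["prevalence"] <= row["interval_high"] <= 1


class TestRunProjection:
    def test_null_trend_projects_flat(self):
        import ncdprev

        cfg = make_scenario(n_per_sex=1200, smoking=(0.30, 0.0), seed=31)
        obs = ncdprev.derive_indicators(ncdprev.generate_survey_data(cfg))
        years = (2020, 2030, 2040)
        fspec = FutureSampleSpec(years, _uniform_projection(years), n_per_year=1500)
        spec = ImputationSpec("smoking", "logistic", ("age", "sex", "year"))
        series, _ = run_projection(
            obs[["year", "sex", "age", "smoking"]], [spec], fspec,
            MiceConfig(m=5, iterations=4, seed=32), indicators=["smoking"])
        p2040 = series[series["year"] == 2040]["prevalence"].mean()
        se = np.sqrt(0.3 * 0.7 / 1500)
        assert abs(p2040 - 0.30) < 3 * se

    def test_future_years_must_follow_observed(self):
        import ncdprev

        cfg = make_scenario(n_per_sex=100, seed=33)
        obs = ncdprev.derive_indicators(ncdprev.generate_survey_data(cfg))
        fspec = FutureSampleSpec((2010,), _uniform_projection((2010,)), n_per_year=10)
        spec = ImputationSpec("smoking", "logistic", ("age", "sex", "year"))
        with pytest.raises(ValueError, match="not after"):
            run_projection(obs[["year", "sex", "age", "smoking"]], [spec],
                           fspec, MiceConfig(m=1, iterations=1))


class TestJointChainAndAgeing:
    def test_multi_target_chain_completes_future_covariates(self, rng):
        """Area (5 categories), marital, education and two indicators are
        jointly imputed on future pseudo-sample rows."""
        import ncdprev
        from ncdprev.synthetic import default_nonresponse

        cfg = make_scenario(n_per_sex=800, seed=41,
                            nonresponse=default_nonresponse(item_rate=0.02))
        obs = ncdprev.derive_indicators(ncdprev.generate_survey_data(cfg))
        cols = ["year", "sex", "age", "area", "marital", "education",
                "smoking", "bmi_cat"]
        obs = obs[cols]
        years = (2020, 2040)
        fspec = FutureSampleSpec(years, _uniform_projection(years), n_per_year=600)
        future = build_future_samples(fspec, columns=cols)
        joint = assemble_joint_frame(obs, future)
        # area is observed for invited persons but missing on future rows
        specs = [
            ImputationSpec("smoking", "logistic",
                           ("age", "sex", "year", "marital", "education")),
            ImputationSpec("bmi_cat", "polytomous", ("age", "sex", "year")),
            ImputationSpec("marital", "logistic", ("age", "sex", "year")),
            ImputationSpec("education", "polytomous", ("age", "sex", "year")),
            ImputationSpec("area", "polytomous", ("age", "sex", "year")),
        ]
        from ncdprev.mice import run_chain

        completed = run_chain(joint, specs, MiceConfig(m=2, iterations=3, seed=42))
        for f in completed.frames:
            for spec in specs:
                assert f[spec.target].notna().all()
            future_rows = f[f["source"] == "future"]
            assert future_rows["area"].isin(range(5)).all()
            assert future_rows["education"].isin(range(3)).all()

    def test_ageing_population_raises_age_driven_prevalence(self):
        """With hypertension rising in age, an ageing projection must
        yield a higher 2040 prevalence than fixed demographics."""
        import ncdprev
        from ncdprev.synthetic import IndicatorTrend, generate_population_projection
        from scipy.special import logit

        cfg = make_scenario(
            n_per_sex=1500, seed=51,
            hypertension=IndicatorTrend(float(logit(0.40)), age_coef=0.06))
        obs = ncdprev.derive_indicators(ncdprev.generate_survey_data(cfg))
        obs = obs[["year", "sex", "age", "hypertension"]]
        years = (2020, 2040)
        spec = ImputationSpec("hypertension", "logistic", ("age", "sex", "year"))
        results = {}
        for label, drift in (("fixed", 0.0), ("ageing", 0.04)):
            proj = generate_population_projection(cfg, years, ageing_drift=drift)
            fspec = FutureSampleSpec(years, proj, n_per_year=2000)
            series, _ = run_projection(obs, [spec], fspec,
                                       MiceConfig(m=5, iterations=4, seed=52),
                                       indicators=["hypertension"])
            results[label] = series[series["year"] == 2040]["prevalence"].mean()
        assert results["ageing"] > results["fixed"]
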