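import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from picnorm.inference import (
    TransformSpec,
    apply_transform,
    compare_class_table,
    compare_classes,
    compute_vif,
    fit_latency_model,
    select_transform,
    spearman_matrix,
)
from picnorm.simulate import (
    SimulationConfig,
    generate_latencies,
    generate_name_responses,
    generate_predictors,
)


def rank_sum_enumeration(x, y):
    """Exact two-sided rank-sum oracle by exhausting rank arrangements.

    Returns (U of the first sample, two-sided p) under the permutation
    null; requires tie-free data.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats_rankdata(combined)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    count = 0
    total = 0
    all_ranks = np.arange(1, n + m + 1)
    for subset in itertools.combinations(range(n + m), n):
        u = all_ranks[list(subset)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


def stats_rankdata(a):
    order = np.argsort(a)
    ranks = np.empty(len(a))
    ranks[order] = np.arange(1, len(a) + 1)
    return ranks


class TestSelectTransform:
    def test_symmetric_untouched(self):
        spec = select_transform([1, 2, 3, 4, 5], "v")
        assert spec.transform == "none"

    def test_high_positive_skew_inverted(self):
        spec = select_transform([1, 2, 3, 4, 100], "v")  # skew ~ 2.23
        assert spec.transform == "inverse_pos"
        assert "invert" in spec.direction_note

    def test_high_negative_skew_reflected_inverse(self):
        spec = select_transform([-100, 1, 2, 3, 4], "v")  # skew ~ -2.23
        assert spec.transform == "inverse_neg"
        assert spec.reflect_max == 4.0

    def test_moderate_skew_sqrt(self):
        spec = select_transform([1, 2, 3, 4, 6, 8], "v")  # skew ~ 0.61
        assert spec.transform == "sqrt"

    def test_latency_and_frequency_overrides(self):
        assert select_transform([500, 700, 900], kind="latency").transform == "reciprocal_rt"
        assert select_transform([1, 2, 3], kind="frequency").transform == "log"

    def test_inverse_needs_positive_values(self):
        with pytest.raises(ValueError, match="positive"):
            select_transform([0, 1, 2, 3, 100], "v")


class TestApplyTransform:
    def test_reciprocal_rt(self):
        spec = TransformSpec("rt", 0.0, "reciprocal_rt", demeaned=False)
        out = apply_transform([1000.0, 500.0], spec)
        np.testing.assert_allclose(out, [-1.0, -2.0])

    def test_sqrt_then_demean(self):
        spec = TransformSpec("v", 0.6, "sqrt", demeaned=True)
        out = apply_transform([4.0, 9.0, 16.0], spec)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_domain_violation_names_rows(self):
        spec = TransformSpec("v", 2.0, "log", demeaned=False)
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            apply_transform([1.0, -1.0, 2.0], spec)

    def test_missing_passes_through(self):
        spec = TransformSpec("v", 0.0, "none", demeaned=False)
        out = apply_transform([1.0, np.nan, 3.0], spec)
        assert np.isnan(out[1])


class TestSpearman:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10],
                           "c": [10, 8, 6, 4, 2]})
        mats = spearman_matrix(df, ["a", "b", "c"])
        assert mats["rho"].loc["a", "b"] == pytest.approx(1.0)
        assert mats["rho"].loc["a", "c"] == pytest.approx(-1.0)

    def test_worked_five_point_example(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        mats = spearman_matrix(df, ["x", "y"])
        assert mats["rho"].loc["x", "y"] == pytest.approx(0.8)

    def test_bonferroni_family_size(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        mats = spearman_matrix(df)
        assert mats["n_pairs"] == 6

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        df = pd.DataFrame({"x": x, "y": y})
        base = spearman_matrix(df, ["x", "y"])["rho"].loc["x", "y"]
        up = spearman_matrix(pd.DataFrame({"x": np.exp(x), "y": y ** 3}),
                             ["x", "y"])["rho"].loc["x", "y"]
        down = spearman_matrix(pd.DataFrame({"x": -x, "y": y}),
                               ["x", "y"])["rho"].loc["x", "y"]
        assert up == pytest.approx(base, abs=1e-12)
        assert down == pytest.approx(-base, abs=1e-12)


class TestRankSum:
    def test_identical_samples_not_significant(self):
        res = compare_classes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.effect_size_r == pytest.approx(0.0, abs=1e-9)
        assert not res.significant

    def test_fully_separated_5v5(self):
        res = compare_classes([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)
        assert res.method == "exact"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        m = int(rng.integers(2, 13 - n))
        x, y = rng.uniform(size=n), rng.uniform(size=m)
        u_oracle, p_oracle = rank_sum_enumeration(x, y)
        res = compare_classes(x, y)
        assert res.w_statistic == pytest.approx(u_oracle, abs=1e-9)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_table_uses_bonferroni_threshold(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame({"v1": rng.normal(size=30), "v2": rng.normal(size=30)})
        b = pd.DataFrame({"v1": rng.normal(size=30), "v2": rng.normal(5, 1, size=30)})
        table = compare_class_table(a, b, ["v1", "v2"], alpha=0.05)
        assert not table.loc[table["variable"] == "v1", "significant"].iloc[0]
        assert table.loc[table["variable"] == "v2", "significant"].iloc[0]
        assert table["effect_size_r"].between(0, 1).all()


class TestVif:
    def test_orthogonal_predictors(self):
        x1 = np.array([1.0, 1.0, -1.0, -1.0])
        x2 = np.array([1.0, -1.0, 1.0, -1.0])
        x3 = np.array([1.0, -1.0, -1.0, 1.0])
        vif = compute_vif(pd.DataFrame({"a": x1, "b": x2, "c": x3}))
        np.testing.assert_allclose(vif.values, 1.0, atol=1e-12)

    def test_correlation_09_closed_form(self):
        # construct two columns with sample correlation exactly 0.9
        z1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        z2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        z2 = z2 - z2 @ z1 / (z1 @ z1) * z1  # orthogonalize
        z2 /= np.sqrt(z2 @ z2 / len(z2))
        x2 = 0.9 * z1 + math.sqrt(1 - 0.81) * z2
        vif = compute_vif(pd.DataFrame({"a": z1, "b": x2}))
        assert vif["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)
        assert vif["b"] == pytest.approx(5.26, abs=5e-3)

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        vif = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vif).all()

    def test_needs_two_predictors(self):
        with pytest.raises(ValueError):
            compute_vif(pd.DataFrame({"a": np.arange(5.0)}))


def _simulate_model_table(cfg, seed):
    trials, gt = generate_name_responses(cfg, seed)
    trials["validity"] = "valid"
    predictors = generate_predictors(cfg, seed)
    trials, gt = generate_latencies(trials, predictors, cfg, seed, ground_truth=gt)
    trials["neg_inv_rt"] = -1000.0 / trials["latency_ms"]
    merged = trials.merge(predictors.drop(columns=["word_class"]),
                          left_on=["picture", "canonical_name"],
                          right_on=["picture", "name"], how="left")
    return merged, gt


class TestLatencyModel:
    def test_zero_variance_generator_reduces_to_ols(self):
        cfg = SimulationConfig(
            n_participants=20, n_pictures_objects=12, n_pictures_actions=1,
            name_pool_size=2,
            true_betas={"H": -0.2, "frequency": 0.1},
            sd_participant=0.0, sd_picture=0.0, sd_name=0.0, sd_residual=0.05,
            seed=5,
        )
        df, _ = _simulate_model_table(cfg, 5)
        df = df[df["word_class"] == "object"]
        result = fit_latency_model(df, ["H", "frequency"])
        assert result.method.startswith("OLS")
        X = sm.add_constant(df[["H", "frequency"]].to_numpy())
        ols = sm.OLS(df["neg_inv_rt"].to_numpy(), X).fit()
        fitted = result.fixed_effects.set_index("term")["estimate"]
        np.testing.assert_allclose(
            [fitted["Intercept"], fitted["H"], fitted["frequency"]],
            ols.params, atol=1e-6,
        )

    def test_true_zero_predictor_rarely_significant(self):
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = SimulationConfig(
                n_participants=25, n_pictures_objects=30, n_pictures_actions=1,
                name_pool_size=2,
                true_betas={"H": -0.25, "frequency": 0.15, "imageability": 0.0},
                seed=100 + rep,
            )
            df, _ = _simulate_model_table(cfg, 100 + rep)
            df = df[df["word_class"] == "object"]
            result = fit_latency_model(df, ["H", "frequency", "imageability"])
            t = result.fixed_effects.set_index("term").loc["imageability", "t"]
            hits += abs(t) < 2
        assert hits >= 0.9 * n_rep

    def test_effect_size_omitted_for_intercept(self):
        cfg = SimulationConfig(
            n_participants=10, n_pictures_objects=8, n_pictures_actions=1,
            name_pool_size=2, true_betas={"H": -0.2}, seed=9,
        )
        df, _ = _simulate_model_table(cfg, 9)
        result = fit_latency_model(df[df["word_class"] == "object"], ["H"])
        fe = result.fixed_effects.set_index("term")
        assert np.isnan(fe.loc["Intercept", "d"])
        t = fe.loc["H", "t"]
        n_obs = result.n_obs
        assert fe.loc["H", "d"] == pytest.approx(2 * t / math.sqrt(n_obs - 2))

    def test_single_level_component_excluded(self):
        cfg = SimulationConfig(
            n_participants=1, n_pictures_objects=30, n_pictures_actions=1,
            name_pool_size=2, true_betas={"H": -0.2}, seed=4,
        )
        df, _ = _simulate_model_table(cfg, 4)
        result = fit_latency_model(df[df["word_class"] == "object"], ["H"])
        assert any("participant" in line and "excluded" in line
                   for line in result.selection_log)

    def test_complete_case_drop_counted(self):
        cfg = SimulationConfig(
            n_participants=8, n_pictures_objects=8, n_pictures_actions=1,
            name_pool_size=2, true_betas={"H": -0.2}, seed=6,
        )
        df, _ = _simulate_model_table(cfg, 6)
        df = df[df["word_class"] == "object"].copy()
        df.loc[df.index[:5], "H"] = np.nan
        result = fit_latency_model(df, ["H"])
        assert result.n_dropped == 5
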