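import numpy as np
import pandas as pd
import pytest

from picnorm.agreement import NameDistribution, entropy_h
from picnorm.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_latencies,
    generate_name_responses,
    generate_predictors,
    generate_ratings,
    generate_trial_outcomes,
    simulate_experiment,
)


def _csv(df: pd.DataFrame) -> str:
    return df.to_csv(index=False)


class TestDeterminism:
    def test_same_config_same_seed_identical(self):
        cfg = SimulationConfig(n_participants=6, n_pictures_objects=3,
                               n_pictures_actions=3, name_pool_size=3, seed=11)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        assert _csv(a.trials) == _csv(b.trials)
        assert _csv(a.word_features) == _csv(b.word_features)
        for study in a.ratings:
            assert _csv(a.ratings[study]) == _csv(b.ratings[study])

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n_participants=6, n_pictures_objects=3,
                               n_pictures_actions=3,
                               true_betas={"H": 0.0}, seed=11)
        a = simulate_experiment(cfg, seed=11)
        b = simulate_experiment(cfg, seed=12)
        assert _csv(a.trials) != _csv(b.trials)


class TestConfigValidation:
    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            SimulationConfig(dominant_concentration={"object": 0.0, "action": 1.0})

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd_participant"):
            SimulationConfig(sd_participant=-0.1)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SimulationConfig(outcome_rates={"object": (1.1, -0.1, 0.0),
                                            "action": (1, 0, 0)})

    def test_default_rates_renormalized_onto_simplex(self):
        cfg = SimulationConfig()
        for rates in cfg.outcome_rates.values():
            assert sum(rates) == pytest.approx(1.0, abs=1e-12)


class TestNameResponses:
    def test_one_row_per_participant_picture(self):
        cfg = SimulationConfig(n_participants=7, n_pictures_objects=4,
                               n_pictures_actions=3, seed=1)
        trials, gt = generate_name_responses(cfg)
        assert len(trials) == 7 * 7
        assert len(gt.name_probs) == 7
        for probs in gt.name_probs.values():
            assert probs.sum() == pytest.approx(1.0)

    def test_spiked_concentration_gives_dominant_names(self):
        # 200 replicate pictures, 100 participants, concentration (1000,1,1,1,1)
        cfg = SimulationConfig(
            n_participants=100, n_pictures_objects=200, n_pictures_actions=1,
            name_pool_size=5,
            dominant_concentration={"object": 1000.0, "action": 1.0},
            seed=7,
        )
        trials, _ = generate_name_responses(cfg)
        obj = trials[trials["word_class"] == "object"]
        shares = obj.groupby("picture")["raw_name"].agg(
            lambda s: s.value_counts(normalize=True).iloc[0]
        )
        assert (shares > 0.9).mean() >= 0.95

    def test_entropy_ordering_symmetric_vs_spiked(self):
        def mean_h(dominant_mass, seed):
            cfg = SimulationConfig(
                n_participants=40, n_pictures_objects=200, n_pictures_actions=1,
                name_pool_size=5,
                dominant_concentration={"object": dominant_mass, "action": 1.0},
                seed=seed,
            )
            trials, _ = generate_name_responses(cfg)
            obj = trials[trials["word_class"] == "object"]
            hs = []
            for _, sub in obj.groupby("picture"):
                counts = sub["raw_name"].value_counts().to_dict()
                hs.append(entropy_h(NameDistribution.from_counts(counts)))
            return np.mean(hs)

        assert mean_h(1.0, seed=3) > mean_h(100.0, seed=3)


class TestOutcomes:
    def _trials(self, n):
        return pd.DataFrame(
            {
                "participant": [f"p{i}" for i in range(n)],
                "picture": ["x"] * n,
                "word_class": ["object"] * n,
                "raw_name": ["kot"] * n,
                "canonical_name": ["kot"] * n,
            }
        )

    def test_all_valid(self):
        out = generate_trial_outcomes(self._trials(50), (1, 0, 0), seed=0)
        assert (out["validity"] == "valid").all()

    def test_all_no_response_empties_names(self):
        out = generate_trial_outcomes(self._trials(50), (0, 0, 1), seed=0)
        assert (out["validity"] == "no_response").all()
        assert (out["raw_name"] == "").all()

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            generate_trial_outcomes(self._trials(5), (-0.5, 1.0, 0.5), seed=0)


class TestLatencies:
    def test_deterministic_inverse_at_zero_effects(self):
        cfg = SimulationConfig(
            n_participants=5, n_pictures_objects=3, n_pictures_actions=1,
            name_pool_size=2,
            true_betas={"H": 0.0, "frequency": 0.0},
            sd_participant=0.0, sd_picture=0.0, sd_name=0.0, sd_residual=0.0,
            seed=2,
        )
        trials, gt = generate_name_responses(cfg)
        trials["validity"] = "valid"
        predictors = generate_predictors(cfg)
        out, _ = generate_latencies(trials, predictors, cfg, seed=2, ground_truth=gt)
        obj = out[out["word_class"] == "object"]
        act = out[out["word_class"] == "action"]
        np.testing.assert_allclose(obj["latency_ms"], 897.33, rtol=1e-12)
        np.testing.assert_allclose(act["latency_ms"], 1157.70, rtol=1e-12)

    def test_doubling_participant_sd_increases_between_participant_variance(self):
        def between_participant_var(sd, seed):
            cfg = SimulationConfig(
                n_participants=12, n_pictures_objects=12, n_pictures_actions=1,
                name_pool_size=2, sd_participant=sd,
                sd_picture=0.02, sd_name=0.02, sd_residual=0.05,
                true_betas={"H": 0.0}, seed=seed,
            )
            trials, gt = generate_name_responses(cfg)
            trials["validity"] = "valid"
            pred = generate_predictors(cfg)
            out, _ = generate_latencies(trials, pred, cfg, seed=seed, ground_truth=gt)
            y = -1000.0 / out["latency_ms"]
            return out.assign(y=y).groupby("participant")["y"].mean().var(ddof=1)

        small = np.mean([between_participant_var(0.05, s) for s in range(50)])
        large = np.mean([between_participant_var(0.10, s) for s in range(50)])
        assert large > small

    def test_positive_violation_fraction_rejected(self):
        cfg = SimulationConfig(
            n_participants=10, n_pictures_objects=5, n_pictures_actions=1,
            name_pool_size=2,
            true_betas={"H": 5.0},  # huge effect pushes y past zero
            predictor_sd=1.0, seed=3,
        )
        trials, gt = generate_name_responses(cfg)
        trials["validity"] = "valid"
        pred = generate_predictors(cfg)
        with pytest.raises(ValueError, match="intercept|latency_location"):
            generate_latencies(trials, pred, cfg, seed=3, ground_truth=gt)


class TestRatings:
    def test_zero_dispersion_at_lower_bound(self):
        out = generate_ratings({"a": 1.0}, (1, 7), n_raters=20, rating_sd=0.0)
        assert (out["value"] == 1).all()

    def test_law_of_large_numbers(self):
        out = generate_ratings({"a": 4.0}, (1, 7), n_raters=5000, seed=1)
        assert out["value"].mean() == pytest.approx(4.0, abs=0.1)

    def test_aoa_bounds_honored(self):
        out = generate_ratings({"a": 2.0, "b": 17.5}, (1, 18), n_raters=300,
                               seed=2, rating_sd=3.0)
        assert out["value"].between(1, 18).all()

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside bounds"):
            generate_ratings({"a": 8.0}, (1, 7), n_raters=5)


def test_experiment_outcome_rates_match_defaults(small_experiment):
    # class fractions converge to configured rates (loose: small n here)
    frac_valid = (small_experiment.trials["validity"] == "valid").mean()
    assert frac_valid > 0.9
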