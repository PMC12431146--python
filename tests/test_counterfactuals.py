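import numpy as np
import pandas as pd
import pytest

from glucolens.counterfactuals import (
    CfConstraints,
    CounterfactualSet,
    generate_counterfactuals,
    score_counterfactuals,
    shap_rank,
    shap_values,
)
from glucolens.predictors import train_soft_voting_classifier
from glucolens.synthetic_cohort import CohortConfig, GroundTruthParams, generate_cohort
from glucolens.behavior_features import assemble_features, FEATURE_SETS
from glucolens.experiments import SplitPlan, make_split

from oracles import cf_metrics_oracle


class ThresholdModel:
    """Hyperglycemic (class 1) iff fiber < 3 g; everything else ignored."""

    feature_names = ["fiber", "bmi"]

    def predict(self, rows):
        return (rows["fiber"].to_numpy(dtype=float) < 3.0).astype(int)

    def predict_proba(self, rows):
        p1 = (rows["fiber"].to_numpy(dtype=float) < 3.0).astype(float)
        return np.column_stack([1 - p1, p1])


@pytest.fixture
def toy_training(rng):
    return pd.DataFrame({"fiber": rng.uniform(0, 10, 50),
                         "bmi": rng.uniform(25, 40, 50)})


class TestGeneration:
    def test_threshold_model_flips_by_raising_fiber(self, toy_training, rng):
        model = ThresholdModel()
        constraints = CfConstraints(mutable={"fiber": (0.0, 10.0, 0.0)},
                                    immutable=("bmi",), k=2)
        query = pd.Series({"fiber": 1.0, "bmi": 33.0})
        cfset = generate_counterfactuals(model, query, constraints,
                                         toy_training, rng)
        assert len(cfset) == 2
        assert (cfset.cf_rows["fiber"] >= 3.0).all()
        assert cfset.metrics["validity"] == 1.0

    def test_immutable_features_never_move(self, toy_training, rng):
        model = ThresholdModel()
        constraints = CfConstraints(mutable={"fiber": (0.0, 10.0, 0.0)},
                                    immutable=("bmi",), k=3)
        query = pd.Series({"fiber": 0.5, "bmi": 31.2})
        cfset = generate_counterfactuals(model, query, constraints,
                                         toy_training, rng)
        assert (cfset.cf_rows["bmi"] == 31.2).all()

    def test_impossible_query_returns_empty_set_with_diagnostic(
            self, toy_training, rng):
        model = ThresholdModel()
        # fiber locked into the hyperglycemic range: no flip possible
        constraints = CfConstraints(mutable={"fiber": (0.0, 2.0, 0.0)},
                                    immutable=("bmi",), k=2)
        query = pd.Series({"fiber": 1.0, "bmi": 30.0})
        cfset = generate_counterfactuals(model, query, constraints,
                                         toy_training, rng, budget=500)
        assert len(cfset) == 0
        assert "no class-flipping" in cfset.diagnostic

    def test_deterministic_under_fixed_seed(self, toy_training):
        model = ThresholdModel()
        constraints = CfConstraints(mutable={"fiber": (0.0, 10.0, 0.0)},
                                    immutable=("bmi",), k=2)
        query = pd.Series({"fiber": 1.0, "bmi": 33.0})
        sets = [
            generate_counterfactuals(model, query, constraints, toy_training,
                                     np.random.default_rng(42))
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(sets[0].cf_rows, sets[1].cf_rows)

    def test_mutable_and_immutable_must_not_overlap(self):
        with pytest.raises(ValueError, match="both mutable and immutable"):
            CfConstraints(mutable={"bmi": (20, 40, 0)}, immutable=("bmi",))

    def test_validity_by_construction_on_trained_classifier(
            self, split, ensemble, rng):
        train, test = split
        constraints = CfConstraints.from_training(train, ensemble.feature_names,
                                                  k=2)
        pred = ensemble.predict(test)
        hyper_queries = test.iloc[np.flatnonzero(pred == 1)[:4]]
        for _, query in hyper_queries.iterrows():
            cfset = generate_counterfactuals(ensemble, query, constraints,
                                             train, rng, budget=2000)
            if len(cfset):
                assert cfset.metrics["validity"] == 1.0
                assert cfset.metrics["diversity"] > 0 or len(cfset) == 1

    def test_more_fiber_and_stepping_lower_hyper_probability(
            self, split, ensemble):
        """Direction check: the generator's protective features protect."""
        train, test = split
        pred = ensemble.predict(test)
        hyper = test.iloc[np.flatnonzero(pred == 1)]
        assert len(hyper) > 0
        modified = hyper.copy()
        modified["fiber"] = train["fiber"].max()
        modified["stepping_total"] = train["stepping_total"].max()
        modified["glycemic_load"] = train["glycemic_load"].min()
        p_before = ensemble.predict_proba(hyper)[:, 1].mean()
        p_after = ensemble.predict_proba(modified)[:, 1].mean()
        assert p_after < p_before


class TestMetrics:
    def test_singleton_set_has_zero_diversity(self, toy_training, rng):
        model = ThresholdModel()
        constraints = CfConstraints(mutable={"fiber": (0.0, 10.0, 0.0)},
                                    immutable=("bmi",), k=1)
        query = pd.Series({"fiber": 1.0, "bmi": 33.0})
        cfset = generate_counterfactuals(model, query, constraints,
                                         toy_training, rng)
        assert cfset.metrics["diversity"] == 0.0

    def test_single_two_sd_move_has_distance_two(self):
        # training stats chosen so z-scoring is the identity on 'fiber'
        rng = np.random.default_rng(0)
        fiber = rng.normal(0, 1, 4000)
        fiber = (fiber - fiber.mean()) / fiber.std()
        train = pd.DataFrame({"fiber": fiber, "bmi": fiber + 30.0})
        model = ThresholdModel()
        query = pd.Series({"fiber": 0.0, "bmi": 30.0})
        cf = pd.DataFrame({"fiber": [2.0], "bmi": [30.0]})
        cfset = CounterfactualSet(query_row=query, cf_rows=cf)
        metrics = score_counterfactuals(cfset, model, train)
        assert metrics["normalized_distance"] == pytest.approx(2.0, abs=1e-9)
        assert metrics["features_changed"] == 1.0

    def test_metrics_match_brute_force_oracle(self, split, ensemble, rng):
        train, test = split
        names = ensemble.feature_names
        query = test.iloc[0]
        cf = test.iloc[1:4][names].reset_index(drop=True)
        cfset = CounterfactualSet(query_row=query, cf_rows=cf)
        metrics = score_counterfactuals(cfset, ensemble, train)
        X = train[names].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        q_class = ensemble.predict(query[names].astype(float).to_frame().T)[0]
        flipped = ensemble.predict(cf) != q_class
        want = cf_metrics_oracle(cf.to_numpy(dtype=float),
                                 query[names].to_numpy(dtype=float),
                                 mu, sd, flipped)
        for key, value in want.items():
            assert metrics[key] == pytest.approx(value, rel=1e-9), key


class LinearProbaModel:
    """P(class 1) = sigmoid(w . x); exposes predict_proba for attribution."""

    def __init__(self, weights, names):
        self.w = np.asarray(weights, dtype=float)
        self.feature_names = list(names)

    def predict_proba(self, rows):
        z = rows[self.feature_names].to_numpy(dtype=float) @ self.w
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def predict(self, rows):
        return (self.predict_proba(rows)[:, 1] > 0.5).astype(int)


class TestShapRanking:
    def test_additivity_to_machine_precision(self, rng):
        model = LinearProbaModel([1.0, -2.0, 0.5], ["a", "b", "c"])
        rows = pd.DataFrame(rng.normal(size=(15, 3)), columns=["a", "b", "c"])
        background = rows.iloc[:8]
        phi, base = shap_values(model, rows, background, rng, n_permutations=3)
        f = model.predict_proba(rows)[:, 1]
        assert np.allclose(phi.sum(axis=1), f - base, atol=1e-9)

    def test_ignored_feature_gets_zero_importance(self, rng):
        model = LinearProbaModel([2.0, 0.0], ["used", "ignored"])
        rows = pd.DataFrame(rng.normal(size=(30, 2)), columns=["used", "ignored"])
        rank = shap_rank(model, rows, rng, n_trials=2, n_background=10,
                         n_permutations=4)
        assert rank["ignored"] == pytest.approx(0.0, abs=1e-12)
        assert rank.index[0] == "used"

    def test_dominant_generator_effect_recovered(self):
        """With a sitting-dominated generator, sitting features rank high."""
        params = GroundTruthParams(gl_effect=0.2, stepping_effect=0.0,
                                   sitting_effect=4.0,
                                   baseline_glucose_mean=90.0,
                                   baseline_glucose_sd=2.0, noise_sd=2.0)
        bundle = generate_cohort(CohortConfig(seed=21, workdays_per_phase=6,
                                              effect_params=params))
        df = assemble_features(bundle.cgm, bundle.activity, bundle.meals,
                               bundle.work, bundle.bmi_by_participant(), "All")
        assert 0.05 < df["hyper_label"].mean() < 0.95
        names = FEATURE_SETS["All"]
        train, _ = make_split(df, SplitPlan(scheme="ratio", seed=0))
        model = train_soft_voting_classifier(train, names, seed=0,
                                             families=("RF", "XGB"))
        rng = np.random.default_rng(5)
        rank = shap_rank(model, train.head(30), rng, n_trials=2,
                         n_background=15, n_permutations=5)
        top5 = set(rank.index[:5])
        assert top5 & {"sitting_total", "sitting_at_work"}
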