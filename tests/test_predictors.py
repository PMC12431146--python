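import numpy as np
import pandas as pd
import pytest

from glucolens.predictors import (
    BackboneSpec,
    LeakageError,
    MLP_LAYOUTS,
    SoftVotingEnsemble,
    adasyn_balance,
    gaussian_augment,
    leaf_limited_rf,
    make_estimator,
    mark_partition,
    nrmse,
    soft_vote_proba,
    tolerance_fractions,
    train_backbone,
)

from oracles import soft_vote_oracle


def toy_frame(rng, n=60, slope=3.0, noise=0.0, partition="train"):
    x1 = rng.uniform(0, 10, n)
    x2 = rng.uniform(0, 10, n)
    y = slope * x1 + 2.0 * x2 + noise * rng.normal(size=n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "auc": y,
                       "hyper_label": (y > np.median(y)).astype(int)})
    return mark_partition(df, partition)


class TestBackboneZoo:
    def test_ridge_recovers_exact_linear_function(self, rng):
        train = toy_frame(rng, n=100)
        model = train_backbone(BackboneSpec(family="Ridge", alpha=0.01),
                               train, ["x1", "x2"], "auc")
        pred = model.predict(train)
        assert nrmse(train["auc"], pred) < 0.01

    def test_mlp_variant_13_layout(self):
        est = make_estimator(BackboneSpec(family="MLP", mlp_variant=13))
        assert est.hidden_layer_sizes == (160, 80, 40, 40, 40, 40, 20, 10)
        assert len(MLP_LAYOUTS) == 13

    def test_rf_reproducible_across_estimator_counts(self, rng):
        train = toy_frame(rng)
        for n_est in (10, 100):
            spec = BackboneSpec(family="RF", n_estimators=n_est)
            p1 = train_backbone(spec, train, ["x1", "x2"], "auc", seed=3).predict(train)
            p2 = train_backbone(spec, train, ["x1", "x2"], "auc", seed=3).predict(train)
            assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("kwargs", [
        {"family": "RF", "n_estimators": 37},
        {"family": "Ridge", "alpha": 0.5},
        {"family": "MLP", "mlp_variant": 14},
        {"family": "Ridge", "task": "classify_hyper"},
    ])
    def test_off_menu_variants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BackboneSpec(**kwargs)

    def test_constant_feature_dropped_with_record(self, rng):
        train = toy_frame(rng)
        train["const"] = 5.0
        model = train_backbone(BackboneSpec(family="RF"), train,
                               ["x1", "x2", "const"], "auc")
        assert model.dropped_features == ["const"]
        assert model.feature_names == ["x1", "x2"]


class TestMetrics:
    def test_nrmse_examples(self):
        assert nrmse([100, 100], [100, 100]) == 0.0
        assert nrmse([100, 100], [110, 90]) == pytest.approx(0.1)

    def test_nrmse_matches_two_line_oracle(self, rng):
        y, p = rng.uniform(50, 150, 40), rng.uniform(50, 150, 40)
        want = np.sqrt(np.mean((y - p) ** 2)) / np.mean(y)
        assert nrmse(y, p) == pytest.approx(want, rel=1e-12)

    def test_tolerance_fraction_examples(self):
        assert tolerance_fractions([100], [100]) == (1, 1, 1, 1)
        assert tolerance_fractions([100], [107]) == (0, 1, 1, 1)

    def test_tolerance_fractions_match_brute_force(self, rng):
        y, p = rng.uniform(50, 150, 50), rng.uniform(50, 150, 50)
        got = tolerance_fractions(y, p)
        for frac, t in zip(got, (0.05, 0.10, 0.15, 0.20)):
            want = sum(abs(a - b) / a < t for a, b in zip(y, p)) / 50
            assert frac == pytest.approx(want)
        assert tuple(sorted(got)) == got  # nondecreasing in threshold


class TestGaussianAugment:
    def test_zero_sigma_appends_identical_copies(self, rng):
        train = toy_frame(rng, n=20)
        out = gaussian_augment(train, ["x1", "x2"], rng, sigma=0.0, multiplier=1)
        assert len(out) == 40
        pd.testing.assert_frame_equal(out.iloc[20:].reset_index(drop=True), train)

    def test_jitter_moments(self, rng):
        train = toy_frame(rng, n=100)
        out = gaussian_augment(train, ["x1"], rng, sigma=0.05, multiplier=100)
        jitter = (out["x1"].to_numpy()[100:]
                  - np.tile(train["x1"].to_numpy(), 100))
        n = len(jitter)
        se_sd = 0.05 / np.sqrt(2 * (n - 1))
        assert jitter.std() == pytest.approx(0.05, abs=3 * se_sd)
        assert abs(jitter.mean()) < 3 * 0.05 / np.sqrt(n)

    def test_labels_copied_unchanged(self, rng):
        train = toy_frame(rng, n=20)
        out = gaussian_augment(train, ["x1"], rng, sigma=0.5, multiplier=2)
        assert np.array_equal(out["hyper_label"][:20], out["hyper_label"][20:40])

    def test_refuses_test_partition(self, rng):
        test = toy_frame(rng, partition="test")
        with pytest.raises(LeakageError):
            gaussian_augment(test, ["x1"], rng)


class TestAdasyn:
    def test_balanced_input_unchanged(self, rng):
        train = toy_frame(rng, n=40)
        out = adasyn_balance(train, ["x1", "x2"], "hyper_label", rng)
        assert len(out) == len(train)

    def test_imbalanced_input_reaches_parity(self, rng):
        train = toy_frame(rng, n=100)
        train = mark_partition(
            pd.concat([train[train.hyper_label == 0].iloc[:70],
                       train[train.hyper_label == 1].iloc[:30]],
                      ignore_index=True), "train")
        out = adasyn_balance(train, ["x1", "x2"], "hyper_label", rng)
        counts = out["hyper_label"].value_counts()
        assert abs(counts[0] - counts[1]) / counts.max() <= 0.05

    def test_synthetic_points_lie_between_minority_neighbors(self, rng):
        # 2-D toy: minority points on a line; synthesis stays on segments
        minority = pd.DataFrame({"x1": np.linspace(0, 1, 10),
                                 "x2": np.linspace(0, 2, 10),
                                 "hyper_label": 1})
        majority = pd.DataFrame({"x1": rng.uniform(5, 6, 40),
                                 "x2": rng.uniform(5, 6, 40),
                                 "hyper_label": 0})
        train = mark_partition(
            pd.concat([minority, majority], ignore_index=True), "train")
        out = adasyn_balance(train, ["x1", "x2"], "hyper_label", rng)
        synth = out.iloc[len(train):]
        assert len(synth) == 30
        # every synthetic point stays on the minority line x2 = 2*x1
        assert np.allclose(synth["x2"], 2 * synth["x1"], atol=1e-9)
        assert (synth["hyper_label"] == 1).all()

    def test_refuses_test_partition(self, rng):
        test = toy_frame(rng, partition="test")
        with pytest.raises(LeakageError):
            adasyn_balance(test, ["x1"], "hyper_label", rng)


class _StubModel:
    def __init__(self, proba, classes=(0, 1)):
        self._proba = np.asarray(proba, dtype=float)

        class _Est:
            classes_ = np.asarray(classes)

        self.estimator = _Est()
        self.feature_names = ["x1"]

    def predict_proba(self, rows):
        return self._proba


class TestSoftVote:
    def test_three_member_average_and_argmax(self):
        members = [_StubModel([[0.6, 0.4]]), _StubModel([[0.4, 0.6]]),
                   _StubModel([[0.8, 0.2]])]
        ens = SoftVotingEnsemble(members)
        proba = ens.predict_proba(pd.DataFrame({"x1": [0.0]}))
        assert np.allclose(proba, [[0.6, 0.4]])
        assert ens.predict(pd.DataFrame({"x1": [0.0]})) == [0]

    def test_identical_members_equal_single_member(self):
        m = _StubModel([[0.3, 0.7], [0.9, 0.1]])
        ens = SoftVotingEnsemble([m, m, m])
        assert np.allclose(ens.predict_proba(None), m.predict_proba(None))

    def test_tie_goes_to_positive_class(self):
        ens = SoftVotingEnsemble([_StubModel([[0.5, 0.5]])])
        assert ens.predict(pd.DataFrame({"x1": [0.0]})) == [1]

    def test_matches_external_probability_averaging(self, rng):
        probas = []
        for _ in range(3):
            p1 = rng.uniform(size=10)
            probas.append(np.column_stack([p1, 1 - p1]))
        members = [_StubModel(p) for p in probas]
        got = soft_vote_proba(members, pd.DataFrame({"x1": np.zeros(10)}))
        assert np.allclose(got, soft_vote_oracle(probas), atol=1e-12)


class TestLeafLimitedRf:
    def test_cap_two_gives_stumps(self, rng):
        train = toy_frame(rng)
        model, gains = leaf_limited_rf(train, ["x1", "x2"], "auc",
                                       max_leaf_nodes=2)
        for tree in model.estimator.estimators_:
            assert tree.get_n_leaves() <= 2
        assert set(gains.index) == {"x1", "x2"}

    def test_cap_48_trains_and_ranks_dominant_feature_first(self, rng):
        train = toy_frame(rng, slope=10.0)
        _, gains = leaf_limited_rf(train, ["x1", "x2"], "auc", max_leaf_nodes=48)
        assert gains.index[0] == "x1"

    def test_gain_ranking_stable_across_seeds(self, rng):
        train = toy_frame(rng, slope=10.0)
        tops = {
            leaf_limited_rf(train, ["x1", "x2"], "auc", 48, seed=s)[1].index[0]
            for s in range(3)
        }
        assert tops == {"x1"}


class TestSkillOnSyntheticData:
    def test_rf_beats_null_model(self, split, feature_names):
        train, test = split
        model = train_backbone(BackboneSpec(family="RF"), train,
                               feature_names, "auc", seed=0)
        rf_err = nrmse(test["auc"], model.predict(test))
        null_err = nrmse(test["auc"], np.full(len(test), train["auc"].mean()))
        assert rf_err < 0.8 * null_err
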