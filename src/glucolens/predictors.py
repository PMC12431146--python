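"""Trainable model zoo, evaluation metrics, augmentation and balancing.

The backbone families are Random Forest (10/50/100 trees), Ridge
(alpha 1/0.1/0.01), thirteen MLP layouts, and XGBoost, for three tasks:
regression of postprandial AUC, regression of MaxBGL, and binary
hyperglycemia classification. Features are standardized with statistics
fitted on the training partition only, and the scaler travels with the
fitted model.

Two training-set-only transforms are provided: Gaussian jitter
augmentation of the scaled features (targets copied unchanged) and ADASYN
minority oversampling for classification. Both refuse to run on anything
not explicitly marked as a training partition; the experiment layer marks
partitions when it splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier, XGBRegressor

Task = Literal["regress_auc", "regress_maxbgl", "classify_hyper"]

#: The thirteen MLP hidden-layer layouts, indexed 1..13.
MLP_LAYOUTS: dict[int, tuple[int, ...]] = {
    1: (20, 10, 5),
    2: (40, 20, 10, 5),
    3: (60, 30, 15, 7),
    4: (80, 40, 20, 10, 5),
    5: (100, 50, 25, 12, 6),
    6: (120, 60, 30, 15, 7),
    7: (140, 70, 35, 17, 8),
    8: (160, 80, 40, 20, 10),
    9: (80, 40, 20, 20, 20, 20, 10, 5),
    10: (100, 50, 25, 25, 25, 25, 12, 6),
    11: (120, 60, 30, 30, 30, 30, 15, 7),
    12: (140, 70, 35, 35, 35, 35, 17, 8),
    13: (160, 80, 40, 40, 40, 40, 20, 10),
}

RF_N_ESTIMATORS = (10, 50, 100)
RIDGE_ALPHAS = (1.0, 0.1, 0.01)


class LeakageError(RuntimeError):
    """A training-only transform was handed non-training rows."""


def mark_partition(df: pd.DataFrame, partition: str) -> pd.DataFrame:
    """Label a frame as 'train' or 'test'; transforms check the label."""
    df = df.copy()
    df.attrs["partition"] = partition
    return df


def _require_train(rows: pd.DataFrame, op: str) -> None:
    if rows.attrs.get("partition", "train") != "train":
        raise LeakageError(f"{op} may only be applied to a training partition")


@dataclass(frozen=True)
class BackboneSpec:
    """One model configuration from the enumerated zoo."""

    family: Literal["RF", "Ridge", "MLP", "XGB", "TabNet"]
    task: Task = "regress_auc"
    n_estimators: int = 100          # RF
    alpha: float = 1.0               # Ridge
    mlp_variant: int = 13            # MLP, 1..13
    max_leaf_nodes: int | None = None  # RF leaf-capped variant

    def __post_init__(self) -> None:
        if self.family == "RF" and self.n_estimators not in RF_N_ESTIMATORS:
            raise ValueError(f"RF n_estimators must be in {RF_N_ESTIMATORS}")
        if self.family == "Ridge" and self.alpha not in RIDGE_ALPHAS:
            raise ValueError(f"Ridge alpha must be in {RIDGE_ALPHAS}")
        if self.family == "MLP" and self.mlp_variant not in MLP_LAYOUTS:
            raise ValueError("MLP variant must be 1..13")
        if self.family == "Ridge" and self.task == "classify_hyper":
            raise ValueError("Ridge is a regression backbone")


def make_estimator(spec: BackboneSpec, seed: int = 0):
    """Instantiate the sklearn/xgboost estimator for a spec."""
    classify = spec.task == "classify_hyper"
    if spec.family == "RF":
        cls = RandomForestClassifier if classify else RandomForestRegressor
        return cls(
            n_estimators=spec.n_estimators,
            max_leaf_nodes=spec.max_leaf_nodes,
            random_state=seed,
        )
    if spec.family == "Ridge":
        return Ridge(alpha=spec.alpha, random_state=seed)
    if spec.family == "MLP":
        cls = MLPClassifier if classify else MLPRegressor
        # early stopping on a 10% validation split; unspecified upstream,
        # chosen for stable small-data training
        return cls(
            hidden_layer_sizes=MLP_LAYOUTS[spec.mlp_variant],
            max_iter=2000,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=20,
            random_state=seed,
        )
    if spec.family == "XGB":
        cls = XGBClassifier if classify else XGBRegressor
        return cls(random_state=seed, n_jobs=1, verbosity=0)
    if spec.family == "TabNet":
        raise NotImplementedError(
            "the attention-tabular backbone is an optional plug-in; "
            "install an adapter and register it to use family='TabNet'"
        )
    raise ValueError(f"unknown backbone family {spec.family!r}")


@dataclass
class FittedModel:
    """Estimator + the train-only scaler + bookkeeping."""

    spec: BackboneSpec
    estimator: object
    scaler: StandardScaler
    feature_names: list[str]
    dropped_features: list[str]
    seed: int

    def _matrix(self, rows: pd.DataFrame) -> np.ndarray:
        return self.scaler.transform(rows[self.feature_names].to_numpy(dtype=float))

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._matrix(rows)))

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict_proba(self._matrix(rows)))


def train_backbone(
    spec: BackboneSpec,
    train_rows: pd.DataFrame,
    feature_names: Sequence[str],
    target: str,
    seed: int = 0,
) -> FittedModel:
    """Fit one backbone on a training frame.

    Standardization statistics come from ``train_rows`` only. Constant
    (zero-variance) feature columns are dropped with a recorded list --
    they carry no information and destabilize scaling.
    """
    if len(train_rows) < 10:
        raise ValueError("need at least 10 training rows")
    _require_train(train_rows, "train_backbone")
    X = train_rows[list(feature_names)].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    kept = [f for f, k in zip(feature_names, keep) if k]
    dropped = [f for f, k in zip(feature_names, keep) if not k]
    scaler = StandardScaler().fit(train_rows[kept].to_numpy(dtype=float))
    est = make_estimator(spec, seed)
    y = train_rows[target].to_numpy()
    est.fit(scaler.transform(train_rows[kept].to_numpy(dtype=float)), y)
    return FittedModel(spec, est, scaler, kept, dropped, seed)


# ---------------------------------------------------------------------------
# metrics


def nrmse(y_true: np.ndarray, y_pred: np.ndarray,
          normalizer: Literal["mean", "range"] = "mean") -> float:
    """RMSE divided by the mean (default) or range of the observed values."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if normalizer == "range":
        denom = float(np.ptp(y_true))
    else:
        denom = float(np.mean(y_true))
    return rmse / denom


def tolerance_fractions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    thresholds: Sequence[float] = (0.05, 0.10, 0.15, 0.20),
) -> tuple[float, ...]:
    """Fraction of cases with relative error |yhat - y| / y below each
    threshold; nondecreasing in the threshold by construction."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rel = np.abs(y_pred - y_true) / np.abs(y_true)
    return tuple(float(np.mean(rel < t)) for t in thresholds)


# ---------------------------------------------------------------------------
# training-set transforms


def gaussian_augment(
    train_rows: pd.DataFrame,
    feature_names: Sequence[str],
    rng: np.random.Generator,
    sigma: float = 0.05,
    multiplier: int = 1,
) -> pd.DataFrame:
    """Append ``multiplier`` jittered copies of the training rows.

    Noise N(0, sigma^2) is added per feature; ``sigma`` is in scaled units,
    and the features here are assumed already scaled (the experiment layer
    augments after standardization). Targets and labels are copied
    unchanged. Raises :class:`LeakageError` for non-training partitions.
    """
    _require_train(train_rows, "gaussian_augment")
    copies = [train_rows]
    for _ in range(multiplier):
        jittered = train_rows.copy()
        noise = rng.normal(0.0, sigma, size=(len(train_rows), len(feature_names)))
        jittered[list(feature_names)] = (
            jittered[list(feature_names)].to_numpy(dtype=float) + noise
        )
        copies.append(jittered)
    out = pd.concat(copies, ignore_index=True)
    out.attrs["partition"] = "train"
    return out


def adasyn_balance(
    train_rows: pd.DataFrame,
    feature_names: Sequence[str],
    label: str,
    rng: np.random.Generator,
    n_neighbors: int = 5,
) -> pd.DataFrame:
    """ADASYN oversampling of the minority class to parity.

    For each minority sample the fraction of majority points among its k
    nearest minority-pool-excluded neighbours sets how many synthetic
    points it spawns; synthetic points are drawn uniformly on the segment
    to a random minority neighbour. Test partitions are refused.
    """
    _require_train(train_rows, "adasyn_balance")
    y = train_rows[label].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("adasyn_balance expects a binary label")
    if counts[0] == counts[1]:
        return train_rows
    minority = classes[np.argmin(counts)]
    X = train_rows[list(feature_names)].to_numpy(dtype=float)
    # work in z-space so no single raw-unit feature dominates the metric
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    min_mask = y == minority
    Z_min = Z[min_mask]
    n_needed = int(counts.max() - counts.min())

    k = min(n_neighbors + 1, len(Z))
    nn_all = NearestNeighbors(n_neighbors=k).fit(Z)
    _, idx = nn_all.kneighbors(Z_min)
    # exclude self, count majority neighbours
    ratios = np.array([
        np.mean(y[row[1:]] != minority) if len(row) > 1 else 0.0 for row in idx
    ])
    if ratios.sum() == 0:
        ratios = np.ones_like(ratios)
    weights = ratios / ratios.sum()
    spawn = rng.multinomial(n_needed, weights)

    k_min = min(n_neighbors + 1, len(Z_min))
    nn_min = NearestNeighbors(n_neighbors=k_min).fit(Z_min)
    _, idx_min = nn_min.kneighbors(Z_min)

    synth_rows = []
    template = train_rows.iloc[0].copy()
    for i, g in enumerate(spawn):
        for _ in range(int(g)):
            if k_min > 1:
                j = int(rng.integers(1, k_min))
                neighbor = Z_min[idx_min[i][j]]
            else:
                neighbor = Z_min[i]
            lam = float(rng.uniform())
            z_new = Z_min[i] + lam * (neighbor - Z_min[i])
            row = template.copy()
            row[list(feature_names)] = z_new * sd + mu
            row[label] = minority
            synth_rows.append(row)
    out = pd.concat([train_rows, pd.DataFrame(synth_rows)], ignore_index=True)
    out.attrs["partition"] = "train"
    return out


# ---------------------------------------------------------------------------
# ensembling


def soft_vote_proba(members: Sequence[FittedModel], rows: pd.DataFrame) -> np.ndarray:
    """Unweighted mean of member class-probability vectors."""
    probas = [m.predict_proba(rows) for m in members]
    return np.mean(probas, axis=0)


def soft_vote_predict(members: Sequence[FittedModel], rows: pd.DataFrame) -> np.ndarray:
    """Argmax of the averaged probabilities; an exact tie goes to the
    positive (hyperglycemia) class."""
    proba = soft_vote_proba(members, rows)
    pred = np.argmax(proba, axis=1)
    ties = proba[:, 0] == proba[:, 1]
    pred[ties] = 1
    classes = np.asarray(members[0].estimator.classes_)
    return classes[pred]


@dataclass
class SoftVotingEnsemble:
    """RF + XGB + MLP soft-voting classifier over a shared feature list."""

    members: list[FittedModel]

    @property
    def feature_names(self) -> list[str]:
        return self.members[0].feature_names

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return soft_vote_predict(self.members, rows)

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        return soft_vote_proba(self.members, rows)


def train_soft_voting_classifier(
    train_rows: pd.DataFrame,
    feature_names: Sequence[str],
    label: str = "hyper_label",
    seed: int = 0,
    families: Sequence[str] = ("RF", "XGB", "MLP"),
) -> SoftVotingEnsemble:
    """Train the hybrid hyperglycemia classifier (members independently on
    the same training data; they cooperate only at inference)."""
    members = [
        train_backbone(
            BackboneSpec(family=f, task="classify_hyper"),
            train_rows, feature_names, label, seed=seed,
        )
        for f in families
    ]
    return SoftVotingEnsemble(members)


def leaf_limited_rf(
    train_rows: pd.DataFrame,
    feature_names: Sequence[str],
    target: str,
    max_leaf_nodes: int,
    seed: int = 0,
    task: Task = "regress_auc",
) -> tuple[FittedModel, pd.Series]:
    """RF with capped leaf count, plus impurity-gain feature ranking.

    Capping leaves forces each tree to spend its few splits on the highest
    information-gain features, which doubles as a feature-search device.
    """
    spec = BackboneSpec(family="RF", task=task, max_leaf_nodes=max_leaf_nodes)
    model = train_backbone(spec, train_rows, feature_names, target, seed=seed)
    gains = pd.Series(
        model.estimator.feature_importances_, index=model.feature_names
    ).sort_values(ascending=False)
    return model, gains
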