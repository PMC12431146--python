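"""Evaluation designs: splits, personalization and repetition harness.

Split schemes
-------------
ratio          shuffled split with floor(n * train_fraction) training rows
               (159 rows at 80/20 -> 127 train, 32 test)
balanced_test  exactly n_per_class real rows per class held out to test
               (the "87/13" design at n_per_class = 10)
kfold10        10-fold cross-validation
loso           leave-one-subject-out: one participant's rows form the test
loo            leave-one-out: a single row forms the test

Balancing (ADASYN) and Gaussian augmentation are applied strictly after
splitting, to the training partition only, in standardized feature space;
test folds contain only real data points. ``personalize`` moves exactly
one positive and one negative row from test to train, emulating a short
calibration sample from a new subject.

Per-repetition seeds derive from the master seed via ``SeedSequence``;
identical master seeds reproduce reports exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.preprocessing import StandardScaler

from glucolens.predictors import (
    BackboneSpec,
    SoftVotingEnsemble,
    adasyn_balance,
    gaussian_augment,
    mark_partition,
    nrmse,
    tolerance_fractions,
    train_backbone,
)

Scheme = Literal["ratio", "balanced_test", "fraction_sweep", "kfold10", "loso", "loo"]


@dataclass(frozen=True)
class SplitPlan:
    scheme: Scheme = "ratio"
    train_fraction: float = 0.8
    n_per_class: int = 10
    fractions: tuple[float, ...] = (0.70, 0.80, 0.87, 0.90, 0.95, 0.99)
    seed: int = 0


@dataclass
class EvalReport:
    scheme: str
    n_train: int
    n_test: int
    seed: int
    metrics: dict[str, float] = field(default_factory=dict)


def make_split(rows: pd.DataFrame, plan: SplitPlan,
               rng: np.random.Generator | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single train/test split for the 'ratio' and 'balanced_test' schemes.

    Partitions are disjoint and exhaustive; the returned frames carry a
    partition mark that the training-only transforms check.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    n = len(rows)
    if plan.scheme == "ratio":
        n_train = int(np.floor(n * plan.train_fraction))
        perm = rng.permutation(n)
        train = rows.iloc[perm[:n_train]]
        test = rows.iloc[perm[n_train:]]
    elif plan.scheme == "balanced_test":
        test_idx: list[int] = []
        for cls in (0, 1):
            members = np.flatnonzero(rows["hyper_label"].to_numpy() == cls)
            if len(members) < plan.n_per_class:
                raise ValueError(
                    f"class {cls} has {len(members)} rows < n_per_class="
                    f"{plan.n_per_class}"
                )
            test_idx.extend(rng.choice(members, size=plan.n_per_class, replace=False))
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train, test = rows.iloc[~mask], rows.iloc[mask]
    else:
        raise ValueError(f"make_split does not handle scheme {plan.scheme!r}")
    return (
        mark_partition(train.reset_index(drop=True), "train"),
        mark_partition(test.reset_index(drop=True), "test"),
    )


def iter_folds(rows: pd.DataFrame, plan: SplitPlan,
               rng: np.random.Generator | None = None
               ) -> Iterator[tuple[pd.DataFrame, pd.DataFrame]]:
    """Yield (train, test) folds for the multi-fold schemes."""
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    n = len(rows)
    if plan.scheme == "kfold10":
        perm = rng.permutation(n)
        for fold in np.array_split(perm, 10):
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            yield (mark_partition(rows.iloc[~mask].reset_index(drop=True), "train"),
                   mark_partition(rows.iloc[mask].reset_index(drop=True), "test"))
    elif plan.scheme == "loso":
        for pid in sorted(rows["participant_id"].unique()):
            mask = (rows["participant_id"] == pid).to_numpy()
            yield (mark_partition(rows.loc[~mask].reset_index(drop=True), "train"),
                   mark_partition(rows.loc[mask].reset_index(drop=True), "test"))
    elif plan.scheme == "loo":
        for i in range(n):
            mask = np.zeros(n, dtype=bool)
            mask[i] = True
            yield (mark_partition(rows.iloc[~mask].reset_index(drop=True), "train"),
                   mark_partition(rows.iloc[mask].reset_index(drop=True), "test"))
    else:
        raise ValueError(f"iter_folds does not handle scheme {plan.scheme!r}")


def personalize(
    train: pd.DataFrame,
    test: pd.DataFrame,
    rng: np.random.Generator,
    n_pos: int = 1,
    n_neg: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Move n_pos positive and n_neg negative rows from test to train."""
    labels = test["hyper_label"].to_numpy()
    moved: list[int] = []
    for cls, count in ((1, n_pos), (0, n_neg)):
        members = np.flatnonzero(labels == cls)
        if len(members) < count:
            raise ValueError(f"test set lacks {count} row(s) of class {cls}")
        moved.extend(rng.choice(members, size=count, replace=False))
    mask = np.zeros(len(test), dtype=bool)
    mask[moved] = True
    train2 = pd.concat([train, test.iloc[mask]], ignore_index=True)
    test2 = test.iloc[~mask].reset_index(drop=True)
    return mark_partition(train2, "train"), mark_partition(test2, "test")


# ---------------------------------------------------------------------------
# the classification pipeline used by every experiment


@dataclass(frozen=True)
class ClassifierConfig:
    families: tuple[str, ...] = ("RF", "XGB", "MLP")
    balance: bool = True
    augment: bool = False
    sigma: float = 0.05
    multiplier: int = 1


def _prepare_training(
    train: pd.DataFrame,
    feature_names: Sequence[str],
    config: ClassifierConfig,
    rng: np.random.Generator,
) -> tuple[StandardScaler, pd.DataFrame]:
    """Standardize on train stats, then balance/augment in z-space."""
    scaler = StandardScaler().fit(train[list(feature_names)].to_numpy(dtype=float))
    train_z = train.copy()
    train_z[list(feature_names)] = scaler.transform(
        train[list(feature_names)].to_numpy(dtype=float)
    )
    train_z = mark_partition(train_z, "train")
    if config.balance:
        train_z = adasyn_balance(train_z, feature_names, "hyper_label", rng)
    if config.augment:
        train_z = gaussian_augment(
            train_z, feature_names, rng, config.sigma, config.multiplier
        )
    return scaler, train_z


def fit_and_score_classifier(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_names: Sequence[str],
    config: ClassifierConfig,
    seed: int,
) -> dict[str, float]:
    """Train the (possibly ensemble) classifier and score the test fold.

    Returns accuracy plus macro-averaged precision/recall/F1. The test
    frame is never modified (asserted byte-identical by the test suite).
    """
    rng = np.random.default_rng(seed)
    scaler, train_z = _prepare_training(train, feature_names, config, rng)
    members = [
        train_backbone(
            BackboneSpec(family=f, task="classify_hyper"),
            train_z, feature_names, "hyper_label", seed=seed,
        )
        for f in config.families
    ]
    ensemble = SoftVotingEnsemble(members)
    test_z = test.copy()
    test_z[list(feature_names)] = scaler.transform(
        test[list(feature_names)].to_numpy(dtype=float)
    )
    y_true = test["hyper_label"].to_numpy()
    y_pred = ensemble.predict(test_z)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
    }


def _repetition_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_experiment(
    rows: pd.DataFrame,
    plan: SplitPlan,
    feature_names: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 20,
    master_seed: int = 0,
    personalization: bool = False,
) -> pd.DataFrame:
    """Repeat an evaluation design and report mean metrics.

    Single-split schemes redraw the split per repetition; fold schemes
    average over folds within each repetition. Returns one row per
    repetition plus a trailing 'mean' row.
    """
    seeds = _repetition_seeds(master_seed, n_repetitions)
    records = []
    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        rep_plan = dataclasses.replace(plan, seed=seed)
        if plan.scheme in ("ratio", "balanced_test"):
            folds = [make_split(rows, rep_plan, rng)]
        else:
            folds = list(iter_folds(rows, rep_plan, rng))
        fold_metrics = []
        for train, test in folds:
            if personalization:
                train, test = personalize(train, test, rng)
            if test["hyper_label"].nunique() < 1 or len(test) == 0:
                continue
            fold_metrics.append(
                fit_and_score_classifier(train, test, feature_names, config, seed)
            )
        mean_metrics = pd.DataFrame(fold_metrics).mean().to_dict()
        records.append({"repetition": rep, "seed": seed, **mean_metrics})
    report = pd.DataFrame(records)
    summary = report.drop(columns=["repetition", "seed"]).mean().to_dict()
    report = pd.concat(
        [report, pd.DataFrame([{"repetition": "mean", "seed": master_seed,
                                **summary}])],
        ignore_index=True,
    )
    return report


def fraction_sweep(
    rows: pd.DataFrame,
    feature_names: Sequence[str],
    fractions: Sequence[float] = (0.70, 0.80, 0.87, 0.90, 0.95, 0.99),
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 10,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Mean metrics as the training fraction grows.

    The 99% point is reported but single-example-per-class test sets make
    its precision/recall fragile; monotonicity checks exclude it.
    """
    out = []
    for frac in fractions:
        plan = SplitPlan(scheme="ratio", train_fraction=frac)
        report = run_experiment(
            rows, plan, feature_names, config, n_repetitions, master_seed
        )
        mean_row = report[report["repetition"] == "mean"].iloc[0].to_dict()
        mean_row["train_fraction"] = frac
        out.append(mean_row)
    return pd.DataFrame(out)[
        ["train_fraction", "accuracy", "precision", "recall", "f1"]
    ]


# ---------------------------------------------------------------------------
# regression evaluation (AUC / MaxBGL)


def evaluate_regressor(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_names: Sequence[str],
    spec: BackboneSpec,
    target: str = "auc",
    seed: int = 0,
) -> EvalReport:
    """Fit one regression backbone and report NRMSE + tolerance fractions."""
    model = train_backbone(spec, train, feature_names, target, seed=seed)
    y_true = test[target].to_numpy(dtype=float)
    y_pred = model.predict(test)
    fracs = tolerance_fractions(y_true, y_pred)
    return EvalReport(
        scheme="ratio",
        n_train=len(train),
        n_test=len(test),
        seed=seed,
        metrics={
            "nrmse": nrmse(y_true, y_pred),
            "tol_5": fracs[0],
            "tol_10": fracs[1],
            "tol_15": fracs[2],
            "tol_20": fracs[3],
        },
    )
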