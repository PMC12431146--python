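"""Diverse counterfactual "treatment pathways" and feature attribution.

Given a hyperglycemia classifier and one query day, the generator searches
for up to ``k`` perturbed feature rows that (a) flip the predicted class,
(b) stay close to the query, (c) differ from each other, and (d) touch
only *actionable* features: diet and activity are mutable within the
ranges observed in training, while history (fasting glucose, overnight
CGM), anthropometry (BMI) and the calendar are immutable.

The search is a seeded random-restart optimization: a large candidate pool
is drawn by perturbing small random subsets of mutable features, invalid
(non-flipping) candidates are discarded, and a greedy pass selects k
candidates maximizing ``lambda2 * diversity - lambda1 * proximity`` in
standardized feature space. Returned sets therefore have validity 1.0 by
construction whenever they are nonempty; an empty set carries a
diagnostic instead of fabricated rows.

Set-level quality metrics (all distances are L1 in z-scored space):
validity (fraction of returned rows that flip), diversity (mean pairwise
distance), normalized distance (mean distance to the query) and features
changed (mean count of raw-unit differences beyond 1e-6).

Feature attribution uses permutation-sampling Shapley values against a
background sample; each sampled permutation telescopes exactly, so
per-row contributions sum to prediction minus the background expectation
to numerical precision regardless of the number of permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Raw-unit tolerance below which a feature does not count as "changed".
CHANGE_TOL = 1e-6

#: Features that interventions cannot retro-act on.
DEFAULT_IMMUTABLE = (
    "bmi",
    "day_of_week",
    "fasting_glucose",
    "recent_cgm",
    "work_from_home",
    "self_activity_score",
)


@dataclass
class CfConstraints:
    """Mutable feature ranges and the immutable set for one model."""

    mutable: dict[str, tuple[float, float, float]]  # name -> (min, max, step)
    immutable: tuple[str, ...] = DEFAULT_IMMUTABLE
    k: int = 2

    def __post_init__(self) -> None:
        clash = set(self.mutable) & set(self.immutable)
        if clash:
            raise ValueError(f"features both mutable and immutable: {sorted(clash)}")

    @classmethod
    def from_training(
        cls,
        train_rows: pd.DataFrame,
        feature_names: list[str],
        immutable: tuple[str, ...] = DEFAULT_IMMUTABLE,
        k: int = 2,
    ) -> "CfConstraints":
        """Mutable = every model feature not immutable, ranged to the
        observed training min/max (interventions stay in-distribution)."""
        mutable = {}
        for name in feature_names:
            if name in immutable:
                continue
            col = train_rows[name].astype(float)
            mutable[name] = (float(col.min()), float(col.max()), 0.0)
        return cls(mutable=mutable, immutable=immutable, k=k)


@dataclass
class CounterfactualSet:
    query_row: pd.Series
    cf_rows: pd.DataFrame
    metrics: dict[str, float] = field(default_factory=dict)
    diagnostic: str = ""

    def __len__(self) -> int:
        return len(self.cf_rows)


def _zstats(train_rows: pd.DataFrame, feature_names: list[str]
            ) -> tuple[np.ndarray, np.ndarray]:
    X = train_rows[feature_names].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def generate_counterfactuals(
    model,
    query: pd.Series,
    constraints: CfConstraints,
    train_rows: pd.DataFrame,
    rng: np.random.Generator,
    budget: int = 5000,
    lambda1: float = 0.5,
    lambda2: float = 1.0,
) -> CounterfactualSet:
    """Search for up to ``constraints.k`` class-flipping perturbations.

    ``model`` must expose ``predict`` and ``feature_names`` (a
    :class:`~glucolens.predictors.SoftVotingEnsemble` or FittedModel);
    ``train_rows`` supplies the standardization statistics for distances.
    """
    feature_names = list(model.feature_names)
    mutable_names = [f for f in feature_names if f in constraints.mutable]
    if not mutable_names:
        raise ValueError("no mutable features overlap the model's features")
    mu, sd = _zstats(train_rows, feature_names)

    query_df = query[feature_names].astype(float).to_frame().T
    query_class = model.predict(query_df)[0]
    x0 = query_df.to_numpy(dtype=float)[0]

    # candidate pool: perturb small random subsets of mutable features
    cand = np.tile(x0, (budget, 1))
    col_of = {f: i for i, f in enumerate(feature_names)}
    # sparse perturbations: 1-4 features per candidate, mostly 1-2
    n_changed = rng.geometric(0.5, size=budget).clip(1, min(4, len(mutable_names)))
    for i in range(budget):
        chosen = rng.choice(len(mutable_names), size=int(n_changed[i]), replace=False)
        for ci in chosen:
            name = mutable_names[ci]
            lo, hi, step = constraints.mutable[name]
            # favor small, achievable moves: mostly local perturbations
            # around the query, occasionally a global redraw
            if rng.uniform() < 0.7:
                q = cand[i, col_of[name]]
                v = float(np.clip(q + rng.normal(0.0, 0.25 * (hi - lo)), lo, hi))
            else:
                v = float(rng.uniform(lo, hi))
            if step > 0:
                v = lo + round((v - lo) / step) * step
            cand[i, col_of[name]] = v

    pred = model.predict(pd.DataFrame(cand, columns=feature_names))
    valid = cand[pred != query_class]
    if len(valid) == 0:
        return CounterfactualSet(
            query_row=query,
            cf_rows=pd.DataFrame(columns=feature_names),
            diagnostic=f"no class-flipping candidate within budget {budget}",
        )
    valid = np.unique(valid, axis=0)

    z_valid = (valid - mu) / sd
    z0 = (x0 - mu) / sd
    prox = np.abs(z_valid - z0).sum(axis=1)

    # greedy: nearest valid candidate first, then best diversity/proximity
    selected = [int(np.argmin(prox))]
    while len(selected) < constraints.k and len(selected) < len(valid):
        best_j, best_score = -1, -np.inf
        sel_z = z_valid[selected]
        for j in range(len(valid)):
            if j in selected:
                continue
            diversity = float(np.mean(np.abs(sel_z - z_valid[j]).sum(axis=1)))
            score = lambda2 * diversity - lambda1 * prox[j]
            if score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)

    cf_rows = pd.DataFrame(valid[selected], columns=feature_names)
    cfset = CounterfactualSet(query_row=query, cf_rows=cf_rows)
    cfset.metrics = score_counterfactuals(cfset, model, train_rows)
    return cfset


def score_counterfactuals(
    cfset: CounterfactualSet, model, train_rows: pd.DataFrame
) -> dict[str, float]:
    """The four set-level quality metrics.

    validity            fraction of returned rows whose predicted class
                        differs from the query's
    diversity           mean pairwise L1 distance among the rows (z-space);
                        0 by convention for singleton sets
    normalized_distance mean L1 distance from the query (z-space)
    features_changed    mean count of features differing beyond 1e-6 (raw)
    """
    feature_names = list(model.feature_names)
    if len(cfset) == 0:
        return {"validity": float("nan"), "diversity": float("nan"),
                "normalized_distance": float("nan"), "features_changed": float("nan")}
    mu, sd = _zstats(train_rows, feature_names)
    X = cfset.cf_rows[feature_names].to_numpy(dtype=float)
    x0 = cfset.query_row[feature_names].to_numpy(dtype=float)
    query_class = model.predict(
        cfset.query_row[feature_names].astype(float).to_frame().T
    )[0]
    pred = model.predict(cfset.cf_rows[feature_names])
    validity = float(np.mean(pred != query_class))

    Z = (X - mu) / sd
    z0 = (x0 - mu) / sd
    if len(X) >= 2:
        pair = [
            float(np.abs(Z[i] - Z[j]).sum())
            for i in range(len(X))
            for j in range(i + 1, len(X))
        ]
        diversity = float(np.mean(pair))
    else:
        diversity = 0.0
    distance = float(np.mean(np.abs(Z - z0).sum(axis=1)))
    changed = float(np.mean((np.abs(X - x0) > CHANGE_TOL).sum(axis=1)))
    return {
        "validity": validity,
        "diversity": diversity,
        "normalized_distance": distance,
        "features_changed": changed,
    }


# ---------------------------------------------------------------------------
# Shapley-style attribution


def _predict_fn(model):
    if hasattr(model, "predict_proba"):
        return lambda df: np.asarray(model.predict_proba(df))[:, 1]
    return lambda df: np.asarray(model.predict(df), dtype=float)


def shap_values(
    model,
    rows: pd.DataFrame,
    background: pd.DataFrame,
    rng: np.random.Generator,
    n_permutations: int = 10,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley contributions, (n_rows, n_features).

    Interventional value function against the background sample. Each
    sampled permutation's marginal contributions telescope, so every row's
    contributions sum to ``f(row) - mean f(background)`` exactly, for any
    number of permutations.
    """
    feature_names = list(model.feature_names)
    f = _predict_fn(model)
    B = background[feature_names].to_numpy(dtype=float)
    X = rows[feature_names].to_numpy(dtype=float)
    d = len(feature_names)
    base = float(np.mean(f(pd.DataFrame(B, columns=feature_names))))

    phi = np.zeros((len(X), d))
    for r, x in enumerate(X):
        acc = np.zeros(d)
        for _ in range(n_permutations):
            order = rng.permutation(d)
            # stacked matrices: background with the first 0..d features of
            # the permutation replaced by x, evaluated in one batch
            mats = np.empty((d + 1, len(B), d))
            mats[0] = B
            cur = B.copy()
            for step, j in enumerate(order, start=1):
                cur[:, j] = x[j]
                mats[step] = cur
            vals = f(
                pd.DataFrame(mats.reshape(-1, d), columns=feature_names)
            ).reshape(d + 1, len(B)).mean(axis=1)
            marginals = np.diff(vals)
            acc[order] += marginals
        phi[r] = acc / n_permutations
    return phi, base


def shap_rank(
    model,
    rows: pd.DataFrame,
    rng: np.random.Generator,
    n_trials: int = 5,
    n_background: int = 25,
    n_permutations: int = 10,
    top: int = 15,
) -> pd.Series:
    """Mean absolute Shapley contribution per feature over seeded trials.

    Each trial redraws the background sample and the permutations; the
    report is the across-trial average of mean |contribution|, sorted
    descending, truncated to ``top`` features.
    """
    feature_names = list(model.feature_names)
    totals = np.zeros(len(feature_names))
    for _ in range(n_trials):
        bg_idx = rng.choice(len(rows), size=min(n_background, len(rows)), replace=False)
        background = rows.iloc[bg_idx]
        phi, _ = shap_values(model, rows, background, rng, n_permutations)
        totals += np.mean(np.abs(phi), axis=0)
    importance = pd.Series(totals / n_trials, index=feature_names)
    return importance.sort_values(ascending=False).head(top)
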