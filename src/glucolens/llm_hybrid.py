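"""Zero-shot language-model AUC prediction and the hybrid fusion variants.

A provider renders one prompt per feature row -- a fixed task description
plus an ``Input:`` block serializing the 'All' feature set -- and returns a
single number, the predicted 3-h postprandial AUC in mg/dL.h. Responses
are cached by prompt hash, parsed for their first numeric token, retried
twice, and a refusal marks the prediction failed (failed providers are
excluded from fusion, as happened to one commercial model in practice).

Fusion variants over a trainable regressor:

* ``Hybrid``    -- append one prediction column per available provider;
* ``Hybrid_v2`` -- append only the designated best provider's column;
* ``Max``       -- Hybrid_v2 plus Gaussian-noise augmentation of the
  training partition.

The test-time provider is :class:`MockProvider`, a deterministic seeded
emulator whose skill is tunable: it parses the prompt back into features
and predicts a linear function of glycemic load, stepping minutes and
fasting glucose plus noise of configurable spread. Live HTTP adapters can
be registered at run time but are deliberately not part of the tested
surface.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from glucolens.behavior_features import FEATURE_SETS
from glucolens.predictors import gaussian_augment

DEFAULT_TEMPLATE = """\
You are a metabolic health assistant. Given one person's diet, physical
activity, work schedule and recent glucose readings for a single workday,
predict the 3-hour postprandial area under the glucose curve (AUC) after
lunch, in mg/dL * hours. Glucose readings are in mg/dL, durations in
seconds, clock times in fractional hours, nutrients in grams unless the
name says otherwise. Answer with a single number and nothing else.

Input:
{input_block}
"""


@dataclass(frozen=True)
class PromptBundle:
    template_text: str
    rendered_prompt: str
    provider_id: str = ""


@dataclass
class LlmPrediction:
    provider_id: str
    auc_pred: float  # NaN when failed
    raw_response: str
    cache_hit: bool = False

    @property
    def failed(self) -> bool:
        return not np.isfinite(self.auc_pred) or self.auc_pred <= 0


def render_prompt(
    feature_row: pd.Series | dict,
    template: str = DEFAULT_TEMPLATE,
    feature_names: Sequence[str] | None = None,
) -> PromptBundle:
    """Serialize a feature row into the Input: block, fixed key order.

    Only the Input: block varies between rows; the rest of the prompt body
    is the template verbatim.
    """
    names = list(feature_names) if feature_names else FEATURE_SETS["All"]
    row = feature_row if isinstance(feature_row, dict) else feature_row.to_dict()
    lines = [f"{name}: {float(row[name]):.6g}" for name in names]
    rendered = template.format(input_block="\n".join(lines))
    return PromptBundle(template_text=template, rendered_prompt=rendered)


def parse_input_block(prompt: str) -> dict[str, float]:
    """Invert :func:`render_prompt`: recover the feature dict from the
    Input: block (used by the mock provider to 'read' the prompt)."""
    block = prompt.split("Input:", 1)[1]
    out: dict[str, float] = {}
    for line in block.strip().splitlines():
        if ":" not in line:
            continue
        name, value = line.split(":", 1)
        out[name.strip()] = float(value.strip())
    return out


_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def parse_numeric_response(text: str) -> float:
    """First numeric token in the response, NaN when there is none."""
    m = _NUMBER_RE.search(text)
    return float(m.group()) if m else float("nan")


class MockProvider:
    """Deterministic stand-in for a zero-shot language model.

    Emits ``intercept + a*GL + b*stepping_total_min + c*fasting_glucose``
    plus seeded Gaussian noise of sd ``noise_sd`` -- an 'LLM' whose skill
    is dialed by the noise level (0 = strong oracle, large = useless).
    ``refuse=True`` emulates a provider that declines the task.
    """

    def __init__(
        self,
        provider_id: str = "mock",
        noise_sd: float = 30.0,
        seed: int = 0,
        refuse: bool = False,
        oracle: Callable[[dict[str, float]], float] | None = None,
    ) -> None:
        self.provider_id = provider_id
        self.noise_sd = noise_sd
        self.refuse = refuse
        self.oracle = oracle
        self._seed = seed
        self.n_invocations = 0

    def _base_prediction(self, features: dict[str, float]) -> float:
        if self.oracle is not None:
            return self.oracle(features)
        gl = features.get("glycemic_load", 20.0)
        stepping_min = features.get("stepping_total", 0.0) / 60.0
        fasting = features.get("fasting_glucose", 90.0)
        return 3.0 * fasting + 4.5 * gl - 1.2 * stepping_min

    def complete(self, prompt: str) -> str:
        self.n_invocations += 1
        if self.refuse:
            return "I cannot provide medical predictions."
        features = parse_input_block(prompt)
        pred = self._base_prediction(features)
        if self.noise_sd > 0:
            # noise keyed to the prompt so identical prompts reply identically
            digest = hashlib.sha256(
                f"{self._seed}:{prompt}".encode()
            ).digest()
            rng = np.random.default_rng(
                int.from_bytes(digest[:8], "little")
            )
            pred += float(rng.normal(0.0, self.noise_sd))
        return f"AUC: {max(pred, 1.0):.3f}"


@dataclass
class ProviderRegistry:
    """Known providers plus a per-run availability flag."""

    providers: dict[str, object] = field(default_factory=dict)
    unavailable: set[str] = field(default_factory=set)

    def register(self, provider: object) -> None:
        self.providers[provider.provider_id] = provider


_prompt_cache: dict[tuple[str, str], LlmPrediction] = {}


def predict_with_provider(
    provider,
    prompt: PromptBundle,
    max_retries: int = 2,
    cache: dict | None = None,
) -> LlmPrediction:
    """Query one provider for one prompt, with caching and retries.

    The cache key is (provider id, sha256 of the rendered prompt); a cache
    hit performs zero provider invocations. A response with no parseable
    positive number counts as a failed attempt; after ``max_retries``
    extra attempts the prediction is returned failed (NaN).
    """
    cache = _prompt_cache if cache is None else cache
    key = (
        provider.provider_id,
        hashlib.sha256(prompt.rendered_prompt.encode()).hexdigest(),
    )
    if key in cache:
        hit = cache[key]
        return LlmPrediction(hit.provider_id, hit.auc_pred, hit.raw_response, True)
    raw = ""
    value = float("nan")
    for _ in range(1 + max_retries):
        raw = provider.complete(prompt.rendered_prompt)
        value = parse_numeric_response(raw)
        if np.isfinite(value) and value > 0:
            break
    result = LlmPrediction(provider.provider_id, value, raw, False)
    cache[key] = result
    return result


def predict_rows(
    provider,
    rows: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    template: str = DEFAULT_TEMPLATE,
    cache: dict | None = None,
) -> pd.Series:
    """Per-row provider predictions, indexed like ``rows``."""
    preds = []
    for _, row in rows.iterrows():
        bundle = render_prompt(row, template, feature_names)
        preds.append(predict_with_provider(provider, bundle, cache=cache).auc_pred)
    return pd.Series(preds, index=rows.index, name=f"llm_{provider.provider_id}")


def build_hybrid_rows(
    base_rows: pd.DataFrame,
    predictions: dict[str, pd.Series],
    variant: str,
    best_provider: str | None = None,
    rng: np.random.Generator | None = None,
    feature_names: Sequence[str] | None = None,
    sigma: float = 0.05,
    multiplier: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Append provider-prediction columns per the fusion variant.

    Returns (augmented frame, names of the appended columns). Providers
    whose predictions are all-NaN (refusals) are dropped from ``Hybrid``.
    ``Max`` additionally jitters the rows when they are a training
    partition -- callers apply it train-side only.
    """
    if variant not in {"Hybrid", "Hybrid_v2", "Max"}:
        raise ValueError(f"unknown hybrid variant {variant!r}")
    rows = base_rows.copy()
    rows.attrs = dict(base_rows.attrs)
    if variant == "Hybrid":
        added = []
        for pid, series in sorted(predictions.items()):
            if series.isna().all():
                continue
            col = f"llm_{pid}"
            rows[col] = series
            added.append(col)
        return rows, added
    if best_provider is None:
        raise ValueError("Hybrid_v2/Max require a designated best provider")
    if best_provider not in predictions:
        raise ValueError(f"no predictions for provider {best_provider!r}")
    col = f"llm_{best_provider}"
    rows[col] = predictions[best_provider]
    if variant == "Max":
        if rng is None:
            raise ValueError("Max variant needs an rng for augmentation")
        aug_features = list(feature_names or []) + [col]
        rows = gaussian_augment(rows, aug_features, rng, sigma, multiplier)
    return rows, [col]
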