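"""Additive feature attributions for fitted risk models.

Attributions are exact interventional Shapley values computed by subset
enumeration against a fixed background sample: the value of a coalition S
for sample x is the mean model output over background rows with the S
features replaced by x's values. Exactness buys the additivity identity —
base value plus the sum of a sample's attributions equals the model's output
for that sample — up to floating-point error, with no sampling noise. The
enumeration costs 2^d model evaluations per background row and sample, so
it is restricted to the post-screening feature counts this pipeline
produces (d <= 14).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = ["AttributionSet", "shapley_attributions", "global_attributions", "local_explanation"]

MAX_EXACT_FEATURES = 14


@dataclass(frozen=True)
class AttributionSet:
    """Per-sample, per-feature additive attributions.

    ``base`` is the mean model output over the background; for every sample
    i, ``base + values[i].sum() == outputs[i]`` (additivity).
    """

    values: np.ndarray  # (n_samples, n_features)
    base: float
    outputs: np.ndarray  # (n_samples,)
    feature_names: tuple[str, ...]

    def ranking(self) -> pd.DataFrame:
        """Global importance: mean absolute attribution, descending."""
        mean_abs = np.abs(self.values).mean(axis=0)
        order = np.argsort(-mean_abs, kind="stable")
        return pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in order],
                "mean_abs_attribution": mean_abs[order],
            }
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.feature_names))


def shapley_attributions(
    predict: callable,
    X: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    feature_names: list[str] | None = None,
    batch_rows: int = 200_000,
) -> AttributionSet:
    """Exact Shapley values of ``predict`` for each row of X.

    ``predict`` maps an (m, d) array to m scalar outputs (for classifiers,
    the positive-class probability). The value function marginalises removed
    features over the background rows (interventional expectation).
    """
    X_arr = np.asarray(X, dtype=float)
    bg = np.asarray(background, dtype=float)
    if X_arr.ndim == 1:
        X_arr = X_arr[None, :]
    n, d = X_arr.shape
    if bg.shape[1] != d:
        raise ValueError(f"background has {bg.shape[1]} features, samples have {d}")
    if d > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration over {d} features needs 2^{d} coalitions; "
            f"limit is {MAX_EXACT_FEATURES}"
        )
    if feature_names is None:
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(d)]
        )
    n_bg = bg.shape[0]
    n_subsets = 1 << d

    # v[i, S] = mean over background of predict(x_i on S, background off S)
    v = np.empty((n, n_subsets))
    masks = np.arange(n_subsets)
    member = ((masks[:, None] >> np.arange(d)[None, :]) & 1).astype(bool)  # (2^d, d)
    for s in range(n_subsets):
        cols = member[s]
        block = np.tile(bg, (n, 1))  # rows grouped by sample
        if cols.any():
            block[:, cols] = np.repeat(X_arr[:, cols], n_bg, axis=0)
        preds = _batched_predict(predict, block, batch_rows)
        v[:, s] = preds.reshape(n, n_bg).mean(axis=1)

    sizes = member.sum(axis=1)
    # Shapley weight for adding feature i to a coalition of size s (of the
    # remaining d-1 features): s! (d-1-s)! / d!
    weights = np.array([1.0 / (d * comb(d - 1, s)) for s in range(d)])
    values = np.zeros((n, d))
    for i in range(d):
        bit = 1 << i
        without = masks[(masks & bit) == 0]
        w = weights[sizes[without]]
        values[:, i] = ((v[:, without | bit] - v[:, without]) * w[None, :]).sum(axis=1)

    base = float(v[:, 0].mean())  # identical across samples by construction
    outputs = v[:, n_subsets - 1]
    return AttributionSet(
        values=values, base=base, outputs=outputs, feature_names=tuple(feature_names)
    )


def _batched_predict(predict, block: np.ndarray, batch_rows: int) -> np.ndarray:
    if len(block) <= batch_rows:
        return np.asarray(predict(block), dtype=float)
    parts = [
        np.asarray(predict(block[i : i + batch_rows]), dtype=float)
        for i in range(0, len(block), batch_rows)
    ]
    return np.concatenate(parts)


def _proba_fn(model, columns=None):
    if not hasattr(model, "predict_proba"):
        raise ValueError("model must expose probability outputs (predict_proba)")
    if columns is not None and getattr(model, "feature_names_in_", None) is not None:
        return lambda A: model.predict_proba(pd.DataFrame(A, columns=columns))[:, 1]
    return lambda A: model.predict_proba(A)[:, 1]


def global_attributions(
    model,
    data: pd.DataFrame,
    background: pd.DataFrame,
) -> tuple[AttributionSet, pd.DataFrame]:
    """Attribution set over a data table plus the global importance ranking."""
    attrs = shapley_attributions(
        _proba_fn(model, list(data.columns)), data, background, list(data.columns)
    )
    return attrs, attrs.ranking()


def local_explanation(
    model,
    sample: pd.Series | pd.DataFrame,
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Signed per-feature contributions for one sample, largest first.

    The contributions plus the base value sum to the model's predicted
    positive-class probability for the sample.
    """
    if isinstance(sample, pd.Series):
        sample = sample.to_frame().T
    if list(sample.columns) != list(background.columns):
        raise ValueError("sample features do not match the background feature set")
    attrs = shapley_attributions(
        _proba_fn(model, list(sample.columns)), sample, background, list(sample.columns)
    )
    out = pd.DataFrame(
        {
            "feature": list(attrs.feature_names),
            "value": np.asarray(sample.iloc[0], dtype=float),
            "contribution": attrs.values[0],
        }
    )
    out["rank"] = np.argsort(np.argsort(-np.abs(out["contribution"]), kind="stable"))
    out = out.sort_values("rank").reset_index(drop=True)
    out.attrs["base"] = attrs.base
    out.attrs["output"] = float(attrs.outputs[0])
    return out
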