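"""Shapley-value attribution, feature pruning, and TR/region aggregation.

A Shapley value phi_j is the average marginal contribution of feature j to
the model output over feature coalitions; contributions satisfy efficiency
(per trial they sum to the model output minus a base value).  Two
computation paths are provided:

* ``tree-exact`` -- exact TreeSHAP for gradient-boosted tree ensembles via
  LightGBM's native contribution predictor (path-dependent value function:
  absent features are marginalized down the tree with training-cover
  weights).  All arithmetic is double precision.
* ``sampling`` -- model-agnostic Monte-Carlo permutation sampling against a
  background sample (absent features take a random background trial's
  values).  Per permutation the telescoping sum makes efficiency exact
  with respect to the sampled baseline.

Attribution magnitudes E(|phi_j|) over trials drive feature pruning (drop
the least informative region/TR pairs, retrain) and the TR- and
region-level relevance aggregations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .decoding import (
    CVConfig,
    DecodingResult,
    FeatureMatrix,
    _undersample,
    crossval_auc,
)

__all__ = [
    "ShapleyMatrix",
    "shapley_values",
    "exact_shapley_bruteforce",
    "rank_features",
    "fit_gbdt",
    "PruneResult",
    "prune_and_retrain",
    "aggregate_shapley",
    "shapley_vs_area",
]


@dataclass
class ShapleyMatrix:
    """Per-trial, per-feature contributions phi.

    ``base_values`` is the expected model output each row is referenced to
    (a constant for the tree path, the per-row sampled baseline for the
    Monte-Carlo path); ``raw_output`` is the model output in margin space.
    Efficiency: each row of ``values`` sums to ``raw_output - base_values``.
    """

    values: np.ndarray
    base_values: np.ndarray
    raw_output: np.ndarray
    columns: list[tuple[str, int]] | None = None
    method: str = "tree-exact"

    @property
    def efficiency_gap(self) -> float:
        """max over trials of |sum_j phi_ij - (f(x_i) - base_i)|."""
        return float(
            np.abs(
                self.values.sum(axis=1) - (self.raw_output - self.base_values)
            ).max()
        )

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


def _get_booster(model):
    import lightgbm as lgb

    if isinstance(model, lgb.Booster):
        return model
    if hasattr(model, "booster_"):
        return model.booster_
    return None


def _output_fn(model):
    """Score function in a monotone-link space (margin / decision value)."""
    booster = _get_booster(model)
    if booster is not None:
        return lambda X: booster.predict(X, raw_score=True)
    if hasattr(model, "decision_function"):
        return model.decision_function
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, 1]
    return model.predict


def shapley_values(
    model,
    features: FeatureMatrix | np.ndarray,
    method: str = "tree-exact",
    *,
    n_samples: int = 200,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> ShapleyMatrix:
    """Shapley contributions for every trial of a feature matrix.

    ``tree-exact`` accepts only tree ensembles (LightGBM); ``sampling``
    works for any model, drawing ``n_samples`` (permutation, background
    trial) pairs per explained trial.
    """
    if isinstance(features, FeatureMatrix):
        X, columns = features.X, features.columns
    else:
        X, columns = np.asarray(features, dtype=float), None

    if method == "tree-exact":
        booster = _get_booster(model)
        if booster is None:
            raise TypeError("tree-exact Shapley values need a tree-ensemble model")
        contrib = np.asarray(booster.predict(X, pred_contrib=True), dtype=float)
        return ShapleyMatrix(
            values=contrib[:, :-1],
            base_values=contrib[:, -1],
            raw_output=np.asarray(
                booster.predict(X, raw_score=True), dtype=float
            ),
            columns=columns,
            method=method,
        )
    if method != "sampling":
        raise ValueError("method must be 'tree-exact' or 'sampling'")

    f = _output_fn(model)
    rng = np.random.default_rng(seed)
    background = X if background is None else np.asarray(background, dtype=float)
    n, m = X.shape
    phi = np.zeros((n, m))
    base = np.zeros(n)
    for i in range(n):
        # walk row k -> k+1 switches the k-th permuted feature from the
        # background value to the explained trial's value
        walks = np.empty((n_samples, m + 1, m))
        perms = np.empty((n_samples, m), dtype=int)
        for s in range(n_samples):
            cur = background[rng.integers(len(background))].copy()
            perm = rng.permutation(m)
            perms[s] = perm
            walks[s, 0] = cur
            for k, j in enumerate(perm):
                cur[j] = X[i, j]
                walks[s, k + 1] = cur
        out = np.asarray(f(walks.reshape(-1, m)), dtype=float).reshape(
            n_samples, m + 1
        )
        diffs = np.diff(out, axis=1)
        acc = np.zeros(m)
        np.add.at(acc, perms.ravel(), diffs.ravel())
        phi[i] = acc / n_samples
        base[i] = out[:, 0].mean()
    raw = np.asarray(f(X), dtype=float)
    return ShapleyMatrix(
        values=phi, base_values=base, raw_output=raw,
        columns=columns, method="sampling",
    )


def exact_shapley_bruteforce(
    model_fn,
    instance: np.ndarray,
    background: np.ndarray,
    max_features: int = 12,
) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^M feature coalitions.

    The value of a coalition S is the model output with features in S taken
    from ``instance`` and the rest marginalized over the ``background``
    sample (interventional convention).  Exponential in M, therefore
    restricted to ``max_features``; serves as the independent oracle for
    the sampling estimator.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    m = instance.size
    if m > max_features:
        raise ValueError(f"brute force limited to {max_features} features, got {m}")
    n_subsets = 1 << m
    b = len(background)
    # composite inputs for every (subset, background row) pair
    composites = np.repeat(background[None, :, :], n_subsets, axis=0)
    for mask in range(n_subsets):
        for j in range(m):
            if mask >> j & 1:
                composites[mask, :, j] = instance[j]
    v = np.asarray(
        model_fn(composites.reshape(n_subsets * b, m)), dtype=float
    ).reshape(n_subsets, b).mean(axis=1)
    phi = np.zeros(m)
    fact = [factorial(k) for k in range(m + 1)]
    for mask in range(n_subsets):
        size = bin(mask).count("1")
        w = fact[size] * fact[m - size - 1] / fact[m]
        for j in range(m):
            if not mask >> j & 1:
                phi[j] += w * (v[mask | (1 << j)] - v[mask])
    return phi


# ---------------------------------------------------------------------------
# ranking / pruning


def rank_features(sh: ShapleyMatrix) -> pd.DataFrame:
    """Features ordered by decreasing E(|phi_j|) (ties keep column order).

    The index is the column position in the originating feature matrix.
    """
    weight = sh.mean_abs()
    order = np.lexsort((np.arange(len(weight)), -weight))
    df = pd.DataFrame({"mean_abs_phi": weight[order]}, index=order)
    df.index.name = "column"
    if sh.columns is not None:
        df["region"] = [sh.columns[i][0] for i in order]
        df["tr_offset"] = [sh.columns[i][1] for i in order]
    return df


def fit_gbdt(
    features: FeatureMatrix,
    seed: int = 0,
    balance: bool = True,
    **params,
):
    """Fit a gradient-boosted tree classifier on the (balanced) full data.

    Trees are scale-invariant so no standardization is applied; this is the
    attribution model the Shapley analysis explains.
    """
    import lightgbm as lgb

    params.setdefault("n_estimators", 300)
    params.setdefault("verbose", -1)
    model = lgb.LGBMClassifier(random_state=seed, **params)
    idx = (
        _undersample(features.y, np.random.default_rng(seed))
        if balance
        else np.arange(len(features.y))
    )
    model.fit(features.X[idx], features.y[idx])
    return model


@dataclass
class PruneResult:
    kept_columns: np.ndarray
    pre: DecodingResult
    post: DecodingResult
    model: object
    keep_fraction: float


def prune_and_retrain(
    model_spec,
    features: FeatureMatrix,
    ranking: pd.DataFrame,
    keep_fraction: float,
    cv: CVConfig | None = None,
) -> PruneResult:
    """Keep the top fraction of features by E(|phi|) and retrain.

    Both the pre-prune and post-prune cross-validated AUC are reported, and
    a final attribution model is refit on the reduced feature set.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    cv = cv or CVConfig()
    n_keep = int(round(keep_fraction * features.n_features))
    if n_keep < 1:
        raise ValueError(
            f"keep_fraction {keep_fraction} retains zero of "
            f"{features.n_features} features"
        )
    kept = np.sort(ranking.index.to_numpy()[:n_keep])
    pre = crossval_auc(features, model_spec, cv)
    reduced = features.select(kept)
    post = crossval_auc(reduced, model_spec, cv)
    model = fit_gbdt(reduced, seed=cv.seed) if _spec_is_tree(model_spec) else None
    return PruneResult(
        kept_columns=kept, pre=pre, post=post, model=model,
        keep_fraction=keep_fraction,
    )


def _spec_is_tree(model_spec) -> bool:
    name = model_spec if isinstance(model_spec, str) else model_spec.get("name")
    return name == "gbdt"


# ---------------------------------------------------------------------------
# aggregation


def _weights(sh: ShapleyMatrix, signed: bool) -> np.ndarray:
    return sh.values.mean(axis=0) if signed else sh.mean_abs()


def aggregate_shapley(
    sh: ShapleyMatrix,
    by: str = "tr",
    window: tuple[int, int] | None = None,
    signed: bool = False,
    normalize: bool = False,
):
    """Aggregate per-feature Shapley weight over the (region, TR) grid.

    ``by='tr'`` returns a long-format table (tr_offset, region, weight) --
    the stacked-histogram data of per-TR region relevance.  ``by='region'``
    sums the weight over the TR offsets of ``window`` (inclusive) per
    region.  Weights default to mean |phi| per trial; ``signed`` uses the
    signed mean instead, ``normalize`` rescales so all feature weights sum
    to one.
    """
    if sh.columns is None:
        raise ValueError("aggregation needs the (region, TR) column mapping")
    df = pd.DataFrame(sh.columns, columns=["region", "tr_offset"])
    df["weight"] = _weights(sh, signed)
    if normalize:
        total = df["weight"].abs().sum()
        if total > 0:
            df["weight"] = df["weight"] / total
    offsets = sorted(df["tr_offset"].unique())
    if by == "tr":
        return (
            df.groupby(["tr_offset", "region"], sort=True)["weight"]
            .sum()
            .reset_index()
        )
    if by != "region":
        raise ValueError("by must be 'tr' or 'region'")
    if window is not None:
        lo, hi = window
        if lo < min(offsets) or hi > max(offsets):
            raise ValueError(
                f"window {window} outside available TR offsets "
                f"[{min(offsets)}, {max(offsets)}]"
            )
        df = df[(df["tr_offset"] >= lo) & (df["tr_offset"] <= hi)]
    return df.groupby("region", sort=True)["weight"].sum()


def shapley_vs_area(
    region_sums: pd.Series,
    area_table: pd.DataFrame,
    critical: float,
) -> pd.DataFrame:
    """Pair each region's Shapley sum with its dArea and relevance flags.

    ``area_table`` is the output of region selection (columns ``delta_area``
    and ``has_maxima``).  The result carries the scatter-quadrant flags:
    dArea exceeding the permutation critical value, and both mean curves
    having an in-window maximum.
    """
    if len(region_sums) == 0 and len(area_table) == 0:
        return pd.DataFrame(
            columns=["shapley_sum", "delta_area", "exceeds_critical", "has_maxima"]
        )
    missing = set(region_sums.index) ^ set(area_table.index)
    if missing:
        raise ValueError(f"region mismatch between tables: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "shapley_sum": region_sums,
            "delta_area": area_table["delta_area"],
            "has_maxima": area_table["has_maxima"],
        }
    )
    out["exceeds_critical"] = out["delta_area"] > critical
    return out[["shapley_sum", "delta_area", "exceeds_critical", "has_maxima"]]
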