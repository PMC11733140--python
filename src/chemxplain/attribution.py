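"""Local attributions (Shapley / LIME-style) and their global aggregation.

Local attributions explain single predictions; the quantity this package
acts on is their aggregate over a dataset: mean absolute Shapley value per
feature, or a cross-feature standardized score for LIME weights, together
with a direction call (positive / negative / unclear) from the sign of the
mean signed attribution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import Ridge

from ._treeshap import interventional_shap, parse_booster
from .data import TASK_CLASSIFICATION, FeatureCatalog, MoleculeTable
from .surrogate import GradientBoostedSurrogate

logger = logging.getLogger(__name__)

LIME_SAMPLE_CAP = 500
SHAP_BACKGROUND_CAP = 100
#: global aggregation attributes at most this many (seeded) rows
GLOBAL_SAMPLE_CAP = 500


@dataclass
class LocalAttribution:
    """Per-row, per-feature attribution matrix phi with base values."""

    values: np.ndarray          # n × d signed attributions
    base_values: np.ndarray     # n, expected prediction over the background
    method: str                 # "tree_shap" | "lime"
    feature_names: list
    sample_row_ids: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    feature_values: Optional[np.ndarray] = None   # the attributed rows, for direction calls

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.base_values = np.asarray(self.base_values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("attribution matrix contains non-finite entries")


@dataclass
class GlobalImportance:
    """Per-feature global score, direction call, and rank."""

    feature_names: list
    scores: np.ndarray          # G_j >= 0
    directions: list            # "positive" | "negative" | "unclear"
    ranks: np.ndarray           # permutation of 1..d
    method: str
    signed_means: np.ndarray
    z: Optional[np.ndarray] = None


@dataclass
class ImpactfulFeatureSet:
    """Top-k features, ordered by descending score."""

    records: list               # {feature, description, direction, score}


class TreeShapExplainer(BaseEstimator):
    """Exact interventional Shapley attributions for the tree surrogate.

    The value function replaces features outside the coalition with rows
    from a background set (the training data, subsampled to
    ``background_cap`` rows). For classification the attribution space is
    the margin (log-odds) — the only space in which tree values are
    additive — recorded in the output metadata.
    """

    def __init__(self, background_cap: int = SHAP_BACKGROUND_CAP, random_state: int = 0):
        self.background_cap = background_cap
        self.random_state = random_state

    def fit(self, model: GradientBoostedSurrogate, background: np.ndarray):
        background = np.asarray(background, dtype=float)
        if background.shape[0] > self.background_cap:
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(background.shape[0], size=self.background_cap, replace=False)
            background = background[np.sort(idx)]
        self.model_ = model
        self.background_ = background
        self.leaves_ = parse_booster(model.booster_, model.feature_names_)
        self.base_value_ = float(np.mean(model.predict_margin(background)))
        return self

    def transform(self, rows, row_ids=None) -> LocalAttribution:
        rows = np.asarray(rows, dtype=float)
        phi = interventional_shap(self.leaves_, rows, self.background_)
        n = rows.shape[0]
        return LocalAttribution(
            values=phi,
            base_values=np.full(n, self.base_value_),
            method="tree_shap",
            feature_names=list(self.model_.feature_names_),
            sample_row_ids=list(row_ids) if row_ids is not None else list(range(n)),
            feature_values=rows,
            metadata={
                "space": "margin" if self.model_.task_kind == TASK_CLASSIFICATION else "prediction",
                "background_rows": int(self.background_.shape[0]),
                "semantics": "interventional",
            },
        )


def local_tree_shap(
    model: GradientBoostedSurrogate,
    rows,
    background=None,
    seed: int = 0,
    row_ids=None,
) -> LocalAttribution:
    """Shapley attributions for ``rows``; background defaults to the rows
    themselves (capped)."""
    rows = np.asarray(rows, dtype=float)
    if rows.shape[1] != len(model.feature_names_):
        raise ValueError(
            f"schema mismatch: expected {len(model.feature_names_)} columns, got {rows.shape[1]}"
        )
    if background is None:
        background = rows
    explainer = TreeShapExplainer(random_state=seed).fit(model, background)
    return explainer.transform(rows, row_ids=row_ids)


def exact_shapley(model, row, background) -> np.ndarray:
    """Brute-force Shapley values by subset enumeration (test oracle).

    v(T) is the mean model margin with features in T fixed to ``row`` and
    the rest replaced by each background row (interventional semantics) —
    the same value function the tree-path closed form computes. Limited to
    d <= 12.
    """
    row = np.asarray(row, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    d = row.shape[0]
    if d > 12:
        raise ValueError("exact_shapley enumeration is limited to d <= 12")
    m = background.shape[0]
    # value of every coalition, one batched predict
    masks = np.array(list(itertools.product([0, 1], repeat=d)), dtype=bool)  # 2^d × d
    hybrids = np.where(masks[:, None, :], row[None, None, :], background[None, :, :])
    preds = model.predict_margin(hybrids.reshape(-1, d)).reshape(len(masks), m)
    v = preds.mean(axis=1)
    vmap = {tuple(mask.nonzero()[0]): val for mask, val in zip(masks, v)}
    phi = np.zeros(d)
    others = list(range(d))
    fact = math.factorial
    for j in range(d):
        rest = [f for f in others if f != j]
        for r in range(d):
            w = fact(r) * fact(d - r - 1) / fact(d)
            for T in itertools.combinations(rest, r):
                with_j = tuple(sorted(T + (j,)))
                phi[j] += w * (vmap[with_j] - vmap[T])
    return phi


def lime_sample(table: MoleculeTable, cap: int = LIME_SAMPLE_CAP, seed: int = 0) -> np.ndarray:
    """Uniform without-replacement row subset of size min(n, cap)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n = table.n
    if n <= cap:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=cap, replace=False))


class LimeExplainer(BaseEstimator):
    """Perturb-and-fit sparse linear local surrogate (LIME-style).

    Each explained row is perturbed ``n_perturb`` times by replacing a
    random subset of features with draws from the training marginals; a
    weighted ridge regression of the model output on same-as-original
    indicators yields per-feature local weights. Kernel width defaults to
    0.75 * sqrt(d) on the indicator (binary) representation, the usual
    tabular-LIME choice.
    """

    def __init__(
        self,
        n_perturb: int = 1000,
        kernel_width: Optional[float] = None,
        ridge_alpha: float = 1.0,
        random_state: int = 0,
    ):
        self.n_perturb = n_perturb
        self.kernel_width = kernel_width
        self.ridge_alpha = ridge_alpha
        self.random_state = random_state

    def fit(self, model: GradientBoostedSurrogate, table: MoleculeTable):
        self.model_ = model
        self.marginals_ = table.features.copy()
        self.d_ = table.d
        self.width_ = self.kernel_width or 0.75 * math.sqrt(table.d)
        return self

    def transform(self, rows, row_ids=None) -> LocalAttribution:
        rows = np.asarray(rows, dtype=float)
        rng = np.random.default_rng(self.random_state)
        n, d = rows.shape
        weights = np.zeros((n, d))
        intercepts = np.zeros(n)
        pool = self.marginals_
        for i in range(n):
            keep = rng.random((self.n_perturb, d)) < 0.5
            draws = pool[rng.integers(0, pool.shape[0], size=(self.n_perturb, d)), np.arange(d)]
            perturbed = np.where(keep, rows[i], draws)
            indicator = (perturbed == rows[i]).astype(float)
            dist = np.sqrt(((1.0 - indicator) ** 2).sum(axis=1))
            kernel = np.exp(-(dist**2) / self.width_**2)
            target = self.model_.predict(perturbed)
            reg = Ridge(alpha=self.ridge_alpha)
            reg.fit(indicator, target, sample_weight=kernel)
            weights[i] = reg.coef_
            intercepts[i] = reg.intercept_
        return LocalAttribution(
            values=weights,
            base_values=intercepts,
            method="lime",
            feature_names=list(self.model_.feature_names_),
            sample_row_ids=list(row_ids) if row_ids is not None else list(range(n)),
            metadata={
                "space": "probability"
                if self.model_.task_kind == TASK_CLASSIFICATION
                else "prediction",
                "n_perturb": self.n_perturb,
                "kernel_width": self.width_,
                "ridge_alpha": self.ridge_alpha,
            },
        )


def local_lime(
    model: GradientBoostedSurrogate,
    table: MoleculeTable,
    row_indices: Optional[np.ndarray] = None,
    seed: int = 0,
) -> LocalAttribution:
    if row_indices is None:
        row_indices = lime_sample(table, seed=seed)
    explainer = LimeExplainer(random_state=seed).fit(model, table)
    return explainer.transform(
        table.features[row_indices], row_ids=[table.row_ids[i] for i in row_indices]
    )


def globalize(local: LocalAttribution) -> GlobalImportance:
    """Aggregate local attributions into per-feature global importance.

    tree_shap: G_j = mean_i |phi_ij|, ranked by G.
    lime: s_j = mean_i |w_ij| standardized across features into z_j;
    G_j = max(z_j, 0), ranked by z_j.

    Direction calls use a signed summary with relative dead-band
    delta = 0.01 * max_j G_j. For LIME the summary is the mean signed local
    weight (a slope). For Shapley values the mean signed value is ~0 by
    construction on balanced features (high rows push one way, low rows the
    other), so the summary is the covariance between the feature's value
    and its attribution — the quantity a beeswarm plot shows — scaled to
    attribution units.
    """
    phi = local.values
    if phi.shape[0] == 0:
        raise ValueError("cannot globalize an empty attribution")
    names = list(local.feature_names)
    d = phi.shape[1]
    mean_abs = np.abs(phi).mean(axis=0)
    if local.method == "tree_shap" and local.feature_values is not None and phi.shape[0] > 1:
        x = np.asarray(local.feature_values, dtype=float)
        xc = x - x.mean(axis=0)
        sd = xc.std(axis=0)
        sd[sd == 0] = 1.0
        signed = (xc * (phi - phi.mean(axis=0))).mean(axis=0) / sd
    else:
        signed = phi.mean(axis=0)
    z = None
    if local.method == "lime":
        sd = mean_abs.std()
        if sd == 0:
            logger.warning("all LIME mean-|weight| scores equal; z-scores set to 0")
            z = np.zeros(d)
        else:
            z = (mean_abs - mean_abs.mean()) / sd
        scores = np.maximum(z, 0.0)
        rank_key = z
    else:
        scores = mean_abs
        rank_key = mean_abs
    order = sorted(range(d), key=lambda j: (-rank_key[j], names[j]))
    ranks = np.empty(d, dtype=int)
    for pos, j in enumerate(order):
        ranks[j] = pos + 1
    delta = 0.01 * scores.max() if scores.max() > 0 else 0.0
    directions = [
        "positive" if signed[j] > delta else ("negative" if signed[j] < -delta else "unclear")
        for j in range(d)
    ]
    return GlobalImportance(
        feature_names=names,
        scores=scores,
        directions=directions,
        ranks=ranks,
        method=local.method,
        signed_means=signed,
        z=z,
    )


def top_k(global_imp: GlobalImportance, catalog: FeatureCatalog, k: int = 3) -> ImpactfulFeatureSet:
    """Top-k features by score; ties broken lexicographically by name."""
    d = len(global_imp.feature_names)
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    order = np.argsort(global_imp.ranks)
    records = []
    for j in order[:k]:
        name = global_imp.feature_names[j]
        records.append(
            {
                "feature": name,
                "description": catalog.describe(name),
                "direction": global_imp.directions[j],
                "score": float(global_imp.scores[j]),
            }
        )
    return ImpactfulFeatureSet(records=records)


def global_importance(
    model: GradientBoostedSurrogate,
    table: MoleculeTable,
    method: str = "tree_shap",
    seed: int = 0,
) -> GlobalImportance:
    """End-to-end: sample rows (cap 500), attribute, aggregate."""
    if method == "tree_shap":
        idx = lime_sample(table, cap=GLOBAL_SAMPLE_CAP, seed=seed)
        local = local_tree_shap(
            model,
            table.features[idx],
            background=table.features,
            seed=seed,
            row_ids=[table.row_ids[i] for i in idx],
        )
    elif method == "lime":
        local = local_lime(model, table, seed=seed)
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    return globalize(local)


def export_importance_plot(global_imp: GlobalImportance, path, max_bars: int = 15) -> None:
    """Horizontal bar chart of the top features, colored by direction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = len(global_imp.feature_names)
    if d == 0:
        raise ValueError("empty importance")
    order = np.argsort(global_imp.ranks)[: min(max_bars, d)][::-1]
    colors = {"positive": "#2166ac", "negative": "#b2182b", "unclear": "#999999"}
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(order) + 1.2))
    ax.barh(
        [global_imp.feature_names[j] for j in order],
        [global_imp.scores[j] for j in order],
        color=[colors[global_imp.directions[j]] for j in order],
    )
    label = "mean |SHAP|" if global_imp.method == "tree_shap" else "max(z, 0) of mean |weight|"
    ax.set_xlabel(label)
    ax.set_title(f"global feature importance ({global_imp.method})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
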