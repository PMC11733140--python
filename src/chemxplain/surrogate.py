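"""Gradient-boosted-tree surrogate model over the feature table.

The surrogate stands in for the unknown structure-property mapping and is
the object every attribution method explains. Hyperparameters are fixed
(and logged) rather than searched, trading a little accuracy for run-to-run
auditability; training is single-threaded so refits are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator
from sklearn.metrics import accuracy_score, f1_score, r2_score
from sklearn.model_selection import train_test_split

from .data import TASK_CLASSIFICATION, TASK_REGRESSION, MoleculeTable

logger = logging.getLogger(__name__)

HOLDOUT_FRACTION = 0.2

#: fixed surrogate hyperparameters, exposed read-only in the run log
DEFAULT_HYPERPARAMS = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "reg_lambda": 1.0,
    "tree_method": "hist",
    "n_jobs": 1,
}


class GradientBoostedSurrogate(BaseEstimator):
    """XGBoost-backed surrogate with a name-based column schema.

    Parameters
    ----------
    task_kind : {"classification", "regression"}
    random_state : int
        Seed passed to the booster.
    n_jobs : int
        Kept at 1 by default; parallel training can break bit-level
        reproducibility of refits.

    Attributes
    ----------
    feature_names_ : list of str
        Schema frozen at fit time; prediction inputs are matched by name.
    booster_ : xgboost.Booster
    hyperparameters_ : dict
    """

    def __init__(self, task_kind: str = TASK_REGRESSION, random_state: int = 0, n_jobs: int = 1):
        self.task_kind = task_kind
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        if self.task_kind == TASK_CLASSIFICATION and len(np.unique(y)) < 2:
            raise ValueError("classification labels are single-class")
        params = dict(DEFAULT_HYPERPARAMS)
        params["n_jobs"] = self.n_jobs
        cls = xgb.XGBClassifier if self.task_kind == TASK_CLASSIFICATION else xgb.XGBRegressor
        model = cls(random_state=self.random_state, **params)
        model.fit(pd.DataFrame(X, columns=feature_names), y)
        self.feature_names_ = list(feature_names)
        self._sk_model = model
        self.booster_ = model.get_booster()
        self.hyperparameters_ = params
        return self

    def _check_frame(self, rows) -> pd.DataFrame:
        """Accept an array (columns in schema order) or a DataFrame (matched
        by name, order-insensitive)."""
        if isinstance(rows, pd.DataFrame):
            unknown = [c for c in rows.columns if c not in self.feature_names_]
            missing = [c for c in self.feature_names_ if c not in rows.columns]
            if unknown or missing:
                raise ValueError(
                    f"schema mismatch: unknown column(s) {unknown}, missing column(s) {missing}"
                )
            return rows[self.feature_names_].astype(float)
        rows = np.asarray(rows, dtype=float)
        if rows.ndim == 1:
            rows = rows[None, :]
        if rows.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"schema mismatch: expected {len(self.feature_names_)} columns, got {rows.shape[1]}"
            )
        return pd.DataFrame(rows, columns=self.feature_names_)

    def predict(self, rows) -> np.ndarray:
        """Regression: real values. Classification: probability of class 1.

        Always routed through the raw booster so fitted and deserialized
        models predict identically."""
        df = self._check_frame(rows)
        out = self.booster_.predict(xgb.DMatrix(df)).astype(float)
        return out

    def predict_margin(self, rows) -> np.ndarray:
        """Raw additive tree output (log-odds for classification); this is
        the space tree-ensemble Shapley attributions live in."""
        df = self._check_frame(rows)
        return self.booster_.predict(xgb.DMatrix(df), output_margin=True).astype(float)


@dataclass
class EvalReport:
    """Holdout evaluation of a fitted surrogate."""

    task_kind: str
    metrics: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    train_size: int
    test_size: int
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)


def fit_surrogate(table: MoleculeTable, split_seed: int = 0):
    """Train on an 80/20 split (stratified for classification) and evaluate
    on the holdout only. Deterministic given (table, split_seed)."""
    if table.n < 10:
        raise ValueError(f"need at least 10 rows to fit a surrogate, got {table.n}")
    stratify = table.labels if table.task_kind == TASK_CLASSIFICATION else None
    if table.task_kind == TASK_CLASSIFICATION and len(np.unique(table.labels)) < 2:
        raise ValueError("classification labels are single-class")
    idx_train, idx_test = train_test_split(
        np.arange(table.n),
        test_size=HOLDOUT_FRACTION,
        random_state=split_seed,
        stratify=stratify,
    )
    model = GradientBoostedSurrogate(task_kind=table.task_kind, random_state=split_seed)
    model.fit(
        table.features[idx_train], table.labels[idx_train], feature_names=table.feature_names
    )
    y_true = table.labels[idx_test]
    if table.task_kind == TASK_CLASSIFICATION:
        proba = model.predict(table.features[idx_test])
        y_pred = (proba >= 0.5).astype(float)
        metrics = {
            "accuracy": float(accuracy_score(y_true, y_pred)),
            "f1": float(f1_score(y_true, y_pred)),
        }
    else:
        y_pred = model.predict(table.features[idx_test])
        metrics = {
            "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
            "r2": float(r2_score(y_true, y_pred)) if len(y_true) > 1 else float("nan"),
        }
    logger.info("surrogate hyperparameters: %s", model.hyperparameters_)
    logger.info("holdout metrics: %s", metrics)
    report = EvalReport(
        task_kind=table.task_kind,
        metrics=metrics,
        y_true=np.asarray(y_true, dtype=float),
        y_pred=np.asarray(y_pred, dtype=float),
        train_size=len(idx_train),
        test_size=len(idx_test),
        train_ids=[table.row_ids[i] for i in idx_train],
        test_ids=[table.row_ids[i] for i in idx_test],
    )
    return model, report


def predict(model: GradientBoostedSurrogate, rows) -> np.ndarray:
    return model.predict(rows)


def save_model(model: GradientBoostedSurrogate, path) -> None:
    """Self-describing JSON: schema + hyperparameters + raw booster."""
    raw = model.booster_.save_raw("json").decode()
    payload = {
        "task_kind": model.task_kind,
        "feature_names": model.feature_names_,
        "hyperparameters": model.hyperparameters_,
        "random_state": model.random_state,
        "booster_json": raw,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> GradientBoostedSurrogate:
    with open(path) as fh:
        payload = json.load(fh)
    model = GradientBoostedSurrogate(
        task_kind=payload["task_kind"], random_state=payload["random_state"]
    )
    booster = xgb.Booster()
    booster.load_model(bytearray(payload["booster_json"].encode()))
    model.feature_names_ = payload["feature_names"]
    model.booster_ = booster
    model.hyperparameters_ = dict(payload["hyperparameters"])
    return model


def export_eval_plot(report: EvalReport, path) -> None:
    """Parity scatter (regression) or confusion-matrix heatmap
    (classification)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.test_size == 0 or len(report.y_true) == 0:
        raise ValueError("empty evaluation report")
    fig, ax = plt.subplots(figsize=(4.5, 4))
    if report.task_kind == TASK_REGRESSION:
        ax.scatter(report.y_true, report.y_pred, s=12, alpha=0.7)
        lo = float(min(report.y_true.min(), report.y_pred.min()))
        hi = float(max(report.y_true.max(), report.y_pred.max()))
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("true")
        ax.set_ylabel("predicted")
        ax.set_title(f"parity plot (RMSE={report.metrics['rmse']:.3g})")
    else:
        from sklearn.metrics import confusion_matrix

        cm = confusion_matrix(report.y_true, report.y_pred, labels=[0, 1])
        im = ax.imshow(cm, cmap="Blues")
        for (i, j), v in np.ndenumerate(cm):
            ax.text(j, i, str(v), ha="center", va="center")
        ax.set_xticks([0, 1]), ax.set_yticks([0, 1])
        ax.set_xlabel("predicted"), ax.set_ylabel("true")
        ax.set_title(f"confusion matrix (acc={report.metrics['accuracy']:.3g})")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
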