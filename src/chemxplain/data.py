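"""Tabular input handling, MACCS featurization, and synthetic fixtures.

The package consumes a molecular dataset in one of two shapes: a CSV of
precomputed human-interpretable feature columns plus a target label column,
or a CSV with a SMILES column that is featurized internally into the 167
public MACCS keys. Either way the validated in-memory container is a
:class:`MoleculeTable`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_MACCS_BITS = 167

TASK_CLASSIFICATION = "classification"
TASK_REGRESSION = "regression"


@dataclass
class MoleculeTable:
    """Validated feature matrix + label vector for one modelling task.

    Parameters
    ----------
    row_ids : list of str
        Opaque identifiers, one per row.
    feature_names : list of str
        Unique, nonempty column names; order fixes the column order of
        ``features``.
    features : ndarray of shape (n, d)
        Numeric feature values, no NaNs.
    labels : ndarray of shape (n,)
        Target values; exactly ``{0, 1}`` for classification.
    task_kind : {"classification", "regression"}
    provenance : {"loaded", "featurized", "synthetic"}
    dropped : list of dict
        Reason-coded records ``{"row": i, "reason": code}`` for rows removed
        during validation.
    """

    row_ids: list
    feature_names: list
    features: np.ndarray
    labels: np.ndarray
    task_kind: str
    provenance: str = "loaded"
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError("table must have at least one row and one feature")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match feature matrix")
        if len(set(self.feature_names)) != d or any(not f for f in self.feature_names):
            raise ValueError("feature names must be unique and nonempty")
        if len(self.row_ids) != n or len(self.labels) != n:
            raise ValueError("row_ids/labels length does not match feature matrix")
        if not np.isfinite(self.features).all():
            raise ValueError("feature matrix contains non-finite values")
        if not np.isfinite(self.labels).all():
            raise ValueError("label vector contains non-finite values")
        if self.task_kind not in (TASK_CLASSIFICATION, TASK_REGRESSION):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.task_kind == TASK_CLASSIFICATION:
            if not set(np.unique(self.labels)) <= {0.0, 1.0}:
                raise ValueError("classification labels must take values in {0, 1}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = self.labels
        return df

    def write_csv(self, path, label_column: str = "label") -> None:
        self.to_frame(label_column).to_csv(path, index=False)


@dataclass
class FeatureCatalog:
    """Mapping from feature names to human-readable descriptions."""

    entries: dict
    source_tag: str = "passthrough"

    @classmethod
    def maccs_standard(cls) -> "FeatureCatalog":
        """Catalog of the 167 public MACCS key definitions (bit 0 is the
        conventional unused placeholder)."""
        text = (
            resources.files("chemxplain")
            .joinpath("resources/maccs_keys.tsv")
            .read_text()
        )
        entries = {}
        for line in text.strip().splitlines()[1:]:
            idx, code, desc = line.split("\t")
            entries[maccs_feature_name(int(idx))] = desc
        return cls(entries=entries, source_tag="maccs_standard")

    @classmethod
    def passthrough(cls) -> "FeatureCatalog":
        return cls(entries={}, source_tag="passthrough")

    @classmethod
    def user_supplied(cls, entries: dict) -> "FeatureCatalog":
        return cls(entries=dict(entries), source_tag="user_supplied")

    def describe(self, name: str) -> str:
        if name in self.entries:
            return self.entries[name]
        if self.source_tag != "passthrough":
            logger.warning("no catalog description for feature %r; using the name itself", name)
        return name


def maccs_feature_name(bit: int) -> str:
    return f"maccs_{bit}"


@dataclass
class SyntheticSpec:
    """Parameters of the planted binary-feature generator.

    Features are i.i.d. Bernoulli(0.5); the label depends linearly on the
    planted support S through signed weights, with Gaussian noise (regression)
    or a logistic link with intercept balancing the classes (classification).
    """

    n: int
    d: int
    planted_support: Sequence[int]
    planted_weights: Sequence[float]
    noise_sd: float = 0.0
    task_kind: str = TASK_REGRESSION
    seed: int = 0

    def validate(self) -> None:
        s = list(self.planted_support)
        if self.n < 1 or self.d < 1:
            raise ValueError("n and d must be positive")
        if len(s) != len(set(s)) or len(s) > self.d:
            raise ValueError("planted support must be distinct indices, |S| <= d")
        if any(j < 0 or j >= self.d for j in s):
            raise ValueError("planted support indices out of range")
        if len(self.planted_weights) != len(s):
            raise ValueError("one weight per planted feature required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.task_kind not in (TASK_CLASSIFICATION, TASK_REGRESSION):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_synthetic(spec: SyntheticSpec) -> MoleculeTable:
    """Draw a reproducible table with a sparse planted feature-label relation."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    x = rng.integers(0, 2, size=(spec.n, spec.d)).astype(float)
    support = np.asarray(list(spec.planted_support), dtype=int)
    weights = np.asarray(list(spec.planted_weights), dtype=float)
    lin = x[:, support] @ weights
    if spec.task_kind == TASK_REGRESSION:
        y = lin + rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else lin
    else:
        # intercept centering the linear term keeps the marginal positive
        # rate at ~0.5 (feature marginals are symmetric Bernoulli(0.5))
        b = -0.5 * weights.sum()
        p = 1.0 / (1.0 + np.exp(-(lin + b)))
        y = rng.binomial(1, p).astype(float)
    return MoleculeTable(
        row_ids=[f"synth_{i}" for i in range(spec.n)],
        feature_names=[f"f{j}" for j in range(spec.d)],
        features=x,
        labels=y,
        task_kind=spec.task_kind,
        provenance="synthetic",
    )


def maccs_featurize(smiles: Sequence[str]):
    """Featurize SMILES into the 167-bit public MACCS keys.

    Returns
    -------
    feature_names : list of str
    features : ndarray of shape (n_valid, 167), values in {0, 1}
    excluded : list of int
        Input indices whose SMILES failed to parse.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    rows, excluded = [], []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        if mol is None:
            excluded.append(i)
            continue
        fp = MACCSkeys.GenMACCSKeys(mol)
        rows.append(np.array([fp.GetBit(b) for b in range(N_MACCS_BITS)], dtype=float))
    if not rows:
        raise ValueError("no valid molecules")
    if excluded:
        logger.warning("excluded %d unparseable SMILES at indices %s", len(excluded), excluded)
    names = [maccs_feature_name(b) for b in range(N_MACCS_BITS)]
    return names, np.vstack(rows), excluded


def humanize_features(names: Sequence[str], catalog: FeatureCatalog) -> list:
    """Resolve feature names to readable descriptions (total function)."""
    return [catalog.describe(n) for n in names]


def infer_task_kind(labels: np.ndarray) -> str:
    vals = set(np.unique(labels[np.isfinite(labels)]))
    return TASK_CLASSIFICATION if vals <= {0.0, 1.0} else TASK_REGRESSION


def load_table(
    path,
    label_column: str = "label",
    smiles_column: Optional[str] = None,
    task_override: Optional[str] = None,
) -> MoleculeTable:
    """Read and validate a CSV dataset.

    Rows with a missing label, an unparseable feature value, or (when
    featurizing) an invalid SMILES are dropped with a reason code recorded in
    ``table.dropped`` and counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not present in {path.name}")

    dropped = []
    labels_raw = pd.to_numeric(df[label_column], errors="coerce")
    for i in np.flatnonzero(~np.isfinite(labels_raw.to_numpy(dtype=float, na_value=np.nan))):
        dropped.append({"row": int(i), "reason": "missing_label"})
    keep = np.isfinite(labels_raw.to_numpy(dtype=float, na_value=np.nan))

    if smiles_column is not None:
        if smiles_column not in df.columns:
            raise ValueError(f"smiles column {smiles_column!r} not present in {path.name}")
        sub = df.loc[keep]
        names, feats, excluded = maccs_featurize(sub[smiles_column].astype(str).tolist())
        sub_idx = sub.index.to_numpy()
        for j in excluded:
            dropped.append({"row": int(sub_idx[j]), "reason": "invalid_smiles"})
        valid_mask = np.ones(len(sub), dtype=bool)
        valid_mask[excluded] = False
        row_idx = sub_idx[valid_mask]
        labels = labels_raw.to_numpy(dtype=float)[row_idx]
        provenance = "featurized"
    else:
        feat_cols = [c for c in df.columns if c != label_column]
        if not feat_cols:
            raise ValueError("no feature columns present")
        feats_df = df[feat_cols].apply(pd.to_numeric, errors="coerce")
        if feats_df.isna().all().any():
            bad = [c for c in feat_cols if feats_df[c].isna().all()]
            raise ValueError(
                f"non-numeric feature column(s) {bad} and no SMILES column to featurize"
            )
        row_ok = ~feats_df.isna().any(axis=1).to_numpy()
        for i in np.flatnonzero(~row_ok & keep):
            dropped.append({"row": int(i), "reason": "bad_feature_value"})
        sel = keep & row_ok
        row_idx = np.flatnonzero(sel)
        names = feat_cols
        feats = feats_df.to_numpy(dtype=float)[row_idx]
        labels = labels_raw.to_numpy(dtype=float)[row_idx]
        provenance = "loaded"

    if len(row_idx) == 0:
        raise ValueError("zero rows survive validation")
    for rec in dropped:
        logger.info("dropped row %d: %s", rec["row"], rec["reason"])
    if dropped:
        logger.warning("dropped %d of %d rows during validation", len(dropped), len(df))

    task = task_override or infer_task_kind(labels)
    return MoleculeTable(
        row_ids=[str(df.index[i]) for i in row_idx],
        feature_names=list(names),
        features=feats,
        labels=labels,
        task_kind=task,
        provenance=provenance,
        dropped=dropped,
    )


def generate_synthetic_corpus(
    claims: Sequence[tuple],
    property_name: str,
    out_dir,
    n_filler: int = 2,
    seed: int = 0,
) -> None:
    """Write a toy literature corpus of short plain-text documents.

    ``claims`` is a sequence of (feature_description, direction) pairs with
    direction in {"positive", "negative", "unclear"}; each directional claim
    becomes one document asserting it ("... increases/decreases <property>"),
    plus ``n_filler`` off-topic documents. Deterministic under seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    year = 2015
    for i, (desc, direction) in enumerate(claims):
        year_i = year + int(rng.integers(0, 10))
        if direction == "positive":
            body = (
                f"We report that a higher count of {desc} increases {property_name}. "
                f"Across the studied series, introducing {desc} enhances {property_name} "
                f"through stronger intermolecular interactions."
            )
        elif direction == "negative":
            body = (
                f"Our measurements show that {desc} decreases {property_name}. "
                f"Substituents adding {desc} systematically reduce {property_name} "
                f"by disrupting the relevant packing motif."
            )
        else:
            body = (
                f"The role of {desc} with respect to {property_name} remains debated; "
                f"no consistent trend was observed in our screening campaign."
            )
        title = f"On the role of {desc} in {property_name}"
        (out_dir / f"study{i}_{year_i}.txt").write_text(f"{title}\n\n{body}\n")
    for i in range(n_filler):
        (out_dir / f"filler{i}.txt").write_text(
            f"Filler article {i}\n\nUnrelated synthesis protocol and "
            f"crystallographic refinement details, with no property claims.\n"
        )


def write_exclusion_report(table: MoleculeTable, path) -> None:
    """JSON-lines report of reason-coded dropped rows."""
    with open(path, "w") as fh:
        for rec in table.dropped:
            fh.write(json.dumps(rec) + "\n")
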