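"""Scoring of generated explanations.

Three complementary evaluators: (1) hypothesis precision — a consistency
score over repeated generation runs that weights per-feature direction
labels +1 (positive), -1 (negative), 0 (unclear) and normalizes by
features × runs; (2) ROUGE-L variability — pairwise longest-common-
subsequence F1 across runs, measuring how much the wording drifts; and
(3) a structural citation audit — every citation must resolve to an
ingested document and the cited chunk must actually mention the feature.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import FeatureCatalog
from .retrieval import CorpusIndex

logger = logging.getLogger(__name__)

DIRECTIONS = ("positive", "negative", "unclear")


@dataclass
class HypothesisTally:
    """Per-feature direction-label counts across runs."""

    features: list
    counts: dict            # feature -> {"positive": int, "negative": int, "unclear": int}
    n_features: int
    n_runs: int

    def validate(self) -> None:
        for f in self.features:
            c = self.counts[f]
            if any(c[d] < 0 for d in DIRECTIONS):
                raise ValueError("negative count")
            if sum(c[d] for d in DIRECTIONS) != self.n_runs:
                raise ValueError(f"counts for {f} do not sum to n_runs")


@dataclass
class PrecisionResult:
    precision: float
    per_feature: dict       # feature -> |n_pos - n_neg|


@dataclass
class RougeReport:
    pairs: list             # {run_a, run_b, lcs, recall, precision, f}
    mean_f: float
    sd_f: float


@dataclass
class CitationAudit:
    records: list           # per citation: explanation, feature, doc_id, resolved, supported
    correct: int
    total: int
    per_explanation: dict = field(default_factory=dict)
    mean_normalized: float = float("nan")


def tally_hypotheses(explanations: Sequence) -> HypothesisTally:
    """Count each feature's direction label per run; a feature absent from a
    run counts as unclear for that run, so every feature sums to N_runs."""
    runs = [e for e in explanations if not getattr(e, "failed", False)]
    if not runs:
        raise ValueError("no successful explanations to tally")
    features: list = []
    for e in runs:
        for hyp in e.hypotheses:
            if hyp["feature"] not in features:
                features.append(hyp["feature"])
    counts = {f: {d: 0 for d in DIRECTIONS} for f in features}
    for e in runs:
        seen = {}
        for hyp in e.hypotheses:
            seen[hyp["feature"]] = hyp["direction"]
        for f in features:
            counts[f][seen.get(f, "unclear")] += 1
    tally = HypothesisTally(
        features=features, counts=counts, n_features=len(features), n_runs=len(runs)
    )
    tally.validate()
    return tally


def precision(tally: HypothesisTally) -> PrecisionResult:
    """Consistency score in [0, 1]:
    (1 / (N_features * N_runs)) * sum_i |n_i,positive - n_i,negative|."""
    tally.validate()
    if tally.n_features < 1 or tally.n_runs < 1:
        raise ValueError("tally must cover at least one feature and one run")
    per = {
        f: abs(tally.counts[f]["positive"] - tally.counts[f]["negative"])
        for f in tally.features
    }
    value = sum(per.values()) / (tally.n_features * tally.n_runs)
    return PrecisionResult(precision=float(value), per_feature=per)


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Dynamic-programming longest-common-subsequence length."""
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for tok in a:
        cur = prev.copy()
        for j, btok in enumerate(b, start=1):
            if tok == btok:
                cur[j] = prev[j - 1] + 1
            elif cur[j - 1] > cur[j]:
                cur[j] = cur[j - 1]
        prev = cur
    return int(prev[-1])


def _whitespace_tokens(text: str) -> list:
    return text.split()


def rouge_l(candidate: str, reference: str):
    """Token-level ROUGE-L with whitespace tokenization and the F1 (beta=1)
    convention: R = LCS/|ref|, P = LCS/|cand|, F = 2RP/(R+P)."""
    cand = _whitespace_tokens(candidate)
    ref = _whitespace_tokens(reference)
    if not cand or not ref:
        return 0.0, 0.0, 0.0
    lcs = lcs_length(cand, ref)
    r = lcs / len(ref)
    p = lcs / len(cand)
    f = 2 * r * p / (r + p) if (r + p) > 0 else 0.0
    return r, p, f


def rouge_variability(explanations: Sequence) -> RougeReport:
    """Pairwise ROUGE-L F over all unordered run pairs, with mean and SD."""
    texts = [
        (getattr(e, "run_id", str(i)), e.text if hasattr(e, "text") else e)
        for i, e in enumerate(explanations)
        if not getattr(e, "failed", False)
    ]
    if len(texts) < 2:
        raise ValueError("need at least 2 explanations for variability")
    pairs = []
    fs = []
    for (ida, ta), (idb, tb) in itertools.combinations(texts, 2):
        r, p, f = rouge_l(ta, tb)
        lcs = lcs_length(_whitespace_tokens(ta), _whitespace_tokens(tb))
        pairs.append(
            {"run_a": ida, "run_b": idb, "lcs": lcs, "recall": r, "precision": p, "f": f}
        )
        fs.append(f)
    return RougeReport(pairs=pairs, mean_f=float(np.mean(fs)), sd_f=float(np.std(fs)))


def audit_citations(
    explanations: Sequence,
    registry: CorpusIndex,
    catalog: FeatureCatalog,
) -> CitationAudit:
    """Structural citation audit.

    A citation is *resolved* iff its doc_id is registered (and the chunk
    exists); *supported* iff the cited chunk's text contains the feature
    description, the feature name, or a catalog synonym (case-insensitive
    substring). Counts are reported raw and normalized per explanation.
    """
    chunk_map = {(c.doc_id, c.chunk_index): c for c in registry.chunks}
    records = []
    per_expl: dict = {}
    for e in explanations:
        if getattr(e, "failed", False):
            continue
        c_total = c_correct = 0
        for hyp in e.hypotheses:
            needles = {hyp["description"].lower(), hyp["feature"].lower()}
            syn = catalog.entries.get(hyp["feature"])
            if syn:
                needles.add(syn.lower())
            for doc_id, idx in hyp["citations"]:
                resolved = doc_id in registry.doc_registry and (doc_id, idx) in chunk_map
                supported = False
                if resolved:
                    text = chunk_map[(doc_id, idx)].text.lower()
                    supported = any(n in text for n in needles if n)
                records.append(
                    {
                        "explanation": e.run_id,
                        "feature": hyp["feature"],
                        "doc_id": doc_id,
                        "chunk_index": idx,
                        "resolved": resolved,
                        "supported": supported,
                    }
                )
                c_total += 1
                c_correct += resolved and supported
        if c_total:
            per_expl[e.run_id] = {"correct": c_correct, "total": c_total}
    correct = sum(r["resolved"] and r["supported"] for r in records)
    total = len(records)
    normalized = [v["correct"] / v["total"] for v in per_expl.values()]
    return CitationAudit(
        records=records,
        correct=correct,
        total=total,
        per_explanation=per_expl,
        mean_normalized=float(np.mean(normalized)) if normalized else float("nan"),
    )
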