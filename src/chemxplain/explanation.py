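"""Prompt assembly, text generation backends, and citation handling.

Retrieved excerpts are "stuffed" into a chain-of-thought prompt that walks
the generator through the reasoning: state each feature's correlation
direction, propose a physical mechanism, cite only the provided excerpts,
and fall back to a verbatim disclaimer when the corpus offers no support.
Generation is pluggable behind a small backend contract; the built-in mock
backend is deterministic and rule-based, which makes every downstream
evaluator testable without any language model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .attribution import ImpactfulFeatureSet
from .retrieval import CorpusIndex, RetrievalResult

logger = logging.getLogger(__name__)

TEMPLATE_VERSION = "cx-prompt-1"
NO_EVIDENCE = "NO_EVIDENCE"
DISCLAIMER = "an explicit relationship was not found in the given documents"

POSITIVE_KEYWORDS = (
    "increase", "increases", "increased", "increasing",
    "enhance", "enhances", "enhanced", "enhancing",
    "improve", "improves", "improved", "improving",
    "promote", "promotes", "promoted",
    "raise", "raises", "raised", "higher",
)
NEGATIVE_KEYWORDS = (
    "decrease", "decreases", "decreased", "decreasing",
    "reduce", "reduces", "reduced", "reducing",
    "lower", "lowers", "lowered", "lowering",
    "diminish", "diminishes", "diminished",
    "suppress", "suppresses", "suppressed",
)


@dataclass
class PromptBundle:
    """Rendered generation context: preamble, per-feature evidence blocks,
    and task instructions."""

    preamble: str
    property_name: str
    feature_blocks: list          # {feature, description, direction, excerpts}
    instructions: str
    template_version: str = TEMPLATE_VERSION


@dataclass
class Citation:
    key: str                      # rendered marker, e.g. "(Smith, 2020)"
    doc_id: str
    chunk_index: int


@dataclass
class Explanation:
    """One generated, parsed explanation run."""

    run_id: str
    seed: int
    text: str
    hypotheses: list              # {feature, description, direction, supported, citations}
    citations: list = field(default_factory=list)
    failed: bool = False
    error: Optional[str] = None
    unresolved: int = 0


def assemble_prompt(
    features: ImpactfulFeatureSet,
    retrievals: dict,
    property_name: str,
) -> PromptBundle:
    """Build the stuffed chain-of-thought prompt bundle.

    ``retrievals`` maps feature name -> RetrievalResult; a feature with no
    retrieved excerpts is still included with an empty-evidence block
    carrying the NO_EVIDENCE marker.
    """
    if not features.records:
        raise ValueError("features must be nonempty")
    preamble = (
        "You are a chemistry research assistant. A surrogate model was trained "
        f"to predict '{property_name}' and analyzed with explainable-AI methods. "
        "The most impactful input features and supporting literature excerpts follow."
    )
    blocks = []
    for rec in features.records:
        result: Optional[RetrievalResult] = retrievals.get(rec["feature"])
        excerpts = []
        if result is not None:
            for chunk, sim in zip(result.chunks, result.similarities):
                excerpts.append(
                    {
                        "text": chunk.text,
                        "doc_id": chunk.doc_id,
                        "chunk_index": chunk.chunk_index,
                        "similarity": float(sim),
                    }
                )
        blocks.append(
            {
                "feature": rec["feature"],
                "description": rec["description"],
                "direction": rec["direction"],
                "excerpts": excerpts,
            }
        )
    instructions = (
        "For each feature, reason step by step:\n"
        "1. State the direction of the correlation found by the XAI analysis "
        "(positive, negative, or unclear).\n"
        "2. Propose a physicochemical mechanism linking the feature to the "
        "target property.\n"
        "3. Support every claim by citing ONLY the provided excerpts, using "
        "their [CITE doc:chunk] tags.\n"
        f"4. If the excerpts do not support the claim, state verbatim: "
        f"'{DISCLAIMER}'.\n"
        "Worked example: 'Feature X correlates positively with the property; "
        "excerpt [CITE ab12:0] reports that increasing X enhances the "
        "property, consistent with mechanism M.'"
    )
    return PromptBundle(
        preamble=preamble,
        property_name=property_name,
        feature_blocks=blocks,
        instructions=instructions,
    )


def render_prompt(bundle: PromptBundle) -> str:
    """Deterministic textual rendering of the bundle."""
    parts = [bundle.preamble, "", bundle.instructions, ""]
    for block in bundle.feature_blocks:
        parts.append(f"## FEATURE: {block['description']}")
        parts.append(f"FEATURE_NAME: {block['feature']}")
        parts.append(f"XAI_DIRECTION: {block['direction']}")
        if not block["excerpts"]:
            parts.append(NO_EVIDENCE)
        for ex in block["excerpts"]:
            parts.append(f"[SOURCE {ex['doc_id']}:{ex['chunk_index']}]")
            parts.append(ex["text"].strip())
        parts.append("")
    parts.append(f"TEMPLATE_VERSION: {bundle.template_version}")
    return "\n".join(parts)


class GenerationBackend:
    """Contract: name, determinism flag, generate(prompt, seed) -> text."""

    name = "abstract"
    deterministic = False

    def generate(self, prompt: str, seed: int) -> str:  # pragma: no cover
        raise NotImplementedError


class MockBackend(GenerationBackend):
    """Deterministic rule-based generator.

    Scans each feature block's excerpts for direction keywords
    ("increase(s)", "enhance(s)" ... vs "decrease(s)", "reduce(s)" ...),
    emits a fixed-format explanation with machine-parseable DIRECTION tags,
    and cites the first excerpt containing a keyword. Features without
    keyword evidence receive the verbatim disclaimer. Identical
    (prompt, seed) pairs produce identical text.
    """

    name = "mock"
    deterministic = True

    def generate(self, prompt: str, seed: int) -> str:
        blocks = _parse_prompt_blocks(prompt)
        prop = _parse_property(prompt)
        out = [f"Explanation of the structure-property relationships for '{prop}'."]
        for block in blocks:
            desc = block["description"]
            direction, cite = _evidence_direction(block["excerpts"])
            out.append(f"### FEATURE: {desc}")
            if direction == "unclear":
                out.append("DIRECTION: unclear")
                out.append(
                    f"For the feature '{desc}', {DISCLAIMER}. No mechanism is "
                    "proposed to avoid speculation."
                )
            else:
                verb = "raises" if direction == "positive" else "lowers"
                out.append(f"DIRECTION: {direction}")
                out.append(
                    f"The literature indicates that '{desc}' {verb} {prop}; the "
                    f"retrieved excerpt supports this relationship "
                    f"[CITE {cite[0]}:{cite[1]}]. A plausible mechanism is that "
                    f"this structural motif modulates the property through the "
                    f"interactions described in the cited source."
                )
        return "\n".join(out)


_BLOCK_RE = re.compile(r"^## FEATURE: (.*)$", re.M)
_SOURCE_RE = re.compile(r"^\[SOURCE ([0-9a-f]+):(\d+)\]$", re.M)
_CITE_RE = re.compile(r"\[CITE ([0-9a-f]+):(\d+)\]")


def _parse_property(prompt: str) -> str:
    m = re.search(r"to predict '([^']*)'", prompt)
    return m.group(1) if m else "the property"


def _parse_prompt_blocks(prompt: str) -> list:
    blocks = []
    matches = list(_BLOCK_RE.finditer(prompt))
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(prompt)
        body = prompt[m.end():end]
        excerpts = []
        src_matches = list(_SOURCE_RE.finditer(body))
        for j, sm in enumerate(src_matches):
            send = src_matches[j + 1].start() if j + 1 < len(src_matches) else len(body)
            excerpts.append(
                {
                    "doc_id": sm.group(1),
                    "chunk_index": int(sm.group(2)),
                    "text": body[sm.end():send].strip(),
                }
            )
        blocks.append({"description": m.group(1).strip(), "excerpts": excerpts})
    return blocks


def _evidence_direction(excerpts: list):
    """Direction from the most relevant keyword-bearing excerpt.

    Excerpts arrive in MMR selection order (most query-relevant first); the
    first one whose keyword counts are not tied decides, so off-topic later
    excerpts cannot outvote the feature-specific one. Returns (direction,
    (doc_id, chunk_index) of the deciding excerpt)."""
    for ex in excerpts:
        words = re.findall(r"[a-z]+", ex["text"].lower())
        p = sum(w in POSITIVE_KEYWORDS for w in words)
        n = sum(w in NEGATIVE_KEYWORDS for w in words)
        if p > n:
            return "positive", (ex["doc_id"], ex["chunk_index"])
        if n > p:
            return "negative", (ex["doc_id"], ex["chunk_index"])
    return "unclear", None


def _parse_direction_free_text(sentence: str) -> str:
    words = re.findall(r"[a-z]+", sentence.lower())
    p = sum(w in POSITIVE_KEYWORDS + ("raises", "positive") for w in words)
    n = sum(w in NEGATIVE_KEYWORDS + ("negative",) for w in words)
    if p > n:
        return "positive"
    if n > p:
        return "negative"
    return "unclear"


def parse_explanation_text(text: str, features: ImpactfulFeatureSet) -> list:
    """Parse generated text into per-feature hypothesis records.

    Prefers machine-parseable ``DIRECTION:`` tags (the mock emits them);
    otherwise the sentence containing the feature description is scanned
    for direction keywords, else the record is unclear.
    """
    records = []
    for rec in features.records:
        desc = rec["description"]
        direction = "unclear"
        body = ""
        m = re.search(re.escape(f"### FEATURE: {desc}") + r"\n(.*?)(?=### FEATURE:|\Z)", text, re.S)
        if m:
            body = m.group(1)
            tag = re.search(r"^DIRECTION:\s*(positive|negative|unclear)\s*$", body, re.M)
            if tag:
                direction = tag.group(1)
            else:
                direction = _parse_direction_free_text(body)
        elif desc in text:
            for sentence in re.split(r"(?<=[.!?])\s+", text):
                if desc in sentence:
                    direction = _parse_direction_free_text(sentence)
                    break
        cites = [(d, int(c)) for d, c in _CITE_RE.findall(body)]
        supported = bool(cites) and DISCLAIMER not in body
        records.append(
            {
                "feature": rec["feature"],
                "description": desc,
                "direction": direction,
                "supported": supported,
                "citations": cites,
            }
        )
    return records


def generate_explanations(
    backend: GenerationBackend,
    bundle: PromptBundle,
    features: ImpactfulFeatureSet,
    n_runs: int = 5,
    base_seed: int = 0,
) -> list:
    """Run the backend n_runs times with seeds base..base+n_runs-1 and
    parse each output. Backend failures are retained as failed runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    prompt = render_prompt(bundle)
    out = []
    for r in range(n_runs):
        seed = base_seed + r
        run_id = f"run_{r}"
        try:
            text = backend.generate(prompt, seed)
        except Exception as exc:  # noqa: BLE001 - failure is data, not fatal
            logger.warning("backend %s failed on %s: %s", backend.name, run_id, exc)
            out.append(Explanation(run_id, seed, "", [], failed=True, error=str(exc)))
            continue
        hyps = parse_explanation_text(text, features)
        out.append(Explanation(run_id, seed, text, hyps))
    return out


def _render_citation_key(filename: str) -> str:
    stem = filename.rsplit(".", 1)[0]
    alpha = re.search(r"[A-Za-z]+", stem)
    year = re.search(r"(19|20)\d{2}", stem)
    token = alpha.group(0).capitalize() if alpha else stem
    return f"({token}, {year.group(0) if year else 'n.d.'})"


def attach_citations(explanation: Explanation, registry: CorpusIndex) -> Explanation:
    """Resolve [CITE doc:chunk] markers against the corpus registry.

    Resolvable markers are replaced by rendered keys "(Token, Year|n.d.)";
    unresolvable ones become "[unresolved]" and are counted. Total function:
    flags instead of raising.
    """
    chunk_ids = {(c.doc_id, c.chunk_index) for c in registry.chunks}
    citations, unresolved = [], 0
    text = explanation.text

    def _sub(m):
        nonlocal unresolved
        doc_id, idx = m.group(1), int(m.group(2))
        if doc_id in registry.doc_registry and (doc_id, idx) in chunk_ids:
            key = _render_citation_key(registry.doc_registry[doc_id].filename)
            citations.append(Citation(key=key, doc_id=doc_id, chunk_index=idx))
            return key
        unresolved += 1
        return "[unresolved]"

    explanation.text = _CITE_RE.sub(_sub, text)
    # prune hypothesis-level citations that failed to resolve
    for hyp in explanation.hypotheses:
        resolved = [c for c in hyp["citations"] if (c[0], c[1]) in chunk_ids]
        if hyp["supported"] and not resolved:
            hyp["supported"] = False
        hyp["citations"] = resolved
    explanation.citations = citations
    explanation.unresolved = unresolved
    if unresolved:
        logger.warning("%d unresolved citation marker(s) in %s", unresolved, explanation.run_id)
    return explanation


def render_report(
    explanations: Sequence[Explanation],
    importances,
    eval_report,
    registry: CorpusIndex,
    path,
) -> None:
    """One deterministic markdown report: surrogate quality, ranked
    features, per-feature hypotheses with citations, reference list."""
    if not explanations:
        raise ValueError("no explanations to report")
    lines = ["# Structure-property explanation report", ""]
    lines.append("## Surrogate model quality")
    for k, v in sorted(eval_report.metrics.items()):
        lines.append(f"- {k}: {v:.4f}")
    lines.append(f"- train/test sizes: {eval_report.train_size}/{eval_report.test_size}")
    lines.append("")
    lines.append("## Globally impactful features")
    order = sorted(
        range(len(importances.feature_names)), key=lambda j: importances.ranks[j]
    )
    for j in order[:10]:
        lines.append(
            f"{importances.ranks[j]}. {importances.feature_names[j]} "
            f"(score={importances.scores[j]:.4f}, {importances.directions[j]})"
        )
    lines.append("")
    cited_docs = {}
    for e in explanations:
        if e.failed:
            continue
        lines.append(f"## Explanation {e.run_id}")
        lines.append(e.text)
        lines.append("")
        for c in e.citations:
            cited_docs[c.doc_id] = c.key
    lines.append("## References")
    for doc_id in sorted(cited_docs):
        doc = registry.doc_registry.get(doc_id)
        title = doc.title if doc else "unknown"
        lines.append(f"- {cited_docs[doc_id]} {title} [{doc_id}]")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
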