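"""Literature corpus ingestion, chunking, embedding, and MMR retrieval.

The retriever is fully offline: chunks are embedded with a hashed
term-frequency / inverse-document-frequency vectorizer (stable token
hashing, L2-normalized), and query-relevant yet mutually diverse excerpts
are selected greedily by maximal marginal relevance (MMR). Remote embedding
services can be slotted in behind the same embedder contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

# hashed embeddings have a nonzero collision floor (~1/sqrt(n_tokens * dim)
# per colliding bucket), so "essentially unrelated" sits above exact zero
LOW_CONFIDENCE_SIMILARITY = 0.1


@dataclass
class Document:
    doc_id: str
    filename: str
    title: str
    text: str


@dataclass
class Chunk:
    doc_id: str
    chunk_index: int
    text: str
    start: int
    end: int


@dataclass
class RetrievalConfig:
    chunk_size: int = 1000
    chunk_overlap: int = 200
    lam: float = 0.5            # MMR relevance-diversity trade-off
    k_retrieve: int = 4
    embedder: str = "hashed_tfidf"
    dim: int = 2048

    def validate(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.chunk_overlap >= self.chunk_size:
            raise ValueError("chunk_overlap must be smaller than chunk_size")
        if self.chunk_size < 1 or self.k_retrieve < 1 or self.dim < 1:
            raise ValueError("chunk_size, k_retrieve and dim must be positive")


@dataclass
class RetrievalResult:
    chunks: list                 # selected Chunk objects, in selection order
    similarities: np.ndarray     # query cosine similarity per selected chunk
    selection_order: list        # candidate indices, in selection order
    low_confidence: bool = False


def _doc_id(filename: str, content: str) -> str:
    return hashlib.sha1((filename + "\0" + content).encode()).hexdigest()[:12]


def ingest_corpus(directory) -> list:
    """Read .txt/.md files verbatim from a directory into Documents.

    Files that cannot be decoded as text (including PDFs, for which no
    extractor is bundled) are skipped with a warning; an empty corpus is an
    error. doc_ids are stable hashes of filename + content.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"corpus directory {directory} does not exist")
    docs = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        if path.suffix.lower() not in {".txt", ".md"}:
            logger.warning("skipping unreadable corpus file %s (only .txt/.md are supported)", path.name)
            continue
        try:
            text = path.read_text(encoding="utf-8")
        except UnicodeDecodeError:
            logger.warning("skipping undecodable corpus file %s", path.name)
            continue
        if not text.strip():
            logger.warning("skipping empty corpus file %s", path.name)
            continue
        first_line = next((ln.strip() for ln in text.splitlines() if ln.strip()), path.stem)
        title = first_line.lstrip("# ").strip()
        docs.append(Document(doc_id=_doc_id(path.name, text), filename=path.name, title=title, text=text))
    if not docs:
        raise ValueError("empty corpus: no readable documents found")
    return docs


def chunk_document(doc: Document, cfg: RetrievalConfig) -> list:
    """Sliding-window chunks of ~chunk_size chars with chunk_overlap,
    preferring to cut at whitespace within a 50-character tolerance.

    Spans are recorded so that concatenating the non-overlapping tails of
    consecutive chunks reconstructs the document text exactly.
    """
    cfg.validate()
    text = doc.text
    n = len(text)
    chunks: list = []
    start = 0
    while True:
        end = min(start + cfg.chunk_size, n)
        if end < n:
            # back off to the nearest whitespace within tolerance
            window = text[max(end - 50, start + 1): end]
            cut = max(
                (i for i, ch in enumerate(window) if ch.isspace()), default=None
            )
            if cut is not None:
                end = max(end - 50, start + 1) + cut + 1
        chunks.append(Chunk(doc.doc_id, len(chunks), text[start:end], start, end))
        if end >= n:
            break
        start = max(end - cfg.chunk_overlap, start + 1)
    return chunks


def reconstruct_text(chunks: Sequence[Chunk]) -> str:
    """Inverse of chunking: strip overlaps by span and concatenate."""
    out = []
    prev_end = 0
    for c in sorted(chunks, key=lambda c: c.chunk_index):
        out.append(c.text[prev_end - c.start:])
        prev_end = c.end
    return "".join(out)


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> list:
    return _TOKEN_RE.findall(text.lower())


def _bucket(token: str, dim: int) -> int:
    return int.from_bytes(hashlib.md5(token.encode()).digest()[:8], "big") % dim


class HashedTfidfEmbedder(BaseEstimator, TransformerMixin):
    """Deterministic offline text embedder: hashed TF(-IDF), L2-normalized.

    Tokens are lowercased word characters, hashed (md5, stable across
    processes) into ``dim`` buckets. ``fit`` learns smoothed IDF weights
    from a corpus; unfitted transform uses plain term frequencies. Identical
    texts embed identically; texts with disjoint vocabularies are
    orthogonal up to hash collisions.
    """

    def __init__(self, dim: int = 2048):
        self.dim = dim

    def fit(self, texts: Sequence[str], y=None):
        df = np.zeros(self.dim)
        for text in texts:
            for b in {_bucket(t, self.dim) for t in _tokens(text)}:
                df[b] += 1
        n = len(texts)
        self.idf_ = np.log((1 + n) / (1 + df)) + 1.0
        return self

    def transform(self, texts: Sequence[str]) -> np.ndarray:
        idf = getattr(self, "idf_", None)
        out = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            toks = _tokens(text)
            if not toks:
                logger.warning("zero-length text at position %d embeds to the zero vector", i)
                continue
            for t in toks:
                out[i, _bucket(t, self.dim)] += 1.0
            if idf is not None:
                out[i] *= idf
            norm = np.linalg.norm(out[i])
            if norm > 0:
                out[i] /= norm
        return out


def embed(texts: Sequence[str], embedder: str = "hashed_tfidf", dim: int = 2048) -> np.ndarray:
    """Contract wrapper: fixed dimensionality per tag, deterministic for the
    default offline embedder."""
    if embedder != "hashed_tfidf":
        raise ValueError(f"unknown embedder tag {embedder!r}")
    if len(texts) == 0:
        raise ValueError("texts must be nonempty")
    return HashedTfidfEmbedder(dim=dim).transform(texts)


def _cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=-1, keepdims=True)
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (a / na) @ (b / nb).T


def mmr_select(query_vec: np.ndarray, candidate_vecs: np.ndarray, lam: float, k: int) -> list:
    """Greedy maximal-marginal-relevance selection.

    First pick maximizes cosine(query, c); each subsequent pick maximizes
    lam * cosine(query, c) - (1 - lam) * max over selected of cosine(c, s).
    Ties resolve to the lowest candidate index. Returns min(k, n) indices
    in selection order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cand = np.asarray(candidate_vecs, dtype=float)
    if cand.shape[0] == 0:
        raise ValueError("candidates must be nonempty")
    q = np.asarray(query_vec, dtype=float).ravel()
    sim_q = _cosine_matrix(q[None, :], cand).ravel()
    sim_cc = _cosine_matrix(cand, cand)
    n = cand.shape[0]
    selected: list = []
    remaining = list(range(n))
    while remaining and len(selected) < k:
        if not selected:
            scores = sim_q[remaining]
        else:
            red = sim_cc[np.ix_(remaining, selected)].max(axis=1)
            scores = lam * sim_q[remaining] - (1 - lam) * red
        best = remaining[int(np.argmax(scores))]  # argmax takes the first max
        selected.append(best)
        remaining.remove(best)
    return selected


class CorpusIndex:
    """Chunked, embedded corpus with provenance; the retrieval substrate."""

    def __init__(self, documents, chunks, vectors, cfg: RetrievalConfig, embedder=None):
        self.documents = list(documents)
        self.chunks = list(chunks)
        self.vectors = np.asarray(vectors, dtype=float)
        self.cfg = cfg
        self.embedder = embedder
        self.doc_registry = {d.doc_id: d for d in self.documents}

    @classmethod
    def build(cls, documents: Sequence[Document], cfg: Optional[RetrievalConfig] = None) -> "CorpusIndex":
        cfg = cfg or RetrievalConfig()
        cfg.validate()
        chunks = [c for doc in documents for c in chunk_document(doc, cfg)]
        embedder = HashedTfidfEmbedder(dim=cfg.dim).fit([c.text for c in chunks])
        vectors = embedder.transform([c.text for c in chunks])
        return cls(documents, chunks, vectors, cfg, embedder)

    @classmethod
    def from_directory(cls, directory, cfg: Optional[RetrievalConfig] = None) -> "CorpusIndex":
        return cls.build(ingest_corpus(directory), cfg)

    def embed_query(self, text: str) -> np.ndarray:
        emb = self.embedder or HashedTfidfEmbedder(dim=self.cfg.dim)
        return emb.transform([text])[0]

    def save(self, path) -> None:
        """Persist as a JSON-lines sidecar (one record per chunk plus a
        header with documents and config)."""
        with open(path, "w") as fh:
            header = {
                "cfg": vars(self.cfg),
                "documents": [vars(d) for d in self.documents],
                "idf": getattr(self.embedder, "idf_", np.ones(self.cfg.dim)).tolist(),
            }
            fh.write(json.dumps(header) + "\n")
            for c, v in zip(self.chunks, self.vectors):
                fh.write(json.dumps({**vars(c), "vector": v.tolist()}) + "\n")

    @classmethod
    def load(cls, path) -> "CorpusIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            cfg = RetrievalConfig(**header["cfg"])
            docs = [Document(**d) for d in header["documents"]]
            chunks, vecs = [], []
            for line in fh:
                rec = json.loads(line)
                vecs.append(rec.pop("vector"))
                chunks.append(Chunk(**rec))
        emb = HashedTfidfEmbedder(dim=cfg.dim)
        emb.idf_ = np.asarray(header["idf"])
        return cls(docs, chunks, np.asarray(vecs), cfg, emb)


def retrieve_for_feature(feature_record: dict, index: CorpusIndex, property_name: str) -> RetrievalResult:
    """Retrieve diverse supporting excerpts for one impactful feature.

    The query is the humanized feature description plus the target property
    name. A result whose best similarity is ~0 (query vocabulary absent
    from the corpus) is flagged low_confidence.
    """
    if not index.chunks:
        raise ValueError("empty corpus index")
    query = f"{feature_record['description']} {property_name}"
    qvec = index.embed_query(query)
    sims = _cosine_matrix(qvec[None, :], index.vectors).ravel()
    picks = mmr_select(qvec, index.vectors, index.cfg.lam, index.cfg.k_retrieve)
    return RetrievalResult(
        chunks=[index.chunks[i] for i in picks],
        similarities=sims[picks],
        selection_order=picks,
        low_confidence=bool(sims.max() < LOW_CONFIDENCE_SIMILARITY),
    )


def arxiv_search_stub(query: str, max_results: int = 10):
    """Interface stub for live arXiv scraping (untested against the live
    service; provided behind this explicit call only)."""
    raise NotImplementedError(
        "live arXiv scraping is not bundled; supply a local corpus directory instead"
    )
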