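"""Vector indexing and retrieval: embeddings, cosine k-NN, and MMR re-ranking.

Terms and issue-tracker records are embedded into separate collections and
queried by cosine similarity.  Retrieval results can be re-ranked with
Maximal Marginal Relevance (MMR) to trade query relevance against redundancy
among the selected documents.

The default :class:`HashingEmbedder` is a deterministic bag-of-tokens
feature-hashing embedder: it needs no network or model weights, is a pure
function of its input text, and preserves token overlap as cosine
similarity, which is exactly what retrieval tests require.  Contextual
embedding models plug in behind the same :class:`EmbeddingBackend` contract.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import DimensionMismatch, DuplicateDocument, EmptyCorpus, EmptyIndex
from .ontology import TermObject, serialize_for_embedding

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


@runtime_checkable
class EmbeddingBackend(Protocol):
    name: str
    dimension: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Seeded feature-hashing text embedder.

    Each token is hashed (blake2b, keyed by the seed) to a coordinate and a
    sign; token vectors are summed and L2-normalized.  Identical text always
    yields an identical vector.
    """

    def __init__(self, dimension: int = 256, seed: int = 0) -> None:
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.dimension = dimension
        self.seed = seed
        self.name = f"hashing-{dimension}-seed{seed}"

    def _token_coord(self, token: str) -> tuple[int, float]:
        h = hashlib.blake2b(f"{self.seed}\x00{token}".encode(), digest_size=8).digest()
        value = int.from_bytes(h, "big")
        return value % self.dimension, 1.0 if (value >> 62) & 1 else -1.0

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for token in tokenize(text):
            idx, sign = self._token_coord(token)
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


@dataclass
class IssueRecord:
    """One issue-tracker record (new term request, change request, ...)."""

    issue_id: int
    title: str
    body: str = ""
    comments: list[str] = field(default_factory=list)

    def text(self) -> str:
        # indexed without any specialized pre-processing
        return "\n".join([self.title, self.body, *self.comments])

    def to_dict(self) -> dict:
        return {
            "number": self.issue_id,
            "title": self.title,
            "body": self.body,
            "comments": [{"body": c} for c in self.comments],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "IssueRecord":
        comments = [c.get("body", "") if isinstance(c, dict) else str(c) for c in data.get("comments", [])]
        return cls(
            issue_id=int(data["number"]),
            title=data.get("title", ""),
            body=data.get("body") or "",
            comments=comments,
        )


def load_issues(path: str) -> list[IssueRecord]:
    """Read the JSON array emitted by a standard issues API export."""
    with open(path) as fh:
        return [IssueRecord.from_dict(rec) for rec in json.load(fh)]


@dataclass
class IndexedDocument:
    doc_id: str
    payload: object
    text: str
    vector: np.ndarray


@dataclass
class RetrievalResult:
    document: IndexedDocument
    similarity: float
    rank: int


class VectorIndex:
    """One persistent collection of embedded documents with exact cosine k-NN.

    Exact search fulfils the ordering contract; an approximate (HNSW-style)
    engine could stand behind the same interface for corpora where exact
    scan is too slow.
    """

    def __init__(self, backend: EmbeddingBackend, collection: str = "default") -> None:
        self.backend = backend
        self.collection = collection
        self._docs: list[IndexedDocument] = []
        self._ids: set[str] = set()
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._docs)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._ids

    @property
    def documents(self) -> Sequence[IndexedDocument]:
        return tuple(self._docs)

    def add(self, doc_id: str, text: str, payload: object) -> IndexedDocument:
        if doc_id in self._ids:
            raise DuplicateDocument(f"doc_id {doc_id!r} already indexed in {self.collection!r}")
        doc = IndexedDocument(doc_id, payload, text, self.backend.embed(text))
        self._docs.append(doc)
        self._ids.add(doc_id)
        self._matrix = None
        return doc

    def _unit_matrix(self) -> np.ndarray:
        if self._matrix is None:
            mat = np.stack([d.vector for d in self._docs])
            norms = np.linalg.norm(mat, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._matrix = mat / norms
        return self._matrix

    def query_vector(self, vector: np.ndarray, k: int = 10, exclude: set[str] | None = None) -> list[RetrievalResult]:
        if not self._docs:
            raise EmptyIndex(f"collection {self.collection!r} is empty")
        if vector.shape[0] != self.backend.dimension:
            raise DimensionMismatch(
                f"query dimension {vector.shape[0]} != index dimension {self.backend.dimension}"
            )
        if k < 1:
            return []
        qnorm = np.linalg.norm(vector)
        unit_q = vector / qnorm if qnorm > 0 else vector
        sims = self._unit_matrix() @ unit_q
        order = sorted(range(len(self._docs)), key=lambda i: (-sims[i], i))
        results = []
        for i in order:
            doc = self._docs[i]
            if exclude and doc.doc_id in exclude:
                continue
            results.append(RetrievalResult(doc, float(sims[i]), rank=len(results) + 1))
            if len(results) == k:
                break
        return results

    def query(self, text: str, k: int = 10, exclude: set[str] | None = None) -> list[RetrievalResult]:
        return self.query_vector(self.backend.embed(text), k=k, exclude=exclude)

    # -- persistence (JSONL; one document per line) --------------------------

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            header = {"collection": self.collection, "backend": self.backend.name, "dimension": self.backend.dimension}
            fh.write(json.dumps(header) + "\n")
            for doc in self._docs:
                payload = doc.payload
                if isinstance(payload, TermObject):
                    payload = {"kind": "term", "data": payload.to_dict()}
                elif isinstance(payload, IssueRecord):
                    payload = {"kind": "issue", "data": payload.to_dict()}
                else:
                    payload = {"kind": "raw", "data": payload}
                fh.write(
                    json.dumps(
                        {"doc_id": doc.doc_id, "text": doc.text, "payload": payload, "vector": [round(v, 12) for v in doc.vector]}
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path: str, backend: EmbeddingBackend) -> "VectorIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            index = cls(backend, collection=header.get("collection", "default"))
            for line in fh:
                rec = json.loads(line)
                payload = rec["payload"]
                if payload["kind"] == "term":
                    payload = TermObject.from_dict(payload["data"])
                elif payload["kind"] == "issue":
                    payload = IssueRecord.from_dict(payload["data"])
                else:
                    payload = payload["data"]
                doc = IndexedDocument(rec["doc_id"], payload, rec["text"], np.asarray(rec["vector"]))
                if doc.doc_id in index._ids:
                    raise DuplicateDocument(doc.doc_id)
                index._docs.append(doc)
                index._ids.add(doc.doc_id)
        return index


def build_index(objects: Sequence[TermObject], backend: EmbeddingBackend) -> VectorIndex:
    """Embed and index term objects (one document per term, keyed by id)."""
    if not objects:
        raise EmptyCorpus("no term objects to index")
    index = VectorIndex(backend, collection="terms")
    for obj in objects:
        index.add(obj.id or obj.label, serialize_for_embedding(obj), obj)
    return index


def index_issues(issues: Sequence[IssueRecord], backend: EmbeddingBackend) -> VectorIndex:
    """Embed and index issue records in a collection separate from terms."""
    if not issues:
        raise EmptyCorpus("no issues to index")
    index = VectorIndex(backend, collection="issues")
    for issue in issues:
        index.add(f"issue-{issue.issue_id}", issue.text(), issue)
    return index


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def mmr_rerank(
    candidates: Sequence[RetrievalResult],
    query_vector: np.ndarray,
    lam: float = 0.5,
    k: int | None = None,
) -> list[RetrievalResult]:
    """Greedy Maximal Marginal Relevance re-ranking.

    At each step the unselected document maximizing
    ``lam * cos(d, query) - (1 - lam) * max_{s selected} cos(d, s)``
    is chosen; the first pick maximizes plain query similarity.  Ties are
    broken by the candidates' original rank.  ``lam=1`` reduces to the input
    similarity ordering.
    """
    if not candidates:
        return []
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    dim = query_vector.shape[0]
    for c in candidates:
        if c.document.vector.shape[0] != dim:
            raise DimensionMismatch("candidate/query vector dimensions differ")
    k = len(candidates) if k is None else min(k, len(candidates))
    query_sims = [_cosine(c.document.vector, query_vector) for c in candidates]
    remaining = list(range(len(candidates)))
    selected: list[int] = []
    while remaining and len(selected) < k:
        best_i, best_score = None, None
        for i in remaining:
            if selected:
                redundancy = max(
                    _cosine(candidates[i].document.vector, candidates[j].document.vector)
                    for j in selected
                )
                score = lam * query_sims[i] - (1.0 - lam) * redundancy
            else:
                # first pick is pure query relevance regardless of lambda
                score = query_sims[i]
            if best_score is None or score > best_score + 1e-12:
                best_i, best_score = i, score
        selected.append(best_i)
        remaining.remove(best_i)
    return [
        RetrievalResult(candidates[i].document, query_sims[i], rank=r + 1)
        for r, i in enumerate(selected)
    ]
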