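"""Evaluation: IC partial credit, reasoner-recovery baseline, definition
similarity, and inter-rater statistics.

Relationship predictions are scored against the ontology's asserted edges
with CAFA-style information-content partial credit: an exact match earns
full credit; a prediction that is merely *more general* than a gold edge
earns the ratio IC(predicted target) / IC(expected target), where
IC(t) = -log P(t) and P(t) is the probability that t subsumes a random term.
A structural subsumption-recovery baseline (remove each asserted is-a edge
and test whether transitive closure or the logical-definition genus
re-derives it) provides the reference point whose precision is 1 by
construction.  Definitions are scored by greedy token-embedding matching
(BERTScore-style precision/recall/F1) and by ordinal human ratings whose
reliability is summarized with a one-way ANOVA intraclass correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVariance,
    EdgeNotAsserted,
    EmptyCorpus,
    InsufficientData,
    InsufficientLevels,
    MalformedLogicalDefinition,
    UnknownTerm,
)
from .index import tokenize
from .ontology import SUBCLASS_OF, Curie, OntologyGraph

EmptyText = EmptyCorpus  # alias: empty string where tokens are required


# ---------------------------------------------------------------------------
# Information content and relationship scoring


def information_content(graph: OntologyGraph, term: Curie, log_base: float = 2) -> float:
    """IC(t) = -log P(t) with P(t) the fraction of terms t subsumes.

    Subsumption is reflexive (every term subsumes itself), so the root of a
    connected ontology has IC 0 and leaves have finite maximal IC.  Base 2
    yields bits.
    """
    if term not in graph.terms:
        raise UnknownTerm(str(term))
    p = len(graph.subsumed_terms(term)) / len(graph.terms)
    return -math.log(p, log_base)


def is_more_general(
    graph: OntologyGraph, subject: Curie, predicate: object, predicted_target: Curie
) -> bool:
    """True iff the predicted target is reachable from the subject over
    edges typed is-a or *predicate*."""
    if predicted_target not in graph.terms:
        raise UnknownTerm(str(predicted_target))
    return predicted_target in graph.reachable(subject, {SUBCLASS_OF, predicate})


@dataclass
class RelationshipJudgement:
    predicted: tuple[object, Curie]  # (predicate, target)
    category: str  # exact | general | false_positive
    matched_gold: tuple[object, Curie] | None
    credit: float

    def to_dict(self) -> dict:
        return {
            "predicted": [str(self.predicted[0]), str(self.predicted[1])],
            "category": self.category,
            "matched_gold": (
                [str(self.matched_gold[0]), str(self.matched_gold[1])]
                if self.matched_gold
                else None
            ),
            "credit": self.credit,
        }


def score_relationships(
    predicted: Sequence[tuple[object, Curie]],
    gold: Sequence[tuple[object, Curie]],
    graph: OntologyGraph,
    subject: Curie,
    task_filter: str = "all",
    log_base: float = 2,
) -> list[RelationshipJudgement]:
    """Judge each predicted ``(predicate, target)`` of *subject* against gold.

    Exact (predicate, target) matches earn credit 1.  Otherwise, if the
    predicted target is an ancestor over {is-a, predicate} edges, the
    prediction is paired with the highest-IC unused same-predicate gold
    target from which the predicted target is reachable, earning
    IC(predicted)/IC(gold).  Everything else is a false positive.  Each gold
    edge is pairable at most once.  ``task_filter="subclass_only"`` restricts
    both sides to is-a edges.
    """
    if task_filter == "subclass_only":
        predicted = [pt for pt in predicted if pt[0] == SUBCLASS_OF]
        gold = [gt for gt in gold if gt[0] == SUBCLASS_OF]
    gold_remaining = list(gold)
    judgements: list[RelationshipJudgement] = []
    others = []
    for pt in predicted:  # exact matches consume gold edges first
        if pt in gold_remaining:
            gold_remaining.remove(pt)
            judgements.append(RelationshipJudgement(pt, "exact", pt, 1.0))
        else:
            others.append(pt)
    for pt in others:
        pred_p, pred_t = pt
        if pred_t in graph.terms and is_more_general(graph, subject, pred_p, pred_t):
            candidates = [
                gt
                for gt in gold_remaining
                if gt[0] == pred_p
                and (pred_t == gt[1] or pred_t in graph.reachable(gt[1], {SUBCLASS_OF, pred_p}))
            ]
            if candidates:
                best = max(
                    candidates,
                    key=lambda gt: (information_content(graph, gt[1], log_base), str(gt[1])),
                )
                gold_remaining.remove(best)
                ic_e = information_content(graph, best[1], log_base)
                ic_p = information_content(graph, pred_t, log_base)
                credit = min(1.0, ic_p / ic_e) if ic_e > 0 else 0.0
                judgements.append(RelationshipJudgement(pt, "general", best, credit))
                continue
        judgements.append(RelationshipJudgement(pt, "false_positive", None, 0.0))
    return judgements


@dataclass
class ScoreSummary:
    precision: float
    recall: float
    f1: float
    n_predicted: int
    n_gold: int
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_predicted": self.n_predicted,
            "n_gold": self.n_gold,
            "flagged": self.flagged,
        }


def _prf(total_credit: float, n_predicted: int, n_gold: int) -> ScoreSummary:
    flagged = n_predicted == 0
    precision = total_credit / n_predicted if n_predicted else 0.0
    recall = total_credit / n_gold if n_gold else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return ScoreSummary(precision, recall, f1, n_predicted, n_gold, flagged)


def aggregate_prf(judgements: Sequence[RelationshipJudgement], n_gold: int) -> ScoreSummary:
    """Micro precision/recall/F1 from partial credits.

    Precision divides total credit by the prediction count, recall by the
    gold count; an empty prediction set is reported as 0/0/0 and flagged.
    """
    if n_gold < 0:
        raise ValueError("n_gold must be >= 0")
    return _prf(sum(j.credit for j in judgements), len(judgements), n_gold)


# ---------------------------------------------------------------------------
# Reasoner-recovery baseline


def entail_subsumption(graph: OntologyGraph, edge: tuple[Curie, object, Curie]) -> bool:
    """After removing the asserted is-a *edge*, is it still derivable?

    Derivation routes: (a) the transitive closure of the remaining asserted
    is-a edges; (b) the genus g of the subject's logical definition, when
    g equals the object or reaches it in that closure.
    """
    s, p, o = edge
    if p != SUBCLASS_OF or edge not in graph.edges:
        raise EdgeNotAsserted(f"{edge} is not an asserted SubClassOf edge")
    adj: dict[Curie, set[Curie]] = {}
    for es, ep, eo in graph.edges:
        if ep == SUBCLASS_OF and (es, ep, eo) != edge:
            adj.setdefault(es, set()).add(eo)

    def reaches(start: Curie) -> bool:
        seen = set()
        stack = [start]
        while stack:
            node = stack.pop()
            if node == o:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj.get(node, ()))
        return False

    if any(reaches(parent) for parent in adj.get(s, ())):
        return True
    ld = graph.logical_definitions.get(s)
    if ld is not None and (ld.genus == o or reaches(ld.genus)):
        return True
    return False


def reasoner_baseline(graph: OntologyGraph, test_terms: Sequence[Curie]) -> ScoreSummary:
    """Subsumption-recovery baseline over the test terms' asserted is-a edges.

    Each asserted edge is predicted iff it remains entailed after removal,
    so every prediction is an asserted edge and precision is structurally 1
    whenever anything is predicted.  Recall measures how much of the
    asserted is-a structure is redundant with the rest of the ontology.
    """
    n_gold = 0
    n_pred = 0
    for term in test_terms:
        for edge in graph.outgoing(term):
            if edge[1] != SUBCLASS_OF:
                continue
            n_gold += 1
            if entail_subsumption(graph, edge):
                n_pred += 1
    return _prf(float(n_pred), n_pred, n_gold)


# ---------------------------------------------------------------------------
# Definition similarity (greedy token-embedding matching)


class OneHotTokenBackend:
    """Token embedder where cosine similarity is exact token identity."""

    name = "one-hot"

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        vocab = {t: i for i, t in enumerate(dict.fromkeys(tokens))}
        mat = np.zeros((len(tokens), len(vocab)))
        for row, tok in enumerate(tokens):
            mat[row, vocab[tok]] = 1.0
        return mat


class HashTokenBackend:
    """Token embedder hashing each token to a dense unit vector."""

    name = "hash-token"

    def __init__(self, dimension: int = 64, seed: int = 0) -> None:
        from .index import HashingEmbedder

        self._embedder = HashingEmbedder(dimension=dimension, seed=seed)

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack([self._embedder.embed(t) for t in tokens])


def definition_similarity(
    candidate: str, reference: str, token_backend=None
) -> tuple[float, float, float]:
    """Greedy-matching precision/recall/F1 over token embeddings.

    Recall is the mean over reference tokens of the best cosine to any
    candidate token; precision is symmetric; F1 is their harmonic mean.
    With the one-hot backend this reduces to soft token overlap.
    """
    token_backend = token_backend or OneHotTokenBackend()
    cand_tokens = tokenize(candidate)
    ref_tokens = tokenize(reference)
    if not cand_tokens or not ref_tokens:
        raise EmptyText("candidate and reference must both contain tokens")
    if isinstance(token_backend, OneHotTokenBackend):
        # shared vocabulary so identical tokens align across the two texts
        joint = token_backend.embed_tokens(list(cand_tokens) + list(ref_tokens))
        cand_vecs, ref_vecs = joint[: len(cand_tokens)], joint[len(cand_tokens):]
    else:
        cand_vecs = token_backend.embed_tokens(cand_tokens)
        ref_vecs = token_backend.embed_tokens(ref_tokens)
    cn = np.linalg.norm(cand_vecs, axis=1, keepdims=True)
    rn = np.linalg.norm(ref_vecs, axis=1, keepdims=True)
    cn[cn == 0] = 1.0
    rn[rn == 0] = 1.0
    sim = (cand_vecs / cn) @ (ref_vecs / rn).T  # candidates x references
    precision = float(sim.max(axis=1).mean())
    recall = float(sim.max(axis=0).mean())
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# Rating sheets, ICC, confidence-gap analysis


@dataclass
class RatingRecord:
    """One evaluator's ordinal rating of one definition."""

    term_id: str
    source: str  # curator or model name whose definition was rated
    metric: str  # accuracy | consistency | score
    value: int  # 1 (worst) .. 5 (best)
    evaluator_id: str
    confidence: int | None = None  # 1 (low) .. 5 (high), optional
    notes: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.value <= 5:
            raise ValueError("rating value must be in 1..5")
        if self.confidence is not None and not 1 <= self.confidence <= 5:
            raise ValueError("confidence must be in 1..5")


RATING_COLUMNS = ["term_id", "source", "metric", "value", "confidence", "evaluator_id", "notes"]


def read_ratings_csv(path: str) -> list[RatingRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        conf = getattr(row, "confidence", None)
        conf = None if conf is None or (isinstance(conf, float) and math.isnan(conf)) else int(conf)
        notes = getattr(row, "notes", "")
        records.append(
            RatingRecord(
                term_id=str(row.term_id),
                source=str(row.source),
                metric=str(row.metric),
                value=int(row.value),
                evaluator_id=str(row.evaluator_id),
                confidence=conf,
                notes="" if (isinstance(notes, float) and math.isnan(notes)) else str(notes),
            )
        )
    return records


def write_ratings_csv(records: Sequence[RatingRecord], path: str) -> None:
    rows = [
        {
            "term_id": r.term_id,
            "source": r.source,
            "metric": r.metric,
            "value": r.value,
            "confidence": r.confidence,
            "evaluator_id": r.evaluator_id,
            "notes": r.notes,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RATING_COLUMNS).to_csv(path, index=False)


@dataclass
class ICCResult:
    metric: str
    icc: float
    msb: float
    mse: float
    k: float
    n_groups: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "icc": self.icc,
            "msb": self.msb,
            "mse": self.mse,
            "k": self.k,
            "n_groups": self.n_groups,
        }


def icc(
    ratings: Sequence[RatingRecord], metric: str, min_confidence: int = 1
) -> ICCResult:
    """One-way ANOVA intraclass correlation with evaluator as random effect.

    Ratings with confidence below *min_confidence* are filtered out
    (unrated confidence counts as the minimum, 1).  From the ANOVA mean
    squares MSB (between evaluators) and MSE (within),
    ICC = (MSB - MSE) / (MSB + (k - 1) * MSE) with k the (mean) group size.
    """
    groups: dict[str, list[float]] = {}
    for r in ratings:
        if r.metric != metric:
            continue
        conf = r.confidence if r.confidence is not None else 1
        if conf < min_confidence:
            continue
        groups.setdefault(r.evaluator_id, []).append(float(r.value))
    return icc_from_groups(groups, metric=metric)


def icc_from_groups(groups: dict[str, list[float]], metric: str = "score") -> ICCResult:
    """The ANOVA ICC over already-grouped values (one list per evaluator)."""
    groups = {g: vals for g, vals in groups.items() if len(vals) >= 2}
    if len(groups) < 2:
        raise InsufficientData(
            f"need >=2 evaluators with >=2 ratings for metric {metric!r} after filtering"
        )
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    n_total = sum(len(v) for v in values)
    grand = sum(v.sum() for v in values) / n_total
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b = len(values) - 1
    df_w = n_total - len(values)
    msb = ssb / df_b
    mse = ssw / df_w
    if msb == 0 and mse == 0:
        raise DegenerateVariance("all ratings identical; ICC undefined")
    k = n_total / len(values)  # mean group size for unbalanced designs
    denom = msb + (k - 1) * mse
    icc_val = (msb - mse) / denom if denom > 0 else 0.0
    return ICCResult(metric=metric, icc=icc_val, msb=msb, mse=mse, k=k, n_groups=len(values))


@dataclass
class ConfidenceGapResult:
    levels: list[int]
    gaps: list[float]
    pearson_r: float
    flagged: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "gaps": self.gaps,
            "pearson_r": self.pearson_r,
            "flagged": self.flagged,
            "note": self.note,
        }


def confidence_gap_correlation(
    ratings: Sequence[RatingRecord],
    human_source: str,
    model_source: str,
    metric: str = "score",
) -> ConfidenceGapResult:
    """Performance gap (human minus model mean rating) per confidence level,
    and the Pearson correlation of gap with confidence.

    Raters who trust their own judgement should discriminate human-authored
    from generated definitions more sharply, so the gap is expected to grow
    with confidence.  Requires >=3 confidence levels carrying both sources;
    a zero-variance gap profile is returned flagged with r = nan.
    """
    by_level: dict[int, dict[str, list[float]]] = {}
    for r in ratings:
        if r.metric != metric or r.confidence is None:
            continue
        if r.source not in (human_source, model_source):
            continue
        by_level.setdefault(r.confidence, {}).setdefault(r.source, []).append(float(r.value))
    levels = sorted(
        c for c, d in by_level.items() if human_source in d and model_source in d
    )
    if len(levels) < 3:
        raise InsufficientLevels(
            f"need >=3 confidence levels with both sources, have {len(levels)}"
        )
    gaps = [
        float(np.mean(by_level[c][human_source]) - np.mean(by_level[c][model_source]))
        for c in levels
    ]
    if np.ptp(gaps) == 0:
        return ConfidenceGapResult(levels, gaps, float("nan"), flagged=True, note="zero gap variance")
    r, _p = stats.pearsonr(levels, gaps)
    return ConfidenceGapResult(levels, gaps, float(r))


# ---------------------------------------------------------------------------
# Logical definition scoring


def _ldef_pairs(ldefs) -> set[tuple[str, str]]:
    pairs = {(r.predicate, r.target) for r in ldefs}
    n_genus = sum(1 for p, _t in pairs if p == SUBCLASS_OF)
    if n_genus != 1:
        raise MalformedLogicalDefinition(f"expected exactly one genus, found {n_genus}")
    return pairs


def score_logical_definitions(predicted, gold) -> ScoreSummary:
    """Exact-match set precision/recall/F1 over (predicate, target) pairs,
    with the genus encoded as the SubClassOf pair."""
    gold_pairs = _ldef_pairs(gold)
    if not predicted:
        return ScoreSummary(0.0, 0.0, 0.0, 0, len(gold_pairs), flagged=True)
    pred_pairs = _ldef_pairs(predicted)
    hits = len(pred_pairs & gold_pairs)
    return _prf(float(hits), len(pred_pairs), len(gold_pairs))
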