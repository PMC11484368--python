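"""Seeded generators for synthetic ontologies, issue trackers, canned
replies, and rating sheets.

The generated ontology emulates the structure the evaluation pipeline
assumes about real OBO-style ontologies: a rooted is-a DAG with
compositional labels (children extend their parent's label, so lexical
overlap tracks taxonomic proximity and retrieval is exercisable with a
bag-of-tokens embedder), templated definitions mentioning parent labels,
heterogeneous relationship types, genus-differentia logical definitions,
redundant (entailed) subclass edges at a configurable rate, and per-term
creation dates.  The content is deliberately nonsense biology; only the
structure matters.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field

from .engine import CannedReplyBook
from .errors import InvalidSpec
from .evaluation import RatingRecord
from .index import IssueRecord
from .ontology import (
    SUBCLASS_OF,
    Curie,
    LogicalDefinition,
    OntologyGraph,
    SymbolTable,
    TermInfo,
    TermObject,
    term_to_object,
)

_NOUNS = [
    "gland", "duct", "membrane", "vesicle", "fiber", "crest", "plate",
    "tube", "node", "ridge", "lobe", "sheath", "crypt", "follicle",
]
_ADJECTIVES = [
    "alpha", "beta", "gamma", "delta", "distal", "proximal", "dorsal",
    "ventral", "lateral", "medial", "primary", "secondary", "basal",
    "apical", "inner", "outer", "upper", "lower", "anterior", "posterior",
]
_PREDICATE_LABELS = [
    "part of", "regulates", "located in", "develops from", "adjacent to",
    "produces", "surrounds", "innervates",
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic ontology."""

    n_terms: int = 200
    max_depth: int = 6
    branching: int = 3
    n_predicates: int = 3
    redundancy_rate: float = 0.3  # fraction of grandparented terms given an entailed extra edge
    logical_def_rate: float = 0.3
    relationship_rate: float = 0.5  # fraction of non-root terms given one typed cross edge
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2020, 1, 1), _dt.date(2023, 8, 1))
    seed: int = 0

    def validate(self) -> None:
        if self.n_terms < 2:
            raise InvalidSpec("n_terms must be >= 2")
        if self.max_depth < 1 or self.branching < 1:
            raise InvalidSpec("max_depth and branching must be >= 1")
        if not 1 <= self.n_predicates <= len(_PREDICATE_LABELS):
            raise InvalidSpec(f"n_predicates must be in 1..{len(_PREDICATE_LABELS)}")
        for rate in (self.redundancy_rate, self.logical_def_rate, self.relationship_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidSpec("rates must be in [0, 1]")
        if self.date_range[0] > self.date_range[1]:
            raise InvalidSpec("date_range start must not exceed end")


def _term_curie(i: int) -> Curie:
    return Curie("T", f"{i:07d}")


def generate_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Generate a rooted synthetic ontology; same spec + seed -> same graph."""
    spec.validate()
    rng = random.Random(spec.seed)
    graph = OntologyGraph()

    predicates = []
    for i in range(spec.n_predicates):
        pred = Curie("REL", f"{i + 1:07d}")
        graph.predicate_labels[pred] = _PREDICATE_LABELS[i]
        predicates.append(pred)

    root = _term_curie(1)
    graph.terms[root] = TermInfo(label="cell", definition="The root unit of the fixture taxonomy.")
    used_labels = {"cell"}
    parent_of: dict[Curie, Curie] = {}
    depth_of = {root: 0}
    frontier = [root]
    next_id = 2

    while len(graph.terms) < spec.n_terms and frontier:
        new_frontier = []
        for parent in frontier:
            for _ in range(spec.branching):
                if len(graph.terms) >= spec.n_terms:
                    break
                parent_label = graph.terms[parent].label
                label = None
                if depth_of[parent] == 0:
                    pool = _NOUNS
                    fmt = "{w} cell"
                else:
                    pool = _ADJECTIVES
                    fmt = "{w} " + parent_label
                for word in rng.sample(pool, len(pool)):
                    cand = fmt.format(w=word)
                    if cand not in used_labels:
                        label = cand
                        break
                if label is None:  # exhausted the word bank under this parent
                    continue
                used_labels.add(label)
                curie = _term_curie(next_id)
                next_id += 1
                graph.terms[curie] = TermInfo(label=label)
                graph.edges.add((curie, SUBCLASS_OF, parent))
                parent_of[curie] = parent
                depth_of[curie] = depth_of[parent] + 1
                if depth_of[curie] < spec.max_depth:
                    new_frontier.append(curie)
        frontier = new_frontier
    if len(graph.terms) < spec.n_terms:
        raise InvalidSpec(
            f"word bank exhausted at {len(graph.terms)} terms; "
            "increase branching/max_depth or lower n_terms"
        )

    terms = sorted(graph.terms)
    # typed cross relationships (never is-a; targets exclude self and own parent)
    for curie in terms:
        if curie == root or rng.random() >= spec.relationship_rate:
            continue
        pred = rng.choice(predicates)
        candidates = [t for t in terms if t not in (curie, parent_of.get(curie))]
        target = rng.choice(candidates)
        graph.edges.add((curie, pred, target))

    # redundant entailed subclass edges: child -> grandparent
    for curie in terms:
        gp = parent_of.get(parent_of.get(curie))
        if gp is not None and rng.random() < spec.redundancy_rate:
            graph.edges.add((curie, SUBCLASS_OF, gp))

    # genus-differentia logical definitions reusing the cross relationship
    for curie in terms:
        if curie == root or rng.random() >= spec.logical_def_rate:
            continue
        cross = [(p, o) for s, p, o in graph.outgoing(curie) if p != SUBCLASS_OF]
        if not cross:
            continue
        graph.logical_definitions[curie] = LogicalDefinition(
            genus=parent_of[curie], differentia=[cross[0]]
        )

    # templated definitions mentioning the parent label
    for curie in terms:
        if curie == root:
            continue
        parent_label = graph.terms[parent_of[curie]].label
        ld = graph.logical_definitions.get(curie)
        if ld is not None:
            pred_label = graph.predicate_labels[ld.differentia[0][0]]
            target_label = graph.terms[ld.differentia[0][1]].label
            definition = f"A {parent_label} that {pred_label} some {target_label}."
        else:
            head = graph.terms[curie].label.split()[0]
            definition = f"Any {parent_label} of the {head} kind."
        graph.terms[curie].definition = definition

    # creation dates uniform over the range; the root is oldest
    start, end = spec.date_range
    span = (end - start).days
    graph.terms[root].creation_date = start
    for curie in terms:
        if curie != root:
            graph.terms[curie].creation_date = start + _dt.timedelta(days=rng.randint(0, span))

    graph.validate()
    return graph


def generate_issues(graph: OntologyGraph, n: int, seed: int = 0) -> list[IssueRecord]:
    """Generate new-term-request issues, each naming one term's label
    verbatim, paraphrasing its definition, and listing parents in prose."""
    if n < 1:
        raise InvalidSpec("n must be >= 1")
    rng = random.Random(seed)
    candidates = sorted(c for c in graph.terms if graph.terms[c].definition)
    if n > len(candidates):
        raise InvalidSpec(f"only {len(candidates)} defined terms available for {n} issues")
    # avoid nested labels among the requested terms: one tracker does not
    # carry open requests for both "fiber cell" and "secondary fiber cell"
    shuffled = rng.sample(candidates, len(candidates))
    chosen: list[Curie] = []
    for curie in shuffled:
        label = graph.terms[curie].label
        if any(
            label in graph.terms[c].label or graph.terms[c].label in label for c in chosen
        ):
            continue
        chosen.append(curie)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise InvalidSpec(f"cannot pick {n} lexically distinct issue terms")
    issues = []
    for i, curie in enumerate(chosen, start=1):
        info = graph.terms[curie]
        parents = [graph.terms[p].label for p in graph.subclass_parents(curie)]
        parent_clause = (
            f" It should be classified under {', '.join(parents)}." if parents else ""
        )
        issues.append(
            IssueRecord(
                issue_id=i,
                title=f"New term request: {info.label}",
                body=(
                    f"Please add the term '{info.label}'. "
                    f"Suggested definition: {info.definition}{parent_clause}"
                ),
                comments=["Thanks, this looks reasonable to me."],
            )
        )
    return issues


def save_issues(issues: list[IssueRecord], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([i.to_dict() for i in issues], fh, indent=1)


# ---------------------------------------------------------------------------
# Canned replies


def gold_reply(term: TermObject, fields: list[str]) -> str:
    """The reply a perfect generator would give for *term* on *fields*."""
    return json.dumps(term.to_dict(fields=tuple(fields)), sort_keys=True)


def build_echo_book(
    graph: OntologyGraph,
    table: SymbolTable,
    terms: list[Curie],
    task_fields: list[str],
) -> CannedReplyBook:
    """Canned replies scripted from the gold objects — the scoring ceiling."""
    book = CannedReplyBook()
    for curie in terms:
        obj = term_to_object(graph, curie, table)
        book.add(obj.label, gold_reply(obj, task_fields))
    return book


# ---------------------------------------------------------------------------
# Rating sheets


def generate_ratings(
    term_ids: list[str],
    evaluator_ids: tuple[str, ...] = ("ev1", "ev2", "ev3"),
    human_source: str = "curator",
    model_source: str = "model",
    seed: int = 0,
    human_mean: float = 4.2,
    gap_slope: float = 0.35,
    sd: float = 0.6,
    consistency_rate: float = 0.7,
) -> list[RatingRecord]:
    """Draw ordinal 1-5 rating sheets for human- and model-authored
    definitions.

    The human-definition mean is flat in confidence; the model-definition
    mean drops by ``gap_slope`` per confidence level above 1, emulating
    raters who, when sure of the domain, spot flaws in generated text (at
    the lowest confidence the two are indistinguishable).  Consistency
    ratings are emitted at ``consistency_rate`` since assigning one is
    optional.
    """
    rng = random.Random(seed)

    def draw(mean: float) -> int:
        return int(min(5, max(1, round(rng.gauss(mean, sd)))))

    records = []
    for term_id in term_ids:
        for evaluator in evaluator_ids:
            confidence = rng.randint(1, 5)
            for source in (human_source, model_source):
                mean = human_mean
                if source == model_source:
                    mean = human_mean - gap_slope * (confidence - 1)
                metrics = ["accuracy", "score"]
                if rng.random() < consistency_rate:
                    metrics.append("consistency")
                for metric in metrics:
                    records.append(
                        RatingRecord(
                            term_id=term_id,
                            source=source,
                            metric=metric,
                            value=draw(mean),
                            evaluator_id=evaluator,
                            confidence=confidence,
                        )
                    )
    return records
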