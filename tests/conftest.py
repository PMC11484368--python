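import datetime as dt
import random

import pytest

from ontorag.ontology import (
    SUBCLASS_OF,
    Curie,
    LogicalDefinition,
    OntologyGraph,
    TermInfo,
)


def make_graph(labels, edges, predicates=None, logical=None, dates=None):
    """Build a small graph from short names: labels {name: label},
    edges [(sub, pred_or_None, obj)] where pred None means is-a."""
    graph = OntologyGraph()
    curies = {name: Curie("X", f"{i + 1:04d}") for i, name in enumerate(labels)}
    for name, label in labels.items():
        date = (dates or {}).get(name)
        graph.terms[curies[name]] = TermInfo(label=label, creation_date=date)
    pred_curies = {}
    for i, (pname, plabel) in enumerate((predicates or {}).items()):
        pred_curies[pname] = Curie("R", f"{i + 1:04d}")
        graph.predicate_labels[pred_curies[pname]] = plabel
    for sub, pred, obj in edges:
        p = SUBCLASS_OF if pred is None else pred_curies[pred]
        graph.edges.add((curies[sub], p, curies[obj]))
    for name, (genus, diffs) in (logical or {}).items():
        graph.logical_definitions[curies[name]] = LogicalDefinition(
            genus=curies[genus],
            differentia=[(pred_curies[p], curies[t]) for p, t in diffs],
        )
    graph.validate()
    return graph, curies, pred_curies


@pytest.fixture
def chain4():
    """R <- A <- {B, D}: IC(B) = 2 bits, IC(A) ~ 0.415 bits."""
    return make_graph(
        {"R": "root", "A": "alpha", "B": "beta", "D": "delta"},
        [("A", None, "R"), ("B", None, "A"), ("D", None, "A")],
    )


@pytest.fixture
def chain5():
    """R <- A <- B <- C, plus D <- A: credit IC(A)/IC(B) ~ 0.2435."""
    return make_graph(
        {"R": "root", "A": "alpha", "B": "beta", "C": "gamma", "D": "delta"},
        [("A", None, "R"), ("B", None, "A"), ("C", None, "B"), ("D", None, "A")],
    )


def random_dag(rng: random.Random, n_max: int = 30):
    """Random rooted is-a DAG with a sprinkling of typed cross edges."""
    n = rng.randint(5, n_max)
    graph = OntologyGraph()
    pred = Curie("P", "0000001")
    graph.predicate_labels[pred] = "part of"
    curies = [Curie("T", f"{i:04d}") for i in range(n)]
    for i, c in enumerate(curies):
        graph.terms[c] = TermInfo(label=f"node {i}")
    for i in range(1, n):
        for parent in rng.sample(range(i), k=min(i, rng.choice([1, 1, 2]))):
            graph.edges.add((curies[i], SUBCLASS_OF, curies[parent]))
    for i in range(1, n):
        if rng.random() < 0.3:
            j = rng.randrange(n)
            if j != i:
                graph.edges.add((curies[i], pred, curies[j]))
    graph.validate()
    return graph, curies, pred


@pytest.fixture
def dated_graph():
    d = dt.date
    labels = {f"t{i}": f"term {i}" for i in range(8)}
    dates = {f"t{i}": d(2022, 1, 1) + dt.timedelta(days=60 * i) for i in range(8)}
    edges = [(f"t{i}", None, "t0") for i in range(1, 8)]
    return make_graph(labels, edges, dates=dates)
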