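"""Ontology model: graphs, symbolized term objects, masking, and date splits.

An ontology is held as a light graph of CURIE-identified terms with typed
edges and optional genus-differentia logical definitions.  For language-model
consumption every term is translated into a *term object* whose identifiers
are camel-case symbols derived from labels (``mitral cell`` -> ``MitralCell``);
numeric CURIEs are notoriously hallucination-prone, label symbols are not.
A :class:`SymbolTable` keeps the translation bijective so predicted symbols
can be resolved back to CURIEs.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml

from .errors import (
    EmptyLabel,
    MalformedFile,
    MissingGoldField,
    NoEligibleTerms,
    UnknownTerm,
)

logger = logging.getLogger(__name__)

#: Reserved predicate symbol for the taxonomic (is-a) relation.
SUBCLASS_OF = "SubClassOf"

_OBO_IRI = re.compile(r"^https?://purl\.obolibrary\.org/obo/([A-Za-z_]+?)_([A-Za-z0-9]+)$")


@dataclass(frozen=True, order=True)
class Curie:
    """Compact identifier ``PREFIX:LOCALID`` (e.g. ``CL:1001502``)."""

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValueError("CURIE prefix must be non-empty")

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    @classmethod
    def parse(cls, text: str) -> "Curie":
        """Parse a CURIE string or an OBO PURL IRI."""
        m = _OBO_IRI.match(text)
        if m:
            return cls(m.group(1), m.group(2))
        if ":" in text:
            prefix, local = text.split(":", 1)
            # strip IRI schemes we cannot compact
            if prefix in ("http", "https"):
                raise ValueError(f"cannot compact IRI: {text}")
            return cls(prefix, local)
        raise ValueError(f"not a CURIE: {text}")


_SYMBOL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*$")
_WORD_SPLIT = re.compile(r"[^A-Za-z0-9]+")


def camel_case(label: str) -> str:
    """Camel-case a label: split on whitespace/hyphens/punctuation, capitalize
    each word's first letter, concatenate, drop non-alphanumerics."""
    if not label or not label.strip():
        raise EmptyLabel("cannot symbolize an empty label")
    words = [w for w in _WORD_SPLIT.split(label) if w]
    sym = "".join(w[:1].upper() + w[1:] for w in words)
    if not sym:
        raise EmptyLabel(f"label {label!r} has no alphanumeric content")
    if not sym[0].isalpha():
        sym = "X" + sym
    return sym


class SymbolTable:
    """Bijective mapping between CURIEs and camel-case symbols.

    Collisions between distinct CURIEs are resolved by numeric suffixing in
    insertion order (``BetaCell``, ``BetaCell2``, ...).  ``SubClassOf`` is
    reserved for the is-a predicate and is never assigned to a term.
    """

    def __init__(self) -> None:
        self._forward: dict[Curie, str] = {}
        self._reverse: dict[str, Curie] = {}

    def __len__(self) -> int:
        return len(self._forward)

    def __contains__(self, symbol: str) -> bool:
        return symbol == SUBCLASS_OF or symbol in self._reverse

    def add(self, curie: Curie, label: str) -> str:
        """Register *curie* under the symbolization of *label*; idempotent."""
        if curie in self._forward:
            return self._forward[curie]
        base = camel_case(label)
        sym = base
        n = 1
        while sym == SUBCLASS_OF or sym in self._reverse:
            n += 1
            sym = f"{base}{n}"
        self._forward[curie] = sym
        self._reverse[sym] = curie
        return sym

    def symbol_for(self, curie: Curie) -> str:
        try:
            return self._forward[curie]
        except KeyError:
            raise UnknownTerm(f"no symbol registered for {curie}") from None

    def resolve(self, symbol: str) -> Curie:
        try:
            return self._reverse[symbol]
        except KeyError:
            raise UnknownTerm(f"unknown symbol {symbol!r}") from None

    def items(self):
        return self._forward.items()


def symbolize(label: str, table: SymbolTable | None = None, curie: Curie | None = None) -> str:
    """Symbolize *label*; with a table and CURIE, register collision-free."""
    if table is not None and curie is not None:
        return table.add(curie, label)
    return camel_case(label)


@dataclass(frozen=True)
class Relationship:
    """A typed edge rendered at the symbol level."""

    predicate: str
    target: str

    def to_dict(self) -> dict:
        return {"predicate": self.predicate, "target": self.target}


@dataclass
class LogicalDefinition:
    """Genus-differentia logical definition: a genus CURIE plus restriction
    (predicate, filler) CURIE pairs."""

    genus: Curie
    differentia: list[tuple[Curie, Curie]] = field(default_factory=list)


@dataclass
class TermInfo:
    label: str
    definition: str | None = None
    creation_date: _dt.date | None = None


@dataclass
class OntologyGraph:
    """Terms, typed edges, and logical definitions of one ontology.

    Edges are ``(subject, predicate, object)`` triples; the predicate is
    either the :data:`SUBCLASS_OF` sentinel or the CURIE of a relation such
    as RO:0002100.  The asserted SubClassOf edge set must be acyclic.
    """

    terms: dict[Curie, TermInfo] = field(default_factory=dict)
    edges: set[tuple[Curie, object, Curie]] = field(default_factory=set)
    logical_definitions: dict[Curie, LogicalDefinition] = field(default_factory=dict)
    predicate_labels: dict[Curie, str] = field(default_factory=dict)

    def __contains__(self, curie: Curie) -> bool:
        return curie in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def outgoing(self, curie: Curie) -> list[tuple[Curie, object, Curie]]:
        return sorted(
            (e for e in self.edges if e[0] == curie),
            key=lambda e: (str(e[1]), str(e[2])),
        )

    def subclass_parents(self, curie: Curie) -> list[Curie]:
        return sorted({o for s, p, o in self.edges if s == curie and p == SUBCLASS_OF})

    def subclass_digraph(self) -> "nx.DiGraph":
        """Child -> parent digraph over asserted SubClassOf edges (all terms
        present as nodes)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((s, o) for s, p, o in self.edges if p == SUBCLASS_OF)
        return g

    def subsumed_terms(self, curie: Curie) -> set[Curie]:
        """Reflexive set of terms having *curie* among their is-a ancestors."""
        if curie not in self.terms:
            raise UnknownTerm(str(curie))
        g = self.subclass_digraph()
        return nx.ancestors(g, curie) | {curie}

    def reachable(self, start: Curie, predicates: set) -> set[Curie]:
        """Terms reachable from *start* via >=1 edge whose predicate is in
        *predicates*."""
        if start not in self.terms:
            raise UnknownTerm(str(start))
        adj: dict[Curie, list[Curie]] = {}
        for s, p, o in self.edges:
            if p in predicates:
                adj.setdefault(s, []).append(o)
        seen: set[Curie] = set()
        stack = list(adj.get(start, []))
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj.get(node, []))
        return seen

    def validate(self) -> None:
        for s, _p, o in self.edges:
            if s not in self.terms or o not in self.terms:
                raise ValueError(f"edge endpoint missing from terms: {s} / {o}")
        if not nx.is_directed_acyclic_graph(self.subclass_digraph()):
            raise ValueError("SubClassOf edge set is cyclic")


@dataclass
class TermObject:
    """One ontology class in symbolized JSON form.

    ``id`` is the camel-case symbol of the label; ``original_id`` retains the
    untranslated CURIE.  ``logical_definitions`` lists the genus as a
    SubClassOf entry plus one entry per differentia.
    """

    id: str | None = None
    original_id: str | None = None
    label: str | None = None
    definition: str | None = None
    relationships: list[Relationship] = field(default_factory=list)
    logical_definitions: list[Relationship] | None = None

    FIELD_ORDER = ("id", "original_id", "label", "definition", "relationships", "logical_definitions")

    def to_dict(self, fields: tuple[str, ...] | None = None) -> dict:
        out: dict = {}
        for name in self.FIELD_ORDER:
            if fields is not None and name not in fields:
                continue
            val = getattr(self, name)
            if val is None:
                continue
            if name in ("relationships", "logical_definitions"):
                if name == "relationships" and not val and fields is None:
                    out[name] = []
                    continue
                out[name] = [r.to_dict() for r in val]
            else:
                out[name] = val
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "TermObject":
        rels = [Relationship(**r) for r in data.get("relationships", [])]
        ldefs = data.get("logical_definitions")
        if ldefs is not None:
            ldefs = [Relationship(**r) for r in ldefs]
        return cls(
            id=data.get("id"),
            original_id=data.get("original_id"),
            label=data.get("label"),
            definition=data.get("definition"),
            relationships=rels,
            logical_definitions=ldefs,
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "TermObject":
        return cls.from_dict(json.loads(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TermObject":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class PartialTerm:
    """A term object with some fields absent and a completion request.

    ``fields_to_complete`` names the fields the generation backend should
    fill; it is disjoint from the fields already present.
    """

    label: str | None = None
    definition: str | None = None
    relationships: list[Relationship] | None = None
    logical_definitions: list[Relationship] | None = None
    fields_to_complete: list[str] = field(default_factory=list)

    def present_fields(self) -> list[str]:
        names = []
        for name in ("label", "definition", "relationships", "logical_definitions"):
            if getattr(self, name) is not None:
                names.append(name)
        return names

    def to_dict(self) -> dict:
        out: dict = {}
        for name in self.present_fields():
            val = getattr(self, name)
            if name in ("relationships", "logical_definitions"):
                out[name] = [r.to_dict() for r in val]
            else:
                out[name] = val
        return out

    def query_text(self) -> str:
        """Text of the present fields, for embedding the completion query."""
        obj = TermObject(
            label=self.label,
            definition=self.definition,
            relationships=self.relationships or [],
        )
        return serialize_for_embedding(obj)


# ---------------------------------------------------------------------------
# Loading OBO Graph JSON

_CREATION_DATE_PREDS = ("creation_date", "creationDate", "date")


def _parse_date(val: str) -> _dt.date | None:
    val = val.strip()
    try:
        return _dt.date.fromisoformat(val[:10])
    except ValueError:
        return None


def load_ontology(path: str, format: str = "obograph-json") -> OntologyGraph:
    """Load an OBO Graph JSON document into an :class:`OntologyGraph`.

    Obsolete and unlabeled classes are skipped with a warning; edges with a
    missing endpoint are dropped with a warning (never an error).  Creation
    dates are read from ``creation_date``-style property annotations.
    """
    if format != "obograph-json":
        raise MalformedFile(f"unsupported format: {format}")
    try:
        with open(path) as fh:
            doc = json.load(fh)
        graphs = doc["graphs"]
    except (OSError, ValueError, KeyError, TypeError) as exc:
        raise MalformedFile(f"cannot parse {path} as OBO Graph JSON: {exc}") from exc

    out = OntologyGraph()
    for g in graphs:
        for node in g.get("nodes", []):
            try:
                curie = Curie.parse(node["id"])
            except (ValueError, KeyError):
                logger.warning("skipping node with uncompactable id: %r", node.get("id"))
                continue
            meta = node.get("meta") or {}
            ntype = node.get("type", "CLASS")
            label = node.get("lbl")
            if ntype == "PROPERTY":
                if label:
                    out.predicate_labels[curie] = label
                continue
            if ntype != "CLASS":
                continue
            if meta.get("deprecated"):
                logger.warning("skipping obsolete class %s", curie)
                continue
            if not label:
                logger.warning("skipping unlabeled class %s", curie)
                continue
            definition = (meta.get("definition") or {}).get("val")
            date = None
            for bpv in meta.get("basicPropertyValues", []):
                pred = bpv.get("pred", "")
                if any(pred.endswith(suffix) for suffix in _CREATION_DATE_PREDS):
                    date = _parse_date(bpv.get("val", ""))
                    if date:
                        break
            out.terms[curie] = TermInfo(label=label, definition=definition, creation_date=date)

    for g in graphs:
        for edge in g.get("edges", []):
            try:
                sub = Curie.parse(edge["sub"])
                obj = Curie.parse(edge["obj"])
            except (ValueError, KeyError):
                logger.warning("dropping unparseable edge: %r", edge)
                continue
            raw_pred = edge.get("pred", "is_a")
            if raw_pred in ("is_a", "rdfs:subClassOf", "subClassOf", "SubClassOf"):
                pred: object = SUBCLASS_OF
            else:
                try:
                    pred = Curie.parse(raw_pred)
                except ValueError:
                    logger.warning("dropping edge with unparseable predicate %r", raw_pred)
                    continue
            if sub not in out.terms or obj not in out.terms:
                logger.warning("dropping dangling edge %s -[%s]-> %s", sub, raw_pred, obj)
                continue
            out.edges.add((sub, pred, obj))

        for axiom in g.get("logicalDefinitionAxioms", []):
            try:
                defined = Curie.parse(axiom["definedClassId"])
                genus_ids = [Curie.parse(x) for x in axiom.get("genusIds", [])]
                restrictions = [
                    (Curie.parse(r["propertyId"]), Curie.parse(r["fillerId"]))
                    for r in axiom.get("restrictions", [])
                ]
            except (ValueError, KeyError):
                logger.warning("dropping unparseable logical definition: %r", axiom)
                continue
            if len(genus_ids) != 1:
                logger.warning("skipping non genus-differentia logical definition for %s", defined)
                continue
            if defined not in out.terms or genus_ids[0] not in out.terms:
                continue
            restrictions = [(p, f) for p, f in restrictions if f in out.terms]
            out.logical_definitions[defined] = LogicalDefinition(genus_ids[0], restrictions)

    out.validate()
    return out


def write_obograph(graph: OntologyGraph, path: str) -> None:
    """Write *graph* back out as OBO Graph JSON (inverse of load)."""
    nodes = []
    for curie in sorted(graph.terms):
        info = graph.terms[curie]
        meta: dict = {}
        if info.definition:
            meta["definition"] = {"val": info.definition}
        if info.creation_date:
            meta["basicPropertyValues"] = [
                {
                    "pred": "http://www.geneontology.org/formats/oboInOwl#creation_date",
                    "val": info.creation_date.isoformat(),
                }
            ]
        node = {"id": str(curie), "lbl": info.label, "type": "CLASS"}
        if meta:
            node["meta"] = meta
        nodes.append(node)
    for curie in sorted(graph.predicate_labels):
        nodes.append({"id": str(curie), "lbl": graph.predicate_labels[curie], "type": "PROPERTY"})
    edges = [
        {
            "sub": str(s),
            "pred": "is_a" if p == SUBCLASS_OF else str(p),
            "obj": str(o),
        }
        for s, p, o in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]), str(e[2])))
    ]
    axioms = [
        {
            "definedClassId": str(c),
            "genusIds": [str(ld.genus)],
            "restrictions": [
                {"propertyId": str(p), "fillerId": str(f)} for p, f in ld.differentia
            ],
        }
        for c, ld in sorted(graph.logical_definitions.items())
    ]
    doc = {"graphs": [{"nodes": nodes, "edges": edges, "logicalDefinitionAxioms": axioms}]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Term-object construction and serialization


def build_symbol_table(graph: OntologyGraph) -> SymbolTable:
    """Symbolize every term and predicate of *graph* in deterministic order."""
    table = SymbolTable()
    for curie in sorted(graph.terms):
        table.add(curie, graph.terms[curie].label)
    for curie in sorted(graph.predicate_labels):
        table.add(curie, graph.predicate_labels[curie])
    return table


def _predicate_symbol(pred: object, graph: OntologyGraph, table: SymbolTable) -> str:
    if pred == SUBCLASS_OF:
        return SUBCLASS_OF
    assert isinstance(pred, Curie)
    label = graph.predicate_labels.get(pred)
    if label is None:
        # relation with no declared label: symbolize its local id
        return table.add(pred, pred.local_id)
    return table.add(pred, label)


def term_to_object(graph: OntologyGraph, curie: Curie, table: SymbolTable) -> TermObject:
    """Render one term as a symbolized :class:`TermObject`.

    Definition provenance (xrefs) is never emitted.
    """
    if curie not in graph.terms:
        raise UnknownTerm(str(curie))
    info = graph.terms[curie]
    rels = [
        Relationship(_predicate_symbol(p, graph, table), table.symbol_for(o))
        for _s, p, o in graph.outgoing(curie)
    ]
    ldefs = None
    if curie in graph.logical_definitions:
        ld = graph.logical_definitions[curie]
        ldefs = [Relationship(SUBCLASS_OF, table.symbol_for(ld.genus))]
        ldefs += [
            Relationship(_predicate_symbol(p, graph, table), table.symbol_for(f))
            for p, f in ld.differentia
        ]
    return TermObject(
        id=table.symbol_for(curie),
        original_id=str(curie),
        label=info.label,
        definition=info.definition,
        relationships=rels,
        logical_definitions=ldefs,
    )


def serialize_for_embedding(term: TermObject) -> str:
    """Deterministic key-value text used as the embedding input for a term.

    Field order is fixed (label, definition, relationships); relationships
    are rendered as ``predicate: target`` pairs joined by ``; ``.
    """
    if not term.label:
        raise EmptyLabel("term must have a label to be serialized")
    lines = [f"label: {term.label}"]
    if term.definition:
        lines.append(f"definition: {term.definition}")
    if term.relationships:
        pairs = "; ".join(f"{r.predicate}: {r.target}" for r in term.relationships)
        lines.append(f"relationships: {pairs}")
    return "\n".join(lines)


_TASK_FIELDS = {
    "relationships": "relationships",
    "definition": "definition",
    "logical_definitions": "logical_definitions",
}


def mask_term(term: TermObject, task: str) -> PartialTerm:
    """Mask the gold field for *task*, yielding the completion input.

    Identifiers are always removed (they leak training data).  For the
    relationships task only the label and the text definition survive.
    """
    if task not in _TASK_FIELDS:
        raise ValueError(f"unknown task {task!r}")
    gold_field = _TASK_FIELDS[task]
    gold = getattr(term, gold_field)
    if gold is None or (isinstance(gold, list) and not gold):
        raise MissingGoldField(f"term {term.label!r} lacks gold field {gold_field!r}")
    if task == "relationships":
        partial = PartialTerm(label=term.label, definition=term.definition)
    elif task == "definition":
        partial = PartialTerm(
            label=term.label,
            relationships=list(term.relationships),
            logical_definitions=list(term.logical_definitions) if term.logical_definitions else None,
        )
    else:
        partial = PartialTerm(
            label=term.label,
            definition=term.definition,
            relationships=list(term.relationships),
        )
    partial.fields_to_complete = [gold_field]
    return partial


def split_by_date(
    graph: OntologyGraph,
    cutoff: _dt.date,
    n: int,
    seed: int | None = None,
) -> tuple[OntologyGraph, list[Curie]]:
    """Split *graph* into a core ontology and a dated test set.

    Eligible terms were created strictly after *cutoff*; the *n* most recent
    (date descending, ties by CURIE) become the test set.  Undated terms are
    never eligible.  The core graph drops test terms, their incident edges,
    and any logical definition mentioning a test term.  *seed* is accepted
    for interface symmetry but unused: the selection rule is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = [
        c
        for c, info in graph.terms.items()
        if info.creation_date is not None and info.creation_date > cutoff
    ]
    if not eligible:
        raise NoEligibleTerms(f"no term dated after {cutoff}")
    eligible.sort(key=lambda c: (-graph.terms[c].creation_date.toordinal(), str(c)))
    if len(eligible) < n:
        logger.warning("only %d terms dated after %s (requested %d)", len(eligible), cutoff, n)
    test = eligible[:n]
    test_set = set(test)
    core = OntologyGraph(
        terms={c: replace(i) for c, i in graph.terms.items() if c not in test_set},
        edges={
            (s, p, o) for s, p, o in graph.edges if s not in test_set and o not in test_set
        },
        logical_definitions={
            c: LogicalDefinition(ld.genus, list(ld.differentia))
            for c, ld in graph.logical_definitions.items()
            if c not in test_set
            and ld.genus not in test_set
            and all(f not in test_set for _p, f in ld.differentia)
        },
        predicate_labels=dict(graph.predicate_labels),
    )
    return core, test
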