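"""Exception hierarchy shared across the package."""


class OntoRagError(Exception):
    """Base class for all package errors."""


class MalformedFile(OntoRagError):
    """Input file could not be parsed in the expected format."""


class EmptyLabel(OntoRagError):
    """A term label was empty where a non-empty one is required."""


class UnknownTerm(OntoRagError):
    """A CURIE or symbol does not resolve in the current graph/table."""


class MissingGoldField(OntoRagError):
    """The field to be masked for an evaluation task is absent from the term."""


class NoEligibleTerms(OntoRagError):
    """No term satisfies the date criterion for the test split."""


class EmptyCorpus(OntoRagError):
    """An index was built from an empty document collection."""


class EmptyIndex(OntoRagError):
    """A query was issued against an index with no documents."""


class DuplicateDocument(OntoRagError):
    """Two documents share a doc_id within one collection."""


class DimensionMismatch(OntoRagError):
    """Vectors of different dimensions were combined."""


class BudgetUnsatisfiable(OntoRagError):
    """Even a zero-example prompt exceeds the generation token budget."""


class ParseFailure(OntoRagError):
    """No parseable JSON object was found in a model reply."""


class EdgeNotAsserted(OntoRagError):
    """An entailment check was requested for an edge not in the graph."""


class InsufficientData(OntoRagError):
    """Too few evaluators/ratings remain after filtering to compute a statistic."""


class DegenerateVariance(OntoRagError):
    """All mean squares are zero; the reliability coefficient is undefined."""


class InsufficientLevels(OntoRagError):
    """Fewer than three distinct confidence levels with data."""


class MalformedLogicalDefinition(OntoRagError):
    """A logical definition does not have exactly one genus."""


class InvalidSpec(OntoRagError):
    """A fixture specification violates its own constraints."""
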