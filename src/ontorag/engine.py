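"""Prompt assembly, generation-backend invocation, parsing, post-filtering.

The completion pipeline embeds a partial term, retrieves the most similar
indexed terms as few-shot input/output example pairs (optionally plus issue
snippets), renders a prompt within the backend's token budget, invokes the
generation backend, extracts the first JSON object from the reply, and
merges the recognized fields back into the input.  Predicted relationships
naming symbols unknown to the symbol table are dropped — the pipeline is
deliberately conservative and never fabricates ontology terms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

from .errors import BudgetUnsatisfiable, ParseFailure
from .index import VectorIndex, mmr_rerank
from .ontology import PartialTerm, Relationship, SymbolTable, TermObject

logger = logging.getLogger(__name__)

DEFAULT_INSTRUCTION = (
    "You are an ontology editor assistant. Complete the partial ontology term "
    "given as the final input, filling in the requested missing fields. "
    "Respond with a single JSON object in the same style as the examples. "
    "Use only term symbols that exist in the ontology."
)


@runtime_checkable
class GenerationBackend(Protocol):
    name: str
    token_budget: int

    def complete(self, prompt: str) -> str: ...


def _label_key(label: str) -> str:
    return hashlib.blake2b(label.encode(), digest_size=8).hexdigest()


class CannedReplyBook:
    """Deterministic reply lookup keyed by a hash of the query label."""

    def __init__(self, default_reply: str = "I cannot help with that.") -> None:
        self._replies: dict[str, str] = {}
        self.default_reply = default_reply

    def add(self, label: str, reply: str) -> None:
        self._replies[_label_key(label)] = reply

    def lookup(self, label: str) -> str:
        return self._replies.get(_label_key(label), self.default_reply)

    def __len__(self) -> int:
        return len(self._replies)


_INPUT_BLOCK = re.compile(r"input:\s*\n(\{.*?\})\s*\noutput:", re.DOTALL)


class MockBackend:
    """Offline generation backend answering from a :class:`CannedReplyBook`.

    The reply is a pure function of the prompt: the backend locates the
    final input JSON block, reads its label, and looks the reply up.
    """

    def __init__(self, book: CannedReplyBook, name: str = "mock", token_budget: int = 4096) -> None:
        self.book = book
        self.name = name
        self.token_budget = token_budget

    def complete(self, prompt: str) -> str:
        blocks = _INPUT_BLOCK.findall(prompt)
        label = ""
        if blocks:
            try:
                label = json.loads(blocks[-1]).get("label", "")
            except ValueError:
                label = ""
        return self.book.lookup(label)


def estimate_tokens(text: str, inflation: float = 1.3) -> int:
    """Whitespace-token count inflated toward subword-tokenizer counts."""
    return math.ceil(len(text.split()) * inflation)


@dataclass
class PromptPayload:
    """A rendered few-shot completion prompt."""

    instruction: str
    examples: list[tuple[dict, dict]]
    issue_snippets: list[str]
    query: dict
    fields_to_complete: list[str] = field(default_factory=list)

    def render(self) -> str:
        parts = [self.instruction, ""]
        if self.fields_to_complete:
            parts.append("Fields to complete: " + ", ".join(self.fields_to_complete))
            parts.append("")
        if self.issue_snippets:
            parts.append("Relevant issue tracker excerpts:")
            for snippet in self.issue_snippets:
                parts.append("---")
                parts.append(snippet)
            parts.append("---")
            parts.append("")
        for inp, out in self.examples:
            parts.append("input:")
            parts.append(json.dumps(inp, sort_keys=True))
            parts.append("output:")
            parts.append(json.dumps(out, sort_keys=True))
            parts.append("")
        parts.append("input:")
        parts.append(json.dumps(self.query, sort_keys=True))
        parts.append("output:")
        return "\n".join(parts)


@dataclass
class CompletionResult:
    completed: TermObject
    dropped_relationships: list[Relationship] = field(default_factory=list)
    raw_reply: str = ""
    failed: bool = False

    def to_dict(self) -> dict:
        return {
            "completed": self.completed.to_dict(),
            "dropped_relationships": [r.to_dict() for r in self.dropped_relationships],
            "raw_reply": self.raw_reply,
            "failed": self.failed,
        }


@dataclass
class CompletionConfig:
    """Tunables of the completion pipeline."""

    k: int = 10  # in-context examples retrieved
    lam: float = 0.5  # MMR relevance/diversity trade-off
    pool_factor: int = 4  # MMR candidate pool = pool_factor * k
    n_issues: int = 2  # issue snippets included when an issue index is given
    snippet_cap: int = 2000  # characters kept per issue snippet
    example_floor: int = 0  # minimum examples kept even over budget
    max_retries: int = 2  # verbatim re-prompts after a parse failure
    token_inflation: float = 1.3
    instruction: str = DEFAULT_INSTRUCTION


def select_examples(
    term_index: VectorIndex,
    partial: PartialTerm,
    k: int = 10,
    lam: float = 0.5,
    pool_factor: int = 4,
    exclude_doc_id: str | None = None,
) -> list[TermObject]:
    """Retrieve the k most relevant terms, MMR-diversified, as examples.

    The gold term itself (by doc_id) is excluded so evaluation never leaks
    the answer into the prompt.
    """
    if k == 0:
        return []
    exclude = {exclude_doc_id} if exclude_doc_id else None
    query_vec = term_index.backend.embed(partial.query_text())
    pool = term_index.query_vector(query_vec, k=max(k, pool_factor * k), exclude=exclude)
    reranked = mmr_rerank(pool, query_vec, lam=lam, k=k)
    return [r.document.payload for r in reranked]


def _example_pair(example: TermObject, partial: PartialTerm) -> tuple[dict, dict]:
    """Render one retrieved term as an input/output training pair.

    The input side carries only the fields present in the partial term; the
    output side carries the fields to be completed.
    """
    inp = example.to_dict(fields=tuple(partial.present_fields()))
    out = example.to_dict(fields=tuple(partial.fields_to_complete))
    return inp, out


def build_prompt(
    partial: PartialTerm,
    examples: Sequence[TermObject],
    issues: Sequence[str] = (),
    backend: GenerationBackend | None = None,
    config: CompletionConfig | None = None,
) -> PromptPayload:
    """Assemble the prompt, trimming tail examples to fit the token budget.

    Examples are dropped from the lowest retrieval rank upward until the
    rendered prompt fits, but never below ``config.example_floor``; if the
    floor forces an overflow a warning is logged and the oversized prompt is
    returned as-is.
    """
    config = config or CompletionConfig()
    budget = backend.token_budget if backend is not None else None
    snippets = [s[: config.snippet_cap] for s in issues]
    pairs = [_example_pair(e, partial) for e in examples]
    payload = PromptPayload(
        instruction=config.instruction,
        examples=pairs,
        issue_snippets=snippets,
        query=partial.to_dict(),
        fields_to_complete=list(partial.fields_to_complete),
    )
    if budget is None:
        return payload
    floor = min(config.example_floor, len(pairs))
    while estimate_tokens(payload.render(), config.token_inflation) > budget:
        if len(payload.examples) <= floor:
            break
        payload.examples = payload.examples[:-1]
    overflow = estimate_tokens(payload.render(), config.token_inflation) > budget
    if overflow and floor == 0 and not payload.examples:
        raise BudgetUnsatisfiable(
            f"prompt exceeds token budget {budget} even with zero examples"
        )
    if overflow:
        logger.warning(
            "example floor %d keeps the prompt over the %d-token budget", floor, budget
        )
    return payload


_RECOGNIZED_FIELDS = ("definition", "relationships", "logical_definitions")


def parse_completion(raw_reply: str) -> dict:
    """Extract the first balanced JSON object from a model reply.

    Preamble, postamble and code fences are tolerated; recognized fields are
    returned with normalized (lower-case) keys, unrecognized keys are
    ignored with a warning.
    """
    decoder = json.JSONDecoder()
    obj = None
    for start in range(len(raw_reply)):
        if raw_reply[start] != "{":
            continue
        try:
            obj, _end = decoder.raw_decode(raw_reply, start)
            break
        except ValueError:
            continue
    if not isinstance(obj, dict):
        raise ParseFailure("no JSON object found in reply")
    out: dict = {}
    for key, value in obj.items():
        norm = key.strip().lower()
        if norm in _RECOGNIZED_FIELDS:
            out[norm] = value
        else:
            logger.warning("ignoring unrecognized reply field %r", key)
    return out


def _coerce_relationships(value: object) -> list[Relationship]:
    rels = []
    if not isinstance(value, list):
        return rels
    for item in value:
        if isinstance(item, dict):
            pred = item.get("predicate")
            target = item.get("target")
            if isinstance(pred, str) and isinstance(target, str):
                rels.append(Relationship(pred, target))
    return rels


def postprocess(parsed: dict, partial: PartialTerm, table: SymbolTable) -> CompletionResult:
    """Filter predicted relationships to known symbols and merge with input.

    Only the requested fields are filled from the reply; fields already
    present in the partial term always win.  Relationships whose predicate
    or target does not resolve through the symbol table are removed and
    recorded in ``dropped_relationships``.
    """
    completed = TermObject(
        label=partial.label,
        definition=partial.definition,
        relationships=list(partial.relationships) if partial.relationships is not None else [],
        logical_definitions=(
            list(partial.logical_definitions) if partial.logical_definitions is not None else None
        ),
    )
    dropped: list[Relationship] = []
    for name in partial.fields_to_complete:
        if name not in parsed:
            continue
        if name == "definition":
            if isinstance(parsed[name], str):
                completed.definition = parsed[name]
        else:
            kept = []
            for rel in _coerce_relationships(parsed[name]):
                if rel.predicate in table and rel.target in table:
                    kept.append(rel)
                else:
                    logger.warning("dropping relationship to unknown symbol: %s", rel)
                    dropped.append(rel)
            setattr(completed, name, kept)
    return CompletionResult(completed=completed, dropped_relationships=dropped)


def complete_term(
    partial: PartialTerm,
    term_index: VectorIndex,
    issue_index: VectorIndex | None,
    backend: GenerationBackend,
    table: SymbolTable,
    config: CompletionConfig | None = None,
    exclude_doc_id: str | None = None,
) -> CompletionResult:
    """Run the full retrieval -> prompt -> generate -> parse -> filter pipeline.

    On a parse failure the identical prompt is retried ``config.max_retries``
    times; if all attempts fail a result flagged ``failed`` is returned with
    the raw reply so batch evaluation can continue.
    """
    config = config or CompletionConfig()
    examples = select_examples(
        term_index,
        partial,
        k=config.k,
        lam=config.lam,
        pool_factor=config.pool_factor,
        exclude_doc_id=exclude_doc_id,
    )
    snippets: list[str] = []
    if issue_index is not None and config.n_issues > 0:
        hits = issue_index.query(partial.query_text(), k=config.n_issues)
        snippets = [h.document.text for h in hits]
    payload = build_prompt(partial, examples, snippets, backend, config)
    prompt = payload.render()
    raw = ""
    for _attempt in range(config.max_retries + 1):
        raw = backend.complete(prompt)
        try:
            parsed = parse_completion(raw)
        except ParseFailure:
            continue
        result = postprocess(parsed, partial, table)
        result.raw_reply = raw
        return result
    logger.warning("all %d attempts failed to parse for %r", config.max_retries + 1, partial.label)
    result = postprocess({}, partial, table)
    result.raw_reply = raw
    result.failed = True
    return result
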