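"""End-to-end evaluation runs: split, index, complete, score, report.

One :func:`run_evaluation` call reproduces the full masked-field experiment
at fixture scale: split the ontology by date into core + test, index the
core terms, mask each test term's gold field, complete it through the
configured generation backend, score the completion against the gold, and
emit a micro-averaged summary plus per-term records.  With the mock backend
the whole run is deterministic, so two runs with the same configuration
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from .engine import CannedReplyBook, CompletionConfig, GenerationBackend, MockBackend
from .errors import MissingGoldField
from .evaluation import (
    ScoreSummary,
    aggregate_prf,
    definition_similarity,
    reasoner_baseline,
    score_logical_definitions,
    score_relationships,
)
from .index import HashingEmbedder, VectorIndex, build_index
from .ontology import (
    SUBCLASS_OF,
    OntologyGraph,
    build_symbol_table,
    load_ontology,
    mask_term,
    split_by_date,
    term_to_object,
)
from . import engine
from .synthetic import FixtureSpec, build_echo_book, generate_ontology

logger = logging.getLogger(__name__)

_TASK_FIELD = {
    "relationships": "relationships",
    "definition": "definition",
    "logical_definitions": "logical_definitions",
}


@dataclass
class RunConfig:
    """Configuration of one evaluation run (YAML-loadable)."""

    task: str = "relationships"
    ontology_path: str | None = None  # OBO Graph JSON; mutually exclusive with fixture
    fixture: FixtureSpec | None = None
    cutoff: _dt.date = _dt.date(2022, 11, 1)
    n_test: int = 50
    seed: int = 0
    backend: str = "echo"  # echo | mock:<replies.json>
    embed_dim: int = 256
    task_filter: str = "all"  # all | subclass_only
    completion: CompletionConfig = field(default_factory=CompletionConfig)
    use_issues: bool = False
    issues_path: str | None = None
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fixture" in raw and raw["fixture"] is not None:
            fx = dict(raw["fixture"])
            if "date_range" in fx:
                fx["date_range"] = tuple(_dt.date.fromisoformat(d) for d in fx["date_range"])
            raw["fixture"] = FixtureSpec(**fx)
        if "cutoff" in raw:
            raw["cutoff"] = _dt.date.fromisoformat(str(raw["cutoff"]))
        if "completion" in raw and raw["completion"] is not None:
            raw["completion"] = CompletionConfig(**raw["completion"])
        return cls(**raw)


@dataclass
class EvaluationReport:
    task: str
    summary: ScoreSummary
    per_term: list[dict]
    n_test: int
    n_skipped: int
    n_failed: int
    reasoner: ScoreSummary | None = None

    def to_dict(self) -> dict:
        out = {
            "task": self.task,
            "summary": self.summary.to_dict(),
            "n_test": self.n_test,
            "n_skipped": self.n_skipped,
            "n_failed": self.n_failed,
        }
        if self.reasoner is not None:
            out["reasoner_baseline"] = self.reasoner.to_dict()
        return out


def _load_graph(config: RunConfig) -> OntologyGraph:
    if (config.ontology_path is None) == (config.fixture is None):
        raise ValueError("exactly one of ontology_path / fixture must be set")
    if config.ontology_path:
        return load_ontology(config.ontology_path)
    return generate_ontology(config.fixture)


def _make_backend(config: RunConfig, graph, table, test_terms) -> GenerationBackend:
    if config.backend == "echo":
        book = build_echo_book(graph, table, test_terms, [_TASK_FIELD[config.task]])
        return MockBackend(book, name="echo")
    if config.backend.startswith("mock:"):
        with open(config.backend[5:]) as fh:
            raw = json.load(fh)
        book = CannedReplyBook(default_reply=raw.get("default", "I cannot help with that."))
        for label, reply in raw.get("replies", {}).items():
            book.add(label, reply if isinstance(reply, str) else json.dumps(reply))
        return MockBackend(book)
    raise ValueError(f"unknown backend spec {config.backend!r}")


def run_evaluation(
    config: RunConfig, backend: GenerationBackend | None = None
) -> EvaluationReport:
    """Execute one masked-completion experiment and score it.

    Per-term failures (missing gold fields, unparseable replies) are
    recorded and skipped; the run always completes.  When ``config.outdir``
    is set, ``report.json`` and ``per_term.jsonl`` are written there with
    sorted keys so identical runs yield byte-identical files.
    """
    task = config.task
    if task not in _TASK_FIELD:
        raise ValueError(f"unknown task {task!r}")
    gold_field = _TASK_FIELD[task]

    graph = _load_graph(config)
    core, test_terms = split_by_date(graph, config.cutoff, config.n_test, seed=config.seed)
    # the symbol vocabulary covers the whole ontology; only core terms are indexed
    table = build_symbol_table(graph)
    embedder = HashingEmbedder(dimension=config.embed_dim, seed=config.seed)
    core_objects = [term_to_object(core, c, table) for c in sorted(core.terms)]
    term_index = build_index(core_objects, embedder)
    issue_index: VectorIndex | None = None
    if config.use_issues and config.issues_path:
        from .index import index_issues, load_issues

        issue_index = index_issues(load_issues(config.issues_path), embedder)
    if backend is None:
        backend = _make_backend(config, graph, table, test_terms)

    per_term: list[dict] = []
    n_skipped = n_failed = 0
    total_credit = 0.0
    total_pred = 0
    total_gold = 0
    sim_p: list[float] = []
    sim_r: list[float] = []

    for curie in test_terms:
        gold_obj = term_to_object(graph, curie, table)
        try:
            partial = mask_term(gold_obj, task)
        except MissingGoldField:
            n_skipped += 1
            per_term.append({"term": str(curie), "skipped": True})
            continue
        result = engine.complete_term(
            partial,
            term_index,
            issue_index,
            backend,
            table,
            config=config.completion,
            exclude_doc_id=gold_obj.id,
        )
        record: dict = {
            "term": str(curie),
            "label": gold_obj.label,
            "failed": result.failed,
            "dropped": [r.to_dict() for r in result.dropped_relationships],
        }
        if result.failed:
            n_failed += 1

        if task == "relationships":
            predicted = [
                (SUBCLASS_OF if r.predicate == SUBCLASS_OF else table.resolve(r.predicate),
                 table.resolve(r.target))
                for r in result.completed.relationships
            ]
            gold = [(p, o) for _s, p, o in graph.outgoing(curie)]
            judgements = score_relationships(
                predicted, gold, graph, curie, task_filter=config.task_filter
            )
            n_gold = len(
                gold if config.task_filter == "all" else [g for g in gold if g[0] == SUBCLASS_OF]
            )
            summary = aggregate_prf(judgements, n_gold)
            total_credit += sum(j.credit for j in judgements)
            total_pred += len(judgements)
            total_gold += n_gold
            record["judgements"] = [j.to_dict() for j in judgements]
            record["scores"] = summary.to_dict()
        elif task == "definition":
            pred_def = result.completed.definition
            if pred_def:
                p, r, f1 = definition_similarity(pred_def, gold_obj.definition)
                sim_p.append(p)
                sim_r.append(r)
                total_pred += 1
                record["scores"] = {"precision": p, "recall": r, "f1": f1}
            else:
                record["scores"] = None
            total_gold += 1
            record["predicted_definition"] = pred_def
        else:  # logical_definitions
            summary = score_logical_definitions(
                result.completed.logical_definitions or [], gold_obj.logical_definitions
            )
            total_credit += summary.precision * summary.n_predicted
            total_pred += summary.n_predicted
            total_gold += summary.n_gold
            record["scores"] = summary.to_dict()
        per_term.append(record)

    if task == "definition":
        if sim_p:
            mp = sum(sim_p) / len(sim_p)
            mr = sum(sim_r) / len(sim_r)
            mf = 2 * mp * mr / (mp + mr) if mp + mr > 0 else 0.0
            summary = ScoreSummary(mp, mr, mf, total_pred, total_gold)
        else:
            summary = ScoreSummary(0.0, 0.0, 0.0, 0, total_gold, flagged=True)
    else:
        flagged = total_pred == 0
        precision = total_credit / total_pred if total_pred else 0.0
        recall = total_credit / total_gold if total_gold else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        summary = ScoreSummary(precision, recall, f1, total_pred, total_gold, flagged)

    reasoner = None
    if task == "relationships":
        reasoner = reasoner_baseline(graph, test_terms)

    report = EvaluationReport(
        task=task,
        summary=summary,
        per_term=per_term,
        n_test=len(test_terms),
        n_skipped=n_skipped,
        n_failed=n_failed,
        reasoner=reasoner,
    )
    if config.outdir:
        write_report(report, config.outdir)
    return report


def write_report(report: EvaluationReport, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "per_term.jsonl"), "w") as fh:
        for record in report.per_term:
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def config_to_yaml(config: RunConfig, path: str) -> None:
    raw = dataclasses.asdict(config)
    raw["cutoff"] = config.cutoff.isoformat()
    if config.fixture is not None:
        raw["fixture"]["date_range"] = [d.isoformat() for d in config.fixture.date_range]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
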