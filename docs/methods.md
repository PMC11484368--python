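# Methods

This note documents the models, procedures, numerical choices and
limitations behind `ontorag`, in the order the pipeline uses them.

## Term representation and symbolization

An ontology class is represented as a JSON term object with fields `id`,
`original_id`, `label`, `definition`, `relationships` (list of
`{predicate, target}`) and optional `logical_definitions`. Identifiers
are *symbolized*: the label is split on whitespace, hyphens and
punctuation, each word's first letter is upper-cased, the words are
concatenated and non-alphanumerics removed (`mitral cell` →
`MitralCell`). Symbolization avoids exposing numeric CURIEs, which
generation models tend to hallucinate, while keeping identifiers
reversible through a bijective symbol table.

Design choices where the mapping is under-determined:

- **Collisions.** Two distinct CURIEs whose labels symbolize identically
  receive numeric suffixes in registration order (`BetaCell`,
  `BetaCell2`). Registration order is the sorted CURIE order of the
  graph, so the mapping is deterministic and reversible.
- **Reserved symbol.** `SubClassOf` names the is-a predicate and is never
  assigned to a term; a term whose label would symbolize to it is
  suffixed instead.
- Labels with no leading letter after cleaning are prefixed with `X` so
  every symbol matches `[A-Za-z][A-Za-z0-9]*`.
- Definition provenance (xref lists) is never carried into term objects
  and never emitted: there is no principled way to regenerate citation
  provenance from context, so the object schema omits it.

Obsolete and unlabeled classes are skipped at load time (they cannot be
symbolized); edges with a missing endpoint are dropped with a warning
rather than failing the load, since released ontologies routinely contain
references to imported terms outside the loaded closure.

## Test-set construction

`split_by_date` mimics the leakage-control protocol for evaluating a
model with a training-data cutoff: only terms created strictly after a
cutoff date (default 2022-11-01) are eligible, the *n* most recent
eligible terms (ties broken by CURIE order) form the test set (default
n = 50), and the core ontology drops the test terms, all their incident
edges, and any logical definition mentioning them. Terms without a
creation date are never eligible — the conservative reading when
provenance is incomplete. Masking removes the task's gold field **and
both identifiers**; for the relationship task only the label and textual
definition survive, since relationships and logical definitions would
leak the answer's neighbourhood.

## Retrieval

Documents are embedded and queried by cosine similarity. Exact scan
implements the k-NN contract; the contract is on the ordering, not the
search algorithm, so an approximate HNSW engine could replace it behind
the same interface for million-term corpora. Results are re-ranked with
greedy Maximal Marginal Relevance: at each step pick the unselected
document maximizing `λ·cos(d, q) − (1−λ)·max_{s∈selected} cos(d, s)`,
first pick by pure query similarity, ties broken by original rank.
λ defaults to 0.5 (balanced relevance/diversity) and is exposed; the MMR
candidate pool defaults to 4·k before re-ranking (`pool_factor`).

The default embedding backend is a seeded feature-hashing bag-of-tokens
embedder (dimension 256): each lower-cased token is hashed (blake2b,
keyed by the seed) to a coordinate and a sign, token vectors are summed
and L2-normalized. It is a pure function of its input text, needs no
network, and makes cosine similarity a proxy for token overlap — exactly
the property retrieval tests need. It does **not** capture synonymy or
word order; conclusions about retrieval quality on real ontologies
require a contextual embedding model behind the same `EmbeddingBackend`
contract.

## Prompt assembly and parsing

Retrieved terms are rendered as `input:`/`output:` JSON pairs: the input
side carries only the fields present in the partial term, the output side
the fields to complete, so the examples demonstrate exactly the requested
transformation. Issue snippets (when an issue index is supplied) are
truncated to 2000 characters each and placed before the examples.

Token budgeting uses whitespace token count × 1.3 as a backend-agnostic
proxy for subword-tokenizer counts; exact tokenizers can be plugged into
the backend. Examples are dropped from the lowest retrieval rank upward
until the prompt fits, but never below the user-specified floor
(default 0); honouring a floor can therefore overflow the budget, which
is logged rather than silently truncated, since the user asked for the
examples explicitly. A prompt that exceeds the budget with zero examples
raises.

Reply parsing extracts the first balanced JSON object from the raw text
(tolerating preamble, postamble and code fences), keeps the recognized
fields (`definition`, `relationships`, `logical_definitions`;
case-insensitive keys because models capitalize freely), and warns on the
rest. A parse failure triggers up to 2 verbatim re-prompts (useful with
sampling backends; a no-op with deterministic ones), after which the
result is returned flagged `failed` so batch runs continue.
Post-filtering removes every predicted relationship whose predicate or
target symbol does not resolve in the symbol table — some of those
removals are meaningful references to terms that do not exist yet, but
the pipeline is deliberately conservative and never creates terms.

## Relationship scoring

`IC(t) = −log P(t)` with `P(t)` the fraction of terms having `t` among
their reflexive is-a ancestors. Reflexivity keeps leaf IC finite; log
base 2 (bits) is the default and configurable. A predicted edge
`(s, p, o')` is *more general* than gold `(s, p, o)` when `o'` is
reachable from `s` over edges typed is-a or `p`. Scoring walks the
predictions in order: exact (predicate, target) matches consume gold
edges at credit 1; a more-general prediction is paired with the unused
same-predicate gold target of highest IC from which the predicted target
is reachable (the most informative gold edge it could have meant),
earning `IC(o')/IC(o)` (clamped to [0,1]; 0 when the prediction is the
root); everything else scores 0. Each gold edge pairs at most once, and
pairing requires predicate equality — granting generality credit across
predicates would conflate distinct relations. Credits aggregate as
micro-P/R/F1 with denominators `n_predicted` and `n_gold`; an empty
prediction set is reported as 0/0/0 with a flag rather than as undefined.

## Subsumption-recovery baseline

For each asserted is-a edge of each test term, remove it and test whether
it is re-derivable from (a) the transitive closure of the remaining
asserted is-a edges or (b) the subject's logical-definition genus (genus
equal to, or subsuming-path-connected to, the removed parent). This is a
minimal structural entailment engine, not a DL reasoner: it covers
exactly the two derivation routes present in the synthetic fixtures and
in genus–differentia-style released ontologies' redundant axioms, and it
is sufficient for the recovery statistic. Precision of the baseline is 1
by construction (every recovered edge is asserted); recall measures
axiom redundancy.

## Definition similarity

Greedy token-matching over token embeddings: precision is the mean over
candidate tokens of the best cosine against reference tokens, recall the
symmetric quantity, F1 their harmonic mean. The token backend is
pluggable: the one-hot backend (cosine = token identity) makes the scores
exact set/multiset overlap quantities suitable for frozen expected
values; the hashing backend gives dense vectors. Neither models synonymy
or context — scores from these backends rank lexical agreement, not
semantic quality, and a contextual-embedding adapter is required for the
latter.

## Rating statistics

Ratings are ordinal 1–5 on three criteria (biological accuracy, internal
consistency — optional, overall score), each optionally carrying a 1–5
confidence. Inter-rater reliability is the one-way ANOVA intraclass
correlation with evaluator as the random effect:
`ICC = (MSB − MSE)/(MSB + (k−1)·MSE)`. For unbalanced designs k is the
mean group size. A minimum-confidence filter is applied before the ANOVA
(records without a confidence count as confidence 1). At least two
evaluators with two ratings each are required; an all-constant sheet
raises a degenerate-variance error instead of returning 0/0.

The confidence-gap analysis computes, per confidence level, the mean
human-authored minus mean model-authored rating, and the Pearson
correlation of that gap with confidence over levels carrying both
sources (at least 3 levels required; a zero-variance gap profile is
returned flagged with r = NaN). A positive correlation means confident
raters discriminate generated from curated definitions more sharply.

## Synthetic fixtures

The generator emulates the structural features the pipeline and its
evaluation depend on, with deliberately nonsense content:

- Rooted is-a DAG grown breadth-first (default 200 terms, depth ≤ 6,
  branching 3). Labels are compositional — children extend the parent's
  label with an adjective/noun from a fixed word bank — so lexical
  overlap tracks taxonomic proximity and hash-embedder retrieval is
  meaningful.
- Templated definitions mention the parent label (and, for terms with a
  logical definition, the differentia predicate and filler), mirroring
  genus–differentia definition style.
- Typed cross relationships (default 3 predicate types, on half the
  terms), redundant entailed is-a edges to the grandparent on a
  configurable fraction of grandparented terms (default 0.3), logical
  definitions on a configurable fraction (default 0.3), and creation
  dates uniform over 2020-01-01..2023-08-01 so the default 2022-11-01
  cutoff yields a meaningful split.
- Issue dumps: one new-term-request per chosen term, naming the label
  verbatim and paraphrasing definition and parents. Requested terms are
  chosen with mutually non-nested labels — a tracker does not hold open
  requests for both "fiber cell" and "secondary fiber cell" — which also
  keeps label-based retrieval unambiguous under the bag-of-tokens
  embedder.
- Rating sheets: human-definition ratings drawn around a flat mean
  (default 4.2, sd 0.6); model-definition means drop by `gap_slope`
  (default 0.35) per confidence level above 1, so at the lowest
  confidence the two sources are indistinguishable and the gap grows
  linearly with confidence.

Everything is driven by `random.Random(seed)` over deterministic
iteration orders: the same spec and seed reproduce byte-identical
fixtures.

What passing tests on these fixtures shows: the plumbing, the scoring
mathematics, retrieval ordering, determinism, and the structural theorems
(baseline precision 1, no hallucinated edges, echo ceiling). What it does
not show: completion quality with a real language model, retrieval
quality with contextual embeddings, or any statement about real
ontologies' content.

## Problem sizes

Defaults were chosen so a full test run and the acceptance script each
finish in seconds on one core: fixtures of 40–200 terms, 200 random DAGs
of ≤ 30 terms for oracle-equivalence checks, 1000 randomized replies for
the no-hallucination property, 100 random vector sets for MMR. The
scoring primitives are O(V·E) per query at worst and scale to real
ontology sizes; the exact k-NN scan is the only quadratic-ish component
and is the designated replacement point for an approximate index.

## Known limitations

- The structural entailment engine handles is-a transitivity and the
  genus route only; existential property chains, equivalence axioms and
  nested class expressions are out of scope, as are non
  genus–differentia logical definitions (skipped at load with a warning).
- The prompt instruction wording is a configurable default, not a claim
  of fidelity to any particular deployed system.
- Token budgeting is approximate by design; a backend with a hard limit
  should supply its own tokenizer.
- The statistics module exposes the rating data and ICC/gap estimates but
  deliberately implements no significance test between definition
  sources; choosing one is left to the analyst.
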