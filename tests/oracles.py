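"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions alone — fixpoint closure
enumeration, explicit path search, direct greedy selection, two-pass ANOVA —
and deliberately shares no code with the package internals it checks.
"""

from __future__ import annotations

import math


def brute_ancestors(edges, node, predicates):
    """Nodes reachable from *node* via >=1 edge whose predicate is allowed,
    by naive fixpoint iteration over the raw edge list."""
    reached = set()
    changed = True
    while changed:
        changed = False
        for s, p, o in edges:
            if p not in predicates:
                continue
            if (s == node or s in reached) and o not in reached:
                reached.add(o)
                changed = True
    return reached


def brute_subsumed(graph, term):
    """Reflexive set of terms that *term* subsumes (closure counting)."""
    from ontorag.ontology import SUBCLASS_OF

    out = {term}
    for other in graph.terms:
        if term in brute_ancestors(graph.edges, other, {SUBCLASS_OF}):
            out.add(other)
    return out


def brute_ic(graph, term, base=2):
    p = len(brute_subsumed(graph, term)) / len(graph.terms)
    return -math.log(p, base)


def brute_more_general(graph, subject, predicate, target):
    from ontorag.ontology import SUBCLASS_OF

    return target in brute_ancestors(graph.edges, subject, {SUBCLASS_OF, predicate})


def brute_score_relationships(predicted, gold, graph, subject, base=2):
    """Judge predictions by the stated rule using only brute primitives:
    exact matches first, then more-general predictions paired with the
    highest-IC unused same-predicate gold target on the traversal path."""
    from ontorag.ontology import SUBCLASS_OF

    remaining = list(gold)
    judgements = []
    deferred = []
    for pt in predicted:
        if pt in remaining:
            remaining.remove(pt)
            judgements.append((pt, "exact", 1.0))
        else:
            deferred.append(pt)
    for pt in deferred:
        p, t = pt
        if t in graph.terms and brute_more_general(graph, subject, p, t):
            candidates = [
                gt
                for gt in remaining
                if gt[0] == p
                and (t == gt[1] or t in brute_ancestors(graph.edges, gt[1], {SUBCLASS_OF, p}))
            ]
            if candidates:
                best = max(candidates, key=lambda gt: (brute_ic(graph, gt[1], base), str(gt[1])))
                remaining.remove(best)
                ic_e = brute_ic(graph, best[1], base)
                ic_p = brute_ic(graph, t, base)
                credit = min(1.0, ic_p / ic_e) if ic_e > 0 else 0.0
                judgements.append((pt, "general", credit))
                continue
        judgements.append((pt, "false_positive", 0.0))
    return judgements


def brute_cosine(a, b):
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(x * x for x in b))
    if na == 0 or nb == 0:
        return 0.0
    return sum(x * y for x, y in zip(a, b)) / (na * nb)


def brute_knn_order(vectors, query):
    """Indices of *vectors* by descending cosine to *query*, ties by index."""
    sims = [brute_cosine(v, query) for v in vectors]
    return sorted(range(len(vectors)), key=lambda i: (-sims[i], i))


def brute_mmr_order(vectors, query, lam, k):
    """Greedy MMR selection order by direct evaluation of the formula."""
    sims = [brute_cosine(v, query) for v in vectors]
    remaining = list(range(len(vectors)))
    selected = []
    while remaining and len(selected) < k:
        best, best_score = None, None
        for i in remaining:
            if selected:
                red = max(brute_cosine(vectors[i], vectors[j]) for j in selected)
                score = lam * sims[i] - (1 - lam) * red
            else:
                score = sims[i]
            if best_score is None or score > best_score + 1e-12:
                best, best_score = i, score
        selected.append(best)
        remaining.remove(best)
    return selected


def anova_icc(groups):
    """Two-pass one-way ANOVA ICC over a list of rating lists (one per
    evaluator); returns (icc, msb, mse, k)."""
    n_groups = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    msb = ssb / (n_groups - 1)
    mse = ssw / (n_total - n_groups)
    k = n_total / n_groups
    icc = (msb - mse) / (msb + (k - 1) * mse)
    return icc, msb, mse, k


def brute_entailed(edges, removed, subject, obj, genus=None):
    """Is subject -> obj derivable after removing *removed*, via remaining
    is-a closure or the genus?"""
    from ontorag.ontology import SUBCLASS_OF

    kept = [e for e in edges if e != removed]
    if obj in brute_ancestors(kept, subject, {SUBCLASS_OF}):
        return True
    if genus is not None and (genus == obj or obj in brute_ancestors(kept, genus, {SUBCLASS_OF})):
        return True
    return False
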