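"""Tangle-resolution cost functions, a brute-force oracle, and the
prescriptive baseline.

Three problem variants share one cost idea: find a walk (or pair of walks)
whose per-node visit counts best match the estimated copy numbers, scored by
the squared deviation summed over base nodes,

    plain      C(W)      = sum_v (#W(v) - w(v))^2
    oriented   C(W)      = sum_v (#W(v+) + #W(v-) - w(v))^2
    diploid    C(W1,W2)  = sum_v (sum_i #Wi(v+) + #Wi(v-) - w(v))^2

Weights may be fractional; the squared deviation is well defined either way.
The prescriptive baseline instead deletes nodes whose rounded copy number is
zero and reports the connected runs that remain — the behaviour of
exhaustive-search path finders, used here as the comparison point.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable

from .graphio import AnnotatedGraph, Step, Walk, WalkPair, validate_walk

VARIANTS = ("plain", "oriented", "diploid")


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves up (copy numbers are non-negative)."""
    return int(math.floor(x + 0.5))


def _effective_weight(w: float) -> float:
    # -1 is the "unknown" sentinel; treat as no copy-number evidence.
    return w if w > 0 else 0.0


def _visit_counts(walks: Iterable[Walk]) -> Counter:
    counts: Counter = Counter()
    for walk in walks:
        for nid, _orient in walk:
            counts[nid] += 1
    return counts


def _cost_from_counts(graph: AnnotatedGraph, counts: Counter) -> float:
    return float(sum((counts.get(nid, 0) - _effective_weight(n.weight)) ** 2
                     for nid, n in graph.nodes.items()))


def walk_cost(graph: AnnotatedGraph, walk: Walk, variant: str = "oriented") -> float:
    """Squared-deviation cost of a single walk (plain or oriented variant).

    Visits are counted per base node, summing both orientations, which
    reduces to plain counting when the walk only uses ``+`` steps.
    """
    _check_variant(variant)
    if variant == "diploid":
        raise ValueError("diploid variant scores a pair of walks; use pair_cost")
    violations = validate_walk(graph, walk)
    if violations:
        raise ValueError(f"invalid walk; non-edge transitions at steps {violations}")
    return _cost_from_counts(graph, _visit_counts([walk]))


def pair_cost(graph: AnnotatedGraph, pair: WalkPair) -> float:
    """Squared-deviation cost of a pair of walks (diploid variant)."""
    for which, walk in (("first", pair.first), ("second", pair.second)):
        violations = validate_walk(graph, walk)
        if violations:
            raise ValueError(f"{which} walk invalid at steps {violations}")
    return _cost_from_counts(graph, _visit_counts([pair.first, pair.second]))


# -- exhaustive oracle -----------------------------------------------------

def _all_walks(graph: AnnotatedGraph, sites: list[Step], max_length: int):
    """Yield every valid walk (as a tuple of steps) of length 0..max_length."""
    adj = graph.successors()
    yield ()

    def extend(prefix: tuple[Step, ...]):
        if len(prefix) == max_length:
            return
        for nxt in adj.get(prefix[-1], ()):
            if nxt in site_set:
                walk = prefix + (nxt,)
                yield walk
                yield from extend(walk)

    site_set = set(sites)
    for start in sites:
        walk = (start,)
        yield walk
        yield from extend(walk)


def enumerate_optimum(graph: AnnotatedGraph, variant: str = "oriented",
                      max_length: int = 6):
    """Exhaustively find a minimum-cost walk (or pair) up to a length bound.

    Deterministic tie-break: lowest cost, then shortest, then lexicographic
    on the step list (pairs compare on combined length, then both lists).
    Returns ``(best_cost, Walk)`` or ``(best_cost, WalkPair)``.
    """
    _check_variant(variant)
    nodes = sorted(graph.nodes)
    if variant == "plain":
        sites: list[Step] = [(v, "+") for v in nodes]
    else:
        sites = [(v, o) for v in nodes for o in "+-"]
    bound = max(1, len(sites)) ** max_length
    if variant == "diploid":
        bound = bound ** 2
    if bound > 10 ** 7:
        raise ValueError(f"search space too large: {bound} > 1e7")

    if variant == "diploid":
        walks = list(_all_walks(graph, sites, max_length))
        best = None
        for w1 in walks:
            for w2 in walks:
                if len(w1) + len(w2) > max_length:
                    continue
                cost = _cost_from_counts(
                    graph, _visit_counts([Walk(list(w1)), Walk(list(w2))]))
                key = (cost, len(w1) + len(w2), w1, w2)
                if best is None or key < best:
                    best = key
        assert best is not None
        return best[0], WalkPair(Walk(list(best[2])), Walk(list(best[3])))

    best = None
    for steps in _all_walks(graph, sites, max_length):
        cost = _cost_from_counts(graph, _visit_counts([Walk(list(steps))]))
        key = (cost, len(steps), steps)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[0], Walk(list(best[2]))


# -- prescriptive baseline -------------------------------------------------

def prescriptive_decompose(graph: AnnotatedGraph) -> list[list[Step]]:
    """Zero-copy-node removal baseline.

    Nodes with a rounded copy number of zero are deleted; the remaining
    nodes split into maximal connected runs along graph edges.  Each run is
    returned as an oriented node list (``+`` orientation), runs ordered by
    their smallest node id.  This mirrors the behaviour of prescriptive
    path finders, which cannot bridge estimated-zero nodes.
    """
    kept = {nid for nid, n in graph.nodes.items()
            if round_half_up(_effective_weight(n.weight)) >= 1}
    # undirected adjacency over base nodes
    adj: dict[str, set[str]] = {nid: set() for nid in kept}
    for a, _oa, b, _ob in graph.edges:
        if a in kept and b in kept and a != b:
            adj[a].add(b)
            adj[b].add(a)

    seen: set[str] = set()
    runs: list[list[Step]] = []
    for start in sorted(kept):
        if start in seen:
            continue
        # collect the component
        comp = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u not in comp:
                    comp.add(u)
                    stack.append(u)
        seen |= comp
        runs.append([(v, "+") for v in _order_component(comp, adj)])
    runs.sort(key=lambda run: run[0][0])
    return runs


def _order_component(comp: set[str], adj: dict[str, set[str]]) -> list[str]:
    """Order a component as a path when it is one, else by traversal."""
    degrees = {v: len(adj[v] & comp) for v in comp}
    ends = sorted(v for v in comp if degrees[v] <= 1)
    start = ends[0] if ends else min(comp)
    order = [start]
    visited = {start}
    cur = start
    while True:
        nxt = sorted(u for u in adj[cur] & comp if u not in visited)
        if not nxt:
            break
        order.append(nxt[0])
        visited.add(nxt[0])
        cur = nxt[0]
    # non-path components: append anything the main traversal missed
    for v in sorted(comp - visited):
        order.append(v)
    return order
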