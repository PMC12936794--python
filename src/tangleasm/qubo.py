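"""Time-indexed QUBO encoding of tangle resolution.

A walk of length at most T over a graph with N base nodes is encoded with
one binary variable per (time step, site) pair, where a *site* is either an
oriented node or a virtual "end" node with no sequence.  The full cost of an
assignment x is

    C(x) = C1(x) + C2(x) + C3(x)

    C1 = L1 * sum_t (sum_s x_{t,s} - 1)^2          one site active per time
    C2 = L2 * sum_t [ non-edge transitions + transitions leaving "end" ]
    C3 = sum_v (sum_t x_{t,v} - w(v))^2            visit totals vs weights

with horizon T = ceil(alpha * sum_v round(w(v))) unless overridden.  Staying
at "end" and entering "end" are free, so walks can finish early; leaving
"end" costs L2.  The oriented variant uses a (v,+)/(v,-) site pair per node
whose visits share one C3 term; the diploid variant duplicates all sites for
a second haplotype, with independent C1/C2 but a combined C3.

Variable counts are (N+1)T for plain, (2N+1)T for oriented and 2(2N+1)T for
diploid.  The instance stores a dense symmetric matrix M and a constant
offset such that C(x) = x^T M x + offset holds exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .graphio import AnnotatedGraph, Step, Walk, WalkPair, validate_walk
from .tangle import round_half_up, _effective_weight

#: Virtual end-of-walk site. Node sites are (id, orient) tuples, so the plain
#: string can never collide with one.
END = "end"


@dataclass
class QuboInstance:
    """A built QUBO: minimize x^T M x + offset over binary x."""

    n_vars: int
    matrix: np.ndarray  # symmetric, dense
    constant_offset: float
    sites: list  # per-haplotype site order; last entry is END
    T: int
    n_haplotypes: int
    lambda1: float
    lambda2: float
    alpha: float | None
    variant: str
    graph_ref: str = ""
    base_nodes: list[str] = field(default_factory=list)

    def var_index(self, hap: int, t: int, site) -> int:
        """Variable index for haplotype ``hap`` (0-based), time ``t`` (1-based)."""
        s = self.sites.index(site)
        return (hap * self.T + (t - 1)) * len(self.sites) + s

    def var_site(self, i: int) -> tuple[int, int, object]:
        """Inverse of :meth:`var_index`: returns (hap, t, site)."""
        s = i % len(self.sites)
        rest = i // len(self.sites)
        return rest // self.T, rest % self.T + 1, self.sites[s]


@dataclass
class BinaryAssignment:
    """A 0/1 vector over the instance's variables."""

    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.bits)


def build_qubo(graph: AnnotatedGraph, variant: str = "oriented",
               alpha: float = 1.2, lambda1: float = 10.0, lambda2: float = 5.0,
               T_override: int | None = None, graph_ref: str = "") -> QuboInstance:
    """Build the QUBO instance for a copy-number-annotated graph.

    ``T`` defaults to ``ceil(alpha * sum_v round(w(v)))``; rounded weights
    set the horizon while C3 keeps the fractional values.  Unknown copy
    numbers (the -1 sentinel) contribute no C3 pull (treated as 0).
    """
    if variant not in ("plain", "oriented", "diploid"):
        raise ValueError(f"unknown variant {variant!r}")
    base_nodes = sorted(graph.nodes)
    if not base_nodes:
        raise ValueError("graph has no nodes")
    w = {v: _effective_weight(graph.nodes[v].weight) for v in base_nodes}

    if T_override is not None:
        T = int(T_override)
        if T < 1:
            raise ValueError("T_override must be >= 1")
    else:
        if alpha <= 1:
            raise ValueError("alpha must be > 1 (or give T_override)")
        sum_w = sum(round_half_up(w[v]) for v in base_nodes)
        if sum_w == 0:
            raise ValueError("all rounded copy numbers are zero; "
                             "give T_override to build an empty-walk problem")
        T = max(1, math.ceil(alpha * sum_w))

    if variant == "plain":
        sites: list = [(v, "+") for v in base_nodes]
    else:
        sites = [(v, o) for v in base_nodes for o in "+-"]
    sites.append(END)
    S = len(sites)
    n_hap = 2 if variant == "diploid" else 1
    n = n_hap * T * S

    M = np.zeros((n, n))
    offset = 0.0

    def idx(hap: int, t: int, s: int) -> int:
        return (hap * T + (t - 1)) * S + s

    def add_quad(i: int, j: int, c: float) -> None:
        if i == j:
            M[i, i] += c
        else:
            M[i, j] += c / 2.0
            M[j, i] += c / 2.0

    # transition penalty table over site indices (independent of t/hap)
    penalized: list[tuple[int, int]] = []
    for si, s_from in enumerate(sites):
        for sj, s_to in enumerate(sites):
            if s_from == END and s_to == END:
                continue  # staying at end is free
            if s_from == END:
                penalized.append((si, sj))  # leaving end
                continue
            if s_to == END:
                continue  # entering end is free
            a, oa = s_from
            b, ob = s_to
            if not graph.has_edge(a, oa, b, ob):
                penalized.append((si, sj))

    for hap in range(n_hap):
        # C1: exactly one site per time step
        for t in range(1, T + 1):
            group = [idx(hap, t, s) for s in range(S)]
            for gi in group:
                M[gi, gi] += -lambda1  # x^2 - 2x terms combined
            for a_i in range(S):
                for b_i in range(a_i + 1, S):
                    add_quad(group[a_i], group[b_i], 2.0 * lambda1)
            offset += lambda1
        # C2: edge constraint between consecutive times
        for t in range(1, T):
            for si, sj in penalized:
                add_quad(idx(hap, t, si), idx(hap, t + 1, sj), lambda2)

    # C3: visit totals vs copy numbers, shared across haplotypes
    site_of = {s: i for i, s in enumerate(sites)}
    for v in base_nodes:
        orients = ["+"] if variant == "plain" else ["+", "-"]
        group = [idx(hap, t, site_of[(v, o)])
                 for hap in range(n_hap) for t in range(1, T + 1) for o in orients]
        wv = w[v]
        for gi in group:
            M[gi, gi] += 1.0 - 2.0 * wv
        for a_i in range(len(group)):
            for b_i in range(a_i + 1, len(group)):
                add_quad(group[a_i], group[b_i], 2.0)
        offset += wv * wv

    return QuboInstance(n_vars=n, matrix=M, constant_offset=offset, sites=sites,
                        T=T, n_haplotypes=n_hap, lambda1=lambda1, lambda2=lambda2,
                        alpha=(None if T_override is not None else alpha),
                        variant=variant, graph_ref=graph_ref, base_nodes=base_nodes)


def energy(instance: QuboInstance, assignment: BinaryAssignment | np.ndarray) -> float:
    """Full cost ``x^T M x + offset`` of an assignment."""
    x = assignment.bits if isinstance(assignment, BinaryAssignment) else np.asarray(assignment)
    if len(x) != instance.n_vars:
        raise ValueError(f"assignment length {len(x)} != n_vars {instance.n_vars}")
    xf = x.astype(float)
    return float(xf @ instance.matrix @ xf) + instance.constant_offset


def encode_walk(instance: QuboInstance, walk: Walk | WalkPair) -> BinaryAssignment:
    """Encode a valid walk (or pair, for diploid) as a binary assignment.

    Step t of the walk switches on the variable at (t, site); all later
    times sit at the end node.
    """
    if instance.variant == "diploid":
        if not isinstance(walk, WalkPair):
            raise TypeError("diploid instance expects a WalkPair")
        walks = [walk.first, walk.second]
    else:
        if isinstance(walk, WalkPair):
            raise TypeError(f"{instance.variant} instance expects a single Walk")
        walks = [walk]

    bits = np.zeros(instance.n_vars, dtype=np.int8)
    for hap, w in enumerate(walks):
        steps = list(w)
        if len(steps) > instance.T:
            raise ValueError(f"walk length {len(steps)} exceeds horizon T={instance.T}")
        for t in range(1, instance.T + 1):
            site = steps[t - 1] if t <= len(steps) else END
            if site != END and site not in instance.sites:
                raise KeyError(f"step {site} not a site of this instance")
            bits[instance.var_index(hap, t, site)] = 1
    return BinaryAssignment(bits)


@dataclass
class DecodedSolution:
    """Result of decoding a (possibly constraint-violating) assignment."""

    walks: list[list[Walk]]  # per haplotype, split at end visits / bad edges
    diagnostics: list[str]

    def all_walks(self) -> list[Walk]:
        return [w for hap in self.walks for w in hap]


def decode_assignment(instance: QuboInstance,
                      assignment: BinaryAssignment | np.ndarray,
                      graph: AnnotatedGraph | None = None) -> DecodedSolution:
    """Total decoder: any assignment yields walks plus a violation report.

    Per haplotype and time the active site is the unique on-bit if there is
    exactly one, else the lowest-index on-bit (recorded), else the end node
    (recorded).  The site sequence is then split into maximal valid
    sub-walks at end visits and at non-edge transitions.
    """
    x = assignment.bits if isinstance(assignment, BinaryAssignment) else np.asarray(assignment)
    if len(x) != instance.n_vars:
        raise ValueError("assignment length mismatch")
    S = len(instance.sites)
    diagnostics: list[str] = []
    walks: list[list[Walk]] = []

    def edge_ok(a: Step, b: Step) -> bool:
        if graph is not None:
            return graph.has_edge(a[0], a[1], b[0], b[1])
        # fall back to the instance's own penalty structure
        return (instance.sites.index(a), instance.sites.index(b)) not in _penalty_pairs(instance)

    for hap in range(instance.n_haplotypes):
        site_seq: list = []
        for t in range(1, instance.T + 1):
            base = (hap * instance.T + (t - 1)) * S
            on = np.flatnonzero(x[base:base + S])
            if len(on) == 1:
                site = instance.sites[on[0]]
            elif len(on) == 0:
                site = END
                diagnostics.append(f"hap {hap} t {t}: no active site")
            else:
                site = instance.sites[on[0]]
                diagnostics.append(f"hap {hap} t {t}: {len(on)} active sites")
            site_seq.append(site)

        hap_walks: list[Walk] = []
        cur: list[Step] = []
        for t, site in enumerate(site_seq, start=1):
            if site == END:
                if cur:
                    hap_walks.append(Walk(cur))
                    cur = []
                continue
            if cur and not edge_ok(cur[-1], site):
                diagnostics.append(f"hap {hap} t {t}: non-edge transition "
                                   f"{cur[-1]} -> {site}")
                hap_walks.append(Walk(cur))
                cur = []
            cur.append(site)
        if cur:
            hap_walks.append(Walk(cur))
        walks.append(hap_walks)
    return DecodedSolution(walks=walks, diagnostics=diagnostics)


def _penalty_pairs(instance: QuboInstance) -> set[tuple[int, int]]:
    """Penalized (site_from, site_to) index pairs, recovered from the matrix."""
    cached = getattr(instance, "_penalty_cache", None)
    if cached is not None:
        return cached
    S = len(instance.sites)
    pairs: set[tuple[int, int]] = set()
    if instance.T >= 2:
        for si in range(S):
            for sj in range(S):
                i = si  # t=1
                j = S + sj  # t=2
                # C2 contributes lambda2/2 off-diagonal; C1 never couples
                # different times; C3 couples same-node sites by 1.0
                val = 2.0 * instance.matrix[i, j]
                a, b = instance.sites[si], instance.sites[sj]
                same_node = (a != END and b != END and a[0] == b[0])
                expected_c3 = 2.0 if same_node else 0.0
                if val - expected_c3 > instance.lambda2 / 2:
                    pairs.add((si, sj))
    object.__setattr__(instance, "_penalty_cache", pairs)
    return pairs


def decoded_cost(graph: AnnotatedGraph, decoded: DecodedSolution) -> float:
    """Tangle-resolution cost of a decoded solution's combined visit counts."""
    from collections import Counter
    counts: Counter = Counter()
    for walk in decoded.all_walks():
        for nid, _o in walk:
            counts[nid] += 1
    return float(sum((counts.get(nid, 0) - _effective_weight(n.weight)) ** 2
                     for nid, n in graph.nodes.items()))


# -- sparse text export ----------------------------------------------------

def write_qubo(instance: QuboInstance, path, sidecar: bool = True) -> None:
    """Write ``i j coeff`` sparse text (total coefficient of x_i x_j, i<=j).

    A JSON sidecar ``<path>.json`` records the variable map so solutions can
    be decoded later.
    """
    with open(path, "w") as fh:
        fh.write(f"# tangleasm qubo n_vars={instance.n_vars} "
                 f"offset={instance.constant_offset!r} T={instance.T} "
                 f"lambda1={instance.lambda1!r} lambda2={instance.lambda2!r} "
                 f"variant={instance.variant}\n")
        M = instance.matrix
        for i in range(instance.n_vars):
            if M[i, i] != 0:
                fh.write(f"{i} {i} {float(M[i, i])!r}\n")
            for j in range(i + 1, instance.n_vars):
                if M[i, j] != 0:
                    fh.write(f"{i} {j} {float(2.0 * M[i, j])!r}\n")
    if sidecar:
        meta = {
            "n_vars": instance.n_vars,
            "T": instance.T,
            "n_haplotypes": instance.n_haplotypes,
            "variant": instance.variant,
            "lambda1": instance.lambda1,
            "lambda2": instance.lambda2,
            "offset": instance.constant_offset,
            "graph_ref": instance.graph_ref,
            "sites": [s if s == END else list(s) for s in instance.sites],
            "base_nodes": instance.base_nodes,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def read_qubo(path) -> QuboInstance:
    """Read an instance written by :func:`write_qubo` (with its sidecar)."""
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    n = meta["n_vars"]
    M = np.zeros((n, n))
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            i_s, j_s, c_s = line.split()
            i, j, c = int(i_s), int(j_s), float(c_s)
            if i == j:
                M[i, i] = c
            else:
                M[i, j] = c / 2.0
                M[j, i] = c / 2.0
    sites = [s if s == END else tuple(s) for s in meta["sites"]]
    return QuboInstance(n_vars=n, matrix=M, constant_offset=meta["offset"],
                        sites=sites, T=meta["T"], n_haplotypes=meta["n_haplotypes"],
                        lambda1=meta["lambda1"], lambda2=meta["lambda2"],
                        alpha=None, variant=meta["variant"],
                        graph_ref=meta.get("graph_ref", ""),
                        base_nodes=meta.get("base_nodes", []))
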