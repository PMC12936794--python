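"""Read-to-node kmer annotation and copy-number estimation.

Each graph node is indexed by its canonical kmers (the lexicographic
minimum of a kmer and its reverse complement, so both read strands hash
identically).  Read kmers owned by exactly one node increment that node's
hit count; kmers shared between nodes are dropped, the counting analogue of
discarding secondary alignments.  Hit counts are then depth-normalized:

    d(v) = hits(v) / (kmer positions of v * unique_fraction(v))

i.e. hits per expected unique kmer position, and the per-copy depth D is
the node-length-weighted median of d(v) over reliably unique nodes
(unique_fraction >= 0.5) with nonzero hits.  The copy number estimate is
d(v)/D.  Nodes with no unique kmers cannot be estimated and receive the
sentinel weight -1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from ._dna import canonical
from .graphio import AnnotatedGraph

_ACGT = frozenset("ACGT")


@dataclass
class KmerIndex:
    k: int
    node_kmers: dict[str, Counter] = field(default_factory=dict)
    kmer_owners: dict[str, set[str]] = field(default_factory=dict)
    unique_fraction: dict[str, float] = field(default_factory=dict)

    def refresh_uniqueness(self) -> None:
        """Recompute unique_fraction from node_kmers/kmer_owners."""
        for nid, kmers in self.node_kmers.items():
            total = sum(kmers.values())
            if total == 0:
                self.unique_fraction[nid] = 0.0
                continue
            unique = sum(cnt for km, cnt in kmers.items()
                         if self.kmer_owners[km] == {nid})
            self.unique_fraction[nid] = unique / total


@dataclass
class NodeCounts:
    counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    total_bases: int = 0


def _kmers_of(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if set(km) <= _ACGT:  # kmers containing N are excluded
            yield canonical(km)


def index_graph(graph: AnnotatedGraph, k: int = 31) -> KmerIndex:
    """Index every node's canonical kmer content and its uniqueness."""
    if k < 3:
        raise ValueError("k must be >= 3")
    if all(n.length < k for n in graph.nodes.values()):
        raise ValueError(f"no node is at least k={k} bases long")
    index = KmerIndex(k=k)
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        if node.length < k:
            continue
        kmers = Counter(_kmers_of(node.sequence, k))
        index.node_kmers[nid] = kmers
        for km in kmers:
            index.kmer_owners.setdefault(km, set()).add(nid)
    index.refresh_uniqueness()
    return index


def add_recognition_sequences(index: KmerIndex,
                              extra: dict[str, Iterable[str]]) -> None:
    """Enrich node kmer sets with extra per-node sequences.

    Emulates feeding training-genome alignments back into the index so that
    divergent copies of a node still hit its kmers; uniqueness fractions are
    recomputed afterwards.
    """
    for nid, seqs in extra.items():
        if nid not in index.node_kmers:
            index.node_kmers[nid] = Counter()
        for seq in seqs:
            for km in _kmers_of(seq, index.k):
                index.node_kmers[nid][km] += 1
                index.kmer_owners.setdefault(km, set()).add(nid)
    index.refresh_uniqueness()


def count_hits(index: KmerIndex, reads: Iterable) -> NodeCounts:
    """Count read kmers attributable to exactly one node.

    ``reads`` may be strings or Biopython SeqRecords.  Ambiguous kmers
    (owned by several nodes) and unknown kmers count nowhere.
    """
    counts: Counter = Counter()
    n_reads = 0
    n_bases = 0
    owners = index.kmer_owners
    k = index.k
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        n_reads += 1
        n_bases += len(seq)
        for km in _kmers_of(seq, k):
            owner = owners.get(km)
            if owner is not None and len(owner) == 1:
                counts[next(iter(owner))] += 1
    return NodeCounts(counts=dict(counts), total_reads=n_reads, total_bases=n_bases)


def estimate_copy_numbers(graph: AnnotatedGraph, counts: NodeCounts,
                          index: KmerIndex) -> AnnotatedGraph:
    """Fill node weights with depth-normalized copy-number estimates.

    Returns a copy of the graph with ``weight`` set to d(v)/D (see module
    docstring) and ``raw_count`` set to the observed hits.  Nodes without
    unique kmers get the unknown sentinel -1.
    """
    depth: dict[str, float] = {}
    for nid in graph.nodes:
        uf = index.unique_fraction.get(nid, 0.0)
        node = graph.nodes[nid]
        positions = node.length - index.k + 1
        if uf <= 0.0 or positions <= 0:
            continue
        hits = counts.counts.get(nid, 0)
        depth[nid] = hits / (positions * uf)

    # Per-copy depth from reliably unique nodes that actually received
    # coverage; zero-hit nodes are evidence of absence, not of depth.
    med_nodes = [nid for nid, d in depth.items()
                 if index.unique_fraction[nid] >= 0.5 and d > 0]
    if not med_nodes:
        raise ValueError("no node with unique_fraction >= 0.5 has coverage; "
                         "try a larger k or check the reads")
    pairs = sorted((depth[nid], graph.nodes[nid].length) for nid in med_nodes)
    total = sum(weight for _d, weight in pairs)
    acc = 0.0
    per_copy = pairs[-1][0]
    for d, weight in pairs:
        acc += weight
        if acc >= total / 2.0:
            per_copy = d
            break

    out = graph.copy()
    for nid, node in out.nodes.items():
        node.raw_count = counts.counts.get(nid, 0)
        if nid in depth:
            node.weight = depth[nid] / per_copy
        elif index.unique_fraction.get(nid, 0.0) == 0.0:
            node.weight = -1.0  # unknown: nothing unique to estimate from
        else:
            node.weight = 0.0
    return out
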