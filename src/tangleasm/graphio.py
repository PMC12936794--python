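"""Oriented, vertex-weighted pangenome graphs and GFA 1.0 I/O.

The central object is :class:`AnnotatedGraph`: a sequence graph whose nodes
carry a DNA fragment plus an estimated copy number (how many times the target
genome is believed to traverse the node, both strands combined), and whose
edges are oriented links closed under reverse-complement pairing — the link
``A+ -> B+`` implies ``B- -> A-`` and vice versa.

Copy numbers are stored on GFA S-lines as a float ``CN:f`` tag; raw kmer hit
counts use the conventional ``KC:i`` tag.  A copy number of ``-1`` is an
in-memory sentinel for "unknown" (no unique kmers to estimate from) and is
written as an *omitted* CN tag on disk.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: An oriented walk step: (node id, orientation "+" or "-").
Step = tuple[str, str]

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]+$")


class GFAError(ValueError):
    """Raised on malformed GFA input."""


def flip(orient: str) -> str:
    """Flip an orientation symbol: ``+`` <-> ``-``."""
    if orient == "+":
        return "-"
    if orient == "-":
        return "+"
    raise ValueError(f"invalid orientation {orient!r}")


def reverse_edge(edge: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    """The reverse-complement pair of an oriented link."""
    a, oa, b, ob = edge
    return (b, flip(ob), a, flip(oa))


@dataclass
class Node:
    """A graph node: a DNA fragment with copy-number annotation."""

    sequence: str
    weight: float = 0.0  # estimated copy number; -1.0 == unknown
    raw_count: int = 0  # observed unique-kmer hits

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Walk:
    """An ordered sequence of oriented node visits; may be empty."""

    steps: list[Step] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterator[Step]:
        return iter(self.steps)

    def __getitem__(self, i):
        return self.steps[i]


@dataclass
class WalkPair:
    """A pair of walks — the solution object of the diploid problem."""

    first: Walk
    second: Walk


@dataclass
class AnnotatedGraph:
    """Oriented, vertex-weighted pangenome graph.

    ``edges`` holds oriented links as ``(from_id, from_orient, to_id,
    to_orient)`` tuples and is kept closed under reverse-complement pairing.
    Unoriented (plain) problems use the same representation, with walks
    restricted to ``+`` orientations.
    """

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: set[tuple[str, str, str, str]] = field(default_factory=set)
    oriented: bool = True

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, sequence: str, weight: float = 0.0,
                 raw_count: int = 0) -> None:
        if node_id in self.nodes:
            raise GFAError(f"duplicate node id {node_id!r}")
        if sequence and not _VALID_SEQ.match(sequence):
            raise GFAError(f"node {node_id!r}: sequence has characters outside ACGTN")
        self.nodes[node_id] = Node(sequence.upper(), weight, raw_count)

    def add_edge(self, from_id: str, from_orient: str, to_id: str,
                 to_orient: str) -> None:
        """Add an oriented link and its implied reverse-complement pair."""
        for nid in (from_id, to_id):
            if nid not in self.nodes:
                raise GFAError(f"edge endpoint {nid!r} is not a node")
        edge = (from_id, from_orient, to_id, to_orient)
        self.edges.add(edge)
        self.edges.add(reverse_edge(edge))

    def has_edge(self, from_id: str, from_orient: str, to_id: str,
                 to_orient: str) -> bool:
        return (from_id, from_orient, to_id, to_orient) in self.edges

    def successors(self) -> dict[Step, list[Step]]:
        """Adjacency map over oriented sites, deterministic order."""
        adj: dict[Step, list[Step]] = {}
        for a, oa, b, ob in sorted(self.edges):
            adj.setdefault((a, oa), []).append((b, ob))
        return adj

    def complete_closure(self) -> int:
        """Add missing reverse-complement pair edges; return how many."""
        missing = {reverse_edge(e) for e in self.edges} - self.edges
        self.edges |= missing
        return len(missing)

    def weights(self) -> dict[str, float]:
        return {nid: n.weight for nid, n in self.nodes.items()}

    def validate(self) -> None:
        """Check the structural invariants; raise GFAError on violation."""
        for a, oa, b, ob in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise GFAError(f"edge ({a},{oa})->({b},{ob}) references unknown node")
            if reverse_edge((a, oa, b, ob)) not in self.edges:
                raise GFAError(f"edge ({a},{oa})->({b},{ob}) missing its reverse pair")
        for nid, n in self.nodes.items():
            if n.weight < 0 and n.weight != -1.0:
                raise GFAError(f"node {nid!r}: negative weight {n.weight}")

    def copy(self) -> "AnnotatedGraph":
        g = AnnotatedGraph(oriented=self.oriented)
        g.nodes = {nid: Node(n.sequence, n.weight, n.raw_count)
                   for nid, n in self.nodes.items()}
        g.edges = set(self.edges)
        return g


# -- GFA 1.0 I/O -----------------------------------------------------------

def _parse_tags(fields: list[str], lineno: int) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise GFAError(f"line {lineno}: malformed tag {f!r}")
        tags[parts[0]] = parts[2]
    return tags


def parse_gfa(path) -> AnnotatedGraph:
    """Read a GFA 1.0 file into an :class:`AnnotatedGraph`.

    Copy numbers are read from ``CN:f`` tags (default 0) and raw kmer counts
    from ``KC:i`` tags (default 0).  Links whose reverse-complement pair is
    absent are completed automatically, with a logged warning.
    """
    graph = AnnotatedGraph(oriented=True)
    pending_links: list[tuple[int, str, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "H":
                continue
            elif kind == "S":
                if len(fields) < 3:
                    raise GFAError(f"line {lineno}: S line needs id and sequence")
                name, seq = fields[1], fields[2]
                if seq == "*":
                    raise GFAError(f"line {lineno}: S line without stored sequence")
                tags = _parse_tags(fields[3:], lineno)
                try:
                    weight = float(tags.get("CN", 0.0))
                    raw = int(tags.get("KC", 0))
                except ValueError as exc:
                    raise GFAError(f"line {lineno}: bad tag value ({exc})") from exc
                try:
                    graph.add_node(name, seq, weight, raw)
                except GFAError as exc:
                    raise GFAError(f"line {lineno}: {exc}") from exc
            elif kind == "L":
                if len(fields) < 6:
                    raise GFAError(f"line {lineno}: L line needs 6 fields")
                a, oa, b, ob, overlap = fields[1:6]
                if oa not in "+-" or ob not in "+-":
                    raise GFAError(f"line {lineno}: bad orientation")
                if overlap not in ("*", "0M"):
                    raise GFAError(
                        f"line {lineno}: only '0M'/'*' overlaps supported, got {overlap!r}")
                pending_links.append((lineno, a, oa, b, ob))
            elif kind in ("P", "W", "C"):
                continue  # path/containment lines are ignored
            else:
                raise GFAError(f"line {lineno}: unknown record type {kind!r}")
    for lineno, a, oa, b, ob in pending_links:
        try:
            graph.add_edge(a, oa, b, ob)
        except GFAError as exc:
            raise GFAError(f"line {lineno}: {exc}") from exc
    # add_edge already closes each pair; detect whether the file itself was open
    explicit = {(a, oa, b, ob) for _, a, oa, b, ob in pending_links}
    completed = {e for e in graph.edges if e not in explicit}
    if completed:
        logger.warning("GFA %s: completed %d implied reverse-complement link(s)",
                       path, len(completed))
    graph.validate()
    return graph


def write_gfa(graph: AnnotatedGraph, path) -> None:
    """Write GFA 1.0; ``parse_gfa(write_gfa(G))`` round-trips exactly.

    Both directions of every link pair are written so that re-parsing needs
    no closure completion.  Unknown copy numbers (-1) omit the CN tag.
    """
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes):
            n = graph.nodes[nid]
            tags = [f"LN:i:{n.length}"]
            if n.raw_count:
                tags.append(f"KC:i:{n.raw_count}")
            if n.weight >= 0:
                tags.append(f"CN:f:{n.weight!r}")
            fh.write("\t".join(["S", nid, n.sequence] + tags) + "\n")
        for a, oa, b, ob in sorted(graph.edges):
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")


# -- walk validation -------------------------------------------------------

def validate_walk(graph: AnnotatedGraph, walk: Walk | Iterable[Step]) -> list[int]:
    """Positions (0-based step indices) where a walk breaks edge validity.

    Position ``i`` is reported when the transition from step ``i-1`` into
    step ``i`` does not traverse a graph edge.  Empty and single-step walks
    are always valid.
    """
    steps = list(walk)
    for nid, orient in steps:
        if nid not in graph.nodes:
            raise KeyError(f"walk references unknown node {nid!r}")
        if orient not in "+-":
            raise ValueError(f"bad orientation {orient!r}")
    bad = []
    for i in range(1, len(steps)):
        a, oa = steps[i - 1]
        b, ob = steps[i]
        if not graph.has_edge(a, oa, b, ob):
            bad.append(i)
    return bad
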