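"""Synthetic genome populations, shotgun reads, and ground-truth graph
instances.

Three generators make the whole pipeline testable without any external
data:

* :func:`generate_population` evolves a founder genome through generations
  of structural mutation (short tandem repeats, CNV duplications, repeat
  element insertions, translocations, inversions) plus point substitutions,
  descendants mutating at a reduced rate — the kind of population a
  pangenome would be built from.
* :func:`shred_reads` emulates single-ended shotgun sequencing: uniform
  start positions and strands, i.i.d. base-substitution errors, no indels.
* :func:`make_instance` builds small annotated graphs with a known
  ground-truth walk, node weights equal to true visit counts (optionally
  Gaussian-perturbed, truncated at zero, rounded to one decimal).

All randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import BASES, random_dna, revcomp
from .graphio import AnnotatedGraph, Step, Walk, WalkPair

_SEG_RANGE = (100, 1000)  # CNV / translocation / inversion segment sizes
_SHORT_REPEAT_RANGE = (100, 300)
_LONG_REPEAT_RANGE = (500, 1500)


@dataclass
class EvolutionConfig:
    """Rates are events (or substitutions) per base of the founder genome."""

    initial_length: int = 10_000
    population_size: int = 100
    generations: int = 10
    str_rate: float = 2e-4
    cnv_rate: float = 1e-4
    short_repeat_rate: float = 2e-4
    long_repeat_rate: float = 5e-5
    translocation_rate: float = 5e-5
    inversion_rate: float = 1e-4
    point_rate: float = 5e-3
    descendant_rate_factor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        rates = (self.str_rate, self.cnv_rate, self.short_repeat_rate,
                 self.long_repeat_rate, self.translocation_rate,
                 self.inversion_rate, self.point_rate)
        if any(r < 0 for r in rates):
            raise ValueError("mutation rates must be >= 0")
        if not (0 < self.descendant_rate_factor <= 1):
            raise ValueError("descendant_rate_factor must be in (0, 1]")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")


@dataclass
class ReadConfig:
    coverage: float = 30.0
    read_length: int = 150
    sub_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0 <= self.sub_error_rate < 1):
            raise ValueError("sub_error_rate must be in [0, 1)")


@dataclass
class SyntheticInstance:
    graph: AnnotatedGraph
    truth_walk: Walk | WalkPair
    truth_sequence: str | tuple[str, str]
    noise_model: str
    shape: str = ""
    seed: int = 0


# -- mutation machinery ----------------------------------------------------

def _required_length(cfg: EvolutionConfig) -> int:
    need = 6  # STR unit
    if cfg.short_repeat_rate > 0:
        need = max(need, _SHORT_REPEAT_RANGE[1])
    if cfg.long_repeat_rate > 0:
        need = max(need, _LONG_REPEAT_RANGE[1])
    if cfg.cnv_rate > 0 or cfg.translocation_rate > 0 or cfg.inversion_rate > 0:
        need = max(need, _SEG_RANGE[1])
    return need


def _make_repeat_library(rng: np.random.Generator) -> dict[str, list[str]]:
    return {
        "short": [random_dna(int(rng.integers(*_SHORT_REPEAT_RANGE)), rng)
                  for _ in range(5)],
        "long": [random_dna(int(rng.integers(*_LONG_REPEAT_RANGE)), rng)
                 for _ in range(3)],
    }


def _insert(seq: str, pos: int, piece: str) -> str:
    return seq[:pos] + piece + seq[pos:]


def _segment(rng: np.random.Generator, length: int) -> tuple[int, int]:
    seg = int(rng.integers(_SEG_RANGE[0], min(_SEG_RANGE[1], max(101, length // 2)) + 1))
    start = int(rng.integers(0, length - seg + 1))
    return start, seg


def _mutate(seq: str, cfg: EvolutionConfig, factor: float,
            library: dict[str, list[str]], rng: np.random.Generator) -> str:
    L0 = len(seq)

    def n_events(rate: float) -> int:
        return int(rng.poisson(rate * factor * L0))

    # repeat-element insertions
    for kind in ("short", "long"):
        rate = cfg.short_repeat_rate if kind == "short" else cfg.long_repeat_rate
        for _ in range(n_events(rate)):
            elem = library[kind][int(rng.integers(len(library[kind])))]
            seq = _insert(seq, int(rng.integers(len(seq) + 1)), elem)
    # short tandem repeats: random 2-6 bp unit repeated 3-8 times
    for _ in range(n_events(cfg.str_rate)):
        unit = random_dna(int(rng.integers(2, 7)), rng)
        seq = _insert(seq, int(rng.integers(len(seq) + 1)),
                      unit * int(rng.integers(3, 9)))
    # CNV: duplicate a segment in place
    for _ in range(n_events(cfg.cnv_rate)):
        start, seg = _segment(rng, len(seq))
        seq = _insert(seq, start + seg, seq[start:start + seg])
    # translocation: cut and paste a segment
    for _ in range(n_events(cfg.translocation_rate)):
        start, seg = _segment(rng, len(seq))
        piece = seq[start:start + seg]
        rest = seq[:start] + seq[start + seg:]
        seq = _insert(rest, int(rng.integers(len(rest) + 1)), piece)
    # inversion: reverse-complement a segment in place (length-preserving)
    for _ in range(n_events(cfg.inversion_rate)):
        start, seg = _segment(rng, len(seq))
        seq = seq[:start] + revcomp(seq[start:start + seg]) + seq[start + seg:]
    # point substitutions
    n_subs = int(rng.binomial(len(seq), min(1.0, cfg.point_rate * factor)))
    if n_subs:
        positions = rng.choice(len(seq), size=n_subs, replace=False)
        chars = list(seq)
        for pos in positions:
            alts = [b for b in BASES if b != chars[pos]]
            chars[pos] = alts[int(rng.integers(3))]
        seq = "".join(chars)
    return seq


def generate_population(config: EvolutionConfig) -> list[tuple[str, int | None]]:
    """Evolve a population of related genomes.

    Genome 0 is the founder (a random base string mutated at the founder
    rates); each later genome derives from a randomly chosen earlier one,
    mutated at ``descendant_rate_factor`` times the founder rates.  New
    genomes are added in ``generations`` batches.  Returns a list of
    ``(sequence, parent_index)`` with ``parent_index`` None for the founder.
    """
    need = _required_length(config)
    if config.initial_length < need:
        raise ValueError(f"initial_length {config.initial_length} is shorter "
                         f"than the largest mutation unit ({need})")
    rng = np.random.default_rng(config.seed)
    library = _make_repeat_library(rng)
    founder = _mutate(random_dna(config.initial_length, rng), config, 1.0,
                      library, rng)
    genomes: list[tuple[str, int | None]] = [(founder, None)]
    remaining = config.population_size - 1
    for gen in range(config.generations):
        batches_left = config.generations - gen
        batch = -(-remaining // batches_left)  # ceil split across generations
        for _ in range(batch):
            parent = int(rng.integers(len(genomes)))
            child = _mutate(genomes[parent][0], config,
                            config.descendant_rate_factor, library, rng)
            genomes.append((child, parent))
        remaining -= batch
        if remaining <= 0:
            break
    return genomes[:config.population_size]


def shred_reads(genome: str, config: ReadConfig) -> list[SeqRecord]:
    """Simulate single-ended shotgun reads at the configured coverage.

    ``round(coverage * L / read_length)`` reads, uniform start positions and
    strands, i.i.d. substitution errors to a uniformly random other base.
    """
    L = len(genome)
    rl = config.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome length {L}")
    rng = np.random.default_rng(config.seed)
    n_reads = int(round(config.coverage * L / rl))
    reads: list[SeqRecord] = []
    for i in range(n_reads):
        start = int(rng.integers(0, L - rl + 1))
        frag = genome[start:start + rl]
        strand = "+"
        if rng.random() < 0.5:
            frag = revcomp(frag)
            strand = "-"
        n_err = int(rng.binomial(rl, config.sub_error_rate))
        if n_err:
            chars = list(frag)
            for pos in rng.choice(rl, size=n_err, replace=False):
                alts = [b for b in BASES if b != chars[pos]]
                chars[pos] = alts[int(rng.integers(3))]
            frag = "".join(chars)
        rec = SeqRecord(Seq(frag), id=f"read{i}",
                        description=f"pos={start} strand={strand}")
        rec.letter_annotations["phred_quality"] = [30] * rl
        reads.append(rec)
    return reads


# -- graph instances with known truth --------------------------------------

SHAPES = ("line", "cycle", "tangle", "random")


def make_line_graph(weights, node_length: int = 100, seed: int = 0,
                    ids: list[str] | None = None) -> AnnotatedGraph:
    """A line graph with given copy-number weights and random sequences."""
    rng = np.random.default_rng(seed)
    n = len(weights)
    if ids is None:
        ids = [chr(ord("A") + i) for i in range(n)] if n <= 26 else \
            [f"n{i:03d}" for i in range(n)]
    g = AnnotatedGraph(oriented=True)
    for nid, w in zip(ids, weights):
        g.add_node(nid, random_dna(node_length, rng), weight=float(w))
    for a, b in zip(ids, ids[1:]):
        g.add_edge(a, "+", b, "+")
    return g


def worked_example_graph(node_length: int = 100, seed: int = 0) -> AnnotatedGraph:
    """The five-node line A-E with estimated copy numbers (1, 1, 0, 1, 1).

    The zero on the middle node models a target genome whose C region is
    too divergent to attract kmer hits: a prescriptive decomposition splits
    here, while the squared-deviation cost still admits one unified walk.
    """
    return make_line_graph([1, 1, 0, 1, 1], node_length=node_length, seed=seed)


def _build_topology(shape: str, n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    edges = [(i, i + 1) for i in range(n - 1)]
    if shape == "cycle" and n > 1:
        edges.append((n - 1, 0))
    elif shape == "tangle" and n > 2:
        # back edges create repeat-style loops that walks may traverse twice
        for _ in range(max(1, n // 3)):
            j = int(rng.integers(1, n))
            i = int(rng.integers(0, j))
            edges.append((j, i))
    elif shape == "random" and n > 1:
        p = min(1.0, 1.5 / n)
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < p:
                    edges.append((i, j))
    return sorted(set(edges))


def _sample_walk(graph: AnnotatedGraph, sites: list[Step], walk_length: int,
                 rng: np.random.Generator, start: Step | None = None) -> Walk:
    """Random walk preferring less-visited nodes, like a genome passing
    mostly linearly through the graph with occasional repeat traversals."""
    adj = graph.successors()
    site_set = set(sites)
    best: list[Step] = []
    for _attempt in range(20):
        cur = start if start is not None else sites[int(rng.integers(len(sites)))]
        steps = [cur]
        visits = {cur[0]: 1}
        while len(steps) < walk_length:
            nxt = [s for s in adj.get(steps[-1], []) if s in site_set]
            if not nxt:
                break
            weights = np.array([1.0 / (1 + 3 * visits.get(s[0], 0)) for s in nxt])
            choice = nxt[int(rng.choice(len(nxt), p=weights / weights.sum()))]
            steps.append(choice)
            visits[choice[0]] = visits.get(choice[0], 0) + 1
        if len(steps) >= len(best):
            best = steps
        if len(best) == walk_length:
            break
    return Walk(best[:walk_length])


def make_instance(shape: str = "line", n_nodes: int = 5, node_length: int = 100,
                  walk_length: int = 5, weight_noise_sd: float = 0.0,
                  orientation: str = "oriented", seed: int = 0) -> SyntheticInstance:
    """Build a graph instance with a known ground-truth walk.

    Node weights equal the truth walk's per-node visit counts (both
    orientations combined) plus optional truncated-at-zero Gaussian noise,
    rounded to one decimal.  For the diploid orientation the truth is a
    pair of walks and weights sum both walks' visits.
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}")
    if orientation not in ("plain", "oriented", "diploid"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if walk_length < 0:
        raise ValueError("walk_length must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    graph = AnnotatedGraph(oriented=True)
    for nid in ids:
        graph.add_node(nid, random_dna(node_length, rng))
    for i, j in _build_topology(shape, n_nodes, rng):
        graph.add_edge(ids[i], "+", ids[j], "+")
    if walk_length > 0 and not graph.edges:
        raise ValueError("walk_length > 0 requires a graph with edges")

    if orientation == "plain":
        sites = [(nid, "+") for nid in ids]
    else:
        sites = [(nid, o) for nid in ids for o in "+-"]

    start = (ids[0], "+") if shape in ("line", "cycle") else None
    if walk_length == 0:
        truth: Walk | WalkPair = Walk([])
    elif orientation == "diploid":
        l1 = walk_length // 2
        truth = WalkPair(_sample_walk(graph, sites, walk_length - l1, rng, start),
                         _sample_walk(graph, sites, l1, rng, start))
    else:
        truth = _sample_walk(graph, sites, walk_length, rng, start)

    walks = ([truth.first, truth.second] if isinstance(truth, WalkPair)
             else [truth])
    visits: dict[str, int] = {nid: 0 for nid in ids}
    for walk in walks:
        for nid, _o in walk:
            visits[nid] += 1
    for nid in ids:
        w = float(visits[nid])
        if weight_noise_sd > 0:
            w = max(0.0, w + rng.normal(0.0, weight_noise_sd))
        graph.nodes[nid].weight = round(w, 1)

    def to_seq(walk: Walk) -> str:
        return "".join(graph.nodes[nid].sequence if o == "+"
                       else revcomp(graph.nodes[nid].sequence)
                       for nid, o in walk)

    truth_seq = ((to_seq(truth.first), to_seq(truth.second))
                 if isinstance(truth, WalkPair) else to_seq(truth))
    noise = (f"gaussian(sd={weight_noise_sd}) truncated at 0, 1 decimal"
             if weight_noise_sd > 0 else "noiseless")
    return SyntheticInstance(graph=graph, truth_walk=truth,
                             truth_sequence=truth_seq, noise_model=noise,
                             shape=shape, seed=seed)
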