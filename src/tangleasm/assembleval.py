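"""Candidate-assembly construction, alignment-based evaluation, and
consensus polishing.

Decoded walks become candidate sequences by concatenating node fragments
(reverse-complementing minus-orientation steps).  Candidates are compared
with the known truth by a deterministic unique-anchor chaining aligner:
21-mers that occur exactly once in both sequences anchor co-linear chains
(strand-consistent, monotone on both axes, bounded gaps), each maximal
chain becomes an alignment block, and base-level counts inside a block come
from a global alignment of the two segments.  The report mirrors the usual
assembly-quality suite: %covered, %used, contig count, N50, breaks (extra
blocks per contig, i.e. false joins), large indels (gap events of >= 10
bases), multi-nucleotide difference regions (>= 30 mismatches within a
fixed 100-base truth window), and overall percent identity.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._dna import revcomp
from .graphio import AnnotatedGraph, Walk, validate_walk

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentBlock:
    """One co-linear match between a candidate contig and the truth."""

    contig_id: int
    contig_start: int  # 0-based half-open, contig coordinates
    contig_end: int
    truth_start: int  # 0-based half-open, truth coordinates
    truth_end: int
    strand: str  # "+" or "-"
    n_matches: int = 0
    n_mismatches: int = 0
    n_ins: int = 0  # inserted bases (present in contig, absent in truth)
    n_del: int = 0  # deleted bases
    indel_event_lengths: list[int] = field(default_factory=list)
    mismatch_truth_positions: list[int] = field(default_factory=list)


@dataclass
class EvaluationReport:
    covered_pct: float
    used_pct: float
    n_contigs: int
    n50: int
    breaks: int
    indels_ge10: int
    diff_regions: int
    identity_pct: float

    #: Table column order used by the one-line TSV output.
    COLUMNS = ("%Covered", "%Used", "Contigs", "Breaks", "Indel", "No.Diff",
               "N50", "%Identity")

    def to_row(self) -> list:
        return [round(self.covered_pct, 1), round(self.used_pct, 1),
                self.n_contigs, self.breaks, self.indels_ge10,
                self.diff_regions, self.n50, round(self.identity_pct, 1)]

    def to_tsv(self) -> str:
        return "\t".join(str(v) for v in self.to_row())

    def to_dict(self) -> dict:
        return {
            "covered_pct": self.covered_pct, "used_pct": self.used_pct,
            "n_contigs": self.n_contigs, "n50": self.n50, "breaks": self.breaks,
            "indels_ge10": self.indels_ge10, "diff_regions": self.diff_regions,
            "identity_pct": self.identity_pct,
        }


def walk_to_sequence(graph: AnnotatedGraph, walk: Walk) -> str:
    """Concatenate node sequences along a walk, reverse-complementing
    minus-orientation steps.  The empty walk gives the empty string."""
    violations = validate_walk(graph, walk)
    if violations:
        raise ValueError(f"invalid walk at steps {violations}")
    return "".join(graph.nodes[nid].sequence if o == "+"
                   else revcomp(graph.nodes[nid].sequence) for nid, o in walk)


# -- anchoring and chaining ------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """Forward kmers occurring exactly once, and whose reverse complement
    does not also occur (so a hit fixes both position and strand)."""
    counts: Counter = Counter(seq[i:i + k] for i in range(len(seq) - k + 1))
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if counts[km] == 1 and counts.get(revcomp(km), 0) == 0:
            pos[km] = i
    return pos


def _anchors(contig: str, truth_pos: dict[str, int],
             k: int) -> list[tuple[int, int, str]]:
    """(contig_pos, truth_pos, strand) anchors, unique on both sides."""
    ccounts: Counter = Counter(contig[i:i + k] for i in range(len(contig) - k + 1))
    out = []
    for i in range(len(contig) - k + 1):
        km = contig[i:i + k]
        if ccounts[km] != 1 or ccounts.get(revcomp(km), 0) != 0:
            continue
        if km in truth_pos:
            out.append((i, truth_pos[km], "+"))
        else:
            rc = revcomp(km)
            if rc in truth_pos:
                out.append((i, truth_pos[rc], "-"))
    return out


def _chain_anchors(anchors: list[tuple[int, int, str]], k: int,
                   max_gap: int) -> list[list[tuple[int, int, str]]]:
    chains: list[list[tuple[int, int, str]]] = []
    cur: list[tuple[int, int, str]] = []
    for a in anchors:  # already sorted by contig position
        if cur:
            pc, pt, ps = cur[-1]
            c, t, s = a
            ok = (s == ps and 0 < c - pc <= max_gap)
            if ok and s == "+":
                ok = 0 < t - pt <= max_gap
            elif ok:
                ok = 0 < pt - t <= max_gap
            if ok:
                cur.append(a)
                continue
            chains.append(cur)
        cur = [a]
    if cur:
        chains.append(cur)
    return chains


def _count_block(contig_seg: str, truth_seg: str, truth_start: int,
                 strand: str, block: AlignmentBlock) -> None:
    """Fill base-level counts from a global alignment of the two segments."""
    if strand == "-":
        truth_seg = revcomp(truth_seg)
    res = edlib.align(contig_seg, truth_seg, mode="NW", task="path")
    cpos = tpos = 0
    tlen = len(truth_seg)
    for m in _CIGAR_RE.finditer(res["cigar"] or ""):
        n, op = int(m.group(1)), m.group(2)
        if op == "=":
            block.n_matches += n
            cpos += n
            tpos += n
        elif op in ("X", "M"):
            for j in range(n):
                local = tpos + j
                real = (truth_start + local if strand == "+"
                        else truth_start + tlen - 1 - local)
                block.mismatch_truth_positions.append(real)
            block.n_mismatches += n
            cpos += n
            tpos += n
        elif op == "I":  # bases in contig missing from truth
            block.n_ins += n
            block.indel_event_lengths.append(n)
            cpos += n
        elif op == "D":
            block.n_del += n
            block.indel_event_lengths.append(n)
            tpos += n


def align_blocks(candidate_contigs: list[str], truth: str,
                 anchor_k: int = 21, max_gap: int = 500) -> list[AlignmentBlock]:
    """Segment each contig into co-linear alignment blocks against truth.

    Deterministic: no anchors means no blocks.  Blocks are sorted by
    (contig id, contig start).
    """
    if not truth:
        raise ValueError("truth sequence must be non-empty")
    truth_pos = _unique_kmers(truth, anchor_k)
    blocks: list[AlignmentBlock] = []
    for cid, contig in enumerate(candidate_contigs):
        if len(contig) < anchor_k:
            continue
        anchors = _anchors(contig, truth_pos, anchor_k)
        for chain in _chain_anchors(anchors, anchor_k, max_gap):
            c0, t0, strand = chain[0]
            c1, t1, _ = chain[-1]
            if strand == "+":
                ts, te = t0, t1 + anchor_k
            else:
                ts, te = t1, t0 + anchor_k
            block = AlignmentBlock(contig_id=cid, contig_start=c0,
                                   contig_end=c1 + anchor_k,
                                   truth_start=ts, truth_end=te, strand=strand)
            _count_block(contig[c0:c1 + anchor_k], truth[ts:te], ts, strand,
                         block)
            blocks.append(block)
    blocks.sort(key=lambda b: (b.contig_id, b.contig_start))
    return blocks


# -- metrics ---------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        s = max(s, end)
        if e > s:
            total += e - s
            end = e
        end = max(end, e)
    return total


def n50(lengths: list[int]) -> int:
    """Largest length L such that contigs >= L cover half the total."""
    if not lengths:
        return 0
    half = sum(lengths) / 2.0
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= half:
            return ln
    return 0  # pragma: no cover


def evaluate(blocks: list[AlignmentBlock], candidate_contigs: list[str],
             truth: str) -> EvaluationReport:
    """Compute the eight-metric assembly-quality report."""
    truth_cov = _union_length([(b.truth_start, b.truth_end) for b in blocks])
    covered = 100.0 * truth_cov / len(truth) if truth else 0.0

    total_contig = sum(len(c) for c in candidate_contigs)
    per_contig: dict[int, list[tuple[int, int]]] = {}
    for b in blocks:
        per_contig.setdefault(b.contig_id, []).append((b.contig_start, b.contig_end))
    used_bases = sum(_union_length(iv) for iv in per_contig.values())
    used = 100.0 * used_bases / total_contig if total_contig else 0.0

    breaks = sum(max(0, len(iv) - 1) for iv in per_contig.values())
    indels = sum(1 for b in blocks for ln in b.indel_event_lengths if ln >= 10)

    window_hits: Counter = Counter()
    for b in blocks:
        for p in b.mismatch_truth_positions:
            window_hits[p // 100] += 1
    diff_regions = sum(1 for _w, c in window_hits.items() if c >= 30)

    matches = sum(b.n_matches for b in blocks)
    columns = sum(b.n_matches + b.n_mismatches + b.n_ins + b.n_del
                  for b in blocks)
    identity = 100.0 * matches / columns if columns else 0.0

    return EvaluationReport(
        covered_pct=min(100.0, covered), used_pct=min(100.0, used),
        n_contigs=len(candidate_contigs),
        n50=n50([len(c) for c in candidate_contigs]),
        breaks=breaks, indels_ge10=indels, diff_regions=diff_regions,
        identity_pct=min(100.0, identity))


def evaluate_assembly(candidate_contigs: list[str], truth: str,
                      anchor_k: int = 21) -> EvaluationReport:
    """Convenience: align then evaluate in one call."""
    blocks = align_blocks(candidate_contigs, truth, anchor_k=anchor_k)
    return evaluate(blocks, candidate_contigs, truth)


# -- consensus polishing ---------------------------------------------------

def consensus_polish(candidate: str, reads, anchor_k: int = 21,
                     min_depth: int = 3) -> str:
    """Majority-vote substitution polishing via unique-anchor read placement.

    Each read is placed by the first of its kmers that is unique in the
    candidate (either strand); placed reads vote per column, and columns
    with at least ``min_depth`` votes take the majority base (ties keep the
    original).  No indel edits are made; with no reads the candidate is
    returned unchanged.
    """
    L = len(candidate)
    if L < anchor_k:
        return candidate
    cand_pos = _unique_kmers(candidate, anchor_k)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    votes = np.zeros((4, L), dtype=np.int32)
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        placed = None
        for i in range(len(seq) - anchor_k + 1):
            km = seq[i:i + anchor_k]
            if km in cand_pos:
                placed = (cand_pos[km] - i, seq)
                break
            rc = revcomp(km)
            if rc in cand_pos:
                rseq = revcomp(seq)
                ri = len(seq) - anchor_k - i
                placed = (cand_pos[rc] - ri, rseq)
                break
        if placed is None:
            continue
        offset, oriented = placed
        for j, base in enumerate(oriented):
            pos = offset + j
            if 0 <= pos < L and base in base_idx:
                votes[base_idx[base], pos] += 1
    out = list(candidate)
    depth = votes.sum(axis=0)
    for pos in np.flatnonzero(depth >= min_depth):
        col = votes[:, pos]
        best = int(col.argmax())
        if np.sum(col == col[best]) == 1 and "ACGT"[best] != out[pos]:
            out[pos] = "ACGT"[best]
    return "".join(out)
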