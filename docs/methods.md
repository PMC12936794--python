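# Methods

## The optimization model

A pangenome graph annotated with copy numbers is a triple `G = (V, E, w)`:
nodes carry DNA fragments, oriented edges carry observed adjacencies, and
`w(v) ≥ 0` estimates how many times the target genome traverses node `v`
(both strands combined). Tangle resolution asks for a walk `W` minimizing
the squared deviation `Σ_v (#W(v) − w(v))²`. The squared form is the point:
a wrong estimate at one node costs a bounded amount rather than forbidding
the traversal, which is what makes the approach robust to the noisy copy
numbers that short-read mapping to a multi-genome graph produces. The
oriented variant counts visits to `v+` and `v−` against a single weight;
the diploid variant scores the combined visits of a pair of walks. Edge
weights are deliberately not part of the objective.

Orientation is handled by reverse-complement closure: the stored link
`(A,+) → (B,+)` always coexists with `(B,−) → (A,−)`, a node's `−` sequence
is the reverse complement of its stored sequence, and plain (unoriented)
problems are just oriented graphs whose walks stay on `+`. Coordinates are
0-based half-open throughout.

## QUBO encoding

Walks are encoded time-indexed: binary `x_{t,s}` for `t = 1..T` and site
`s` (an oriented node, or the virtual **end** node with no sequence).
Three terms:

* **C1** (`Λ₁ = 10`): `(Σ_s x_{t,s} − 1)²` per time step — exactly one
  site active at a time.
* **C2** (`Λ₂ = 5`): `Λ₂` per non-edge transition between consecutive
  steps, and per transition that *leaves* the end node. Entering or staying
  at end is free, so walks may finish early; a decoded end visit terminates
  a contig.
* **C3**: `(Σ_t x_{t,v} − w(v))²` per base node, summing both orientations
  (and both haplotypes in the diploid variant, which otherwise has
  independent C1/C2 per haplotype).

The horizon is `T = ⌈α · Σ_v round(w(v))⌉` with `α = 1.2` — slack for the
walk to visit some nodes more often than the data suggest. Rounding
half-up integerizes the horizon only; C3 keeps fractional weights. Unknown
copy numbers (see below) contribute nothing to C3 or the horizon. All
constant terms accumulate into an explicit offset so the full cost of any
assignment is reproduced exactly; an encoded valid walk's energy equals its
tangle cost to machine precision because every penalty term vanishes.

The penalty magnitudes are a balance: large enough that the global minimum
satisfies the constraints on accurately-annotated instances, small enough
that the C3 signal is not drowned. At `Λ₁=10, Λ₂=5` the brute-force QUBO
minimum decodes to an enumeration-optimal walk on every instance family we
test; the package makes both dials available rather than fixing them.

Decoding is total: any bit vector yields walks plus a diagnostics list.
Per time step the active site is the unique on-bit, else the lowest-index
on-bit (recorded), else end (recorded); the site sequence splits into
maximal valid sub-walks at end visits and non-edge transitions. Heuristic
solvers therefore always produce an interpretable answer.

## Solvers

* **Exhaustive** (`n ≤ 24` variables): energies of all `2^n` assignments
  via a doubling recursion (`O(n·2^n)` additions), ties broken toward the
  lowest assignment read as a little-endian integer.
* **Simulated annealing**: single-bit-flip Metropolis, geometric inverse
  temperature 0.1 → 10, 2000 sweeps, multiple restarts.
* **Multistart tabu search**: steepest single-flip descent, tabu tenure
  `max(10, n/10)` with best-ever aspiration, restart after 500
  non-improving moves, 10 starts. This is a generic multistart tabu in the
  Palubeckis style, not a replication of any specific library's internals.

Both heuristics maintain local fields (`ΔE_i = (1−2x_i)·g_i`, `g` updated
in `O(n)` per flip) and are deterministic per seed (tabu only when no
wall-clock limit is set); reported energies are recomputed from the
returned assignment.

## QAOA simulation

The QUBO becomes a diagonal Hamiltonian by the substitution
`x_i → (I − Z_i)/2`, so basis-state energies equal assignment costs
exactly. The circuit is Hadamards followed by `p` alternating layers: an
elementwise cost phase `exp(−iγH)` and a product mixer `exp(−iβΣX_i)`
applied axis-by-axis — a dense statevector capped at 20 qubits. Sampling
noise is the only noise model: each optimizer iteration draws a finite
number of shots (default 256) from the exact distribution.

The classical loop minimizes the **CVaR** of the sampled energies — the
mean of the best `⌈α_CVaR·shots⌉` samples, `α_CVaR = 0.1` by default —
which discards high-energy outliers and rewards distributions with a good
low-energy tail. The optimizer is Nelder–Mead with the iteration budget
(default 100) split over 4 restarts from small random angles in
`(0, 0.1π)`; sampled objectives are noisy and multimodal, and restarts
recover from bad initializations more reliably than one long descent. A
linear-ramp initialization is available as an option. Final samples are
drawn at the best parameters seen, and the lowest-energy sample is the
reported solution.

## Copy-number annotation

Nodes are indexed by canonical kmers (lexicographic min of kmer and
reverse complement; default `k = 31`; kmers containing N excluded). Read
kmers owned by exactly one node increment that node's count; shared kmers
are dropped entirely — the counting analogue of discarding secondary
alignments, chosen over fractional assignment to keep counting
deterministic. Each node's *unique fraction* (share of its kmer positions
owned by it alone) converts raw hits into a depth:

    d(v) = hits(v) / ((len(v) − k + 1) · unique_fraction(v))

The per-copy depth `D` is the node-length-weighted median of `d(v)` over
nodes with unique fraction ≥ 0.5 **and nonzero hits** — the median is
robust to repeat-inflated nodes, and zero-hit nodes are evidence that the
genome skips them, not evidence about sequencing depth. The estimate is
`w(v) = d(v)/D`. Nodes with no unique kmers are flagged unknown (−1
sentinel in memory, omitted CN tag on disk). An optional
recognition-sequence hook enriches a node's kmer set with externally
aligned training sequences.

Two identifiability limits are inherent: if *every* covered node shares
one copy number the median normalizes it to 1, and near genome ends read
depth ramps down, bending estimates on terminal nodes by up to ~10% at
150 bp reads on few-hundred-bp nodes.

## Synthetic data

The generator emulates the study conditions rather than any particular
organism. A founder genome (default 10 kb) accumulates short tandem
repeats (2–6 bp units × 3–8), CNV duplications (100–1000 bp, in place),
short/long repeat-element insertions from a per-run random library
(100–300 / 500–1500 bp), cut-and-paste translocations, in-place
reverse-complement inversions, and point substitutions; descendants mutate
at 0.1× the founder rates, each derived from a random earlier member, in
batches across generations (defaults: 100 genomes, 10 generations). Read
simulation is single-ended, 30× coverage, 150 bp, uniform starts and
strands, i.i.d. substitution errors (default 0.5%), no indel errors.
Founder-rate magnitudes are this package's own choices, set to produce
structured, tangle-prone sequence at the few-kilobase scale.

Graph instances with known truth come from `make_instance`: line, cycle,
tangle (line plus back edges) or random topologies with random node
sequences; the truth walk prefers less-visited successors, like a genome
passing mostly linearly through a graph with occasional repeat
traversals, and node weights are the walk's exact visit counts plus
optional truncated Gaussian noise rounded to one decimal. What the
generator does **not** model: real pangenome construction (node splitting,
variant collapsing by tools like minigraph), paired-end reads, indel
sequencing errors, quality-score structure, and realistic diploid phasing.
Passing tests show the optimization machinery is sound at desk scale, not
that the pipeline matches production annotators on real data.

## Evaluation

Candidate sequences are walks' node fragments concatenated with
reverse-complementing. Comparison to truth uses a deterministic in-house
aligner suited to ≤ ~50 kb synthetic genomes: 21-mers unique in both
sequences (and strand-unambiguous) anchor chains that are greedy,
strand-consistent, monotone on both axes with gaps ≤ 500 bp; each maximal
chain is an alignment block, and block-internal base counts come from a
global edlib alignment of the two segments. Metrics: %covered (union of
truth intervals), %used (union of contig intervals over contig length),
contig count, N50 (largest-first cumulative-half), breaks (blocks minus
one per contig, summed — the operationalization of false joins), large
indels (gap *events* ≥ 10 bp), difference regions (fixed disjoint 100 bp
truth windows with ≥ 30 mismatching aligned bases), and %identity
(matches over aligned columns). Note that a minimal-edit alignment may
represent part of a dense substitution cluster as offsetting indels, so
window mismatch counts are counted after alignment, not against the
planted truth.

Consensus polishing places reads by their first candidate-unique kmer
(either strand) and substitutes per-column majority bases where at least 3
reads vote, ties keeping the original; no indel edits.

## Problem sizes used in tests and the acceptance script

Exhaustive QUBO checks use ≤ 22 variables; walk enumeration stays under
10⁷ candidate walks; the QAOA proof of principle uses the 10-qubit
oriented two-node problem at T=2 with p=4, 256 shots and ≤ 100 iterations;
copy-number recovery uses 8-node, 400 bp-node instances at 30× with
error-free reads; the end-to-end comparison uses 5–8-node noiseless
instances. These sizes keep every check exact or statistically
well-powered while the whole suite runs in well under a minute.

## Known limitations

* Edge-weight objective terms are out of scope by design.
* Polyploidy beyond the diploid pair-of-walks variant is not modelled.
* The QAOA simulator is dense and capped at 20 qubits; no hardware noise
  model or error mitigation.
* The annotator's uniqueness-based expectation is a stated stand-in for
  supplementary-grade hit-rate modelling in production tools.
* The anchor-chain aligner assumes unique 21-mers anchor reliably, true
  for random synthetic sequence but not for low-complexity real genomes.
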