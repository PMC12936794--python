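# tangleasm

Pangenome-guided sequence assembly as binary optimization.

Short-read assembly through repetitive regions is hard: *de novo* assemblers
fragment, and a single linear reference biases the result. A pangenome graph
— nodes are DNA fragments, edges are adjacencies observed across a
population — offers a middle way: align the reads of a *new* sample onto the
graph, estimate how many times the sample's genome traverses each node (its
**copy number**), and then search for a walk through the graph that best
explains those copy numbers. `tangleasm` implements that search as a
Quadratic Unconstrained Binary Optimization (QUBO), solvable with classical
heuristics today and mapped onto gate-model quantum optimization
(a simulated CVaR-QAOA) as a proof of principle.

## The model

Given a vertex-weighted graph `G = (V, E, w)` where `w(v)` is the estimated
copy number of node `v`, **tangle resolution** seeks a walk `W` minimizing

    C(W) = Σ_v (#W(v) − w(v))²

where `#W(v)` counts visits of `W` to `v`. The **oriented** variant works on
a strand-aware graph (every link `A+→B+` pairs with `B−→A−`) and counts
`#W(v+) + #W(v−)` against a single `w(v)`; the **diploid** variant scores a
*pair* of walks against shared weights.

The QUBO encoding is time-indexed: one binary variable `x_{t,v}` per time
step `t ≤ T` and site `v` (oriented node or a virtual *end* node that
absorbs finished walks), with `T = ⌈α·Σ_v w(v)⌉`, `α = 1.2` by default.
The cost is

    C = Λ₁ Σ_t (Σ_v x_{t,v} − 1)²                 (one site per step)
      + Λ₂ Σ_t [non-edge transitions + leaving end]
      + Σ_v (Σ_t x_{t,v} − w(v))²                  (visits match weights)

with `Λ₁ = 10`, `Λ₂ = 5`. Variable counts are `(N+1)T` (plain), `(2N+1)T`
(oriented), `2(2N+1)T` (diploid). Because the deviation is *squared*, a
noisy copy-number estimate of 0 on a true path node costs only 1 — the
optimizer can bridge it — whereas prescriptive exhaustive-search tools
split the assembly there.

The package is self-contained: a synthetic-genome module evolves
populations (STRs, CNVs, repeat insertions, translocations, inversions,
point mutations), shreds genomes into error-bearing 30× single-end reads,
and builds graph instances with known ground-truth walks; a kmer annotator
(canonical kmers, ambiguity-dropping unique counting, depth-normalized
estimates) fills in copy numbers; exhaustive/annealing/tabu solvers and a
≤20-qubit statevector QAOA with CVaR objective minimize the QUBO; an
anchor-chaining evaluator scores decoded assemblies against the truth
(%covered, %used, contigs, breaks, large indels, difference regions, N50,
%identity) with optional consensus polishing.

## Worked example

The five-node line graph `A→B→C→D→E` with estimated copy numbers
`(1, 1, 0, 1, 1)` — a target genome whose `C` region is too divergent to
attract kmer hits:

```python
from tangleasm import (worked_example_graph, prescriptive_decompose,
                       build_qubo, solve_tabu, decode_assignment, walk_cost)

g = worked_example_graph()
print(prescriptive_decompose(g))
# [[('A', '+'), ('B', '+')], [('D', '+'), ('E', '+')]]

inst = build_qubo(g, "plain")          # T=5, 30 binary variables
res = solve_tabu(inst, seed=0)
dec = decode_assignment(inst, res.best_assignment, g)
print(res.best_energy)                  # 1.0
print([w.steps for w in dec.all_walks()])
# [[('A', '+'), ('B', '+'), ('C', '+'), ('D', '+'), ('E', '+')]]
print(walk_cost(g, dec.all_walks()[0], "plain"))   # 1.0
```

Zero-copy-node removal yields **two** contigs (`A–B`, `D–E`); the QUBO
route pays the single unit of squared deviation at `C` and recovers **one**
unified walk `A→…→E`, energy 1.0 — exactly the walk-enumeration optimum.

The same objects are scriptable from the shell:

```bash
tangleasm synth instance --shape tangle --nodes 6 --walk-length 7 --seed 1 -o inst.gfa
tangleasm qubo build inst.gfa --variant oriented -o inst.qubo
tangleasm solve inst.qubo --method tabu --seed 1
tangleasm qaoa inst.qubo -p 4 --shots 256 --seed 1   # ≤ 20 variables
```

## Layout

| Module | Role |
| --- | --- |
| `tangleasm.graphio` | GFA 1.0 I/O, oriented weighted graphs, walk validity |
| `tangleasm.synthgen` | genome populations, shotgun reads, truth instances |
| `tangleasm.annotate` | kmer indexing, unique-hit counting, copy numbers |
| `tangleasm.tangle` | the three cost functions, enumeration oracle, baseline |
| `tangleasm.qubo` | QUBO build/energy/encode/decode |
| `tangleasm.solvers` | exhaustive, simulated annealing, multistart tabu |
| `tangleasm.qaoa` | statevector QAOA with shot sampling and CVaR |
| `tangleasm.assembleval` | walk→sequence, anchor-chain alignment, metrics, polish |

See `docs/methods.md` for modelling assumptions, parameter choices and
known limitations.
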