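"""Classical QUBO solvers: exhaustive enumeration, simulated annealing, and
multistart tabu search.

All heuristics maintain the local-field vector g with g_i = M_ii +
2 * sum_{j != i} M_ij x_j, so that flipping bit i changes the energy by
(1 - 2 x_i) g_i and a flip updates g in O(n).  Every solver is
seed-deterministic (tabu only when no wall-clock limit is set).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .qubo import BinaryAssignment, QuboInstance, energy

EXHAUSTIVE_MAX_VARS = 24


@dataclass
class SolveResult:
    best_assignment: BinaryAssignment
    best_energy: float
    n_evaluations: int
    trace: list[tuple[int, float]] = field(default_factory=list)
    seed: int | None = None
    wall_limit_honored: bool = True


def all_bitstring_energies(matrix: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Energies of every bitstring, indexed by the little-endian integer b
    (bit i of b is variable i).  Doubling recursion, O(n * 2^n) additions.
    """
    n = len(matrix)
    E = np.array([offset])
    for i in range(n):
        f = np.array([matrix[i, i]])
        for j in range(i):
            f = np.concatenate([f, f + (matrix[i, j] + matrix[j, i])])
        E = np.concatenate([E, E + f])
    return E


def bits_from_int(b: int, n: int) -> np.ndarray:
    return np.array([(b >> i) & 1 for i in range(n)], dtype=np.int8)


def solve_exhaustive(instance: QuboInstance) -> SolveResult:
    """Global minimum over all 2^n assignments (n <= 24 enforced).

    Ties break toward the lowest assignment read as a little-endian integer.
    """
    n = instance.n_vars
    if n > EXHAUSTIVE_MAX_VARS:
        raise ValueError(f"n_vars {n} > {EXHAUSTIVE_MAX_VARS}: exhaustive "
                         "search refused")
    E = all_bitstring_energies(instance.matrix, instance.constant_offset)
    b = int(np.argmin(E))  # argmin returns the first == lowest integer
    best = BinaryAssignment(bits_from_int(b, n))
    return SolveResult(best_assignment=best, best_energy=float(E[b]),
                       n_evaluations=2 ** n, trace=[(0, float(E[b]))])


def _local_fields(matrix: np.ndarray, x: np.ndarray) -> np.ndarray:
    off = matrix - np.diag(np.diag(matrix))
    return np.diag(matrix) + 2.0 * off @ x


def solve_anneal(instance: QuboInstance, n_sweeps: int = 2000,
                 beta_schedule: tuple[float, float] = (0.1, 10.0),
                 n_restarts: int = 10, seed: int = 0) -> SolveResult:
    """Single-bit-flip Metropolis annealing with a geometric beta schedule."""
    beta0, beta1 = beta_schedule
    if not (beta0 < beta1):
        raise ValueError("beta schedule must have start < end")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    n = instance.n_vars
    M = instance.matrix
    Moff = M - np.diag(np.diag(M))
    diag = np.diag(M).copy()
    rng = np.random.default_rng(seed)
    betas = beta0 * (beta1 / beta0) ** (np.arange(n_sweeps) / max(1, n_sweeps - 1))

    best_x = None
    best_e = np.inf
    n_eval = 0
    trace: list[tuple[int, float]] = []
    for _restart in range(n_restarts):
        x = rng.integers(0, 2, size=n).astype(np.int8)
        xf = x.astype(float)
        g = diag + 2.0 * Moff @ xf
        e = float(xf @ M @ xf) + instance.constant_offset
        if e < best_e:
            best_e, best_x = e, x.copy()
        for beta in betas:
            flips = rng.integers(0, n, size=n)
            accept_u = rng.random(n)
            for k in range(n):
                i = flips[k]
                de = (1.0 - 2.0 * x[i]) * g[i]
                if de < 0 or accept_u[k] < np.exp(-beta * de):
                    delta = 1.0 - 2.0 * x[i]
                    x[i] = 1 - x[i]
                    g += 2.0 * delta * Moff[:, i]
                    e += de
                    if e < best_e - 1e-12:
                        best_e, best_x = e, x.copy()
                        trace.append((n_eval + k, best_e))
                n_eval += 1
    assert best_x is not None
    best = BinaryAssignment(best_x)
    return SolveResult(best_assignment=best, best_energy=energy(instance, best),
                       n_evaluations=n_eval, trace=trace, seed=seed)


def solve_tabu(instance: QuboInstance, tenure: int | None = None,
               max_stagnation: int = 500, n_starts: int = 10,
               time_limit: float | None = None, seed: int = 0) -> SolveResult:
    """Multistart tabu search: steepest single-flip descent with a tabu list.

    Recently flipped variables are tabu for ``tenure`` moves unless the move
    would improve on the best energy seen anywhere (aspiration).  A start
    ends after ``max_stagnation`` consecutive non-improving moves; up to
    ``n_starts`` random restarts are made, or until ``time_limit`` seconds.
    """
    n = instance.n_vars
    if tenure is None:
        tenure = max(10, n // 10)
    if tenure < 1:
        raise ValueError("tenure must be >= 1")
    M = instance.matrix
    Moff = M - np.diag(np.diag(M))
    diag = np.diag(M).copy()
    rng = np.random.default_rng(seed)
    t0 = time.monotonic()

    best_x: np.ndarray | None = None
    best_e = np.inf
    n_eval = 0
    trace: list[tuple[int, float]] = []
    honored = True
    for _start in range(n_starts):
        if time_limit is not None and time.monotonic() - t0 > time_limit:
            honored = best_x is not None
            break
        x = rng.integers(0, 2, size=n).astype(np.int8)
        xf = x.astype(float)
        g = diag + 2.0 * Moff @ xf
        e = float(xf @ M @ xf) + instance.constant_offset
        if e < best_e:
            best_e, best_x = e, x.copy()
            trace.append((n_eval, best_e))
        tabu_until = np.zeros(n, dtype=np.int64)
        move = 0
        stagnation = 0
        while stagnation < max_stagnation:
            if time_limit is not None and move % 256 == 0 \
                    and time.monotonic() - t0 > time_limit:
                break
            de = (1.0 - 2.0 * x) * g
            n_eval += n
            allowed = (tabu_until <= move) | (e + de < best_e - 1e-12)
            if not allowed.any():
                allowed = np.ones(n, dtype=bool)
            cand = np.where(allowed, de, np.inf)
            i = int(np.argmin(cand))
            delta = 1.0 - 2.0 * x[i]
            x[i] = 1 - x[i]
            g += 2.0 * delta * Moff[:, i]
            e += de[i]
            tabu_until[i] = move + tenure + 1
            move += 1
            if e < best_e - 1e-12:
                best_e, best_x = e, x.copy()
                trace.append((n_eval, best_e))
                stagnation = 0
            else:
                stagnation += 1
    assert best_x is not None
    best = BinaryAssignment(best_x)
    return SolveResult(best_assignment=best, best_energy=energy(instance, best),
                       n_evaluations=n_eval, trace=trace, seed=seed,
                       wall_limit_honored=honored)
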