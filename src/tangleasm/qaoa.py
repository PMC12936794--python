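"""Statevector simulation of QAOA on QUBO-derived diagonal Hamiltonians.

The QUBO cost becomes a diagonal Hamiltonian by substituting each binary
variable x_i with (I - Z_i)/2, so the energy of a computational basis state
|b> equals the cost of the assignment b exactly.  The circuit is a layer of
Hadamards (the uniform superposition) followed by p alternating layers:

    cost layer   U_C(gamma) = exp(-i gamma H)     -- elementwise phase
    mixer layer  U_M(beta)  = exp(-i beta sum_i X_i)  -- RX(2 beta) per qubit

Shot-sampled energies feed a derivative-free classical optimizer through a
CVaR objective: the mean of the best (lowest-energy) alpha-fraction of the
samples, which discards high-energy outliers and sharpens convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .qubo import QuboInstance
from .solvers import all_bitstring_energies

MAX_QUBITS = 20


@dataclass
class DiagonalHamiltonian:
    n_qubits: int
    energies: np.ndarray  # length 2^n; entry b = cost of bitstring b
    offset_included: bool = True


@dataclass
class QaoaRun:
    p: int
    shots: int
    cvar_alpha: float
    max_iters: int
    seed: int
    trace: list[tuple[int, np.ndarray, float]] = field(default_factory=list)
    best_params: np.ndarray | None = None
    final_samples: list[tuple[str, float]] = field(default_factory=list)
    best_sample: tuple[str, float] | None = None


def hamiltonian_from_qubo(instance: QuboInstance) -> DiagonalHamiltonian:
    """Diagonal Hamiltonian whose basis-state energies equal QUBO costs."""
    n = instance.n_vars
    if n > MAX_QUBITS:
        raise ValueError(f"{n} qubits exceeds the dense statevector cap "
                         f"({MAX_QUBITS})")
    E = all_bitstring_energies(instance.matrix, instance.constant_offset)
    return DiagonalHamiltonian(n_qubits=n, energies=E)


def qaoa_statevector(h: DiagonalHamiltonian, gammas, betas) -> np.ndarray:
    """Probability vector of the p-layer QAOA state.

    Index b of the result uses the same little-endian convention as the
    Hamiltonian: bit i of b is qubit/variable i.
    """
    gammas = np.atleast_1d(np.asarray(gammas, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if len(gammas) != len(betas) or len(gammas) < 1:
        raise ValueError("gamma and beta vectors must have equal length p >= 1")
    n = h.n_qubits
    psi = np.full(2 ** n, 2.0 ** (-n / 2.0), dtype=complex)
    for gamma, beta in zip(gammas, betas):
        psi = psi * np.exp(-1j * gamma * h.energies)
        c, s = math.cos(beta), math.sin(beta)
        psi = psi.reshape((2,) * n)
        for axis in range(n):
            psi = c * psi - 1j * s * np.flip(psi, axis=axis)
        psi = psi.reshape(-1)
    return np.abs(psi) ** 2


def cvar(energies, alpha: float) -> float:
    """Mean of the ceil(alpha*n) smallest energies (0 < alpha <= 1)."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy list")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    m = math.ceil(alpha * e.size)
    return float(np.mean(np.partition(e, m - 1)[:m]))


def run_qaoa(h: DiagonalHamiltonian, p: int = 4, shots: int = 256,
             cvar_alpha: float = 0.1, max_iters: int = 100,
             seed: int = 0, init: str = "random", n_restarts: int = 4) -> QaoaRun:
    """Optimize QAOA parameters against a shot-sampled CVaR objective.

    A Nelder-Mead simplex minimizes the CVaR of ``shots`` samples drawn
    from the exact statevector distribution at each parameter setting; the
    ``max_iters`` evaluation budget is split over ``n_restarts`` fresh
    starts, keeping the best parameters seen anywhere (sampled objectives
    are noisy and multimodal, so restarts beat one long descent).  ``init``
    is "random" (small angles in (0, 0.1*pi) per start) or "ramp" (linear
    gamma up / beta down, perturbed on later starts).  Fully reproducible
    for a fixed seed.
    """
    if p < 1 or shots < 1 or max_iters < 1:
        raise ValueError("p, shots and max_iters must be >= 1")
    n_restarts = max(1, min(n_restarts, max_iters))
    rng = np.random.default_rng(seed)

    run = QaoaRun(p=p, shots=shots, cvar_alpha=cvar_alpha,
                  max_iters=max_iters, seed=seed)
    best_val = np.inf

    def objective(params: np.ndarray) -> float:
        nonlocal best_val
        if len(run.trace) >= max_iters:
            return run.trace[-1][2]
        probs = qaoa_statevector(h, params[:p], params[p:])
        probs = probs / probs.sum()
        idx = rng.choice(probs.size, size=shots, p=probs)
        val = cvar(h.energies[idx], cvar_alpha)
        run.trace.append((len(run.trace), params.copy(), val))
        if val < best_val:
            best_val = val
            run.best_params = params.copy()
        return val

    per_start = max_iters // n_restarts
    for start in range(n_restarts):
        if len(run.trace) >= max_iters:
            break
        if init == "ramp":
            ramp = (np.arange(1, p + 1) - 0.5) / p
            x0 = np.concatenate([0.1 * np.pi * ramp, 0.1 * np.pi * (1 - ramp)])
            if start > 0:
                x0 = x0 + rng.normal(0.0, 0.02 * np.pi, size=2 * p)
        else:
            x0 = rng.uniform(0.0, 0.1 * np.pi, size=2 * p)
        budget = min(per_start, max_iters - len(run.trace))
        minimize(objective, x0, method="Nelder-Mead",
                 options={"maxfev": budget, "maxiter": budget,
                          "xatol": 1e-3, "fatol": 1e-3})
    if run.best_params is None:  # pragma: no cover - budget >= 1 always samples
        run.best_params = x0
    probs = qaoa_statevector(h, run.best_params[:p], run.best_params[p:])
    probs = probs / probs.sum()
    idx = rng.choice(probs.size, size=shots, p=probs)
    run.final_samples = [(_bitstring(b, h.n_qubits), float(h.energies[b]))
                         for b in idx]
    run.best_sample = min(run.final_samples, key=lambda se: (se[1], se[0]))
    return run


def _bitstring(b: int, n: int) -> str:
    """Little-endian bitstring: character i is variable/qubit i."""
    return "".join(str((b >> i) & 1) for i in range(n))


def sample_to_bits(bitstring: str) -> np.ndarray:
    return np.array([int(c) for c in bitstring], dtype=np.int8)
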