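"""Hawk-style population metaheuristic for box-constrained minimization.

A population of ``f`` candidate positions ("hawks") is updated once per
iteration.  For each hawk a branch draw against 0.5 selects one of two
position-update rules built from the hawk's own position ``A`` and the
position ``A_rand`` of a uniformly chosen population member:

    exploration:   A' = A_rand - v1 * |A_rand - 2 * v2 * A|
    exploitation:  A' = A_rand - v1 * A_rand + 2 * v1 * v2 * A
                      = (1 - v1) * A_rand + 2 * v1 * v2 * A

``v2`` is drawn uniformly in [0, 1] per update and per dimension (a random
vector, as is usual in this algorithm family, so proposals are not confined
to a line through the origin); ``v1`` decays linearly from
1 to 0 over the iteration budget, shrinking the step size so the search
shifts from exploration to exploitation.  Proposals are clamped to the
feasible box.

Neither rule references the incumbent best, so selection supplies the only
pressure toward good solutions: a hawk adopts its proposal only when the
proposal's cost does not exceed its current cost (greedy per-hawk
acceptance), and the best position ever evaluated is retained separately
(elitism), making the best-fitness trace monotone nonincreasing.

An optional variant adds the coefficient-vector step ``A_rand + B * C``
(``B`` uniform in [0, 2] per iteration, ``C = |best - A|``); it is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["mse_loss", "update_position", "optimize", "OptimizeResult"]


def mse_loss(expected: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean squared error ``(1/g) * sum (F - F*)^2`` between two sequences."""
    e = np.asarray(expected, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if e.shape != p.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {p.shape}")
    if e.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean((e - p) ** 2))


def update_position(
    current: np.ndarray,
    rand_pos: np.ndarray,
    v1: float,
    v2: float | np.ndarray,
    mode: str,
    bounds: np.ndarray | None = None,
    best: np.ndarray | None = None,
    B: np.ndarray | None = None,
) -> np.ndarray:
    """One position update in *mode* ``"exploration"`` or ``"exploitation"``.

    With *best* and *B* supplied, the coefficient-vector term ``B * C`` with
    ``C = |best - current|`` is added to the proposal before clamping.
    """
    a = np.asarray(current, dtype=np.float64)
    ar = np.asarray(rand_pos, dtype=np.float64)
    if a.shape != ar.shape:
        raise ValueError("dimension mismatch between current and rand positions")
    if mode == "exploration":
        new = ar - v1 * np.abs(ar - 2.0 * v2 * a)
    elif mode == "exploitation":
        new = ar - v1 * ar + 2.0 * v1 * v2 * a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if best is not None and B is not None:
        best = np.asarray(best, dtype=np.float64)
        if best.shape != a.shape:
            raise ValueError("dimension mismatch with best position")
        new = new + np.asarray(B, dtype=np.float64) * np.abs(best - a)
    if bounds is not None:
        new = np.clip(new, bounds[:, 0], bounds[:, 1])
    return new


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best fitness after each iteration
    n_evaluations: int

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(1, len(self.trace) + 1), "best_fitness": self.trace}
        )


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    f: int = 20,
    iterations: int = 200,
    seed: int = 0,
    init: np.ndarray | None = None,
    use_coefficient_step: bool = False,
) -> OptimizeResult:
    """Minimize *objective* over the box *bounds* with *f* hawks.

    The population is initialized uniformly in the box from *seed*; *init*
    optionally replaces the first member (useful to continue from an
    incumbent solution).  Deterministic given the seed.  The total number
    of objective evaluations is at most ``f + f * iterations``.
    """
    bounds = np.asarray(bounds, dtype=np.float64)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a (D, 2) array of (low, high)")
    if (bounds[:, 1] < bounds[:, 0]).any():
        raise ValueError("each bound must satisfy low <= high")
    if f < 2:
        raise ValueError("population size must be at least 2")
    if iterations < 1:
        raise ValueError("need at least one iteration")
    dim = bounds.shape[0]
    rng = np.random.default_rng(seed)

    def evaluate(pos: np.ndarray) -> float:
        val = float(objective(pos))
        if not np.isfinite(val):
            raise ValueError(f"non-finite objective value at position {pos}")
        return val

    pop = rng.uniform(bounds[:, 0], bounds[:, 1], size=(f, dim))
    if init is not None:
        init = np.asarray(init, dtype=np.float64)
        if init.shape != (dim,):
            raise ValueError("init has wrong dimension")
        pop[0] = np.clip(init, bounds[:, 0], bounds[:, 1])
    fitness = np.array([evaluate(p) for p in pop])
    n_eval = f
    best_idx = int(np.argmin(fitness))
    best_pos = pop[best_idx].copy()
    best_fit = float(fitness[best_idx])

    trace = np.empty(iterations)
    for b in range(iterations):
        v1 = 1.0 - (b + 1) / iterations  # linear decay toward 0 at the last iteration
        B = rng.uniform(0.0, 2.0, size=dim) if use_coefficient_step else None
        for e in range(f):
            r_idx = int(rng.integers(f))
            branch = rng.uniform()
            v2 = rng.uniform(size=dim)
            mode = "exploitation" if branch >= 0.5 else "exploration"
            proposal = update_position(
                pop[e],
                pop[r_idx],
                v1,
                v2,
                mode,
                bounds=bounds,
                best=best_pos if use_coefficient_step else None,
                B=B,
            )
            val = evaluate(proposal)
            n_eval += 1
            if val <= fitness[e]:
                pop[e] = proposal
                fitness[e] = val
            if val < best_fit:
                best_fit = val
                best_pos = proposal.copy()
        trace[b] = best_fit
    return OptimizeResult(
        best_position=best_pos,
        best_fitness=best_fit,
        trace=trace,
        n_evaluations=n_eval,
    )
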