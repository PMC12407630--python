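"""Box-constrained global minimization by differential evolution
(DE/rand/1/bin with reflection at the bounds).

The optimizer operates on the sampling scale (log10 for rate constants and
scale factors), is deterministic for a fixed seed, and records the best
objective value of every generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitResult", "fit_de"]


@dataclass
class FitResult:
    best_x: np.ndarray
    best_value: float
    history: np.ndarray  # best-so-far value after each generation
    evaluations: int
    seed: int


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-bounds coordinates back into the box."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def fit_de(
    func,
    bounds: np.ndarray,
    seed: int,
    popsize: int | None = None,
    maxiter: int = 100,
    mutation: float = 0.8,
    crossover: float = 0.9,
    init: np.ndarray | None = None,
    tol: float = 0.0,
) -> FitResult:
    """Minimize ``func(x)`` over the box ``bounds`` (shape (p, 2)).

    ``popsize`` defaults to max(20, 15 * dimension). ``init`` optionally
    seeds part of the initial population (rows clipped into the box), which
    profile sweeps use for warm starts. A positive ``tol`` stops early when
    the population spread of objective values falls below it.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo >= hi):
        raise ValueError("each bound must satisfy low < high")
    dim = len(lo)
    if popsize is None:
        popsize = max(20, 15 * dim)
    if popsize < 4:
        raise ValueError("population size must be at least 4")

    rng = np.random.default_rng(seed)
    pop = lo + rng.random((popsize, dim)) * (hi - lo)
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        k = min(len(init), popsize)
        pop[:k] = np.clip(init[:k], lo, hi)

    values = np.empty(popsize)
    n_eval = 0
    errors = []
    for i in range(popsize):
        try:
            values[i] = func(pop[i])
        except Exception as exc:  # noqa: BLE001 - objective may legitimately raise
            values[i] = np.inf
            errors.append(exc)
        n_eval += 1
    if not np.any(np.isfinite(values)):
        raise RuntimeError(
            "objective failed on every initial population member"
        ) from (errors[0] if errors else None)

    best_idx = int(np.argmin(values))
    best_x = pop[best_idx].copy()
    best_value = float(values[best_idx])
    history = []

    for _gen in range(maxiter):
        for i in range(popsize):
            candidates = [j for j in range(popsize) if j != i]
            r1, r2, r3 = rng.choice(candidates, size=3, replace=False)
            mutant = pop[r1] + mutation * (pop[r2] - pop[r3])
            mutant = _reflect(mutant, lo, hi)
            cross = rng.random(dim) < crossover
            cross[rng.integers(dim)] = True
            trial = np.where(cross, mutant, pop[i])
            try:
                trial_value = func(trial)
            except Exception:  # noqa: BLE001
                trial_value = np.inf
            n_eval += 1
            if trial_value <= values[i]:
                pop[i] = trial
                values[i] = trial_value
                if trial_value < best_value:
                    best_value = float(trial_value)
                    best_x = trial.copy()
        history.append(best_value)
        finite = values[np.isfinite(values)]
        if tol > 0 and finite.size == popsize and np.ptp(finite) < tol:
            break

    return FitResult(
        best_x=best_x,
        best_value=best_value,
        history=np.asarray(history),
        evaluations=n_eval,
        seed=seed,
    )
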