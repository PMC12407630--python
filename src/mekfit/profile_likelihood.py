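"""Profile-likelihood analysis: re-optimize all remaining parameters while
one parameter sweeps a grid, then classify practical identifiability from
threshold crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimize_de import fit_de

__all__ = ["ProfileCurve", "profile_parameter", "classify_identifiability",
           "DEFAULT_THRESHOLD", "default_grid"]

#: Pointwise chi-square cut (95% quantile of chi2 with 1 dof, halved).
DEFAULT_THRESHOLD = 1.92


@dataclass
class ProfileCurve:
    """Objective values along a one-parameter sweep.

    ``grid`` holds the fixed parameter's values on the *sampling* scale
    (log10 for log-scaled parameters); ``values`` the re-optimized objective
    at each grid point (NaN where the re-fit failed); ``mle_value`` the
    unconstrained optimum for reference.
    """

    name: str
    grid: np.ndarray
    values: np.ndarray
    mle_value: float


def default_grid(low: float, high: float, per_decade: int = 11) -> np.ndarray:
    """Log10-spaced grid spanning [low, high] with ~11 points per decade."""
    lo, hi = np.log10(low), np.log10(high)
    n = max(5, int(round((hi - lo) * per_decade)) + 1)
    return np.linspace(lo, hi, n)


def profile_parameter(
    func,
    bounds: np.ndarray,
    index: int,
    grid: np.ndarray,
    seed: int,
    mle_x: np.ndarray | None = None,
    mle_value: float | None = None,
    name: str = "",
    popsize: int | None = None,
    maxiter: int = 40,
) -> ProfileCurve:
    """Profile parameter ``index`` of ``func`` over ``grid`` (sampling scale).

    At each grid point the remaining parameters are re-optimized with
    differential evolution, warm-started from the neighboring optimum;
    the sweep proceeds outward from the grid point nearest the MLE.
    Failed re-fits leave NaN gaps rather than aborting the curve.
    """
    bounds = np.asarray(bounds, dtype=float)
    grid = np.asarray(grid, dtype=float)
    dim = bounds.shape[0]
    free = [j for j in range(dim) if j != index]
    sub_bounds = bounds[free]

    if mle_x is None:
        fit = fit_de(func, bounds, seed=seed, popsize=popsize, maxiter=2 * maxiter)
        mle_x, mle_value = fit.best_x, fit.best_value
    mle_x = np.asarray(mle_x, dtype=float)
    if mle_value is None:
        mle_value = float(func(mle_x))

    def fixed_func(sub_x, fixed_value):
        x = np.empty(dim)
        x[free] = sub_x
        x[index] = fixed_value
        return func(x)

    values = np.full(len(grid), np.nan)
    start = int(np.argmin(np.abs(grid - mle_x[index])))
    order = list(range(start, len(grid))) + list(range(start - 1, -1, -1))
    warm_right = warm_left = mle_x[free]
    for pos, g in enumerate(order):
        warm = warm_right if grid[g] >= grid[start] else warm_left
        try:
            fit = fit_de(
                lambda s, gv=grid[g]: fixed_func(s, gv),
                sub_bounds,
                seed=seed + 1000 + g,
                popsize=popsize,
                maxiter=maxiter,
                init=warm,
            )
        except RuntimeError:
            continue
        values[g] = fit.best_value
        if grid[g] >= grid[start]:
            warm_right = fit.best_x
        if grid[g] <= grid[start]:
            warm_left = fit.best_x

    return ProfileCurve(name=name or str(index), grid=grid, values=values,
                        mle_value=float(mle_value))


def classify_identifiability(curve: ProfileCurve,
                             threshold: float = DEFAULT_THRESHOLD) -> str:
    """Label the curve by where it crosses ``mle_value + threshold``.

    Crossing on both sides of the curve's minimum -> ``identifiable``;
    one-sided crossing -> ``practically-unidentifiable-low``/``-high``
    (naming the side that never crosses); no crossing -> ``unidentifiable``.
    """
    values = np.asarray(curve.values, dtype=float)
    ok = np.isfinite(values)
    if not ok.any():
        raise ValueError("profile curve has no finite values")
    cut = curve.mle_value + threshold
    vmin_idx = int(np.nanargmin(values))
    left = values[:vmin_idx + 1]
    right = values[vmin_idx:]
    crosses_left = bool(np.any(left[np.isfinite(left)] > cut))
    crosses_right = bool(np.any(right[np.isfinite(right)] > cut))
    if crosses_left and crosses_right:
        return "identifiable"
    if crosses_left:
        return "practically-unidentifiable-high"
    if crosses_right:
        return "practically-unidentifiable-low"
    return "unidentifiable"
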