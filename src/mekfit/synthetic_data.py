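"""Synthetic datasets with the exact statistical structure the analysis
assumes, generated from a known ground-truth parameterization.

Quantitative tables emulate WT relative time series: absolute model outputs
multiplied by true scale factors (chosen so that noiseless outputs peak near
1), plus i.i.d. Gaussian noise, clipped into (0, 1], with optional missing
cells. Qualitative statements emulate up/down comparisons at 300/1800/3600 s
across cell-line variants, with Bernoulli noise whose success probability is
the logistic function of the true model difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .objective import CalibrationProblem, ParamSpec, ThetaVector
from .qualdata import Condition, QualStatement
from .quantdata import QuantTable
from .reaction_model import (
    DEFAULT_PARAMS,
    build_variant_network,
    observable_series,
    simulate,
)

__all__ = [
    "SyntheticDesign",
    "true_scale_factors",
    "generate_quant",
    "generate_qual",
    "default_comparison_pairs",
    "wt_comparison_pairs",
    "recovery_problem",
    "bayesian_problem",
]

logger = logging.getLogger(__name__)

#: Lowest representable relative intensity; the measurement scale is (0, 1].
_CLIP_LOW = 1e-6


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for synthetic data generation.

    Defaults: six measurement times in (0, 3600] s for the quantitative WT
    table over pEGFR/pSOS1/ERK_pp; pairwise comparisons of MEK_pRDS and
    ERK_pp at 300/1800/3600 s; measurement noise sigma = 0.02 relative
    units; logistic scale s = 1 molecule for statement noise (negligible
    against molecule-scale differences, so orderings are essentially
    noiseless, as for real scored blots); 5% missing cells.
    """

    variants: tuple[str, ...] = ("WT", "KO", "N78G", "T292A", "T292D")
    quant_times: tuple[float, ...] = (300.0, 600.0, 900.0, 1800.0, 2700.0, 3600.0)
    quant_observables: tuple[str, ...] = ("pEGFR", "pSOS1", "ERK_pp")
    qual_observables: tuple[str, ...] = ("MEK_pRDS", "ERK_pp")
    comparison_times: tuple[float, ...] = (300.0, 1800.0, 3600.0)
    sigma: float = 0.02
    statement_scale: float = 1.0
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.statement_scale < 0:
            raise ValueError("statement scale must be nonnegative")
        if not set(self.comparison_times) <= set(self.comparison_times) | set(self.quant_times):
            raise ValueError("comparison times must be simulatable")

    @property
    def time_grid(self) -> np.ndarray:
        times = {0.0} | set(self.quant_times) | set(self.comparison_times)
        return np.array(sorted(times))


def _simulate_variant(variant: str, rates: dict[str, float],
                      design: SyntheticDesign):
    network = build_variant_network(variant)
    params = {**DEFAULT_PARAMS, **rates}
    return simulate(network, params, design.time_grid)


def true_scale_factors(rates: dict[str, float],
                       design: SyntheticDesign) -> dict[str, float]:
    """Scale factors putting each noiseless WT output's peak at 0.95.

    Mirrors relative intensity measurements normalized to their maximum,
    with headroom so that Gaussian noise rarely exceeds 1.
    """
    traj = _simulate_variant("WT", rates, design)
    scales = {}
    for obs in design.quant_observables:
        peak = float(observable_series(traj, obs).max())
        if peak <= 0:
            raise RuntimeError(f"observable {obs} is identically zero at truth")
        scales[obs] = 0.95 / peak
    return scales


def generate_quant(
    rates: dict[str, float],
    design: SyntheticDesign,
    scales: dict[str, float] | None = None,
    seed: int | None = None,
) -> tuple[QuantTable, dict]:
    """Noisy WT relative time-series table at the ground truth.

    Returns the table and an info dict with the scale factors used and the
    number of cells clipped back into (0, 1].
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    if scales is None:
        scales = true_scale_factors(rates, design)
    traj = _simulate_variant("WT", rates, design)
    idx = [traj.time_index(t) for t in design.quant_times]
    data = {}
    clipped = 0
    for obs in design.quant_observables:
        truth = scales[obs] * observable_series(traj, obs)[idx]
        noisy = truth + rng.normal(0.0, design.sigma, size=len(idx))
        clipped += int(np.sum((noisy <= 0.0) | (noisy > 1.0)))
        data[obs] = np.clip(noisy, _CLIP_LOW, 1.0)
    df = pd.DataFrame(data, index=pd.Index(design.quant_times, name="time"))
    if design.missing_fraction > 0:
        mask = rng.random(df.shape) < design.missing_fraction
        df = df.mask(mask)
    if clipped:
        logger.info("generate_quant: clipped %d cells into (0, 1]", clipped)
    return QuantTable(df), {"scales": scales, "clipped": clipped}


def default_comparison_pairs(design: SyntheticDesign) -> list[tuple[Condition, Condition]]:
    """The 15 default comparisons: each mutant in {KO, N78G, T292D} against
    WT for MEK_pRDS at the three comparison times, plus WT cross-time
    comparisons of MEK_pRDS and ERK_pp."""
    pairs = []
    for mutant in ("KO", "N78G", "T292D"):
        for t in design.comparison_times:
            pairs.append((Condition(mutant, "MEK_pRDS", t),
                          Condition("WT", "MEK_pRDS", t)))
    t1, t2, t3 = design.comparison_times
    for obs in ("MEK_pRDS", "ERK_pp"):
        pairs.append((Condition("WT", obs, t1), Condition("WT", obs, t2)))
        pairs.append((Condition("WT", obs, t1), Condition("WT", obs, t3)))
        pairs.append((Condition("WT", obs, t2), Condition("WT", obs, t3)))
    return pairs


def wt_comparison_pairs(design: SyntheticDesign) -> list[tuple[Condition, Condition]]:
    """Reduced two-variant comparison set (WT and KO) for sampling runs."""
    pairs = []
    for t in design.comparison_times:
        pairs.append((Condition("KO", "MEK_pRDS", t),
                      Condition("WT", "MEK_pRDS", t)))
    t1, t2, t3 = design.comparison_times
    for obs in ("MEK_pRDS", "ERK_pp"):
        pairs.append((Condition("WT", obs, t1), Condition("WT", obs, t2)))
        pairs.append((Condition("WT", obs, t1), Condition("WT", obs, t3)))
        pairs.append((Condition("WT", obs, t2), Condition("WT", obs, t3)))
    return pairs


def generate_qual(
    rates: dict[str, float],
    design: SyntheticDesign,
    pairs: list[tuple[Condition, Condition]] | None = None,
    seed: int | None = None,
) -> list[QualStatement]:
    """Draw statement outcomes z ~ Bernoulli(1/(1+exp(-delta/s))) at truth.

    ``s = 0`` means the noiseless limit z = H(delta). The relation written
    into each statement encodes the drawn z.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    if pairs is None:
        pairs = default_comparison_pairs(design)
    variants = sorted({c.variant for ab in pairs for c in ab})
    trajs = {v: _simulate_variant(v, rates, design) for v in variants}

    def value(cond: Condition) -> float:
        traj = trajs[cond.variant]
        return float(observable_series(traj, cond.observable)[traj.time_index(cond.time)])

    statements = []
    s = design.statement_scale
    for a, b in pairs:
        d = value(a) - value(b)
        if s == 0:
            z = 1 if d >= 0 else 0
        else:
            p = 1.0 / (1.0 + np.exp(-np.clip(d / s, -700, 700)))
            z = int(rng.random() < p)
        statements.append(QualStatement(side_a=a, side_b=b, z=z, scale=max(s, 1.0)))
    return statements


# -- standard desk-scale problems -------------------------------------------

#: Ground truth for the two focal rate constants (reference estimates).
TRUE_RATES = {"d3": 1.0e-3, "u3": 1.0e-3}

#: Optimization box for d3 and u3 (one to two orders around the truth).
MLE_RATE_BOUNDS = {"d3": (8.0e-5, 3.0e-2), "u3": (8.0e-5, 3.0e-2)}

#: Wider sampling box for Bayesian UQ.
BAYES_RATE_BOUNDS = {"d3": (1.0e-5, 1.0e-1), "u3": (1.0e-5, 1.0e-1)}

#: Sigma prior box, geometrically centered on the generator's noise level.
SIGMA_BOUNDS = (2.0e-3, 2.0e-1)

#: Half-width of scale-factor boxes in log10 units around the true factor.
SCALE_HALF_DECADES = 0.5


def _scale_specs(scales: dict[str, float]) -> list[ParamSpec]:
    f = 10.0 ** SCALE_HALF_DECADES
    return [ParamSpec(f"Scale_{obs}", s / f, s * f) for obs, s in sorted(scales.items())]


def recovery_problem(
    seed: int,
    design: SyntheticDesign | None = None,
) -> tuple[CalibrationProblem, dict[str, float]]:
    """The (d3, u3) recovery problem: penalty-form objective over synthetic
    WT quantitative data plus the 15 default statements.

    Returns the calibration problem and the flat ground-truth dict.
    """
    if design is None:
        design = SyntheticDesign(seed=seed)
    scales = true_scale_factors(TRUE_RATES, design)
    table, _info = generate_quant(TRUE_RATES, design, scales=scales, seed=seed)
    statements = generate_qual(TRUE_RATES, design, seed=seed + 1)
    specs = [
        ParamSpec("d3", *MLE_RATE_BOUNDS["d3"]),
        ParamSpec("u3", *MLE_RATE_BOUNDS["u3"]),
        *_scale_specs(scales),
    ]
    theta = ThetaVector(specs)
    problem = CalibrationProblem(theta, quant_table=table, statements=statements,
                                 on_failure="penalize")
    truth = {**TRUE_RATES, **{f"Scale_{k}": v for k, v in scales.items()}}
    return problem, truth


def bayesian_problem(
    seed: int,
    design: SyntheticDesign | None = None,
) -> tuple[CalibrationProblem, dict[str, float]]:
    """The six-parameter Bayesian problem (d3, u3, three scale factors,
    sigma) with the exact-likelihood posterior over synthetic WT data and
    the reduced WT/KO statement set."""
    if design is None:
        design = SyntheticDesign(seed=seed)
    scales = true_scale_factors(TRUE_RATES, design)
    table, _info = generate_quant(TRUE_RATES, design, scales=scales, seed=seed)
    statements = generate_qual(TRUE_RATES, design,
                               pairs=wt_comparison_pairs(design), seed=seed + 1)
    specs = [
        ParamSpec("d3", *BAYES_RATE_BOUNDS["d3"]),
        ParamSpec("u3", *BAYES_RATE_BOUNDS["u3"]),
        *_scale_specs(scales),
        ParamSpec("sigma", *SIGMA_BOUNDS),
    ]
    theta = ThetaVector(specs)
    problem = CalibrationProblem(theta, quant_table=table, statements=statements,
                                 on_failure="penalize")
    truth = {**TRUE_RATES, **{f"Scale_{k}": v for k, v in scales.items()},
             "sigma": design.sigma}
    return problem, truth
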