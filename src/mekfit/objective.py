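"""Combined fitting objective F = Fquant + Fqual and the Bayesian
log-posterior.

Two scoring modes mirror the two inference modes:

* MLE/optimization uses the penalty form: raw sum-of-squares over the
  quantitative cells plus the hinge penalty over the qualitative statements.
* Bayesian sampling uses the exact likelihoods: the homoscedastic Gaussian
  negative log-likelihood (with sigma an adjustable hyperparameter) plus the
  Bernoulli-logistic negative log-likelihood, under a proper uniform prior
  on the box of adjustable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import reaction_model
from .qualdata import QualStatement, TrajectoryBank
from .quantdata import QuantTable
from .reaction_model import (
    ADJUSTABLE_NAMES,
    OBSERVABLES,
    build_variant_network,
    precompile,
    simulate_compiled,
)

__all__ = ["ParamSpec", "ThetaVector", "ObjectiveValue", "CalibrationProblem"]


@dataclass(frozen=True)
class ParamSpec:
    """One adjustable parameter: box bounds and sampling-scale flag."""

    name: str
    low: float
    high: float
    log10: bool = True

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"{self.name}: bounds must satisfy low < high")
        if self.log10 and self.low <= 0:
            raise ValueError(f"{self.name}: log10 scale requires positive bounds")


class ThetaVector:
    """Ordered named adjustable parameters with box bounds.

    Values live on the natural scale; ``to_array``/``from_array`` move to and
    from the sampling scale (log10 where flagged), on which optimizers and
    samplers operate.
    """

    def __init__(self, specs: list[ParamSpec], values: dict[str, float] | None = None):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        self.specs = list(specs)
        self.names = names
        if values is None:
            values = {s.name: math.sqrt(s.low * s.high) if s.log10
                      else 0.5 * (s.low + s.high) for s in specs}
        missing = set(names) - set(values)
        if missing:
            raise KeyError(f"missing values for {sorted(missing)}")
        self.values = {n: float(values[n]) for n in names}

    def __len__(self) -> int:
        return len(self.specs)

    def spec(self, name: str) -> ParamSpec:
        return self.specs[self.names.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def in_bounds(self, values: dict[str, float] | None = None) -> bool:
        values = self.values if values is None else values
        return all(s.low <= values[s.name] <= s.high for s in self.specs)

    def sampling_bounds(self) -> np.ndarray:
        """(p, 2) array of bounds on the sampling scale."""
        out = np.empty((len(self.specs), 2))
        for i, s in enumerate(self.specs):
            if s.log10:
                out[i] = (math.log10(s.low), math.log10(s.high))
            else:
                out[i] = (s.low, s.high)
        return out

    def to_array(self, values: dict[str, float] | None = None) -> np.ndarray:
        values = self.values if values is None else values
        return np.array([
            math.log10(values[s.name]) if s.log10 else values[s.name]
            for s in self.specs
        ])

    def from_array(self, x: np.ndarray) -> dict[str, float]:
        if len(x) != len(self.specs):
            raise ValueError("array length does not match parameter count")
        return {
            s.name: (10.0 ** float(v) if s.log10 else float(v))
            for s, v in zip(self.specs, x)
        }

    def with_values(self, values: dict[str, float]) -> "ThetaVector":
        merged = {**self.values, **values}
        return ThetaVector(self.specs, merged)


@dataclass(frozen=True)
class ObjectiveValue:
    fquant: float
    fqual: float

    @property
    def total(self) -> float:
        return self.fquant + self.fqual


def _split_theta(values: dict[str, float]):
    """Split a flat parameter dict into rate overrides, scale factors, sigma."""
    rates, scales = {}, {}
    sigma = None
    for name, v in values.items():
        if name in ADJUSTABLE_NAMES:
            rates[name] = v
        elif name.startswith("Scale_"):
            scales[name[len("Scale_"):]] = v
        elif name == "sigma":
            sigma = v
        else:
            raise KeyError(f"unknown adjustable parameter {name!r}")
    return rates, scales, sigma


class CalibrationProblem:
    """One fitting/sampling problem: model variants, data, adjustable set.

    Quantitative data are compared against the WT variant only (scale
    factors map absolute WT outputs onto the relative measurements);
    qualitative statements may reference any variant. Every referenced
    variant is simulated once per evaluation on a common time grid covering
    all data and statement times.
    """

    def __init__(
        self,
        theta: ThetaVector,
        quant_table: QuantTable | None = None,
        statements: list[QualStatement] | None = None,
        base_params: dict[str, float] | None = None,
        on_failure: str = "error",
        failure_value: float = 1e12,
        rtol: float = 1e-6,
        atol: float = 1e-1,
    ):
        if on_failure not in ("error", "penalize"):
            raise ValueError("on_failure must be 'error' or 'penalize'")
        self.rtol = rtol
        self.atol = atol
        self.theta = theta
        self.quant_table = quant_table
        self.statements = list(statements or [])
        self.base_params = dict(reaction_model.DEFAULT_PARAMS
                                if base_params is None else base_params)
        self.on_failure = on_failure
        self.failure_value = failure_value
        self.n_evaluations = 0

        variants = {"WT"} if (quant_table is not None and quant_table.n > 0) else set()
        times = set()
        if quant_table is not None:
            times.update(float(t) for t in quant_table.times)
        for s in self.statements:
            for cond in (s.side_a, s.side_b):
                variants.add(cond.variant)
                times.add(float(cond.time))
        self.variants = tuple(sorted(variants)) or ("WT",)
        self.time_grid = np.array(sorted({0.0} | times))
        if self.time_grid.size < 2:
            self.time_grid = np.array([0.0, 3600.0])
        self._networks = {v: build_variant_network(v) for v in self.variants}
        self._compiled = {v: precompile(n) for v, n in self._networks.items()}
        self._prepare_fast_paths()

    def _obs_weights(self, name: str) -> np.ndarray:
        w = np.zeros(len(reaction_model.SPECIES))
        for sp, coeff in OBSERVABLES[name].items():
            w[reaction_model.SPECIES.index(sp)] = coeff
        return w

    def _prepare_fast_paths(self) -> None:
        """Precompute numpy views so per-evaluation cost is dominated by the
        ODE solves (the public quantdata/qualdata functions remain the
        reference implementations)."""
        grid = list(self.time_grid)
        self._has_quant = self.quant_table is not None and self.quant_table.n > 0
        if self._has_quant:
            tbl = self.quant_table
            self._q_obs = list(tbl.observables)
            self._q_tidx = np.array([grid.index(float(t)) for t in tbl.times])
            self._q_w = np.stack([self._obs_weights(o) for o in self._q_obs])  # (obs, sp)
            self._q_y = tbl.data.to_numpy(dtype=float)  # (times, obs), NaN = missing
            self._q_mask = ~np.isnan(self._q_y)
            self._q_n = int(self._q_mask.sum())
        stmts = []
        for s in self.statements:
            stmts.append((
                s.side_a.variant, self._obs_weights(s.side_a.observable),
                grid.index(float(s.side_a.time)),
                s.side_b.variant, self._obs_weights(s.side_b.observable),
                grid.index(float(s.side_b.time)),
                s.z, s.scale, s.weight,
            ))
        self._stmt_fast = stmts

    # -- simulation ---------------------------------------------------------
    def _simulate_all(self, rate_overrides: dict[str, float]):
        params = {**self.base_params, **rate_overrides}
        return {
            v: simulate_compiled(self._compiled[v], params, self.time_grid,
                                 rtol=self.rtol, atol=self.atol)
            for v in self.variants
        }

    def simulate_bank(self, rate_overrides: dict[str, float]) -> TrajectoryBank:
        return TrajectoryBank(self._simulate_all(rate_overrides))

    def _quant_sse_fast(self, trajs, scales: dict[str, float]) -> float:
        wt = trajs["WT"].values[self._q_tidx]  # (times, sp)
        pred = np.maximum(wt @ self._q_w.T, 0.0)  # (times, obs)
        svec = np.array([scales[o] for o in self._q_obs])
        resid = np.where(self._q_mask, self._q_y - pred * svec, 0.0)
        return float(np.sum(resid * resid))

    def _deltas_fast(self, trajs) -> np.ndarray:
        out = np.empty(len(self._stmt_fast))
        for i, (va, wa, ta, vb, wb, tb, _z, _s, _w) in enumerate(self._stmt_fast):
            a = max(float(trajs[va].values[ta] @ wa), 0.0)
            b = max(float(trajs[vb].values[tb] @ wb), 0.0)
            out[i] = a - b
        return out

    # -- penalty-form objective (MLE) --------------------------------------
    def evaluate_objective(self, values: dict[str, float] | np.ndarray) -> ObjectiveValue:
        """F(theta) = Fquant (raw SSE) + Fqual (hinge penalty)."""
        if isinstance(values, np.ndarray):
            values = self.theta.from_array(values)
        rates, scales, _sigma = _split_theta(values)
        self.n_evaluations += 1
        try:
            trajs = self._simulate_all(rates)
        except RuntimeError:
            if self.on_failure == "penalize":
                return ObjectiveValue(self.failure_value, 0.0)
            raise
        fquant = self._quant_sse_fast(trajs, scales) if self._has_quant else 0.0
        fqual = 0.0
        if self._stmt_fast:
            deltas = self._deltas_fast(trajs)
            for d, (*_ab, z, _s, w) in zip(deltas, self._stmt_fast):
                fqual += w * (max(0.0, -d) + (1 - z) * d)
        return ObjectiveValue(fquant, fqual)

    def objective_total(self, x: np.ndarray) -> float:
        return self.evaluate_objective(x).total

    def profile_objective(self, x: np.ndarray) -> float:
        """Objective on the likelihood (chi-square) scale, for profiling.

        The Gaussian noise variance is concentrated out analytically, giving
        (n/2) ln(Fquant / n) up to an additive constant, plus the hinge
        penalty (whose molecule-scale weights make any ordering violation
        decisive). The chi-square threshold of the identifiability
        classification applies on this scale.
        """
        v = self.evaluate_objective(x)
        out = v.fqual
        if self._has_quant:
            out += 0.5 * self._q_n * math.log(max(v.fquant, 1e-300) / self._q_n)
        return out

    # -- exact-likelihood log-posterior (Bayesian) --------------------------
    def log_posterior(self, values: dict[str, float] | np.ndarray) -> float:
        """Uniform-box prior; -inf outside the box or on simulation failure."""
        if isinstance(values, np.ndarray):
            values = self.theta.from_array(values)
        if not self.theta.in_bounds(values):
            return -math.inf
        rates, scales, sigma = _split_theta(values)
        self.n_evaluations += 1
        try:
            trajs = self._simulate_all(rates)
        except RuntimeError:
            return -math.inf
        nll = 0.0
        if self._has_quant:
            if sigma is None:
                raise KeyError("log_posterior with quantitative data requires 'sigma'")
            sse = self._quant_sse_fast(trajs, scales)
            nll += (0.5 * self._q_n * math.log(2.0 * math.pi * sigma * sigma)
                    + sse / (2.0 * sigma * sigma))
        if self._stmt_fast:
            deltas = self._deltas_fast(trajs)
            for d, (*_ab, z, s, _w) in zip(deltas, self._stmt_fast):
                r = d / s
                nll += float(np.logaddexp(0.0, -r)) + (1 - z) * r
        return -nll
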