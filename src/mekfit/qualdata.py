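"""Qualitative ordering observations: statement parsing, model-data
differences, and the logistic likelihood / hinge penalty used to score them.

A statement compares one observable between two conditions (cell-line
variant, time), e.g.::

    WT.MEK_pRDS at time = 300 < N78G.MEK_pRDS at time = 300

The binary outcome z encodes the observed ordering (z = 1 means the left
side was at least the right side). The model prediction for a statement is
the Heaviside step of delta = g(A) - g(B), the difference of the two
(unscaled) model outputs; a Bernoulli noise model with sigmoid success
probability 1/(1 + exp(-delta/s)) links delta to z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .reaction_model import OBSERVABLES, VARIANTS, Trajectory, observable_series

__all__ = [
    "Condition",
    "QualStatement",
    "TrajectoryBank",
    "parse_statements",
    "write_statements",
    "delta",
    "heaviside_prediction",
    "sigmoid_prob",
    "qual_neg_loglik",
    "qual_penalty",
]


@dataclass(frozen=True)
class Condition:
    """One (variant, observable, time) measurement condition."""

    variant: str
    observable: str
    time: float


@dataclass(frozen=True)
class QualStatement:
    """One formalized qualitative comparison between two conditions.

    z = 1 encodes "A >= B", z = 0 encodes "A < B". ``scale`` is the logistic
    scale s > 0 of the Bernoulli noise model; ``weight`` = 1/scale is the
    hinge-penalty weight.
    """

    side_a: Condition
    side_b: Condition
    z: int
    scale: float = 1.0
    line: int | None = None

    def __post_init__(self):
        if self.z not in (0, 1):
            raise ValueError("z must be 0 or 1")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.side_a == self.side_b:
            raise ValueError("the two sides of a statement must differ")

    @property
    def weight(self) -> float:
        return 1.0 / self.scale

    def with_scale(self, scale: float) -> "QualStatement":
        return replace(self, scale=scale)

    def as_text(self) -> str:
        rel = ">" if self.z == 1 else "<"
        a, b = self.side_a, self.side_b
        return (
            f"{a.variant}.{a.observable} at time = {a.time:g} {rel} "
            f"{b.variant}.{b.observable} at time = {b.time:g}"
        )


_STMT_RE = re.compile(
    r"^\s*(\w+)\s*\.\s*(\w+)\s+at\s+time\s*=\s*([0-9eE.+-]+)"
    r"\s*([<>])\s*"
    r"(\w+)\s*\.\s*(\w+)\s+at\s+time\s*=\s*([0-9eE.+-]+)\s*$"
)


def _check_condition(variant: str, observable: str, lineno: int) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"line {lineno}: unknown variant {variant!r}")
    if observable not in OBSERVABLES:
        raise ValueError(f"line {lineno}: unknown observable {observable!r}")


def parse_statements(text: str, default_scale: float = 1.0) -> list[QualStatement]:
    """Parse PROP-dialect text, one comparison statement per line.

    Blank lines and ``#`` comments are ignored. Whitespace around tokens
    (including after the variant dot) is tolerated. Raises ``ValueError``
    naming the offending line on a grammar violation.
    """
    statements = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _STMT_RE.match(line)
        if m is None:
            raise ValueError(f"line {lineno}: cannot parse statement {raw!r}")
        va, oa, ta, rel, vb, ob, tb = m.groups()
        _check_condition(va, oa, lineno)
        _check_condition(vb, ob, lineno)
        try:
            ta_f, tb_f = float(ta), float(tb)
        except ValueError:
            raise ValueError(f"line {lineno}: bad time in {raw!r}") from None
        statements.append(
            QualStatement(
                side_a=Condition(va, oa, ta_f),
                side_b=Condition(vb, ob, tb_f),
                z=1 if rel == ">" else 0,
                scale=default_scale,
                line=lineno,
            )
        )
    return statements


def write_statements(statements: list[QualStatement]) -> str:
    """Serialize statements to PROP-dialect text (round-trip stable)."""
    return "\n".join(s.as_text() for s in statements) + "\n"


class TrajectoryBank:
    """Trajectories for every variant, all simulated at a common parameter set."""

    def __init__(self, trajectories: dict[str, Trajectory]):
        self._traj = dict(trajectories)

    def __contains__(self, variant: str) -> bool:
        return variant in self._traj

    def lookup(self, cond: Condition) -> float:
        if cond.variant not in self._traj:
            raise KeyError(f"variant {cond.variant!r} not in trajectory bank")
        traj = self._traj[cond.variant]
        idx = traj.time_index(cond.time)
        return float(observable_series(traj, cond.observable)[idx])

    def check_covers(self, statements: list[QualStatement]) -> None:
        for s in statements:
            for cond in (s.side_a, s.side_b):
                self.lookup(cond)


def delta(stmt: QualStatement, bank: TrajectoryBank) -> float:
    """Model difference g(A) - g(B) in raw model units (no scale factors)."""
    return bank.lookup(stmt.side_a) - bank.lookup(stmt.side_b)


def heaviside_prediction(d: float) -> int:
    """Predicted binary outcome; the boundary d = 0 predicts z = 1 (A >= B)."""
    return 1 if d >= 0 else 0


def sigmoid_prob(d: float, scale: float) -> float:
    """P(z = 1) = 1/(1 + exp(-d/scale)); overflow-safe for any d/scale."""
    if not scale > 0:
        raise ValueError("scale must be positive")
    return float(expit(d / scale))


def qual_neg_loglik(statements: list[QualStatement], bank: TrajectoryBank) -> float:
    """Exact Bernoulli-logistic negative log-likelihood of the statements.

    Sum over statements of ln(1 + exp(-delta/s)) + (1 - z) * delta / s,
    evaluated with logaddexp for stability.
    """
    total = 0.0
    for s in statements:
        r = delta(s, bank) / s.scale
        total += float(np.logaddexp(0.0, -r)) + (1 - s.z) * r
    return total


def qual_penalty(statements: list[QualStatement], bank: TrajectoryBank) -> float:
    """Hinge-penalty form: sum of w * [max(0, -delta) + (1 - z) * delta].

    Each term is w*|delta| when the sign of delta contradicts z and 0
    otherwise (delta = 0 incurs no penalty for either outcome). This is the
    small-scale limit of s * qual_neg_loglik with w = 1/s.
    """
    total = 0.0
    for s in statements:
        d = delta(s, bank)
        total += s.weight * (max(0.0, -d) + (1 - s.z) * d)
    return total
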