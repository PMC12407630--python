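"""Reduced mass-action ODE network for the EGFR→SOS1→RAS→RAF→MEK1/MEK2→ERK
cascade and its five cell-line variants.

The network is an explicitly enumerated surrogate for the rule-based
MEK-isoform model: ligand-driven EGFR dimerization and transphosphorylation,
SOS1 recruitment, RAS/RAF activation, activation-site phosphorylation of the
two MEK isoforms, MEK homo-/hetero-dimerization (dimer-bound active MEK
phosphorylates ERK), and two ERK-mediated negative feedbacks — SOS1
phosphorylation (p3/u3) and MEK1 Thr292 phosphorylation (p4/u4) with
phosphatase (PHP) recruitment to Thr292p (b5/n5/u5).

Units: time in seconds, abundances in molecules/cell, first-order rate
constants in 1/s, second-order in 1/(molecule*s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import odeint

__all__ = [
    "ADJUSTABLE_NAMES",
    "DEFAULT_PARAMS",
    "DEFAULT_INITIAL",
    "VARIANTS",
    "OBSERVABLES",
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "CompiledNetwork",
    "build_variant_network",
    "precompile",
    "simulate",
    "simulate_compiled",
    "observable_series",
    "moiety_totals",
    "parameter_table",
]

#: The 28 adjustable rate constants of the reference parameterization.
ADJUSTABLE_NAMES = (
    "c1L", "c2", "t1", "d3", "b1", "n1", "b2", "n2", "b3", "n3", "b4", "n4",
    "a1", "i1", "a2", "i2", "p1", "u1", "p2a", "p2b", "u2", "p3", "u3",
    "p4", "u4", "b5", "n5", "u5",
)

#: Reference rate-constant estimates (the original authors' values).
#: p3 is a bimolecular feedback rate of order 1e-9, consistent with the
#: published optimization bounds [9e-11, 4e-8] centered on it.
DEFAULT_PARAMS: dict[str, float] = {
    "c1L": 2.0e-2,   # ligand-driven receptor activation (with c2)
    "c2": 2.0e-7,    # EGFR dimerization due to ligand
    "t1": 1.0e2,     # transphosphorylation within the EGFR dimer
    "d3": 1.0e-3,    # degradation of ligand-bound dimer complexes
    "b1": 4.0e-8,    # pEGFR + SOS1 association
    "n1": 2.0e-3,    # pEGFR·SOS1 dissociation
    "b2": 1.0e-5,    # MEK1 homodimer formation
    "n2": 1.0e-3,    # MEK1 homodimer dissociation
    "b3": 1.0e-5,    # MEK2 homodimer formation
    "n3": 3.0e-2,    # MEK2 homodimer dissociation
    "b4": 1.0e-5,    # MEK1:MEK2 heterodimer formation
    "n4": 1.0e-3,    # MEK1:MEK2 heterodimer dissociation
    "a1": 1.5e-7,    # RAS GDP→GTP exchange driven by pEGFR·SOS1
    "i1": 2.0e-2,    # RAS GTP hydrolysis
    "a2": 4.0e-8,    # RAF activation by RAS-GTP
    "i2": 1.0e-2,    # RAF inactivation
    "p1": 1.5e-7,    # MEK1/MEK2 activation-site phosphorylation by RAF
    "u1": 5.0e-3,    # MEK activation-site dephosphorylation
    "p2a": 1.0e-6,   # ERK phosphorylation by dimer-bound MEK1
    "p2b": 5.0e-6,   # ERK phosphorylation by dimer-bound MEK2 (= X * p2a)
    "u2": 2.0e-2,    # ERK dephosphorylation
    "p3": 2.0e-9,    # ERK feedback phosphorylation of SOS1
    "u3": 1.0e-3,    # SOS1 feedback-site dephosphorylation
    "p4": 1.2e-9,    # ERK feedback phosphorylation of MEK1 Thr292
    "u4": 2.0e-4,    # Thr292 dephosphorylation
    "b5": 4.0e-9,    # PHP binding to Thr292p-MEK1
    "n5": 2.0e-4,    # PHP dissociation from Thr292p-MEK1
    "u5": 2.0e1,     # PHP-catalyzed activation-site dephosphorylation
}

#: Fixed initial abundances (molecules/cell). EGFR0 and SOS10 are the peak
#: copy numbers of the receptor/adaptor pools; the original pre-stimulation
#: "setup" simulation is replaced by these fixed values.
DEFAULT_INITIAL: dict[str, float] = {
    "EGFR0": 5.0e5,
    "SOS10": 2.0e5,
    "RAS0": 5.0e5,
    "RAF0": 5.0e5,
    "MEK10": 1.34e5,
    "MEK20": 6.6e4,
    "MEK1_T292p0": 0.0,
    "ERK0": 3.0e6,
    "PHP_MEK0": 3.0e6,
}

#: MEK1 fraction of total MEK and MEK2/MEK1 activity ratio (fixed metadata;
#: the activity ratio is already folded into p2b = X * p2a).
MEK1_FRACTION = 0.67
MEK2_ACTIVITY_RATIO_X = 5.0

VARIANTS = ("WT", "KO", "N78G", "T292A", "T292D")

SPECIES = (
    "EGFR", "EGFRd", "pEGFR", "SOS1", "pSOS1", "pEGFR_SOS1",
    "RAS_GDP", "RAS_GTP", "RAF", "RAF_act",
    "MEK1", "pMEK1", "MEK1_T292p", "pMEK1_T292p", "PHP_MEK1_T292p",
    "MEK2", "pMEK2", "MEK1_MEK1", "MEK2_MEK2", "MEK1_MEK2",
    "ERK", "ERK_pp", "PHP",
)

#: Named observables as linear combinations of species. Dimers carry two
#: activation-phosphorylated MEK subunits; pEGFR counts phospho-subunits
#: (two per receptor dimer).
OBSERVABLES: dict[str, dict[str, float]] = {
    "MEK_pRDS": {
        "pMEK1": 1.0, "pMEK2": 1.0, "pMEK1_T292p": 1.0,
        "PHP_MEK1_T292p": 1.0,
        "MEK1_MEK1": 2.0, "MEK2_MEK2": 2.0, "MEK1_MEK2": 2.0,
    },
    "ERK_pp": {"ERK_pp": 1.0},
    "pEGFR": {"pEGFR": 2.0, "pEGFR_SOS1": 2.0},
    "pSOS1": {"pSOS1": 1.0},
}

#: Conserved moieties (species -> stoichiometric weight). EGFR and SOS1
#: totals are conserved only when d3 = 0, because d3 degrades ligand-bound
#: dimer complexes outright.
MOIETIES: dict[str, dict[str, float]] = {
    "EGFR": {"EGFR": 1, "EGFRd": 2, "pEGFR": 2, "pEGFR_SOS1": 2},
    "SOS1": {"SOS1": 1, "pSOS1": 1, "pEGFR_SOS1": 1},
    "RAS": {"RAS_GDP": 1, "RAS_GTP": 1},
    "RAF": {"RAF": 1, "RAF_act": 1},
    "MEK": {
        "MEK1": 1, "pMEK1": 1, "MEK1_T292p": 1, "pMEK1_T292p": 1,
        "PHP_MEK1_T292p": 1, "MEK2": 1, "pMEK2": 1,
        "MEK1_MEK1": 2, "MEK2_MEK2": 2, "MEK1_MEK2": 2,
    },
    "ERK": {"ERK": 1, "ERK_pp": 1},
    "PHP": {"PHP": 1, "PHP_MEK1_T292p": 1},
}

#: Moieties that are only conserved in the absence of receptor degradation.
DEGRADABLE_MOIETIES = ("EGFR", "SOS1")


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction; rate constant = product of named parameters."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_params: tuple[str, ...]
    tag: str = ""

    def rate_constant(self, params: dict[str, float]) -> float:
        k = 1.0
        for name in self.rate_params:
            k *= params[name]
        return k


def _base_reactions() -> list[Reaction]:
    R = Reaction
    return [
        R(("EGFR", "EGFR"), ("EGFRd",), ("c1L", "c2")),
        R(("EGFRd",), ("pEGFR",), ("t1",)),
        R(("pEGFR",), (), ("d3",), tag="degradation"),
        R(("pEGFR", "SOS1"), ("pEGFR_SOS1",), ("b1",)),
        R(("pEGFR_SOS1",), ("pEGFR", "SOS1"), ("n1",)),
        R(("pEGFR_SOS1",), (), ("d3",), tag="degradation"),
        R(("RAS_GDP", "pEGFR_SOS1"), ("RAS_GTP", "pEGFR_SOS1"), ("a1",)),
        R(("RAS_GTP",), ("RAS_GDP",), ("i1",)),
        R(("RAF", "RAS_GTP"), ("RAF_act", "RAS_GTP"), ("a2",)),
        R(("RAF_act",), ("RAF",), ("i2",)),
        R(("MEK1", "RAF_act"), ("pMEK1", "RAF_act"), ("p1",)),
        R(("MEK2", "RAF_act"), ("pMEK2", "RAF_act"), ("p1",)),
        R(("pMEK1",), ("MEK1",), ("u1",)),
        R(("pMEK2",), ("MEK2",), ("u1",)),
        R(("pMEK1", "pMEK1"), ("MEK1_MEK1",), ("b2",)),
        R(("MEK1_MEK1",), ("pMEK1", "pMEK1"), ("n2",)),
        R(("pMEK2", "pMEK2"), ("MEK2_MEK2",), ("b3",)),
        R(("MEK2_MEK2",), ("pMEK2", "pMEK2"), ("n3",)),
        R(("pMEK1", "pMEK2"), ("MEK1_MEK2",), ("b4",)),
        R(("MEK1_MEK2",), ("pMEK1", "pMEK2"), ("n4",)),
        R(("ERK", "MEK1_MEK1"), ("ERK_pp", "MEK1_MEK1"), ("p2a",)),
        R(("ERK", "MEK2_MEK2"), ("ERK_pp", "MEK2_MEK2"), ("p2b",)),
        R(("ERK", "MEK1_MEK2"), ("ERK_pp", "MEK1_MEK2"), ("p2a",)),
        R(("ERK", "MEK1_MEK2"), ("ERK_pp", "MEK1_MEK2"), ("p2b",)),
        R(("ERK_pp",), ("ERK",), ("u2",)),
        R(("SOS1", "ERK_pp"), ("pSOS1", "ERK_pp"), ("p3",)),
        R(("pSOS1",), ("SOS1",), ("u3",)),
        R(("MEK1", "ERK_pp"), ("MEK1_T292p", "ERK_pp"), ("p4",)),
        R(("pMEK1", "ERK_pp"), ("pMEK1_T292p", "ERK_pp"), ("p4",)),
        R(("MEK1_T292p",), ("MEK1",), ("u4",)),
        R(("pMEK1_T292p", "PHP"), ("PHP_MEK1_T292p",), ("b5",)),
        R(("PHP_MEK1_T292p",), ("pMEK1_T292p", "PHP"), ("n5",)),
        R(("PHP_MEK1_T292p",), ("MEK1_T292p", "PHP"), ("u5",)),
    ]


@dataclass(frozen=True)
class ReactionNetwork:
    """Enumerated species and mass-action reactions for one cell-line variant."""

    label: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    initial: dict[str, float] = field(repr=False)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(len(self.species))
        for name, value in self.initial.items():
            x0[self.species_index(name)] = value
        return x0

    def validate(self, params: dict[str, float]) -> None:
        """Check parameter completeness and nonnegativity."""
        for rxn in self.reactions:
            for name in rxn.rate_params:
                if name not in params:
                    raise KeyError(f"missing rate parameter {name!r}")
        for name, value in params.items():
            if name in ADJUSTABLE_NAMES and value < 0:
                raise ValueError(f"negative rate parameter {name} = {value}")


def _check_complete(params: dict[str, float]) -> None:
    missing = [n for n in ADJUSTABLE_NAMES if n not in params]
    if missing:
        raise KeyError(f"missing rate parameter(s): {', '.join(missing)}")


def build_variant_network(
    label: str,
    params: dict[str, float] | None = None,
    init: dict[str, float] | None = None,
) -> ReactionNetwork:
    """Derive the network for one cell-line variant from the WT base.

    KO zeroes the MEK1 pool; N78G removes MEK1 homo- and heterodimer
    formation (b2 = b4 = 0); T292A removes ERK-mediated Thr292
    phosphorylation of MEK1 (p4 = 0); T292D starts the entire MEK1 pool in
    the Thr292-phosphorylated (activation-incompetent) state with u4 = 0.
    """
    if label not in VARIANTS:
        raise ValueError(f"unknown variant label {label!r}; expected one of {VARIANTS}")
    params = dict(DEFAULT_PARAMS if params is None else params)
    _check_complete(params)
    init = dict(DEFAULT_INITIAL if init is None else init)

    reactions = _base_reactions()
    x0 = {
        "EGFR": init["EGFR0"],
        "SOS1": init["SOS10"],
        "RAS_GDP": init["RAS0"],
        "RAF": init["RAF0"],
        "MEK1": init["MEK10"],
        "MEK2": init["MEK20"],
        "MEK1_T292p": init.get("MEK1_T292p0", 0.0),
        "ERK": init["ERK0"],
        "PHP": init["PHP_MEK0"],
    }

    if label == "KO":
        x0["MEK1"] = 0.0
    elif label == "N78G":
        reactions = [r for r in reactions
                     if not {"b2", "b4"} & set(r.rate_params)]
    elif label == "T292A":
        reactions = [r for r in reactions if "p4" not in r.rate_params]
    elif label == "T292D":
        x0["MEK1_T292p"] = x0["MEK1_T292p"] + x0["MEK1"]
        x0["MEK1"] = 0.0
        reactions = [r for r in reactions if "u4" not in r.rate_params]

    return ReactionNetwork(
        label=label, species=SPECIES, reactions=tuple(reactions), initial=x0,
    )


@dataclass(frozen=True)
class Trajectory:
    """Deterministic simulation output on a fixed time grid."""

    times: np.ndarray
    values: np.ndarray  # (n_times, n_species)
    species: tuple[str, ...]

    def species_series(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def time_index(self, t: float) -> int:
        idx = np.nonzero(np.isclose(self.times, t, rtol=1e-9, atol=1e-9))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not on the simulated grid")
        return int(idx[0])


@njit(cache=True)
def _mass_action_rhs(x, t, k, r1, r2, stoich):  # pragma: no cover - jitted
    n_rxn = k.shape[0]
    n_sp = x.shape[0]
    dx = np.zeros(n_sp)
    for j in range(n_rxn):
        v = k[j] * x[r1[j]]
        if r2[j] >= 0:
            v *= x[r2[j]]
        for i in range(n_sp):
            s = stoich[i, j]
            if s != 0.0:
                dx[i] += s * v
    return dx


@njit(cache=True)
def _mass_action_jac(x, t, k, r1, r2, stoich):  # pragma: no cover - jitted
    n_rxn = k.shape[0]
    n_sp = x.shape[0]
    jac = np.zeros((n_sp, n_sp))
    for j in range(n_rxn):
        a = r1[j]
        b = r2[j]
        if b >= 0:
            da = k[j] * x[b]
            db = k[j] * x[a]
        else:
            da = k[j]
            db = 0.0
        for i in range(n_sp):
            s = stoich[i, j]
            if s != 0.0:
                jac[i, a] += s * da
                if b >= 0:
                    jac[i, b] += s * db
        # loop body no-op when s == 0
    return jac


@dataclass(frozen=True)
class CompiledNetwork:
    """Index arrays and stoichiometry of a network, ready for integration."""

    species: tuple[str, ...]
    label: str
    r1: np.ndarray
    r2: np.ndarray
    stoich: np.ndarray
    rate_param_names: tuple[tuple[str, ...], ...]
    x0: np.ndarray

    def rate_constants(self, params: dict[str, float]) -> np.ndarray:
        k = np.empty(len(self.rate_param_names))
        for j, names in enumerate(self.rate_param_names):
            kj = 1.0
            for name in names:
                kj *= params[name]
            k[j] = kj
        return k


def precompile(network: ReactionNetwork) -> CompiledNetwork:
    """Stoichiometry matrix and reactant index arrays (parameter-free)."""
    n_sp = len(network.species)
    n_rxn = len(network.reactions)
    index = {name: i for i, name in enumerate(network.species)}
    stoich = np.zeros((n_sp, n_rxn))
    r1 = np.empty(n_rxn, dtype=np.int64)
    r2 = np.empty(n_rxn, dtype=np.int64)
    for j, rxn in enumerate(network.reactions):
        if not 1 <= len(rxn.reactants) <= 2:
            raise ValueError("mass-action order must be 1 or 2")
        r1[j] = index[rxn.reactants[0]]
        r2[j] = index[rxn.reactants[1]] if len(rxn.reactants) == 2 else -1
        for sp in rxn.reactants:
            stoich[index[sp], j] -= 1.0
        for sp in rxn.products:
            stoich[index[sp], j] += 1.0
    return CompiledNetwork(
        species=network.species, label=network.label, r1=r1, r2=r2,
        stoich=stoich,
        rate_param_names=tuple(r.rate_params for r in network.reactions),
        x0=network.initial_state(),
    )


def simulate_compiled(
    comp: CompiledNetwork,
    params: dict[str, float],
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> Trajectory:
    """Integrate a precompiled network (the hot path behind :func:`simulate`)."""
    k = comp.rate_constants(params)
    values, info = odeint(
        _mass_action_rhs, comp.x0, times, args=(k, comp.r1, comp.r2, comp.stoich),
        Dfun=_mass_action_jac, rtol=rtol, atol=atol, mxstep=100_000,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        t_fail = float(info["tcur"][-1]) if len(info.get("tcur", [])) else float("nan")
        raise RuntimeError(
            f"integration failed for variant {comp.label} near t = {t_fail:.6g} s: "
            f"{info['message']}"
        )
    return Trajectory(times=times, values=values, species=comp.species)


def simulate(
    network: ReactionNetwork,
    params: dict[str, float] | None = None,
    times: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> Trajectory:
    """Integrate the network with a stiff-capable (LSODA) solver.

    ``times`` must be strictly increasing and start at 0. Tolerances default
    to rtol 1e-8 and atol 1e-2 molecules; results are deterministic for
    fixed inputs.
    """
    params = dict(DEFAULT_PARAMS if params is None else params)
    network.validate(params)
    if times is None:
        times = np.linspace(0.0, 3600.0, 121)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if times[0] != 0.0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    return simulate_compiled(precompile(network), params, times, rtol=rtol, atol=atol)


def observable_series(traj: Trajectory, name: str) -> np.ndarray:
    """Evaluate a named observable (linear combination of species).

    Tiny negative excursions from the integrator are clamped to zero here,
    never in the raw state.
    """
    if name not in OBSERVABLES:
        raise KeyError(
            f"unknown observable {name!r}; expected one of {sorted(OBSERVABLES)}"
        )
    out = np.zeros(len(traj.times))
    for sp, coeff in OBSERVABLES[name].items():
        out += coeff * traj.species_series(sp)
    return np.maximum(out, 0.0)


def moiety_totals(traj: Trajectory) -> dict[str, np.ndarray]:
    """Weighted totals of each conserved moiety along the trajectory."""
    totals = {}
    for name, weights in MOIETIES.items():
        tot = np.zeros(len(traj.times))
        for sp, w in weights.items():
            tot += w * traj.species_series(sp)
        totals[name] = tot
    return totals


def load_sbml(path: str) -> ReactionNetwork:
    """Optional alternative backend: read an SBML level-2/3 model.

    Requires the optional ``python-libsbml`` dependency. Only plain
    mass-action models (kinetic law = a product of one rate parameter and
    the reactant concentrations) can be represented; anything else raises.
    The built-in network is the tested path.
    """
    try:
        import libsbml
    except ImportError as exc:
        raise ImportError(
            "SBML loading requires the optional dependency python-libsbml"
        ) from exc
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"invalid SBML file: {path}")
    model = doc.getModel()
    species = tuple(s.getId() for s in model.getListOfSpecies())
    initial = {s.getId(): float(s.getInitialAmount())
               for s in model.getListOfSpecies() if s.getInitialAmount()}
    reactions = []
    for rxn in model.getListOfReactions():
        law = rxn.getKineticLaw()
        if law is None or law.getNumParameters() + law.getNumLocalParameters() > 1:
            raise ValueError(
                f"reaction {rxn.getId()}: only single-constant mass-action "
                "kinetic laws are supported")
        names = [p.getId() for p in law.getListOfParameters()] or \
            [p.getId() for p in law.getListOfLocalParameters()]
        reactants = tuple(
            r.getSpecies() for r in rxn.getListOfReactants()
            for _ in range(int(r.getStoichiometry() or 1)))
        products = tuple(
            p.getSpecies() for p in rxn.getListOfProducts()
            for _ in range(int(p.getStoichiometry() or 1)))
        reactions.append(Reaction(reactants, products, tuple(names)))
    return ReactionNetwork(label=model.getId() or "SBML", species=species,
                           reactions=tuple(reactions), initial=initial)


def parameter_table(params: dict[str, float] | None = None) -> str:
    """Serialize rate parameters to a plain-text table (name, value, fixed)."""
    params = dict(DEFAULT_PARAMS if params is None else params)
    lines = ["name\tvalue\tfixed"]
    for name in ADJUSTABLE_NAMES:
        lines.append(f"{name}\t{params[name]:.6g}\tno")
    for name, value in DEFAULT_INITIAL.items():
        lines.append(f"{name}\t{value:.6g}\tyes")
    return "\n".join(lines) + "\n"
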