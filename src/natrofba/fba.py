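"""Flux balance analysis core: the steady-state LP.

Fluxes v over the network's reactions are constrained by mass balance
S·v = 0 (S the stoichiometric matrix, metabolites x reactions) together
with directionality bounds per reaction class:

* internal reversible reactions: free in sign;
* internal irreversible (and growth) reactions: v >= 0;
* exchange fluxes of ubiquitous compounds (CO2, H2O, Na+, Cl-, K+, H+ by
  default): free two-way;
* parameterized exchanges (the carbon source and O2): fixed uptake values,
  entered as equalities;
* one-way secretion exchanges: v >= 0 (outflow only);
* abundant-compound exchanges (sulfate, phosphate, trace ions): free
  uptake, no secretion.

Exchange fluxes use the convention that the reaction exports its
metabolite left-to-right, so secretion is positive and uptake negative.
The objective (typically the growth reaction) is maximized by a linear
solver behind a minimal backend interface.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import scipy.optimize

from .network import UNKNOWN, MetabolicNetwork, Reaction

FEASIBILITY_TOL = 1e-7


# -- stoichiometric matrix ---------------------------------------------------


@dataclass
class StoichiometricMatrix:
    """Dense S with explicit row (metabolite) and column (reaction) orders."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray

    def column(self, reaction_id: str) -> np.ndarray:
        return self.S[:, self.reaction_ids.index(reaction_id)]


def build_stoichiometric_matrix(network: MetabolicNetwork) -> StoichiometricMatrix:
    """S[i, j] = coefficient of metabolite i in reaction j (0 elsewhere)."""
    met_ids = list(network.metabolites)
    rxn_ids = list(network.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in network.reactions[rid].stoichiometry.items():
            S[met_index[met_id], j] = float(coeff)
    return StoichiometricMatrix(met_ids, rxn_ids, S)


# -- exchange specification --------------------------------------------------

DEFAULT_UBIQUITOUS = frozenset({"co2", "h2o", "na1", "cl", "k", "h"})


@dataclass
class ExchangeSpec:
    """Boundary condition classes, keyed by metabolite id.

    The four groups must be pairwise disjoint.  ``parameterized`` maps a
    metabolite to its fixed uptake value (positive number = that much
    taken up).
    """

    ubiquitous: frozenset[str] = frozenset()
    parameterized: dict[str, float] = field(default_factory=dict)
    secretion_only: frozenset[str] = frozenset()
    abundant: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.ubiquitous = frozenset(self.ubiquitous)
        self.secretion_only = frozenset(self.secretion_only)
        self.abundant = frozenset(self.abundant)
        groups = [
            set(self.ubiquitous),
            set(self.parameterized),
            set(self.secretion_only),
            set(self.abundant),
        ]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                overlap = groups[i] & groups[j]
                if overlap:
                    raise ValueError(
                        f"exchange classes overlap on metabolites {sorted(overlap)}"
                    )

    def all_metabolites(self) -> set[str]:
        return (
            set(self.ubiquitous)
            | set(self.parameterized)
            | set(self.secretion_only)
            | set(self.abundant)
        )


# -- flux problem ------------------------------------------------------------


@dataclass
class FluxProblem:
    """An FBA instance: matrix, objective, per-reaction bounds, fixed fluxes."""

    matrix: StoichiometricMatrix
    objective: dict[str, float]
    bounds: dict[str, tuple[float | None, float | None]]
    fixed: dict[str, float]
    network: MetabolicNetwork
    exchanges: ExchangeSpec


def _exchange_reaction_for(network: MetabolicNetwork, met_id: str) -> str | None:
    for rxn in network.reactions.values():
        if rxn.kind == "EXCHANGE" and set(rxn.stoichiometry) == {met_id}:
            return rxn.id
    return None


def build_flux_problem(
    network: MetabolicNetwork,
    exchanges: ExchangeSpec,
    objective: str | Mapping[str, float],
) -> FluxProblem:
    """Classify every reaction into exactly one bound class and build the LP.

    Exchange reactions are synthesized (id ``EX_<met>``, stoichiometry
    {met: -1}) for metabolites named in the ExchangeSpec that lack one.
    Pre-existing exchange reactions for metabolites in no class are closed
    (flux fixed to 0): nothing else crosses the boundary.
    """
    network = copy.deepcopy(network)
    for met_id in sorted(exchanges.all_metabolites()):
        if met_id not in network.metabolites:
            raise KeyError(f"ExchangeSpec names unknown metabolite {met_id!r}")
        if _exchange_reaction_for(network, met_id) is None:
            network.reactions[f"EX_{met_id}"] = Reaction(
                id=f"EX_{met_id}",
                name=f"{met_id} exchange",
                stoichiometry={met_id: Fraction(-1)},
                reversible=True,
                kind="EXCHANGE",
            )

    matrix = build_stoichiometric_matrix(network)
    bounds: dict[str, tuple[float | None, float | None]] = {}
    fixed: dict[str, float] = {}
    for rid, rxn in network.reactions.items():
        if rxn.kind == "EXCHANGE":
            met_id = next(iter(rxn.stoichiometry))
            sign = float(rxn.stoichiometry[met_id])  # -1 for export convention
            if met_id in exchanges.parameterized:
                # uptake u of met: export flux is -u (for sign -1)
                fixed[rid] = exchanges.parameterized[met_id] * sign
                bounds[rid] = (fixed[rid], fixed[rid])
            elif met_id in exchanges.ubiquitous:
                bounds[rid] = (None, None)
            elif met_id in exchanges.secretion_only:
                bounds[rid] = (0.0, None) if sign < 0 else (None, 0.0)
            elif met_id in exchanges.abundant:
                bounds[rid] = (None, 0.0) if sign < 0 else (0.0, None)
            else:
                bounds[rid] = (0.0, 0.0)
        elif rxn.kind == "GROWTH":
            bounds[rid] = (0.0, None)
        else:
            bounds[rid] = (None, None) if rxn.reversible else (0.0, None)

    if isinstance(objective, str):
        objective = {objective: 1.0}
    for rid in objective:
        if rid not in network.reactions:
            raise KeyError(f"objective reaction {rid!r} not in network")
    return FluxProblem(
        matrix=matrix,
        objective=dict(objective),
        bounds=bounds,
        fixed=fixed,
        network=network,
        exchanges=exchanges,
    )


# -- solving -----------------------------------------------------------------


@dataclass
class FluxSolution:
    """Solver outcome; ``v`` is populated only for OPTIMAL status."""

    status: str  # OPTIMAL | INFEASIBLE | UNBOUNDED | NUMERICAL
    v: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None
    message: str = ""


def _solve_highs(
    c: np.ndarray, A_eq: np.ndarray, b_eq: np.ndarray, bounds: list
) -> tuple[str, np.ndarray | None, str]:
    res = scipy.optimize.linprog(
        c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    status = {0: "OPTIMAL", 2: "INFEASIBLE", 3: "UNBOUNDED"}.get(res.status, "NUMERICAL")
    return status, (res.x if res.status == 0 else None), res.message


SOLVER_BACKENDS: dict[str, Callable] = {"highs": _solve_highs}


def solve_flux_problem(problem: FluxProblem, backend: str = "highs") -> FluxSolution:
    """Maximize the objective subject to S·v = 0 and the class bounds.

    OPTIMAL solutions satisfy the steady-state constraint to within an
    absolute tolerance of 1e-7 after scaling each S row to unit maximum;
    violations downgrade the status to NUMERICAL rather than returning a
    spurious optimum.
    """
    rxn_ids = problem.matrix.reaction_ids
    n = len(rxn_ids)
    c = np.zeros(n)
    for rid, w in problem.objective.items():
        c[rxn_ids.index(rid)] = -w  # linprog minimizes
    bounds = [problem.bounds[rid] for rid in rxn_ids]
    A_eq = problem.matrix.S
    b_eq = np.zeros(A_eq.shape[0])

    solver = SOLVER_BACKENDS[backend]
    status, x, message = solver(c, A_eq, b_eq, bounds)
    if status != "OPTIMAL":
        return FluxSolution(status=status, message=message)

    resid = A_eq @ x
    scale = np.maximum(np.abs(A_eq).max(axis=1), 1.0)
    if np.max(np.abs(resid) / scale) > FEASIBILITY_TOL:
        return FluxSolution(
            status="NUMERICAL",
            message=f"steady-state residual {np.max(np.abs(resid / scale)):.2e} above tolerance",
        )
    v = {rid: float(x[i]) for i, rid in enumerate(rxn_ids)}
    obj = float(sum(problem.objective[rid] * v[rid] for rid in problem.objective))
    return FluxSolution(status="OPTIMAL", v=v, objective_value=obj)


# -- carbon closure ----------------------------------------------------------


@dataclass
class CarbonLedger:
    """Signed carbon account over the boundary of an OPTIMAL solution.

    uptake_C counts carbon entering (negative exchange fluxes x carbon
    atoms), the outflow routes are split into CO2, biomass and other
    secreted metabolites.  delta = in - out, ~0 for a mass-consistent
    solution.  Exchanged metabolites with UNKNOWN formulas make the check
    unverifiable.
    """

    uptake_C: float
    co2_C: float
    biomass_C: float
    other_secreted_C: float
    delta: float
    unverifiable: tuple[str, ...] = ()

    @property
    def out_C(self) -> float:
        return self.co2_C + self.biomass_C + self.other_secreted_C


def carbon_closure_check(
    solution: FluxSolution,
    problem: FluxProblem,
    co2_id: str = "co2",
    biomass_id: str = "biomass",
    flux_tol: float = 1e-9,
) -> CarbonLedger:
    """Audit that boundary carbon in equals boundary carbon out."""
    if solution.status != "OPTIMAL":
        raise ValueError("carbon closure requires an OPTIMAL solution")
    network = problem.network
    uptake = co2 = bio = other = 0.0
    unverifiable: list[str] = []
    for rid, rxn in network.reactions.items():
        if rxn.kind != "EXCHANGE":
            continue
        met_id = next(iter(rxn.stoichiometry))
        sign = float(rxn.stoichiometry[met_id])
        flux = solution.v.get(rid, 0.0)
        export = -sign * flux  # amount of met leaving the system
        if abs(export) <= flux_tol:
            continue
        met = network.metabolites[met_id]
        if met.formula is UNKNOWN:
            unverifiable.append(met_id)
            continue
        carbon = float(met.formula["C"]) * export
        if export < 0:
            uptake += -carbon
        elif met_id == co2_id:
            co2 += carbon
        elif met_id == biomass_id:
            bio += carbon
        else:
            other += carbon
    return CarbonLedger(
        uptake_C=uptake,
        co2_C=co2,
        biomass_C=bio,
        other_secreted_C=other,
        delta=uptake - (co2 + bio + other),
        unverifiable=tuple(sorted(unverifiable)),
    )


# -- audit export ------------------------------------------------------------


def export_lp_text(problem: FluxProblem, path: str | Path) -> None:
    """Dump the LP in CPLEX LP text format for external audit."""
    rxn_ids = problem.matrix.reaction_ids
    lines = ["Maximize", " obj: " + " + ".join(
        f"{w} {rid}" for rid, w in problem.objective.items()
    ), "Subject To"]
    S = problem.matrix.S
    for i, met_id in enumerate(problem.matrix.metabolite_ids):
        terms = [
            f"{'+' if S[i, j] >= 0 else '-'} {abs(S[i, j])} {rxn_ids[j]}"
            for j in range(len(rxn_ids))
            if S[i, j] != 0
        ]
        if terms:
            lines.append(f" m_{met_id}: {' '.join(terms)} = 0")
    lines.append("Bounds")
    for rid in rxn_ids:
        lo, hi = problem.bounds[rid]
        lo_s = "-inf" if lo is None else repr(lo)
        hi_s = "+inf" if hi is None else repr(hi)
        lines.append(f" {lo_s} <= {rid} <= {hi_s}")
    lines.append("End")
    Path(path).write_text("\n".join(lines) + "\n")
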