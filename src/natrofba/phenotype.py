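"""Phenotype plane analysis: maximum growth over the substrate:O2 ratio
and the maintenance energy.

The two analysis parameters are the acetate fraction
f = acetate / (acetate + O2) of a fixed total uptake (the LP scales
linearly with the total, so only the ratio matters) and the maintenance
energy in µmol ATP per ΔOD·ml.  For each grid cell the growth reaction is
rebuilt with the cell's maintenance term and the steady-state LP is solved
with the growth flux as objective.  From the resulting surface the module
extracts per-maintenance feasibility bounds, the ridge of optimal ratios,
and how close an observed ratio comes to that optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fba import ExchangeSpec, build_flux_problem, solve_flux_problem
from .network import MetabolicNetwork, Reaction


@dataclass
class SweepGrid:
    """Acetate fractions in (0,1) x maintenance values (>= 0), plus the
    total uptake scale (arbitrary; results scale linearly with it)."""

    acetate_fractions: Sequence[float]
    maintenance_values: Sequence[float]
    total_uptake: float = 10.0

    def __post_init__(self) -> None:
        fr = [float(f) for f in self.acetate_fractions]
        mv = [float(m) for m in self.maintenance_values]
        if any(not 0.0 < f < 1.0 for f in fr):
            raise ValueError("acetate fractions must lie strictly within (0, 1)")
        if fr != sorted(fr) or mv != sorted(mv):
            raise ValueError("grid axes must be ascending")
        if any(m < 0 for m in mv):
            raise ValueError("maintenance values must be >= 0")
        if self.total_uptake <= 0:
            raise ValueError("total_uptake must be > 0")
        self.acetate_fractions = fr
        self.maintenance_values = mv


def default_grid(total_uptake: float = 10.0) -> SweepGrid:
    """81 fractions (0.10..0.90, i.e. ratios 1:9 to 9:1) x 21 maintenance
    values (0..100 step 5 µmol ATP per ΔOD·ml)."""
    fractions = [round(0.10 + 0.01 * i, 2) for i in range(81)]
    maintenance = [5.0 * i for i in range(21)]
    return SweepGrid(fractions, maintenance, total_uptake)


@dataclass
class SweepResult:
    """Max-growth surface; ``growth[i][j]`` for maintenance i, fraction j
    (None marks an infeasible cell)."""

    grid: SweepGrid
    growth: list[list[float | None]]

    def growth_array(self) -> np.ndarray:
        return np.array(
            [[math.nan if g is None else g for g in row] for row in self.growth]
        )


class SweepNumericalError(RuntimeError):
    """A sweep cell failed numerically (distinct from proven infeasibility)."""


# -- single-point solve ------------------------------------------------------


def max_growth(
    network: MetabolicNetwork,
    growth_reaction: Reaction,
    acetate_uptake: float,
    o2_uptake: float,
    acetate_id: str = "acetate",
    o2_id: str = "o2",
    ubiquitous: Sequence[str] = ("co2", "h2o"),
    secretion_only: Sequence[str] = ("biomass",),
    abundant: Sequence[str] = (),
    backend: str = "highs",
) -> float | None:
    """Optimal growth flux at fixed acetate and O2 uptakes, or None if the
    uptake pair admits no steady-state flux distribution.

    ``growth_reaction`` (already carrying its maintenance ATP term)
    replaces any same-id reaction in the network.
    """
    if acetate_uptake <= 0 or o2_uptake <= 0:
        raise ValueError("uptakes must be > 0")
    net = MetabolicNetwork(
        metabolites=dict(network.metabolites), reactions=dict(network.reactions)
    )
    net.reactions = dict(net.reactions)
    net.reactions[growth_reaction.id] = growth_reaction
    exchanges = ExchangeSpec(
        ubiquitous=frozenset(ubiquitous),
        parameterized={acetate_id: float(acetate_uptake), o2_id: float(o2_uptake)},
        secretion_only=frozenset(secretion_only),
        abundant=frozenset(abundant),
    )
    problem = build_flux_problem(net, exchanges, growth_reaction.id)
    sol = solve_flux_problem(problem, backend=backend)
    if sol.status == "OPTIMAL":
        return sol.objective_value
    if sol.status == "INFEASIBLE":
        return None
    raise SweepNumericalError(
        f"solver failure at acetate={acetate_uptake}, o2={o2_uptake}: "
        f"{sol.status} {sol.message}"
    )


# -- sweep -------------------------------------------------------------------


def sweep_phenotype(
    network: MetabolicNetwork,
    grid: SweepGrid,
    growth_builder: Callable[[float], Reaction],
    **max_growth_kwargs,
) -> SweepResult:
    """Solve one LP per (maintenance, fraction) cell.

    ``growth_builder(m)`` returns the growth reaction for maintenance m
    (rebuilt once per maintenance row).  Numerical failures raise; they are
    never conflated with proven infeasibility.
    """
    rows: list[list[float | None]] = []
    for m in grid.maintenance_values:
        growth_rxn = growth_builder(m)
        row: list[float | None] = []
        for f in grid.acetate_fractions:
            a = grid.total_uptake * f
            w = grid.total_uptake * (1.0 - f)
            row.append(max_growth(network, growth_rxn, a, w, **max_growth_kwargs))
        rows.append(row)
    return SweepResult(grid=grid, growth=rows)


def composition_growth_builder(
    composition,
    network: MetabolicNetwork,
    component_to_metabolite=None,
    energy_metabolites=None,
    unit_scale: float = 1000.0,
    reaction_id: str = "GROWTH",
) -> Callable[[float], Reaction]:
    """Growth-reaction factory backed by a measured biomass composition:
    each sweep row assembles the growth reaction with that row's
    maintenance (µmol ATP per ΔOD·ml, converted by ``unit_scale``)."""
    from .biomass import GrowthReactionSpec, assemble_growth_reaction

    def build(maintenance: float) -> Reaction:
        return assemble_growth_reaction(
            GrowthReactionSpec(composition, maintenance_atp=maintenance),
            network,
            component_to_metabolite=component_to_metabolite,
            energy_metabolites=energy_metabolites,
            unit_scale=unit_scale,
            reaction_id=reaction_id,
        )

    return build


# -- feasibility bounds ------------------------------------------------------


@dataclass
class FeasibilityBounds:
    """First/last feasible fraction per maintenance row, and the envelope
    (min lower bound, max upper bound) over all rows with any feasible cell."""

    per_row: list[tuple[float, float] | None]
    envelope: tuple[float, float] | None


def feasibility_bounds(sweep: SweepResult) -> FeasibilityBounds:
    per_row: list[tuple[float, float] | None] = []
    lows: list[float] = []
    highs: list[float] = []
    fr = sweep.grid.acetate_fractions
    for row in sweep.growth:
        feas = [fr[j] for j, g in enumerate(row) if g is not None]
        if not feas:
            per_row.append(None)
            continue
        per_row.append((feas[0], feas[-1]))
        lows.append(feas[0])
        highs.append(feas[-1])
    envelope = (min(lows), max(highs)) if lows else None
    return FeasibilityBounds(per_row=per_row, envelope=envelope)


# -- optimality curve --------------------------------------------------------


@dataclass
class CurvePoint:
    maintenance: float
    optimal_fraction: float  # plateau midpoint when ties
    optimal_growth: float
    plateau_interval: tuple[float, float]


@dataclass
class OptimalityCurve:
    points: list[CurvePoint]
    omitted_maintenance: list[float] = field(default_factory=list)

    def optimal_fractions(self) -> list[float]:
        return [p.optimal_fraction for p in self.points]


def optimality_curve(sweep: SweepResult, tie_tol: float = 1e-9) -> OptimalityCurve:
    """Per-maintenance argmax fraction; ties within ``tie_tol`` (relative)
    become a plateau reported by its interval and midpoint.  Rows with no
    feasible cell are omitted and listed."""
    points: list[CurvePoint] = []
    omitted: list[float] = []
    fr = sweep.grid.acetate_fractions
    for m, row in zip(sweep.grid.maintenance_values, sweep.growth):
        feas = [(fr[j], g) for j, g in enumerate(row) if g is not None]
        if not feas:
            omitted.append(m)
            continue
        best = max(g for _, g in feas)
        tol = tie_tol * max(1.0, abs(best))
        plateau = [f for f, g in feas if g >= best - tol]
        points.append(
            CurvePoint(
                maintenance=m,
                optimal_fraction=(plateau[0] + plateau[-1]) / 2.0,
                optimal_growth=best,
                plateau_interval=(plateau[0], plateau[-1]),
            )
        )
    return OptimalityCurve(points=points, omitted_maintenance=omitted)


# -- near-optimality ---------------------------------------------------------


def near_optimality(
    sweep: SweepResult, observed_fraction: float, maintenance: float
) -> float:
    """growth(observed) / growth(optimal) at the nearest maintenance row;
    0.0 when the observed cell is infeasible."""
    fr = sweep.grid.acetate_fractions
    mv = sweep.grid.maintenance_values
    if not fr[0] <= observed_fraction <= fr[-1]:
        raise ValueError("observed_fraction outside grid span")
    if not mv[0] <= maintenance <= mv[-1]:
        raise ValueError("maintenance outside grid span")
    i = min(range(len(mv)), key=lambda k: abs(mv[k] - maintenance))
    j = min(range(len(fr)), key=lambda k: abs(fr[k] - observed_fraction))
    row = sweep.growth[i]
    g_obs = row[j]
    if g_obs is None:
        return 0.0
    feas = [g for g in row if g is not None]
    g_best = max(feas)
    if g_best <= 0:
        return 1.0 if g_obs >= g_best else 0.0
    return g_obs / g_best


# -- maintenance from respiration --------------------------------------------


def estimate_maintenance_energy(
    o2_per_biomass: float, p_o_ratio: float = 1.0, atoms_per_o2: int = 2
) -> float:
    """Maintenance ATP from respiration: O2 consumed per unit biomass gain
    (µmol O2 per ΔOD·ml) times oxygen atoms per O2 times the P:O ratio
    (ATP per O atom).  ``atoms_per_o2=1`` gives the per-O2 reading of P:O.
    """
    if o2_per_biomass < 0 or p_o_ratio < 0 or atoms_per_o2 < 0:
        raise ValueError("inputs must be >= 0")
    return o2_per_biomass * atoms_per_o2 * p_o_ratio
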