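"""Synthetic data: toy networks with closed-form optima, simulated growth
experiments with known ground truth, and a brute-force LP oracle.

The AC-CORE toy network is a stylized aerobic acetate metabolism: acetate
is activated at an ATP cost, fully oxidized for ATP with O2 (releasing
CO2), or incorporated into biomass together with an ATP demand.  Its
stoichiometric parameters are small integers, so the maximum-growth LP has
closed-form solutions that exercise every downstream stage.  The
ATP/ADP/phosphate triple carries real formulas forming an exactly
conserved moiety (ATP = ADP + HPO3), so the toy passes the same
mass/charge audit as a curated reconstruction.

The growth-experiment simulator produces OD/acetate/O2 series whose
carbon fates are set by construction, plus optional Gaussian noise; the
composition simulator produces linear analyte-vs-OD panels.  Both are
seed-deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .carbon import GrowthExperiment
from .biomass import CompositionSample
from .fba import FluxProblem, FluxSolution
from .network import ElementalFormula, MetabolicNetwork, Metabolite, Reaction

# -- toy network -------------------------------------------------------------


@dataclass
class ToyNetworkSpec:
    """Stoichiometric parameters of the AC-CORE toy.

    activation_atp_cost: ATP per acetate activated; atp_per_acetyl_oxidation:
    ATP yielded per acetyl fully oxidized; o2_per_acetyl / co2_per_acetyl:
    respiration stoichiometry; biomass_acetyl / biomass_atp: precursor and
    energy demand per biomass unit.  The ATP sink keeps surplus-energy
    states feasible (a toy-only construct; curated networks dissipate
    surplus through their own cycles).
    """

    activation_atp_cost: float = 1.0
    atp_per_acetyl_oxidation: float = 4.0
    o2_per_acetyl: float = 2.0
    co2_per_acetyl: float = 2.0
    biomass_acetyl: float = 1.0
    biomass_atp: float = 2.0
    include_atp_sink: bool = True

    def __post_init__(self) -> None:
        for name in (
            "activation_atp_cost",
            "atp_per_acetyl_oxidation",
            "o2_per_acetyl",
            "co2_per_acetyl",
            "biomass_acetyl",
            "biomass_atp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _frac(x: float) -> Fraction:
    return Fraction(repr(float(x)))


def generate_toy_network(spec: ToyNetworkSpec | None = None) -> MetabolicNetwork:
    """Build AC-CORE.  Synthetic substrate formulas are chosen so every
    internal reaction is exactly mass and charge balanced for the spec's
    respiration stoichiometry."""
    spec = spec or ToyNetworkSpec()
    q = _frac(spec.activation_atp_cost)
    y = _frac(spec.atp_per_acetyl_oxidation)
    n_o2 = _frac(spec.o2_per_acetyl)
    n_co2 = _frac(spec.co2_per_acetyl)
    b_ac = _frac(spec.biomass_acetyl)
    b_atp = _frac(spec.biomass_atp)

    # acetyl = C_c H4 O_x with x fixed by O balance of
    # acetyl + n O2 -> c CO2 + 2 H2O
    x_o = 2 * n_co2 + 2 - 2 * n_o2
    if x_o < 0:
        raise ValueError("o2_per_acetyl too large for an elementally balanced substrate")
    substrate = ElementalFormula({"C": n_co2, "H": Fraction(4), "O": x_o})
    atp = ElementalFormula.parse("C10H16N5O13P3")
    adp = ElementalFormula.parse("C10H15N5O10P2")
    pi = ElementalFormula.parse("HPO3")

    mets = [
        Metabolite("acetate", "acetate", substrate, 0),
        Metabolite("acetyl", "activated acetate", substrate, 0),
        Metabolite("o2", "dioxygen", ElementalFormula.parse("O2"), 0),
        Metabolite("co2", "carbon dioxide", ElementalFormula.parse("CO2"), 0),
        Metabolite("h2o", "water", ElementalFormula.parse("H2O"), 0),
        Metabolite("atp", "ATP", atp, 0),
        Metabolite("adp", "ADP", adp, 0),
        Metabolite("pi", "phosphate (metaphosphate moiety)", pi, 0),
        Metabolite("biomass", "biomass unit", substrate * b_ac, 0),
    ]
    rxns = [
        Reaction(
            "ACT",
            {"acetate": -1, "atp": -q, "acetyl": 1, "adp": q, "pi": q},
            name="acetate activation",
        ),
        Reaction(
            "OX",
            {
                "acetyl": -1,
                "o2": -n_o2,
                "adp": -y,
                "pi": -y,
                "co2": n_co2,
                "h2o": 2,
                "atp": y,
            },
            name="complete oxidation",
        ),
        Reaction(
            "BIO",
            {"acetyl": -b_ac, "atp": -b_atp, "biomass": 1, "adp": b_atp, "pi": b_atp},
            name="biomass formation",
            kind="GROWTH",
        ),
    ]
    if spec.include_atp_sink:
        rxns.append(
            Reaction("ATPS", {"atp": -1, "adp": 1, "pi": 1}, name="ATP sink (toy-only)")
        )
    for met_id in ("acetate", "o2", "co2", "h2o", "biomass"):
        rxns.append(
            Reaction(
                f"EX_{met_id}",
                {met_id: Fraction(-1)},
                name=f"{met_id} exchange",
                reversible=True,
                kind="EXCHANGE",
            )
        )
    return MetabolicNetwork.from_parts(mets, rxns)


def toy_growth_builder(spec: ToyNetworkSpec | None = None):
    """Growth-reaction factory for sweeps over AC-CORE: maintenance m (ATP
    per biomass unit) is added to the biomass ATP demand."""
    spec = spec or ToyNetworkSpec()

    def build(maintenance: float) -> Reaction:
        demand = _frac(spec.biomass_atp) + _frac(maintenance)
        return Reaction(
            "BIO",
            {
                "acetyl": -_frac(spec.biomass_acetyl),
                "atp": -demand,
                "biomass": 1,
                "adp": demand,
                "pi": demand,
            },
            name="biomass formation",
            kind="GROWTH",
        )

    return build


# -- closed forms ------------------------------------------------------------


def closed_form_max_growth(
    spec: ToyNetworkSpec, acetate_uptake: float, o2_uptake: float, maintenance: float = 0.0
) -> float | None:
    """Analytic optimum of the AC-CORE LP; None where infeasible.

    All O2 must be consumed by oxidation (x = w/n) and all acetate
    activated, so growth g = (a - w/n)/b_ac; the ATP sink absorbs surplus
    energy, so feasibility needs g >= 0 and ATP production >= demand.
    """
    a, w, m = acetate_uptake, o2_uptake, maintenance
    q = spec.activation_atp_cost
    y = spec.atp_per_acetyl_oxidation
    n = spec.o2_per_acetyl
    ox = w / n
    g = (a - ox) / spec.biomass_acetyl
    if g < 0:
        return None
    atp_production = y * ox
    atp_demand = q * a + (spec.biomass_atp + m) * g
    if atp_production < atp_demand - 1e-12:
        return None
    return g


def closed_form_optimal_fraction(spec: ToyNetworkSpec, maintenance: float) -> float:
    """Acetate fraction a*/T maximizing growth at maintenance m: the ATP
    constraint is tight at the optimum, giving
    a*/T = (y + B) / (y + q n + B (n + 1)) with B = (b_atp + m)/b_ac.
    Defaults reduce to (6 + m)/(12 + 3 m)."""
    q = spec.activation_atp_cost
    y = spec.atp_per_acetyl_oxidation
    n = spec.o2_per_acetyl
    B = (spec.biomass_atp + maintenance) / spec.biomass_acetyl
    return (y + B) / (y + q * n + B * (n + 1))


def closed_form_feasible_fraction_interval(
    spec: ToyNetworkSpec, maintenance: float
) -> tuple[float, float]:
    """Feasible acetate-fraction interval [1/(n+1), a*/T] at maintenance m."""
    return (
        1.0 / (spec.o2_per_acetyl + 1.0),
        closed_form_optimal_fraction(spec, maintenance),
    )


# -- growth-experiment simulation --------------------------------------------


@dataclass
class ExperimentParams:
    """Ground truth for a simulated batch culture on acetate.

    The defaults emulate the study conditions: a 35 ml culture, TOC slope
    18.2 mmol C/OD·L, carbon fates 35% incorporated / 63% respired at
    RER 1.  Noise sigmas are per-channel Gaussian; 0 gives an exact,
    closed-ledger series.
    """

    toc_slope: float = 18.2
    incorporation_fraction: float = 0.35
    respiration_fraction: float = 0.63
    rer: float = 1.0
    initial_od: float = 0.1
    initial_acetate_mM: float = 100.0
    volume_ml: float = 35.0
    times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 168, 12))
    growth_rate_per_h: float = 0.02
    sigma_od: float = 0.0
    sigma_acetate_mM: float = 0.0
    sigma_o2_umol: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.incorporation_fraction <= 1 and 0 <= self.respiration_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.incorporation_fraction + self.respiration_fraction > 1:
            raise ValueError("incorporation + respiration fractions exceed 1")
        if min(self.sigma_od, self.sigma_acetate_mM, self.sigma_o2_umol) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.rer <= 0:
            raise ValueError("rer must be > 0")


def simulate_growth_experiment(params: ExperimentParams) -> GrowthExperiment:
    """Exponential-OD batch culture whose carbon ledger is exact by
    construction: per interval, incorporated C = ΔOD x V x TOC slope,
    uptake C = incorporated / incorporation_fraction, respired C =
    respiration_fraction x uptake (converted to O2 through the RER).

    Noise is added per channel (on O2 as truncated interval increments, so
    cumulative O2 stays monotone); a fixed seed reproduces the series
    bit-for-bit.
    """
    p = params
    times = np.asarray(p.times_h, float)
    od_true = p.initial_od * np.exp(p.growth_rate_per_h * (times - times[0]))
    v_l = p.volume_ml / 1000.0

    inc_C = np.diff(od_true) * v_l * p.toc_slope * 1000.0  # µmol C per interval
    uptake_C = inc_C / p.incorporation_fraction
    resp_C = p.respiration_fraction * uptake_C
    acetate_consumed_umol = uptake_C / 2.0
    o2_increments = resp_C / p.rer

    acetate_mM = p.initial_acetate_mM - np.concatenate(
        [[0.0], np.cumsum(acetate_consumed_umol)]
    ) / p.volume_ml
    if acetate_mM[-1] < 0:
        raise ValueError("initial_acetate_mM too low: medium runs out of acetate")
    o2_cum = np.concatenate([[0.0], np.cumsum(o2_increments)])

    rng = np.random.default_rng(p.seed)
    od = od_true + rng.normal(0.0, p.sigma_od, size=len(times))
    od = np.maximum(od, 1e-6)
    acetate_mM = np.maximum(
        acetate_mM + rng.normal(0.0, p.sigma_acetate_mM, size=len(times)), 0.0
    )
    noisy_incr = np.maximum(
        o2_increments + rng.normal(0.0, p.sigma_o2_umol, size=len(o2_increments)), 0.0
    )
    o2_cum = np.concatenate([[0.0], np.cumsum(noisy_incr)])
    return GrowthExperiment(
        times_h=times,
        od=od,
        acetate_mM=acetate_mM,
        o2_cum_umol=o2_cum,
        volume_ml=p.volume_ml,
    )


def simulate_composition_samples(
    slopes: dict[str, float],
    ods: list[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> list[CompositionSample]:
    """Linear analyte panels: value = slope x od + N(0, sigma), floored at 0."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for od in ods:
        values = {
            a: max(0.0, s * od + (rng.normal(0.0, sigma) if sigma > 0 else 0.0))
            for a, s in sorted(slopes.items())
        }
        out.append(CompositionSample(od=od, values=values))
    return out


# -- brute-force LP oracle ---------------------------------------------------


class OracleDimensionError(ValueError):
    """The instance is too large for exhaustive vertex enumeration."""


def brute_force_lp(
    problem: FluxProblem, max_dims: int = 8, tol: float = 1e-8
) -> FluxSolution:
    """Exhaustive vertex enumeration of the FBA polytope (oracle only).

    Equality constraints are the steady-state rows plus any fixed-flux
    bounds; every subset of the remaining finite bound constraints of the
    right size is activated in turn and the resulting linear system solved
    and checked.  Returns the best vertex or INFEASIBLE when no subset
    yields a feasible point.  Assumes the optimum is attained at a vertex
    (true for the pointed toy instances this oracle serves); refuses
    instances with more than ``max_dims`` degrees of freedom.
    """
    rxn_ids = problem.matrix.reaction_ids
    n = len(rxn_ids)
    S = problem.matrix.S

    eq_rows = [S[i, :] for i in range(S.shape[0])]
    eq_rhs = [0.0] * S.shape[0]
    ineq: list[tuple[int, float, int]] = []  # (var, bound value, sign: +1 lower, -1 upper)
    for j, rid in enumerate(rxn_ids):
        lo, hi = problem.bounds[rid]
        if lo is not None and hi is not None and lo == hi:
            row = np.zeros(n)
            row[j] = 1.0
            eq_rows.append(row)
            eq_rhs.append(lo)
            continue
        if lo is not None:
            ineq.append((j, lo, +1))
        if hi is not None:
            ineq.append((j, hi, -1))

    A = np.array(eq_rows)
    b = np.array(eq_rhs)
    rank = np.linalg.matrix_rank(A)
    free = n - rank
    if free > max_dims:
        raise OracleDimensionError(f"{free} degrees of freedom exceed max_dims={max_dims}")

    c = np.zeros(n)
    for rid, w in problem.objective.items():
        c[rxn_ids.index(rid)] = w

    def feasible(x: np.ndarray) -> bool:
        if np.max(np.abs(A @ x - b)) > tol * max(1.0, np.abs(b).max(initial=1.0)):
            return False
        for j, val, sign in ineq:
            if sign * (x[j] - val) < -tol:
                return False
        return True

    best_x = None
    best_obj = -np.inf
    for active in itertools.combinations(range(len(ineq)), free):
        rows = [A]
        rhs = [b]
        for k in active:
            j, val, _ = ineq[k]
            row = np.zeros(n)
            row[j] = 1.0
            rows.append(row[None, :])
            rhs.append([val])
        M = np.vstack(rows)
        r = np.concatenate(rhs)
        if np.linalg.matrix_rank(M) < n:
            continue
        x, *_ = np.linalg.lstsq(M, r, rcond=None)
        if np.max(np.abs(M @ x - r)) > tol * max(1.0, np.abs(r).max(initial=1.0)):
            continue
        if feasible(x):
            obj = float(c @ x)
            if obj > best_obj:
                best_obj = obj
                best_x = x
    if best_x is None:
        return FluxSolution(status="INFEASIBLE", message="no feasible vertex")
    return FluxSolution(
        status="OPTIMAL",
        v={rid: float(best_x[i]) for i, rid in enumerate(rxn_ids)},
        objective_value=best_obj,
    )
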