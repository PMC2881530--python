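"""Biomass composition analysis and growth-reaction assembly.

The growth (biomass) pseudo-reaction consumes precursors in measured
ratios and produces one unit of population; its flux is the growth-rate
proxy in flux balance analysis.  Coefficients are derived from culture
measurements taken at several optical densities:

* bulk carbon: total-organic-carbon (TOC) vs. OD regression through the
  origin, in mmol C per OD·L;
* amino acids: per-analyte slopes vs. OD; analytically combined pools
  (Asp+Asn, Glu+Gln) are split by proteome frequency, and analytes that
  cannot be measured (Cys, Trp) are estimated from proteome frequencies
  relative to the measured total;
* nucleotides: a pooled amount (fixed fraction of TOC, or the residual
  carbon after the other components) allocated to the four NMP+dNMP pairs
  by a configurable AT share;
* minor components (lipids, S-layer sugars, free ATP): reference values
  from a related halophile, scaled by the ratio of measured amino-acid
  content.

Maintenance energy — ATP hydrolysed per unit biomass formed over and above
biosynthesis — enters the growth reaction as an extra ATP term.  The
canonical biomass unit is OD·L; maintenance stated per ΔOD·ml converts by
a factor of 1000.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import EMPTY_LOGIC, Evidence, MetabolicNetwork, Reaction

PROVENANCES = (
    "MEASURED",
    "SPLIT_FROM_POOL",
    "PROTEOME_ESTIMATED",
    "GC_ALLOCATED",
    "REFERENCE_SCALED",
    "FIXED",
)

#: reference minor-component coefficients (µmol per OD·L), already scaled to
#: this organism's amino-acid content; see scale_reference_components.
DEFAULT_REFERENCE_COMPONENTS = {
    "archaeol": 20.0,
    "GalNAc": 2.2,
    "GlcNAc": 2.2,
    "Gal": 9.6,
    "Glc": 9.6,
    "ATP": 2.0,
}

#: intracellular salt per biomass unit (µmol per OD·L); Na+ (or K+) and Cl-
DEFAULT_SALT_UMOL = 2813.4

#: default AT share of the nucleotide pool (matches the published growth
#: reaction's 81.6 : 47.1 split between the A- and G-pairs)
DEFAULT_SPLIT_FRACTION_AT = 0.634


@dataclass
class CompositionSample:
    """One culture sample: optical density and per-analyte amounts."""

    od: float
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.od <= 0:
            raise ValueError("od must be > 0")
        for k, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative amount for analyte {k!r}")


@dataclass
class LinearFit:
    """Through-origin regression result: slope ± stderr over n samples."""

    slope: float
    stderr: float
    n: int


@dataclass
class BiomassComposition:
    """Per-component coefficients (µmol per OD·L) with provenance tags."""

    coefficients: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, component: str, value: float, provenance: str) -> None:
        if value < 0:
            raise ValueError(f"negative coefficient for {component!r}")
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        self.coefficients[component] = float(value)
        self.provenance[component] = provenance

    def update(self, values: Mapping[str, float], provenance: str) -> None:
        for k, v in values.items():
            self.set(k, v, provenance)

    def total(self) -> float:
        return float(sum(self.coefficients.values()))


@dataclass
class GrowthReactionSpec:
    """Composition plus a maintenance-ATP term (µmol ATP per ΔOD·ml)."""

    composition: BiomassComposition
    maintenance_atp: float = 0.0
    biomass_unit: str = "OD*L"

    def __post_init__(self) -> None:
        if self.maintenance_atp < 0:
            raise ValueError("maintenance_atp must be >= 0")


# -- regression --------------------------------------------------------------


def fit_through_origin(samples: Sequence[tuple[float, float]]) -> LinearFit:
    """Least-squares slope of amount vs. OD constrained through the origin.

    The zero intercept encodes "no biomass at zero optical density".
    stderr is the slope's standard error from the residuals (n-1 dof).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    x = np.asarray([s[0] for s in samples], float)
    y = np.asarray([s[1] for s in samples], float)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("degenerate input: all od values are 0")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    s2 = float(resid @ resid) / (len(x) - 1)
    return LinearFit(slope=slope, stderr=math.sqrt(s2 / sxx), n=len(x))


def fit_amino_acid_slopes(samples: Sequence[CompositionSample]) -> dict[str, LinearFit]:
    """One through-origin fit per analyte across samples.

    All samples must report the same analyte set; pooled analytes such as
    "Asp+Asn" are ordinary keys here and are split downstream.
    """
    if not samples:
        raise ValueError("no samples")
    analytes = set(samples[0].values)
    for s in samples[1:]:
        if set(s.values) != analytes:
            raise ValueError("inconsistent analyte sets across samples")
    return {
        a: fit_through_origin([(s.od, s.values[a]) for s in samples]) for a in sorted(analytes)
    }


# -- pool splitting and estimation -------------------------------------------


def split_combined_pool(
    pool_total: float, member_freqs: Mapping[str, float]
) -> dict[str, float]:
    """Split a combined measurement by relative proteome abundance.

    Shares are total x freq / sum(freq) and sum to the input exactly.
    """
    freqs = {k: float(v) for k, v in member_freqs.items()}
    if any(v < 0 for v in freqs.values()):
        raise ValueError("negative frequency")
    total_freq = sum(freqs.values())
    if total_freq == 0:
        raise ValueError("all member frequencies are zero")
    # divide first: keeps shares exact even for subnormal frequencies
    return {k: pool_total * (v / total_freq) for k, v in freqs.items()}


def estimate_unmeasured_aa(
    measured: Mapping[str, float],
    proteome_freqs: Mapping[str, float],
    targets: Iterable[str] = ("Cys", "Trp"),
) -> dict[str, float]:
    """Estimate unmeasurable amino acids from proteome frequencies.

    target = (sum of measured amounts) x freq_target / (sum of freqs over
    the measured amino acids).
    """
    targets = list(targets)
    if not measured:
        raise ValueError("empty measured set")
    overlap = set(targets) & set(measured)
    if overlap:
        raise ValueError(f"targets {sorted(overlap)} already measured")
    measured_total = sum(measured.values())
    freq_measured = sum(proteome_freqs.get(a, 0.0) for a in measured)
    if freq_measured == 0:
        raise ValueError("zero total frequency over measured amino acids")
    return {t: measured_total * proteome_freqs.get(t, 0.0) / freq_measured for t in targets}


def allocate_nucleotides(
    nucleotide_pool: float, split_fraction_AT: float = DEFAULT_SPLIT_FRACTION_AT
) -> dict[str, float]:
    """Allocate a total nucleotide pool to the four NMP+dNMP pairs.

    The A and T/U pairs each get split_fraction_AT/2 of the pool, the G and
    C pairs (1-split_fraction_AT)/2; the four coefficients sum to the pool.
    """
    if not 0.0 <= split_fraction_AT <= 1.0:
        raise ValueError("split_fraction_AT must be in [0, 1]")
    if nucleotide_pool < 0:
        raise ValueError("negative nucleotide pool")
    at = nucleotide_pool * split_fraction_AT / 2.0
    gc = nucleotide_pool * (1.0 - split_fraction_AT) / 2.0
    return {"AMP+dAMP": at, "UMP+dTMP": at, "GMP+dGMP": gc, "CMP+dCMP": gc}


def residual_nucleotide_pool(
    toc_slope: float,
    composition_so_far: BiomassComposition | None = None,
    carbon_per_component: Mapping[str, float] | None = None,
    assumed_fraction: float = 0.2,
    mean_carbon_per_nucleotide: float = 9.66,
    mode: str = "fraction",
) -> float:
    """Total nucleotide pool in µmol/OD·L from the TOC budget.

    mode="fraction": the pool carries ``assumed_fraction`` of the TOC
    carbon (toc_slope, mmol C/OD·L).  mode="residual": the pool carries
    whatever carbon the other components leave over.  Either carbon amount
    is divided by the mean carbon per nucleotide to give moles.
    """
    if toc_slope < 0:
        raise ValueError("negative toc_slope")
    if mode == "fraction":
        if not 0.0 <= assumed_fraction <= 1.0:
            raise ValueError("assumed_fraction must be in [0, 1]")
        carbon_mmol = toc_slope * assumed_fraction
    elif mode == "residual":
        if composition_so_far is None or carbon_per_component is None:
            raise ValueError("residual mode needs composition_so_far and carbon_per_component")
        used_mmol = sum(
            coeff * carbon_per_component.get(comp, 0.0) / 1000.0
            for comp, coeff in composition_so_far.coefficients.items()
        )
        carbon_mmol = toc_slope - used_mmol
        if carbon_mmol < -1e-9:
            raise ValueError(
                f"negative residual carbon: components consume {used_mmol:.4f} mmol C "
                f"vs TOC {toc_slope:.4f} mmol C per OD*L"
            )
        carbon_mmol = max(carbon_mmol, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return carbon_mmol / mean_carbon_per_nucleotide * 1000.0


def scale_reference_components(
    reference: Mapping[str, float], aa_ratio: float
) -> dict[str, float]:
    """Scale reference coefficients by the between-organism amino-acid ratio."""
    if aa_ratio <= 0:
        raise ValueError("aa_ratio must be > 0")
    return {k: float(v) * aa_ratio for k, v in reference.items()}


DEFAULT_COMBINED_POOLS = {"Asp+Asn": ("Asp", "Asn"), "Glu+Gln": ("Glu", "Gln")}


def build_full_composition(
    aa_slopes: Mapping[str, float],
    proteome_freqs: Mapping[str, float],
    toc_slope: float,
    split_fraction_AT: float = DEFAULT_SPLIT_FRACTION_AT,
    nucleotide_fraction: float = 0.2,
    mean_carbon_per_nucleotide: float = 9.66,
    reference_components: Mapping[str, float] = DEFAULT_REFERENCE_COMPONENTS,
    reference_aa_ratio: float = 1.0,
    salt_umol: float = DEFAULT_SALT_UMOL,
    combined_pools: Mapping[str, Sequence[str]] = DEFAULT_COMBINED_POOLS,
    estimate_targets: Sequence[str] = ("Cys", "Trp"),
) -> BiomassComposition:
    """Assemble a complete biomass composition from its inputs.

    Measured amino-acid slopes (µmol/OD·L) enter directly; combined pools
    (e.g. Asp+Asn) are split by proteome frequency; unmeasurable residues
    (Cys, Trp) are estimated from the measured total; the nucleotide pool
    takes ``nucleotide_fraction`` of the TOC carbon and is allocated to
    the four NMP+dNMP pairs; reference minor components are scaled by the
    amino-acid content ratio; Na+/K+ and Cl- salt terms are fixed.
    """
    comp = BiomassComposition()
    measured_aa: dict[str, float] = {}
    for analyte, slope in aa_slopes.items():
        if analyte in combined_pools:
            shares = split_combined_pool(
                slope, {m: proteome_freqs[m] for m in combined_pools[analyte]}
            )
            for member, value in shares.items():
                comp.set(member, value, "SPLIT_FROM_POOL")
                measured_aa[member] = value
        else:
            comp.set(analyte, slope, "MEASURED")
            measured_aa[analyte] = slope
    estimated = estimate_unmeasured_aa(measured_aa, proteome_freqs, estimate_targets)
    comp.update(estimated, "PROTEOME_ESTIMATED")

    pool = residual_nucleotide_pool(
        toc_slope,
        assumed_fraction=nucleotide_fraction,
        mean_carbon_per_nucleotide=mean_carbon_per_nucleotide,
        mode="fraction",
    )
    comp.update(allocate_nucleotides(pool, split_fraction_AT), "GC_ALLOCATED")

    scaled = scale_reference_components(reference_components, reference_aa_ratio)
    for name, value in scaled.items():
        comp.set(name, value, "FIXED" if name == "ATP" else "REFERENCE_SCALED")
    comp.set("Na+(K+)", salt_umol, "FIXED")
    comp.set("Cl-", salt_umol, "FIXED")
    return comp


# -- growth reaction ---------------------------------------------------------

DEFAULT_ENERGY_METABOLITES = {
    "atp": "atp",
    "adp": "adp",
    "phosphate": "pi",
    "water": "h2o",
    "biomass": "biomass",
}

#: ΔOD·ml per OD·L
OD_ML_PER_OD_L = 1000.0


class UnmappedComponentError(KeyError):
    """A composition component has no metabolite mapping in the network."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(f"unmapped biomass components: {', '.join(self.missing)}")


def assemble_growth_reaction(
    spec: GrowthReactionSpec,
    network: MetabolicNetwork,
    component_to_metabolite: Mapping[str, str] | None = None,
    energy_metabolites: Mapping[str, str] | None = None,
    unit_scale: float = OD_ML_PER_OD_L,
    reaction_id: str = "GROWTH",
) -> Reaction:
    """Assemble the irreversible growth pseudo-reaction.

    Consumes each composition component (coefficient in µmol/OD·L) plus the
    maintenance ATP-hydrolysis term (maintenance_atp x unit_scale, i.e.
    per-ΔOD·ml converted to the OD·L biomass unit, with matching H2O
    consumption and ADP/phosphate production), and produces one biomass
    unit.  Component ids are mapped to network metabolite ids through
    ``component_to_metabolite`` (identity for ids already in the network).
    """
    mapping = dict(component_to_metabolite or {})
    energy = dict(DEFAULT_ENERGY_METABOLITES)
    if energy_metabolites:
        energy.update(energy_metabolites)

    stoich: dict[str, Fraction] = {}
    missing: list[str] = []
    for comp, coeff in spec.composition.coefficients.items():
        met_id = mapping.get(comp, comp if comp in network.metabolites else None)
        if met_id is None or met_id not in network.metabolites:
            missing.append(comp)
            continue
        stoich[met_id] = stoich.get(met_id, Fraction(0)) - Fraction(repr(float(coeff)))
    if missing:
        raise UnmappedComponentError(sorted(missing))

    hydrolysis = Fraction(repr(float(spec.maintenance_atp))) * Fraction(repr(float(unit_scale)))
    if hydrolysis > 0:
        for role, sign in (("atp", -1), ("water", -1), ("adp", +1), ("phosphate", +1)):
            met_id = energy[role]
            if met_id not in network.metabolites:
                raise UnmappedComponentError([f"{role} ({met_id})"])
            stoich[met_id] = stoich.get(met_id, Fraction(0)) + sign * hydrolysis

    biomass_id = energy["biomass"]
    if biomass_id not in network.metabolites:
        raise UnmappedComponentError([f"biomass ({biomass_id})"])
    stoich[biomass_id] = stoich.get(biomass_id, Fraction(0)) + Fraction(1)

    return Reaction(
        id=reaction_id,
        name="growth pseudo-reaction",
        stoichiometry=stoich,
        reversible=False,
        kind="GROWTH",
        gene_logic=EMPTY_LOGIC,
        evidence=Evidence(),
        category="growth",
    )


def write_composition_report(composition: BiomassComposition, path: str | Path) -> None:
    """TSV report: component, coefficient (µmol/OD·L), provenance."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["component", "umol_per_od_l", "provenance"])
        for comp in sorted(composition.coefficients):
            w.writerow(
                [comp, repr(composition.coefficients[comp]), composition.provenance[comp]]
            )
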