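"""Readers and writers: reaction-equation strings, SBML, tabular networks,
growth-series CSV and sweep result tables.

All readers are total over their accepted dialects: every input either
yields a value or raises a located error (tabular rows that fail to parse
are collected into a rejects report rather than silently dropped).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .network import (
    UNKNOWN,
    ElementalFormula,
    Evidence,
    GeneLogic,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    parse_gene_logic,
    render_gene_logic,
)

# -- reaction-equation strings -----------------------------------------------


class EquationError(ValueError):
    """Raised for a malformed reaction-equation string."""


_ARROWS = ("<=>", "=>")
_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)$")


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"2 A + B => C"`` into (stoichiometry, reversible).

    Coefficient omitted means 1; ``<=>`` marks a reversible reaction.
    Metabolite tokens may carry a ``[compartment]`` suffix, which stays part
    of the token.  An empty side is allowed (boundary reactions).
    """
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise EquationError(f"no arrow ('=>' or '<=>') in equation {text!r}")
    lhs_text, rhs_text = text.split(arrow, 1)
    if any(a in rhs_text for a in _ARROWS):
        raise EquationError(f"multiple arrows in equation {text!r}")

    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            m = _TERM.match(term)
            if m is None:
                raise EquationError(f"cannot parse term {term!r} in equation {text!r}")
            coeff_text, met = m.groups()
            coeff = Fraction(coeff_text) if coeff_text else Fraction(1)
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff
    add_side(lhs_text, -1)
    add_side(rhs_text, +1)
    return stoich, arrow == "<=>"


def _coeff_str(c: Fraction) -> str:
    c = abs(c)
    if c.denominator == 1:
        return "" if c == 1 else f"{c.numerator} "
    return f"{c} "


def render_equation(stoichiometry: dict[str, Fraction], reversible: bool) -> str:
    """Inverse of :func:`parse_equation` (round-trips exactly)."""
    lhs = [f"{_coeff_str(c)}{m}" for m, c in stoichiometry.items() if c < 0]
    rhs = [f"{_coeff_str(c)}{m}" for m, c in stoichiometry.items() if c > 0]
    arrow = "<=>" if reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# -- SBML --------------------------------------------------------------------

# Notes-field conventions of 2010-era constraint-based models: formula,
# charge, gene association and curation metadata travel in COBRA-style
# KEY: value note lines.

_SID_SAFE = re.compile(r"[A-Za-z0-9_]")


def _encode_sid(prefix: str, raw: str) -> str:
    out = [prefix]
    for ch in raw:
        out.append(ch if _SID_SAFE.match(ch) else f"__{ord(ch)}__")
    return "".join(out)


def _decode_sid(prefix: str, sid: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return re.sub(r"__(\d+)__", lambda m: chr(int(m.group(1))), sid)


class SBMLError(ValueError):
    """Raised for malformed or unsupported SBML input."""


def _import_libsbml():
    import libsbml

    return libsbml


def _notes_dict(notes_text: str | None) -> dict[str, str]:
    out: dict[str, str] = {}
    if not notes_text:
        return out
    for m in re.finditer(r">\s*([A-Z_]+):\s*([^<]*?)\s*<", notes_text):
        out[m.group(1)] = m.group(2)
    return out


def _set_notes(libsbml, node, pairs: dict[str, str]) -> None:
    lines = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items() if v != "")
    if lines:
        node.setNotes(f'<body xmlns="http://www.w3.org/1999/xhtml">{lines}</body>')


def write_sbml_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Serialize to SBML L3V1; formula/charge/GPR/evidence in notes.

    UNKNOWN formulas/charges simply omit their note line, so they read back
    as UNKNOWN.  Stoichiometric coefficients are written as decimal floats;
    the round-trip is exact for coefficients with finite decimal expansion.
    """
    libsbml = _import_libsbml()
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("model")

    compartments = sorted({m.compartment for m in network.metabolites.values()} | {"c"})
    for comp in compartments:
        c = model.createCompartment()
        c.setId(_encode_sid("", comp) or "c")
        c.setConstant(True)

    for met in network.metabolites.values():
        sp = model.createSpecies()
        sp.setId(_encode_sid("M_", met.id))
        sp.setName(met.name)
        sp.setCompartment(_encode_sid("", met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        notes = {}
        if met.formula is not UNKNOWN:
            notes["FORMULA"] = str(met.formula)
        if met.charge is not UNKNOWN:
            notes["CHARGE"] = str(met.charge)
        _set_notes(libsbml, sp, notes)

    for rxn in network.reactions.values():
        rx = model.createReaction()
        rx.setId(_encode_sid("R_", rxn.id))
        rx.setName(rxn.name)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(_encode_sid("M_", met_id))
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
        notes = {
            "GENE_ASSOCIATION": render_gene_logic(rxn.gene_logic),
            "KIND": rxn.kind,
            "EVIDENCE_CLASS": rxn.evidence.genetic_class,
            "LITERATURE": "1" if rxn.evidence.literature else "0",
            "GAP_FILL": "1" if rxn.evidence.gap_fill else "0",
            "CATEGORY": rxn.category,
        }
        _set_notes(libsbml, rx, notes)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


def read_sbml_network(path: str | Path) -> MetabolicNetwork:
    """Read an SBML L2/L3 model into a :class:`MetabolicNetwork`.

    Species without formula/charge annotations get UNKNOWN; boundary
    species are mapped to the extracellular compartment "e"; gene
    associations are read from notes when present, else EMPTY.
    """
    libsbml = _import_libsbml()
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLError(f"SBML parse error in {path}: {err.getMessage() if err else 'unknown'}")
    model = doc.getModel()
    if model is None:
        raise SBMLError(f"no model element in {path}")
    if doc.getLevel() not in (2, 3):
        raise SBMLError(f"unsupported SBML level {doc.getLevel()} (need 2 or 3)")

    mets: list[Metabolite] = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        notes = _notes_dict(sp.getNotesString() if sp.isSetNotes() else None)
        formula = ElementalFormula.parse(notes["FORMULA"]) if notes.get("FORMULA") else UNKNOWN
        charge = int(notes["CHARGE"]) if notes.get("CHARGE") else UNKNOWN
        # pre-fbc models may carry the deprecated species charge attribute
        if charge is UNKNOWN and hasattr(sp, "isSetCharge") and sp.isSetCharge():
            charge = sp.getCharge()
        comp = _decode_sid("", sp.getCompartment())
        if sp.getBoundaryCondition():
            comp = "e"
        mets.append(
            Metabolite(
                id=_decode_sid("M_", sp.getId()),
                name=sp.getName(),
                formula=formula,
                charge=charge,
                compartment=comp,
            )
        )

    rxns: list[Reaction] = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        notes = _notes_dict(rx.getNotesString() if rx.isSetNotes() else None)
        stoich: dict[str, Fraction] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _decode_sid("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, Fraction(0)) - Fraction(repr(ref.getStoichiometry()))
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _decode_sid("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, Fraction(0)) + Fraction(repr(ref.getStoichiometry()))
        gpr_text = notes.get("GENE_ASSOCIATION", "")
        kind = notes.get("KIND")
        if kind is None:
            kind = "EXCHANGE" if len(stoich) == 1 else "INTERNAL"
        rxns.append(
            Reaction(
                id=_decode_sid("R_", rx.getId()),
                name=rx.getName(),
                stoichiometry=stoich,
                reversible=rx.getReversible(),
                kind=kind,
                gene_logic=parse_gene_logic(gpr_text) if gpr_text else GeneLogic(None),
                evidence=Evidence(
                    genetic_class=notes.get("EVIDENCE_CLASS", "NONE"),
                    literature=notes.get("LITERATURE", "0") == "1",
                    gap_fill=notes.get("GAP_FILL", "0") == "1",
                ),
                category=notes.get("CATEGORY", ""),
            )
        )
    return MetabolicNetwork.from_parts(mets, rxns)


# -- tabular networks --------------------------------------------------------

DEFAULT_TABLE_COLUMNS = {
    "id": "id",
    "name": "name",
    "equation": "equation",
    "genes": "genes",
    "evidence_class": "evidence_class",
    "literature": "literature",
    "gap_fill": "gap_fill",
    "category": "category",
    "kind": "kind",
}


@dataclass
class TableReject:
    row: int
    reason: str


@dataclass
class NetworkTableResult:
    network: MetabolicNetwork
    rejects: list[TableReject] = field(default_factory=list)


class TableConfigError(ValueError):
    """Raised when mandatory columns are missing from a network table."""


def read_network_table(
    path: str | Path,
    columns: dict[str, str] | None = None,
    metabolite_table: str | Path | None = None,
    sep: str | None = None,
) -> NetworkTableResult:
    """Read a delimited reaction table (spreadsheet export) into a network.

    ``columns`` remaps logical column names (see DEFAULT_TABLE_COLUMNS) to
    the file's headers; only ``id`` and ``equation`` are mandatory.
    Metabolites are declared implicitly by the equations (formula/charge
    UNKNOWN) unless ``metabolite_table`` (columns: id, name, formula,
    charge, compartment) supplies annotations.  Rows that fail to parse go
    to the rejects report.
    """
    cols = dict(DEFAULT_TABLE_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, comment="#").fillna("")
    for mandatory in ("id", "equation"):
        if cols[mandatory] not in df.columns:
            raise TableConfigError(f"missing mandatory column {cols[mandatory]!r} in {path}")

    def col(row, key, default=""):
        name = cols.get(key)
        return str(row[name]).strip() if name in df.columns else default

    annotations: dict[str, Metabolite] = {}
    if metabolite_table is not None:
        mdf = pd.read_csv(metabolite_table, sep=sep, engine="python", dtype=str).fillna("")
        for _, row in mdf.iterrows():
            mid = str(row["id"]).strip()
            annotations[mid] = Metabolite(
                id=mid,
                name=str(row.get("name", "")).strip(),
                formula=(
                    ElementalFormula.parse(str(row["formula"]).strip())
                    if str(row.get("formula", "")).strip()
                    else UNKNOWN
                ),
                charge=(
                    int(str(row["charge"]).strip()) if str(row.get("charge", "")).strip() else UNKNOWN
                ),
                compartment=str(row.get("compartment", "c")).strip() or "c",
            )

    rejects: list[TableReject] = []
    reactions: list[Reaction] = []
    met_ids: set[str] = set()
    seen_rxn: set[str] = set()
    for idx, row in df.iterrows():
        rid = col(row, "id")
        try:
            if not rid:
                raise EquationError("empty reaction id")
            if rid in seen_rxn:
                raise EquationError(f"duplicate reaction id {rid!r}")
            stoich, reversible = parse_equation(col(row, "equation"))
            kind = col(row, "kind") or ("EXCHANGE" if len(stoich) == 1 else "INTERNAL")
            genes_text = col(row, "genes")
            evidence = Evidence(
                genetic_class=col(row, "evidence_class") or "NONE",
                literature=col(row, "literature") in ("1", "true", "True", "yes"),
                gap_fill=col(row, "gap_fill") in ("1", "true", "True", "yes"),
            )
            reactions.append(
                Reaction(
                    id=rid,
                    name=col(row, "name"),
                    stoichiometry=stoich,
                    reversible=reversible,
                    kind=kind,
                    gene_logic=parse_gene_logic(genes_text),
                    evidence=evidence,
                    category=col(row, "category"),
                )
            )
            seen_rxn.add(rid)
            met_ids.update(stoich)
        except (EquationError, ValueError) as exc:
            rejects.append(TableReject(row=int(idx), reason=str(exc)))

    mets = [
        annotations.get(mid, Metabolite(id=mid, compartment="e" if mid.endswith("[e]") else "c"))
        for mid in sorted(met_ids)
    ]
    return NetworkTableResult(MetabolicNetwork.from_parts(mets, reactions), rejects)


# -- growth-series CSV -------------------------------------------------------

GROWTH_SERIES_COLUMNS = ("time_h", "od", "acetate_mM", "o2_cum_umol", "volume_ml")


class GrowthSeriesError(ValueError):
    """Raised for a malformed growth-series file."""


def read_growth_series(path: str | Path):
    """Read a growth-experiment CSV (time_h, od, acetate_mM, o2_cum_umol,
    volume_ml; rows time-sorted) into a :class:`~natrofba.carbon.GrowthExperiment`."""
    from .carbon import GrowthExperiment

    df = pd.read_csv(path, comment="#")
    missing = [c for c in GROWTH_SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise GrowthSeriesError(f"missing columns {missing} in {path}")
    times = df["time_h"].to_numpy(float)
    if len(times) >= 2 and not (times[1:] > times[:-1]).all():
        raise GrowthSeriesError(f"time_h not strictly increasing in {path}")
    volumes = df["volume_ml"].to_numpy(float)
    return GrowthExperiment(
        times_h=times,
        od=df["od"].to_numpy(float),
        acetate_mM=df["acetate_mM"].to_numpy(float),
        o2_cum_umol=df["o2_cum_umol"].to_numpy(float),
        volume_ml=volumes,
    )


def write_growth_series(experiment, path: str | Path) -> None:
    """Inverse of :func:`read_growth_series`."""
    pd.DataFrame(
        {
            "time_h": experiment.times_h,
            "od": experiment.od,
            "acetate_mM": experiment.acetate_mM,
            "o2_cum_umol": experiment.o2_cum_umol,
            "volume_ml": experiment.volume_ml,
        }
    ).to_csv(path, index=False)


# -- sweep result tables -----------------------------------------------------


def write_sweep_table(sweep, path: str | Path) -> None:
    """Write a phenotype sweep as TSV, one row per grid cell,
    maintenance-major order; columns: maintenance, acetate_fraction,
    status, growth (empty growth for infeasible cells)."""
    import math

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["maintenance", "acetate_fraction", "status", "growth"])
        for i, m in enumerate(sweep.grid.maintenance_values):
            for j, f in enumerate(sweep.grid.acetate_fractions):
                g = sweep.growth[i][j]
                feasible = g is not None and not (isinstance(g, float) and math.isnan(g))
                w.writerow(
                    [
                        repr(float(m)),
                        repr(float(f)),
                        "OPTIMAL" if feasible else "INFEASIBLE",
                        repr(float(g)) if feasible else "",
                    ]
                )
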