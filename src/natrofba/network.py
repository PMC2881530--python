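"""Core data model for curated metabolic reconstructions.

A reconstruction is a set of metabolites (with elemental formula and
ionization state, here taken as annotated at the organism's growth pH) and
reactions (stoichiometry over metabolite ids, reversibility, gene logic and
curation evidence).  The module provides structural validation, exact
mass/charge balance auditing, boolean gene-logic evaluation and evidence
tabulation.

Coefficients and element counts are exact :class:`fractions.Fraction`
values throughout, so balance sums never suffer float drift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

Number = Union[int, Fraction]

# -- elemental formulas ------------------------------------------------------

_ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for an unparseable formula or an unknown element symbol."""


@dataclass(frozen=True)
class ElementalFormula:
    """Multiset of chemical elements; supports exact addition and scaling.

    Absent elements are count zero.  Counts may be any non-negative exact
    number (fractional counts arise only as intermediates of balance sums).
    """

    element_counts: Mapping[str, Number]

    def __post_init__(self) -> None:
        cleaned = {}
        for sym, n in self.element_counts.items():
            if sym not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol {sym!r}")
            n = Fraction(n)
            if n < 0:
                raise FormulaError(f"negative count for element {sym}")
            if n != 0:
                cleaned[sym] = n
        object.__setattr__(self, "element_counts", cleaned)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C2H3O2``."""
        counts: dict[str, Fraction] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            sym, digits = m.groups()
            if sym not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
            counts[sym] = counts.get(sym, Fraction(0)) + Fraction(int(digits) if digits else 1)
            pos = m.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __getitem__(self, element: str) -> Fraction:
        return self.element_counts.get(element, Fraction(0))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            counts[sym] = counts.get(sym, Fraction(0)) + n
        return ElementalFormula(counts)

    def __mul__(self, k: Number) -> "ElementalFormula":
        k = Fraction(k)
        return ElementalFormula({s: n * k for s, n in self.element_counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        parts = []
        for sym in sorted(self.element_counts):
            n = self.element_counts[sym]
            n = int(n) if n.denominator == 1 else n
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)


#: sentinel for a metabolite whose formula or charge was not annotated
UNKNOWN = None


@dataclass
class Metabolite:
    """A network compound; ``formula``/``charge`` may be UNKNOWN (None).

    The charge is the annotated ionization state (for the organism modelled
    here, the dominant microspecies at pH 9).
    """

    id: str
    name: str = ""
    formula: ElementalFormula | None = UNKNOWN
    charge: int | None = UNKNOWN
    compartment: str = "c"


# -- gene logic --------------------------------------------------------------


class GeneLogicError(ValueError):
    """Raised for a malformed gene-logic expression."""


@dataclass(frozen=True)
class GeneRef:
    gene: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


#: boolean expression tree: GeneRef | And | Or, or None for EMPTY
GeneExpr = Union[GeneRef, And, Or, None]


@dataclass(frozen=True)
class GeneLogic:
    """Gene-protein-reaction boolean rule.

    AND joins obligatory partners (subunits of a complex), OR alternative
    catalysts (isoenzymes).  EMPTY logic (``expression is None``) means the
    reaction has no genetic support and evaluates to False for any gene set.
    """

    expression: GeneExpr = None

    @property
    def is_empty(self) -> bool:
        return self.expression is None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node: GeneExpr) -> None:
            if node is None:
                return
            if isinstance(node, GeneRef):
                out.add(node.gene)
            elif isinstance(node, (And, Or)):
                for c in node.children:
                    walk(c)
            else:
                raise GeneLogicError(f"malformed gene-logic node {node!r}")

        walk(self.expression)
        return frozenset(out)


EMPTY_LOGIC = GeneLogic(None)

_GENE_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gene_logic(text: str) -> GeneLogic:
    """Parse ``"a AND (b OR c)"`` into a :class:`GeneLogic` tree.

    Grammar: identifiers, AND, OR (case-insensitive keywords), parentheses;
    AND binds tighter than OR.  Empty/blank input yields EMPTY logic.
    """
    tokens = _GENE_TOKEN.findall(text)
    if not tokens:
        return EMPTY_LOGIC
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_atom() -> GeneExpr:
        tok = peek()
        if tok is None:
            raise GeneLogicError(f"unexpected end of expression in {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GeneLogicError(f"missing ')' at token {pos} in {text!r}")
            take()
            return node
        if tok == ")" or tok.upper() in ("AND", "OR"):
            raise GeneLogicError(f"unexpected {tok!r} at token {pos} in {text!r}")
        return GeneRef(take())

    def parse_and() -> GeneExpr:
        terms = [parse_atom()]
        while peek() is not None and peek().upper() == "AND":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_or() -> GeneExpr:
        terms = [parse_and()]
        while peek() is not None and peek().upper() == "OR":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    node = parse_or()
    if pos != len(tokens):
        raise GeneLogicError(f"trailing tokens at position {pos} in {text!r}")
    return GeneLogic(node)


def render_gene_logic(logic: GeneLogic) -> str:
    """Inverse of :func:`parse_gene_logic` (round-trips structurally)."""

    def walk(node: GeneExpr, parent_and: bool) -> str:
        if isinstance(node, GeneRef):
            return node.gene
        if isinstance(node, And):
            return " AND ".join(walk(c, True) for c in node.children)
        if isinstance(node, Or):
            inner = " OR ".join(walk(c, False) for c in node.children)
            return f"({inner})" if parent_and else inner
        raise GeneLogicError(f"malformed gene-logic node {node!r}")

    if logic.is_empty:
        return ""
    return walk(logic.expression, False)


def evaluate_gene_logic(logic: GeneLogic, present_genes: Iterable[str]) -> bool:
    """Evaluate a GPR rule against a set of present genes.

    EMPTY logic is False under any gene set (no genetic support).
    """
    present = set(present_genes)

    def walk(node: GeneExpr) -> bool:
        if isinstance(node, GeneRef):
            return node.gene in present
        if isinstance(node, And):
            return all(walk(c) for c in node.children)
        if isinstance(node, Or):
            return any(walk(c) for c in node.children)
        raise GeneLogicError(f"malformed gene-logic node {node!r}")

    if logic.is_empty:
        return False
    return walk(logic.expression)


# -- evidence ----------------------------------------------------------------

GENETIC_CLASSES = ("SPECIFIC", "GENERAL_ONLY", "NONE")


@dataclass(frozen=True)
class Evidence:
    """Curation evidence for a reaction.

    genetic_class: SPECIFIC (enzyme-coding gene reliably assigned),
    GENERAL_ONLY (only genes with general functional annotation), or NONE.
    literature is an independent, possibly overlapping flag.  A gap-filled
    reaction has, by definition, neither genetic nor literature support.
    """

    genetic_class: str = "NONE"
    literature: bool = False
    gap_fill: bool = False

    def __post_init__(self) -> None:
        if self.genetic_class not in GENETIC_CLASSES:
            raise ValueError(f"invalid genetic_class {self.genetic_class!r}")
        if self.gap_fill and (self.genetic_class != "NONE" or self.literature):
            raise ValueError("gap_fill implies genetic_class NONE and no literature")


# -- reactions and networks --------------------------------------------------

REACTION_KINDS = ("INTERNAL", "EXCHANGE", "GROWTH")


@dataclass
class Reaction:
    """A stoichiometric reaction; negative coefficient = consumed left-to-right."""

    id: str
    stoichiometry: dict[str, Fraction]
    name: str = ""
    reversible: bool = False
    kind: str = "INTERNAL"
    gene_logic: GeneLogic = EMPTY_LOGIC
    evidence: Evidence = field(default_factory=Evidence)
    category: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"invalid reaction kind {self.kind!r}")
        self.stoichiometry = {m: Fraction(c) for m, c in self.stoichiometry.items()}


@dataclass
class MetabolicNetwork:
    """A reconstruction: metabolites and reactions, indexed by id."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    @classmethod
    def from_parts(
        cls, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction]
    ) -> "MetabolicNetwork":
        net = cls()
        for met in metabolites:
            if met.id in net.metabolites:
                raise ValueError(f"duplicate metabolite id {met.id!r}")
            net.metabolites[met.id] = met
        for rxn in reactions:
            if rxn.id in net.reactions:
                raise ValueError(f"duplicate reaction id {rxn.id!r}")
            net.reactions[rxn.id] = rxn
        return net

    @property
    def gene_ids(self) -> frozenset[str]:
        """Union of gene identifiers over all gene-logic rules."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.gene_logic.genes()
        return frozenset(out)


@dataclass(frozen=True)
class Violation:
    """One structural-invariant violation found by :func:`validate_network`."""

    kind: str
    subject: str
    message: str


def validate_network(network: MetabolicNetwork) -> list[Violation]:
    """Check referential integrity and per-reaction structural invariants.

    Returns one descriptor per violation; an empty list means the network
    satisfies all structural invariants.  Violations are data, not errors.
    """
    out: list[Violation] = []
    for rxn in network.reactions.values():
        for met_id in rxn.stoichiometry:
            if met_id not in network.metabolites:
                out.append(
                    Violation(
                        "dangling-metabolite",
                        rxn.id,
                        f"reaction {rxn.id} references undeclared metabolite {met_id!r}",
                    )
                )
        if rxn.kind in ("INTERNAL", "GROWTH") and not rxn.stoichiometry:
            out.append(
                Violation("empty-stoichiometry", rxn.id, f"{rxn.kind} reaction {rxn.id} is empty")
            )
        if rxn.kind == "EXCHANGE" and len(rxn.stoichiometry) != 1:
            out.append(
                Violation(
                    "malformed-exchange",
                    rxn.id,
                    f"exchange reaction {rxn.id} touches {len(rxn.stoichiometry)} metabolites",
                )
            )
    return out


# -- balance auditing --------------------------------------------------------

VERDICTS = ("BALANCED", "UNBALANCED", "UNVERIFIABLE")


@dataclass
class BalanceReport:
    """Outcome of mass/charge balancing one reaction.

    ``element_deltas`` is the signed per-element net (products minus
    reactants); BALANCED iff every delta and the charge delta are zero and
    every participant had a known formula and charge.  Boundary-crossing
    reactions (EXCHANGE, GROWTH) are skipped: they are not elementally
    closed by construction.
    """

    reaction_id: str
    verdict: str
    element_deltas: dict[str, Fraction] = field(default_factory=dict)
    charge_delta: Fraction | None = Fraction(0)
    skipped: bool = False
    unknown_participants: tuple[str, ...] = ()


def check_reaction_balance(rxn: Reaction, network: MetabolicNetwork) -> BalanceReport:
    """Exact elemental and charge balance for one internal reaction."""
    if rxn.kind in ("EXCHANGE", "GROWTH"):
        return BalanceReport(rxn.id, "UNVERIFIABLE", {}, None, skipped=True)

    deltas: dict[str, Fraction] = {}
    charge = Fraction(0)
    unknown: list[str] = []
    for met_id, coeff in rxn.stoichiometry.items():
        met = network.metabolites[met_id]
        if met.formula is UNKNOWN or met.charge is UNKNOWN:
            unknown.append(met_id)
            continue
        for sym, n in met.formula.element_counts.items():
            deltas[sym] = deltas.get(sym, Fraction(0)) + coeff * n
        charge += coeff * met.charge
    deltas = {s: d for s, d in deltas.items() if d != 0}

    if unknown:
        return BalanceReport(
            rxn.id, "UNVERIFIABLE", deltas, None, unknown_participants=tuple(sorted(unknown))
        )
    verdict = "BALANCED" if not deltas and charge == 0 else "UNBALANCED"
    return BalanceReport(rxn.id, verdict, deltas, charge)


@dataclass
class BalanceAudit:
    """Network-wide audit: per-verdict counts over internal reactions and
    the sorted list of reactions that failed or could not be checked."""

    counts: dict[str, int]
    offenders: list[BalanceReport]
    reports: dict[str, BalanceReport]

    @property
    def n_not_balanced(self) -> int:
        return self.counts["UNBALANCED"] + self.counts["UNVERIFIABLE"]


def network_balance_audit(network: MetabolicNetwork) -> BalanceAudit:
    """Audit every INTERNAL reaction; EXCHANGE/GROWTH are out of scope."""
    counts = {v: 0 for v in VERDICTS}
    reports: dict[str, BalanceReport] = {}
    offenders: list[BalanceReport] = []
    for rxn in network.reactions.values():
        if rxn.kind != "INTERNAL":
            continue
        try:
            rep = check_reaction_balance(rxn, network)
        except FormulaError as exc:
            raise FormulaError(f"in reaction {rxn.id}: {exc}") from exc
        reports[rxn.id] = rep
        counts[rep.verdict] += 1
        if rep.verdict != "BALANCED":
            offenders.append(rep)
    offenders.sort(key=lambda r: r.reaction_id)
    return BalanceAudit(counts, offenders, reports)


# -- evidence summary --------------------------------------------------------


@dataclass
class EvidenceSummary:
    """Reaction counts partitioned by genetic class, cross-tabulated with
    functional category; literature is an overlapping tally."""

    by_class: dict[str, int]
    by_category_class: dict[tuple[str, str], int]
    literature: int
    gap_fill: int
    total: int


def evidence_summary(network: MetabolicNetwork) -> EvidenceSummary:
    by_class = {c: 0 for c in GENETIC_CLASSES}
    by_cat: dict[tuple[str, str], int] = {}
    lit = 0
    gap = 0
    for rxn in network.reactions.values():
        ev = rxn.evidence
        by_class[ev.genetic_class] += 1
        key = (rxn.category, ev.genetic_class)
        by_cat[key] = by_cat.get(key, 0) + 1
        if ev.literature:
            lit += 1
        if ev.gap_fill:
            gap += 1
    return EvidenceSummary(by_class, by_cat, lit, gap, len(network.reactions))
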