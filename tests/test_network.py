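"""Network data model: balance auditing, gene logic, evidence, validation."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from natrofba import (
    And,
    ElementalFormula,
    Evidence,
    FormulaError,
    GeneLogic,
    GeneRef,
    MetabolicNetwork,
    Metabolite,
    Or,
    Reaction,
    check_reaction_balance,
    evaluate_gene_logic,
    evidence_summary,
    network_balance_audit,
    parse_gene_logic,
    render_gene_logic,
    validate_network,
)


def met(mid, formula, charge=0):
    return Metabolite(mid, formula=ElementalFormula.parse(formula), charge=charge)


def two_met_network(reaction_stoich, mets):
    rxn = Reaction("R1", reaction_stoich)
    return MetabolicNetwork.from_parts(mets, [rxn])


class TestElementalFormula:
    def test_parse_and_str_roundtrip(self):
        f = ElementalFormula.parse("C10H16N5O13P3")
        assert f["C"] == 10 and f["P"] == 3 and f["Fe"] == 0
        assert ElementalFormula.parse(str(f)).element_counts == f.element_counts

    def test_addition_and_scaling_are_exact(self):
        a = ElementalFormula.parse("CH4")
        total = a + a * Fraction(1, 2)
        assert total["C"] == Fraction(3, 2)
        assert total["H"] == 6

    @pytest.mark.parametrize("bad", ["Xx2", "C-1", "c2h4", "C2 H4"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            ElementalFormula.parse(bad)


class TestBalance:
    def test_balanced_deprotonation(self):
        # CH4 -> CH3(-1) + H(+1): every element and the charge cancel
        net = two_met_network(
            {"A": -1, "B": 1, "Hp": 1},
            [met("A", "CH4"), met("B", "CH3", -1), met("Hp", "H", +1)],
        )
        rep = check_reaction_balance(net.reactions["R1"], net)
        assert rep.verdict == "BALANCED"
        assert rep.element_deltas == {} and rep.charge_delta == 0

    def test_unbalanced_reports_deltas(self):
        net = two_met_network({"A": -1, "B": 1}, [met("A", "CH4"), met("B", "CH3", -1)])
        rep = check_reaction_balance(net.reactions["R1"], net)
        assert rep.verdict == "UNBALANCED"
        assert rep.element_deltas == {"H": -1}
        assert rep.charge_delta == -1

    def test_unknown_formula_gives_unverifiable_not_unbalanced(self):
        net = MetabolicNetwork.from_parts(
            [Metabolite("A"), met("B", "CH3", -1)],
            [Reaction("R1", {"A": -1, "B": 1})],
        )
        rep = check_reaction_balance(net.reactions["R1"], net)
        assert rep.verdict == "UNVERIFIABLE"
        assert rep.unknown_participants == ("A",)

    def test_exchange_and_growth_skipped(self):
        net = MetabolicNetwork.from_parts(
            [met("A", "CH4")],
            [
                Reaction("EX", {"A": -1}, kind="EXCHANGE"),
                Reaction("G", {"A": -1}, kind="GROWTH"),
            ],
        )
        for rid in ("EX", "G"):
            rep = check_reaction_balance(net.reactions[rid], net)
            assert rep.verdict == "UNVERIFIABLE" and rep.skipped

    @given(
        scale=st.fractions(min_value=Fraction(1, 100), max_value=100),
        reverse=st.booleans(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_verdict_invariant_under_reversal_and_rescaling(self, scale, reverse):
        base = {"A": Fraction(-1), "B": Fraction(1)}
        sign = -1 if reverse else 1
        stoich = {k: v * scale * sign for k, v in base.items()}
        net = two_met_network(stoich, [met("A", "CH4"), met("B", "CH3", -1)])
        assert check_reaction_balance(net.reactions["R1"], net).verdict == "UNBALANCED"
        balanced = {"A": Fraction(-1) * scale * sign, "C": Fraction(1) * scale * sign}
        net2 = two_met_network(balanced, [met("A", "CH4"), met("C", "CH4")])
        assert check_reaction_balance(net2.reactions["R1"], net2).verdict == "BALANCED"

    def test_delta_linearity_over_reaction_sums(self):
        # deltas of the stoichiometric sum equal the sum of per-reaction deltas
        mets = [met("A", "CH4"), met("B", "CH3", -1), met("C", "C2H4O2")]
        r1 = Reaction("R1", {"A": -1, "B": 1})
        r2 = Reaction("R2", {"B": -2, "C": 1})
        net = MetabolicNetwork.from_parts(mets, [r1, r2])
        d1 = check_reaction_balance(r1, net)
        d2 = check_reaction_balance(r2, net)
        summed = Reaction("RS", {"A": -1, "B": -1, "C": 1})
        net2 = MetabolicNetwork.from_parts(mets, [summed])
        ds = check_reaction_balance(summed, net2)
        for el in set(d1.element_deltas) | set(d2.element_deltas) | set(ds.element_deltas):
            assert ds.element_deltas.get(el, 0) == d1.element_deltas.get(
                el, 0
            ) + d2.element_deltas.get(el, 0)
        assert ds.charge_delta == d1.charge_delta + d2.charge_delta


class TestAudit:
    def test_counts_partition_internal_reactions(self, toy_net):
        audit = network_balance_audit(toy_net)
        n_internal = sum(1 for r in toy_net.reactions.values() if r.kind == "INTERNAL")
        assert sum(audit.counts.values()) == n_internal
        assert audit.counts["UNBALANCED"] == 0 and audit.counts["UNVERIFIABLE"] == 0
        assert audit.offenders == []

    def test_offenders_sorted_by_reaction_id(self):
        mets = [met("A", "CH4"), met("B", "CH3", -1)]
        rxns = [Reaction(r, {"A": -1, "B": 1}) for r in ("Rz", "Ra", "Rm")]
        audit = network_balance_audit(MetabolicNetwork.from_parts(mets, rxns))
        assert [r.reaction_id for r in audit.offenders] == ["Ra", "Rm", "Rz"]


class TestValidation:
    def test_empty_network_is_valid(self):
        assert validate_network(MetabolicNetwork()) == []

    def test_toy_network_is_valid(self, toy_net):
        assert validate_network(toy_net) == []

    def test_dangling_reference_and_malformed_exchange(self):
        net = MetabolicNetwork.from_parts(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction("R1", {"A": -1, "X": 1}),
                Reaction("EX", {"A": -1, "B": 1}, kind="EXCHANGE"),
                Reaction("R2", {}, kind="INTERNAL"),
            ],
        )
        kinds = sorted(v.kind for v in validate_network(net))
        assert kinds == ["dangling-metabolite", "empty-stoichiometry", "malformed-exchange"]


# gene-logic expression generator for the round-trip property
_idents = st.from_regex(r"NP[0-9]{4}A", fullmatch=True)


def _exprs(depth=3):
    """Alternating AND/OR trees: the grammar flattens associative chains,
    so same-type nesting can never come back from a parse."""
    atom = _idents.map(GeneRef)
    if depth == 0:
        return atom
    sub = _exprs(depth - 1)

    def node(cls, other_cls):
        return st.lists(
            sub.filter(lambda e: not isinstance(e, cls)), min_size=2, max_size=3
        ).map(lambda c: cls(tuple(c)))

    return st.one_of(atom, node(And, Or), node(Or, And))


class TestGeneLogic:
    def test_two_subunit_complex_requires_both(self):
        logic = parse_gene_logic("NP4044A AND NP4046A")
        assert not evaluate_gene_logic(logic, {"NP4044A"})
        assert evaluate_gene_logic(logic, {"NP4044A", "NP4046A"})

    def test_and_binds_tighter_than_or(self):
        logic = parse_gene_logic("a OR b AND c")
        assert logic.expression == Or((GeneRef("a"), And((GeneRef("b"), GeneRef("c")))))

    def test_empty_logic_is_false_for_any_set(self):
        assert not evaluate_gene_logic(GeneLogic(None), {"a", "b"})
        assert parse_gene_logic("").is_empty

    @pytest.mark.parametrize("bad", ["a AND", "(a OR b", "AND a", "a b"])
    def test_syntax_errors(self, bad):
        from natrofba import GeneLogicError

        with pytest.raises(GeneLogicError):
            parse_gene_logic(bad)

    @given(expr=_exprs())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_parse_render_roundtrip(self, expr):
        logic = GeneLogic(expr)
        assert parse_gene_logic(render_gene_logic(logic)).expression == expr

    @given(expr=_exprs(), present=st.sets(_idents, max_size=5), extra=_idents)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_evaluation_is_monotone_in_present_genes(self, expr, present, extra):
        logic = GeneLogic(expr)
        if evaluate_gene_logic(logic, present):
            assert evaluate_gene_logic(logic, present | {extra})


class TestEvidence:
    def test_gap_fill_implies_no_other_support(self):
        with pytest.raises(ValueError):
            Evidence(genetic_class="SPECIFIC", gap_fill=True)
        with pytest.raises(ValueError):
            Evidence(literature=True, gap_fill=True)

    def test_summary_partitions_and_tallies(self):
        rxns = [
            Reaction("R1", {"A": -1}, kind="INTERNAL",
                     evidence=Evidence("SPECIFIC", literature=True), category="tca"),
            Reaction("R2", {"A": -1}, kind="INTERNAL",
                     evidence=Evidence("SPECIFIC"), category="tca"),
            Reaction("R3", {"A": -1}, kind="INTERNAL",
                     evidence=Evidence("NONE", gap_fill=True), category="transport"),
        ]
        net = MetabolicNetwork.from_parts([Metabolite("A")], rxns)
        s = evidence_summary(net)
        assert s.by_class == {"SPECIFIC": 2, "GENERAL_ONLY": 0, "NONE": 1}
        assert sum(s.by_class.values()) == s.total == 3
        assert s.literature == 1 and s.gap_fill == 1
        assert s.by_category_class[("tca", "SPECIFIC")] == 2

    def test_empty_network_all_zero(self):
        s = evidence_summary(MetabolicNetwork())
        assert s.total == 0 and s.literature == 0 and s.gap_fill == 0

    def test_gene_ids_union(self):
        rxns = [
            Reaction("R1", {"A": -1}, gene_logic=parse_gene_logic("g1 AND g2")),
            Reaction("R2", {"A": -1}, gene_logic=parse_gene_logic("g2 OR g3")),
        ]
        net = MetabolicNetwork.from_parts([Metabolite("A")], rxns)
        assert net.gene_ids == {"g1", "g2", "g3"}
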