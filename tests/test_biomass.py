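"""Biomass composition: regression, pool splitting, allocation, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from natrofba import (
    BiomassComposition,
    GrowthReactionSpec,
    allocate_nucleotides,
    assemble_growth_reaction,
    estimate_unmeasured_aa,
    fit_amino_acid_slopes,
    fit_through_origin,
    residual_nucleotide_pool,
    scale_reference_components,
    simulate_composition_samples,
    split_combined_pool,
)
from natrofba.biomass import DEFAULT_REFERENCE_COMPONENTS, build_full_composition


class TestFitThroughOrigin:
    def test_exact_line(self):
        fit = fit_through_origin([(1.0, 18.2), (2.0, 36.4)])
        assert fit.slope == pytest.approx(18.2)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)
        assert fit.n == 2

    def test_zero_signal(self):
        assert fit_through_origin([(1.0, 0.0), (2.0, 0.0)]).slope == 0.0

    def test_degenerate_all_zero_od(self):
        with pytest.raises(ValueError):
            fit_through_origin([(0.0, 1.0), (0.0, 2.0)])

    def test_noisy_recovery_within_three_stderr(self):
        rng = np.random.default_rng(42)
        ods = np.linspace(0.2, 2.0, 20)
        samples = [(od, 18.2 * od + rng.normal(0, 1.0)) for od in ods]
        fit = fit_through_origin(samples)
        assert abs(fit.slope - 18.2) <= 3 * fit.stderr


class TestAminoAcidPanel:
    def test_exact_panel_recovery(self):
        slopes = {"Ala": 290.0, "Gly": 280.0, "Asp+Asn": 220.0}
        samples = simulate_composition_samples(slopes, [0.2, 0.5, 1.0, 1.5], sigma=0.0)
        fits = fit_amino_acid_slopes(samples)
        for analyte, s in slopes.items():
            assert fits[analyte].slope == pytest.approx(s)

    def test_noisy_panel_recovery_within_three_stderr(self):
        slopes = {f"aa{i}": 100.0 + 10.0 * i for i in range(18)}
        samples = simulate_composition_samples(
            slopes, list(np.linspace(0.2, 2.0, 20)), sigma=2.0, seed=7
        )
        fits = fit_amino_acid_slopes(samples)
        for analyte, s in slopes.items():
            assert abs(fits[analyte].slope - s) <= 3 * max(fits[analyte].stderr, 1e-9)

    def test_inconsistent_analyte_sets_rejected(self):
        from natrofba import CompositionSample

        with pytest.raises(ValueError):
            fit_amino_acid_slopes(
                [
                    CompositionSample(0.5, {"Ala": 1.0}),
                    CompositionSample(1.0, {"Gly": 1.0}),
                ]
            )


class TestPoolSplitting:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ({"Asp": 1.0, "Asn": 1.0}, {"Asp": 50.0, "Asn": 50.0}),
            ({"Asp": 3.0, "Asn": 1.0}, {"Asp": 75.0, "Asn": 25.0}),
        ],
    )
    def test_proportional_shares(self, freqs, expected):
        assert split_combined_pool(100.0, freqs) == pytest.approx(expected)

    @given(
        total=st.floats(min_value=0.0, max_value=1e4),
        freqs=st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.floats(min_value=0.0, max_value=10.0),
            min_size=2,
        ).filter(lambda d: sum(d.values()) > 0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shares_conserve_total(self, total, freqs):
        shares = split_combined_pool(total, freqs)
        assert sum(shares.values()) == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_all_zero_freqs_rejected(self):
        with pytest.raises(ValueError):
            split_combined_pool(10.0, {"a": 0.0, "b": 0.0})


class TestUnmeasuredEstimation:
    def test_single_ratio(self):
        out = estimate_unmeasured_aa({"Ala": 100.0}, {"Ala": 0.1, "Cys": 0.01}, ["Cys"])
        assert out["Cys"] == pytest.approx(10.0)

    def test_zero_target_frequency(self):
        out = estimate_unmeasured_aa({"Ala": 100.0}, {"Ala": 0.1}, ["Trp"])
        assert out["Trp"] == 0.0

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_in_measured_total(self, scale):
        measured = {"Ala": 50.0, "Gly": 30.0}
        freqs = {"Ala": 0.09, "Gly": 0.08, "Cys": 0.01, "Trp": 0.012}
        base = estimate_unmeasured_aa(measured, freqs)
        scaled = estimate_unmeasured_aa({k: v * scale for k, v in measured.items()}, freqs)
        for t in base:
            assert scaled[t] == pytest.approx(base[t] * scale, rel=1e-9)


class TestNucleotides:
    def test_even_split(self):
        out = allocate_nucleotides(100.0, 0.5)
        assert all(v == pytest.approx(25.0) for v in out.values())

    def test_published_ratio(self):
        # the A and G pairs of the published growth reaction are 81.6 and
        # 47.1 µmol/OD·L; their total with the default AT share recovers both
        out = allocate_nucleotides(2 * 81.6 + 2 * 47.1, 0.634)
        assert out["AMP+dAMP"] == pytest.approx(81.6, abs=0.05)
        assert out["UMP+dTMP"] == pytest.approx(81.6, abs=0.05)
        assert out["GMP+dGMP"] == pytest.approx(47.1, abs=0.05)
        assert out["CMP+dCMP"] == pytest.approx(47.1, abs=0.05)

    @given(split=st.floats(min_value=0.0, max_value=1.0),
           pool=st.floats(min_value=0.0, max_value=1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_allocation_conserves_pool(self, split, pool):
        out = allocate_nucleotides(pool, split)
        assert sum(out.values()) == pytest.approx(pool, rel=1e-9, abs=1e-9)

    def test_fraction_mode_arithmetic(self):
        # 18.2 mmol C x 20% / 9.66 C per nucleotide = 376.8 µmol
        pool = residual_nucleotide_pool(18.2, assumed_fraction=0.2,
                                        mean_carbon_per_nucleotide=9.66)
        assert pool == pytest.approx(18.2 * 0.2 / 9.66 * 1000, rel=1e-12)
        assert pool == pytest.approx(376.8, abs=0.05)

    def test_fraction_zero_gives_zero(self):
        assert residual_nucleotide_pool(18.2, assumed_fraction=0.0) == 0.0

    def test_residual_mode_closure(self):
        comp = BiomassComposition()
        comp.set("Ala", 1000.0, "MEASURED")  # 3 C each -> 3 mmol C
        pool = residual_nucleotide_pool(
            3.0, comp, {"Ala": 3.0}, mode="residual", mean_carbon_per_nucleotide=9.66
        )
        assert pool == pytest.approx(0.0, abs=1e-9)

    def test_residual_overdraw_rejected(self):
        comp = BiomassComposition()
        comp.set("Ala", 2000.0, "MEASURED")
        with pytest.raises(ValueError):
            residual_nucleotide_pool(3.0, comp, {"Ala": 3.0}, mode="residual")


class TestReferenceComponents:
    def test_identity_and_doubling(self):
        assert scale_reference_components({"archaeol": 20.0}, 1.0) == {"archaeol": 20.0}
        assert scale_reference_components({"archaeol": 20.0}, 2.0) == {"archaeol": 40.0}

    def test_shipped_defaults(self):
        assert DEFAULT_REFERENCE_COMPONENTS == {
            "archaeol": 20.0, "GalNAc": 2.2, "GlcNAc": 2.2,
            "Gal": 9.6, "Glc": 9.6, "ATP": 2.0,
        }


class TestGrowthReactionAssembly:
    def _network(self):
        from natrofba import MetabolicNetwork, Metabolite

        return MetabolicNetwork.from_parts(
            [Metabolite(m) for m in ("X", "atp", "adp", "pi", "h2o", "biomass")], []
        )

    def test_single_component_zero_maintenance(self):
        comp = BiomassComposition()
        comp.set("X", 1.0, "MEASURED")
        rxn = assemble_growth_reaction(GrowthReactionSpec(comp, 0.0), self._network())
        assert rxn.kind == "GROWTH" and not rxn.reversible
        assert rxn.stoichiometry == {"X": -1, "biomass": 1}

    def test_maintenance_unit_conversion(self):
        # 10 µmol ATP per ΔOD·ml = 10,000 µmol per OD·L
        comp = BiomassComposition()
        comp.set("X", 1.0, "MEASURED")
        rxn = assemble_growth_reaction(GrowthReactionSpec(comp, 10.0), self._network())
        assert float(rxn.stoichiometry["atp"]) == pytest.approx(-10_000.0)
        assert float(rxn.stoichiometry["adp"]) == pytest.approx(10_000.0)
        assert float(rxn.stoichiometry["pi"]) == pytest.approx(10_000.0)
        assert float(rxn.stoichiometry["h2o"]) == pytest.approx(-10_000.0)

    def test_unmapped_component_errors_with_names(self):
        from natrofba.biomass import UnmappedComponentError

        comp = BiomassComposition()
        comp.set("nosuch", 1.0, "MEASURED")
        with pytest.raises(UnmappedComponentError) as err:
            assemble_growth_reaction(GrowthReactionSpec(comp, 0.0), self._network())
        assert "nosuch" in str(err.value)


class TestFullComposition:
    def test_assembles_all_provenances_and_salt(self):
        aa_slopes = {"Ala": 290.0, "Gly": 280.0, "Asp+Asn": 220.0, "Glu+Gln": 240.0}
        freqs = {"Ala": 0.10, "Gly": 0.08, "Asp": 0.05, "Asn": 0.03,
                 "Glu": 0.06, "Gln": 0.02, "Cys": 0.008, "Trp": 0.01}
        comp = build_full_composition(aa_slopes, freqs, toc_slope=18.2)
        assert comp.provenance["Ala"] == "MEASURED"
        assert comp.provenance["Asp"] == "SPLIT_FROM_POOL"
        assert comp.coefficients["Asp"] + comp.coefficients["Asn"] == pytest.approx(220.0)
        assert comp.provenance["Cys"] == "PROTEOME_ESTIMATED"
        assert comp.provenance["AMP+dAMP"] == "GC_ALLOCATED"
        assert comp.provenance["archaeol"] == "REFERENCE_SCALED"
        assert comp.provenance["ATP"] == "FIXED"
        assert comp.coefficients["Na+(K+)"] == pytest.approx(2813.4)
        assert comp.coefficients["Cl-"] == pytest.approx(2813.4)
        # nucleotide pairs carry the default AT:GC ratio 0.634 : 0.366
        ratio = comp.coefficients["AMP+dAMP"] / (
            comp.coefficients["AMP+dAMP"] + comp.coefficients["GMP+dGMP"]
        )
        assert ratio == pytest.approx(0.634)
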