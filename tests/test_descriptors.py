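"""Descriptor computation, Hill formulas, CHEMINF typing, atomic weights."""

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from chemrdf.chem import MolecularGraph
from chemrdf.descriptors import (
    DEFAULT_CATALOG,
    DEFAULT_WEIGHTS,
    CatalogError,
    adapter_descriptors,
    build_descriptor_assertions,
    compute_native_descriptors,
    hill_formula,
    parse_formula,
)


def graph_from_smiles(smiles: str) -> MolecularGraph:
    mol = Chem.MolFromSmiles(smiles)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return MolecularGraph.from_rdkit(mol)


class TestNativeDescriptors:
    def test_atorvastatin_molecular_weight(self, worked_example):
        values = compute_native_descriptors(worked_example.structure)
        assert values["Molecular_Formula"] == "C33H35FN2O5"
        assert values["Molecular_Weight"] == pytest.approx(558.639803, abs=5e-7)
        assert values["Heavy_Atom_Count"] == 41

    def test_water(self):
        values = compute_native_descriptors(graph_from_smiles("O"))
        assert values["Molecular_Formula"] == "H2O"
        assert values["Heavy_Atom_Count"] == 1
        assert values["Total_Formal_Charge"] == 0
        assert values["Rotatable_Bond_Count"] == 0

    def test_methane_monoisotopic_mass(self):
        # independent sum from the isotope-mass table: 12C + 4 * 1H
        expected = 12.0 + 4 * 1.00782503207
        values = compute_native_descriptors(graph_from_smiles("C"))
        assert values["Mono_Isotopic_Weight"] == pytest.approx(expected, abs=1e-9)
        assert values["Exact_Mass"] == values["Mono_Isotopic_Weight"]

    def test_explicit_isotopes_shift_exact_mass_only(self):
        protio = compute_native_descriptors(graph_from_smiles("CCO"))
        deuterated = compute_native_descriptors(graph_from_smiles("[2H]C([2H])(C)O"))
        assert deuterated["Isotope_Atom_Count"] == 2
        assert deuterated["Mono_Isotopic_Weight"] == pytest.approx(
            protio["Mono_Isotopic_Weight"], abs=1e-9
        )
        shift = 2 * (2.01410177785 - 1.00782503207)
        assert deuterated["Exact_Mass"] - protio["Exact_Mass"] == pytest.approx(shift, abs=1e-8)

    def test_covalent_unit_count_on_mixture(self, worked_example):
        from chemrdf.chem import parse_sdf
        (graph, _), = parse_sdf(worked_example.salt_molfile + "$$$$\n")
        values = compute_native_descriptors(graph)
        assert values["Covalent_Unit_Count"] == 3

    def test_hbond_and_rotatable_counts(self):
        # ethanolamine: N and O donors/acceptors, C-C and two C-heteroatom bonds
        values = compute_native_descriptors(graph_from_smiles("OCCN"))
        assert values["Hydrogen_Bond_Donor_Count"] == 2
        assert values["Hydrogen_Bond_Acceptor_Count"] == 2
        assert values["Rotatable_Bond_Count"] == 1  # only the central C-C qualifies

    def test_amide_bond_not_rotatable(self):
        values = compute_native_descriptors(graph_from_smiles("CC(=O)NC"))
        assert values["Rotatable_Bond_Count"] == 0

    def test_stereocenter_counts(self, worked_example):
        values = compute_native_descriptors(worked_example.structure)
        assert values["Defined_Atom_Stereocenter_Count"] == 2
        assert values["Undefined_Atom_Stereocenter_Count"] == 0

    def test_missing_element_reported(self):
        graph = graph_from_smiles("[Au]")
        with pytest.raises(KeyError, match="Au"):
            compute_native_descriptors(graph)

    def test_mw_and_mono_close_for_chnops(self, synth_result):
        """Standard and monoisotopic weight agree within 1% for small
        CHNOPS(+F) molecules; F is mononuclidic so it cannot widen the gap."""
        _, result = synth_result
        checked = 0
        for comp in result.registry:
            elements = {a.element for a in comp.graph.atoms}
            if not elements <= {"C", "H", "N", "O", "P", "S", "F"}:
                continue
            if any(a.isotope for a in comp.graph.atoms):
                continue  # explicit labels shift exact/mono apart by design
            values = compute_native_descriptors(comp.graph)
            mw, mono = values["Molecular_Weight"], values["Mono_Isotopic_Weight"]
            assert mw > 0 and mono > 0
            if mw < 1000:
                assert abs(mw - mono) / mw < 0.01
                checked += 1
        assert checked > 0


class TestFormula:
    @pytest.mark.parametrize("comp, expected", [
        ({"C": 33, "H": 35, "F": 1, "N": 2, "O": 5}, "C33H35FN2O5"),
        ({"H": 2, "O": 1}, "H2O"),
        ({"O": 1, "H": 2, "C": 1}, "CH2O"),
        ({"Ca": 1}, "Ca"),
    ])
    def test_hill_order(self, comp, expected):
        assert hill_formula(comp) == expected

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "P", "Cl", "Ca", "Na"]),
            st.integers(min_value=1, max_value=99),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, comp):
        assert parse_formula(hill_formula(comp)) == comp

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_formula("C3#H8")


class TestAdapterDescriptors:
    def test_atorvastatin_inchikey(self, worked_example):
        adapted = adapter_descriptors(worked_example.structure)
        assert adapted["IUPAC_InChIKey"] == "XUKUURHRXDUEBC-KAYWLYCHSA-N"
        assert adapted["IUPAC_InChI"].startswith("InChI=1S/C33H35FN2O5/")

    def test_passthrough_fields(self):
        g = graph_from_smiles("CCO")
        adapted = adapter_descriptors(g, {"PUBCHEM_XLOGP3": "5.0"})
        assert adapted["XLogP3"] == "5.0"

    def test_absent_passthrough_is_omitted_silently(self):
        adapted = adapter_descriptors(graph_from_smiles("CCO"))
        assert "XLogP3" not in adapted and "TPSA" not in adapted
        assert "Canonical_SMILES" in adapted


class TestAssertions:
    def test_molecular_weight_assertion(self, worked_example):
        values = compute_native_descriptors(worked_example.structure)
        assertions = build_descriptor_assertions("CID60823", values)
        by_label = {a.descriptor_label: a for a in assertions}
        mw = by_label["Molecular_Weight"]
        assert mw.value == "558.639803"
        assert mw.cheminf_type == "CHEMINF_000334"
        assert mw.unit == "UO_0000055"
        assert mw.datatype == "double"
        assert mw.software == "CHEMINF_000333"  # PubChem 2.1

    def test_substance_version_assertion(self):
        (a,) = build_descriptor_assertions("SID43118161", {"Substance_Version": 1})
        assert a.entity_label == "SID43118161"
        assert a.datatype == "nonNegativeInteger"
        assert a.cheminf_type is None

    def test_every_emitted_label_is_typed(self, worked_example):
        values = {
            **compute_native_descriptors(worked_example.structure),
            **adapter_descriptors(worked_example.structure),
        }
        assertions = build_descriptor_assertions("CID60823", values)
        assert len(assertions) == len(values)
        for a in assertions:
            if a.descriptor_label != "Substance_Version":
                assert a.cheminf_type and a.cheminf_type.startswith("CHEMINF_")

    def test_unknown_label_rejected(self):
        with pytest.raises(CatalogError):
            build_descriptor_assertions("CID1", {"Bogus_Thing": 5})

    def test_synonym_type_fallback(self):
        assert DEFAULT_CATALOG.synonym_type("CAS registry number") == "CHEMINF_000446"
        assert DEFAULT_CATALOG.synonym_type("made-up label") == "CHEMINF_000339"


class TestAtomicWeights:
    def test_pinned_2005_values(self):
        assert DEFAULT_WEIGHTS.standard_weight("C") == 12.0107
        assert DEFAULT_WEIGHTS.standard_weight("H") == 1.00794
        assert DEFAULT_WEIGHTS.principal_mass("C") == 12.0

    def test_isotope_fallback_is_mass_number(self):
        assert DEFAULT_WEIGHTS.isotope_mass("C", 11) == 11.0
        assert DEFAULT_WEIGHTS.isotope_mass("H", 2) == pytest.approx(2.0141017, abs=1e-6)
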