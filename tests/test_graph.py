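"""Triple emission, synonym vote, entailment closure, Turtle I/O, queries."""

import random

import pytest
from rdflib import RDF, Literal, URIRef
from rdflib.namespace import SKOS

from chemrdf.chem import CompoundRecord, SubstanceRecord
from chemrdf.graph import (
    SUBPROPERTY_AXIOMS,
    SYMMETRIC_PREDICATES,
    SynonymAssertion,
    TripleGraph,
    TurtleSyntaxError,
    emit_annotation_triples,
    emit_compound_triples,
    emit_substance_triples,
    materialize_inferences,
    parse_turtle,
    partition_by_subdomain,
    run_example_query,
    serialize_turtle,
    synonym_vote,
)
from chemrdf.identity import CigRelation, ISOTOPOLOGUE_OF
from chemrdf.namespaces import DEFAULT_NAMESPACES

SIO = DEFAULT_NAMESPACES.namespace("sio")
VOCAB = DEFAULT_NAMESPACES.namespace("vocab")
DCTERMS = DEFAULT_NAMESPACES.namespace("dcterms")
CITO = DEFAULT_NAMESPACES.namespace("cito")
PDBO = DEFAULT_NAMESPACES.namespace("pdbo")
COMPOUND = DEFAULT_NAMESPACES.namespace("compound")
SUBSTANCE = DEFAULT_NAMESPACES.namespace("substance")
DESCR = DEFAULT_NAMESPACES.namespace("descr")
SYNO = DEFAULT_NAMESPACES.namespace("syno")
SOURCE = DEFAULT_NAMESPACES.namespace("source")


class TestSynonymVote:
    def _assertions(self, spec):
        # spec: list of (sid, source)
        return [SynonymAssertion("name", sid, src) for sid, src in spec]

    def test_majority_promotes_single_cid(self):
        assertions = self._assertions([(1, "A"), (2, "B"), (3, "C")])
        normalization = {1: 10, 2: 10, 3: 20}
        assert synonym_vote(assertions, normalization) == {("name", 10)}

    def test_tie_promotes_nothing(self):
        assertions = self._assertions([(1, "A"), (2, "B")])
        assert synonym_vote(assertions, {1: 10, 2: 20}) == set()

    def test_single_source_single_cid_promotes(self):
        assert synonym_vote(self._assertions([(1, "A")]), {1: 10}) == {("name", 10)}

    def test_votes_count_distinct_sources_not_substances(self):
        # one source re-depositing many substances is still one vote
        assertions = self._assertions([(1, "A"), (2, "A"), (3, "A"), (4, "B")])
        normalization = {1: 10, 2: 10, 3: 10, 4: 20}
        assert synonym_vote(assertions, normalization) == set()

    def test_unnormalized_substances_do_not_vote(self):
        assertions = self._assertions([(1, "A"), (2, "B")])
        assert synonym_vote(assertions, {1: 10}) == {("name", 10)}


class TestSubstanceTriples:
    def test_printed_chembl_substance_block(self):
        record = SubstanceRecord(
            sid=103554720, source_name="ChEMBL", chembl_id="CHEMBL1487",
            synonyms=[("atorvastatin", [])],
        )
        triples = set(emit_substance_triples(record, 60823))
        s = SUBSTANCE["SID103554720"]
        assert (s, DCTERMS["source"], SOURCE["ChEMBL"]) in triples
        assert (s, SIO["CHEMINF_000477"], COMPOUND["CID60823"]) in triples
        assert (s, SKOS.exactMatch,
                URIRef("http://rdf.ebi.ac.uk/resource/chembl/molecule/CHEMBL1487")) in triples
        assert (s, SKOS.exactMatch,
                URIRef("http://linkedchemistry.info/chembl/chemblid/CHEMBL1487")) in triples
        assert (s, SIO["has-attribute"],
                SYNO["MD5_9a05646d461669f86de312d88ab5748a"]) in triples

    def test_pdb_crosslink(self):
        record = SubstanceRecord(sid=822166, source_name="MMDB", pdb_id="1HWK")
        triples = set(emit_substance_triples(record, 60823))
        assert (SUBSTANCE["SID822166"], PDBO["link_to_pdb"],
                URIRef("http://rdf.wwpdb.org/pdb/1HWK")) in triples

    def test_pubmed_reference(self):
        record = SubstanceRecord(sid=1950, source_name="ChemIDplus", pubmed_ids=[11676470])
        triples = set(emit_substance_triples(record, None))
        assert (SUBSTANCE["SID1950"], CITO["isDiscussedBy"],
                URIRef("http://rdf.ncbi.nlm.nih.gov/pubchem/reference/PMID11676470")) in triples

    def test_failed_standardization_has_no_normalization_link(self):
        record = SubstanceRecord(sid=7, source_name="X")
        triples = emit_substance_triples(record, None)
        assert not any(p == SIO["CHEMINF_000477"] for _, p, _ in triples)
        assert sum(1 for _, p, _ in triples if p == DCTERMS["source"]) == 1


class TestCompoundTriples:
    def _mixture(self, parent):
        from chemrdf.chem import MolecularGraph, Atom
        g = MolecularGraph([Atom("C")], [])
        return CompoundRecord(
            cid=23665101, graph=g, canonical_key="InChI=1S/x",
            component_cids=[60823, 5360545],
            parent_cid=60823 if parent else None, is_mixture=True,
        )

    def test_mixture_with_parent(self):
        triples = set(emit_compound_triples(self._mixture(parent=True)))
        s = COMPOUND["CID23665101"]
        assert (s, VOCAB["has_parent"], COMPOUND["CID60823"]) in triples
        assert (s, SIO["CHEMINF_000480"], COMPOUND["CID5360545"]) in triples
        # the parent link is asserted as has_parent only; 000480 comes by inference
        assert (s, SIO["CHEMINF_000480"], COMPOUND["CID60823"]) not in triples

    def test_mixture_without_parent_gets_component_links_only(self):
        triples = set(emit_compound_triples(self._mixture(parent=False)))
        s = COMPOUND["CID23665101"]
        assert (s, SIO["CHEMINF_000480"], COMPOUND["CID60823"]) in triples
        assert (s, SIO["CHEMINF_000480"], COMPOUND["CID5360545"]) in triples
        assert not any(p == VOCAB["has_parent"] for _, p, _ in triples)

    def test_single_unit_compound_has_no_component_triples(self):
        from chemrdf.chem import MolecularGraph, Atom
        record = CompoundRecord(
            cid=1, graph=MolecularGraph([Atom("C")], []), canonical_key="InChI=1S/y",
        )
        triples = emit_compound_triples(record, descriptor_labels=["Molecular_Weight"])
        preds = {p for _, p, _ in triples}
        assert preds == {SIO["has-attribute"]}


def closure_oracle(triples: set) -> set:
    """Independent brute-force fixpoint: apply each rule until nothing new."""
    out = set(triples)
    sub = {}
    for specific, generic in SUBPROPERTY_AXIOMS:
        sub.setdefault(specific, []).append(generic)
    while True:
        new = set()
        for s, p, o in out:
            for generic in sub.get(p, []):
                new.add((s, generic, o))
            if p in SYMMETRIC_PREDICATES:
                new.add((o, p, s))
        if new <= out:
            return out
        out |= new


def random_relation_graph(rng: random.Random, n_triples: int) -> TripleGraph:
    predicates = [spec for spec, _ in SUBPROPERTY_AXIOMS] + list(SYMMETRIC_PREDICATES) + [
        DCTERMS["source"], SIO["has-attribute"],
    ]
    tg = TripleGraph()
    for _ in range(n_triples):
        s = COMPOUND[f"CID{rng.randint(1, 200)}"]
        o = COMPOUND[f"CID{rng.randint(1, 200)}"]
        tg.add((s, rng.choice(predicates), o))
    return tg


class TestMaterialization:
    def test_has_parent_entails_component_link(self):
        tg = TripleGraph()
        tg.add((COMPOUND["CID23665101"], VOCAB["has_parent"], COMPOUND["CID60823"]))
        inferred = materialize_inferences(tg)
        assert (COMPOUND["CID23665101"], SIO["CHEMINF_000480"], COMPOUND["CID60823"]) in inferred

    def test_specific_cig_entails_generic_and_mirror(self):
        tg = TripleGraph()
        a, b = COMPOUND["CID60823"], COMPOUND["CID10507504"]
        tg.add((a, SIO["CHEMINF_000455"], b))
        inferred = materialize_inferences(tg)
        for t in [(a, SIO["CHEMINF_000462"], b), (b, SIO["CHEMINF_000455"], a),
                  (b, SIO["CHEMINF_000462"], a)]:
            assert t in inferred

    def test_empty_graph_stays_empty(self):
        assert len(materialize_inferences(TripleGraph(), include_schema=False)) == 0

    def test_monotone_and_idempotent(self, synth_result):
        _, result = synth_result
        inferred = materialize_inferences(result.graph)
        assert set(result.graph) <= set(inferred)
        again = materialize_inferences(inferred)
        assert set(again) == set(inferred)

    @pytest.mark.parametrize("n_triples", [50, 500])
    def test_matches_brute_force_fixpoint(self, n_triples):
        rng = random.Random(n_triples)
        tg = random_relation_graph(rng, n_triples)
        inferred = materialize_inferences(tg, include_schema=False)
        assert set(inferred) == closure_oracle(set(tg))


class TestTurtleIO:
    def test_round_trip_worked_example(self, worked_example):
        text = serialize_turtle(worked_example.graph)
        assert parse_turtle(text).isomorphic(worked_example.graph)

    def test_serialization_stable(self, worked_example):
        g = worked_example.graph
        first = parse_turtle(serialize_turtle(g))
        second = parse_turtle(serialize_turtle(first))
        assert first.isomorphic(second)

    def test_prefix_header_present(self, worked_example):
        text = serialize_turtle(worked_example.graph)
        assert "@prefix compound: <http://rdf.ncbi.nlm.nih.gov/pubchem/compound/> ." in text
        assert "@prefix vocab: <http://rdf.ncbi.nlm.nih.gov/pubchem/vocabulary#> ." in text

    def test_double_literal_preserved_exactly(self, worked_example):
        text = serialize_turtle(worked_example.graph)
        assert '"558.639803"^^xsd:double' in text

    def test_undefined_prefix_raises_with_line(self):
        with pytest.raises(TurtleSyntaxError, match="line"):
            parse_turtle("foo:a foo:b foo:c .")


class TestPartition:
    def test_subjects_route_to_their_subdomain(self, synth_result):
        _, result = synth_result
        parts = partition_by_subdomain(result.graph)
        for name, expected_prefix in [
            ("substance", str(SUBSTANCE)), ("compound", str(COMPOUND)),
            ("descriptor", str(DESCR)), ("synonym", str(SYNO)),
        ]:
            assert name in parts
            for s, _, _ in parts[name]:
                assert str(s).startswith(expected_prefix)
        total = sum(len(g) for g in parts.values())
        assert total == len(result.graph)


class TestExampleQueries:
    def test_substances_by_compound(self, worked_example):
        inferred = materialize_inferences(worked_example.graph)
        rows = run_example_query(inferred, "substances-by-compound")
        assert len(rows) == 5
        assert all(row[0].startswith(str(SUBSTANCE)) for row in rows)
        sources = {row[1] for row in rows}
        assert str(SOURCE["ChEMBL"]) in sources and str(SOURCE["MMDB"]) in sources

    def test_pdb_ligand_roles_returns_two_roles(self, worked_example):
        inferred = materialize_inferences(worked_example.graph)
        rows = run_example_query(inferred, "pdb-ligand-roles")
        assert [r[0] for r in rows] == [
            "antilipemic drug",
            "hydroxymethylglutaryl-CoA reductase inhibitor",
        ]

    def test_mw_filter_excludes_heavy_compound(self, worked_example):
        inferred = materialize_inferences(worked_example.graph)
        assert run_example_query(inferred, "nsaid-mw-filter") == []

    def test_unknown_query_name_rejected(self, worked_example):
        with pytest.raises(KeyError):
            run_example_query(worked_example.graph, "no-such-query")

    def test_rows_are_sorted(self, worked_example):
        inferred = materialize_inferences(worked_example.graph)
        rows = run_example_query(inferred, "substances-by-compound")
        assert rows == sorted(rows)
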