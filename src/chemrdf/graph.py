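"""Triple assembly, entailment materialization, Turtle I/O and queries.

Triples are organized exactly as the subdomain model prescribes: substance
provenance and attributes, compound descriptors and interrelations
(components, parent, identity groups, similarity), synonym/InChIKey
annotations, and data-source metadata as SKOS-categorized Datasets.  The
asserted graph stays minimal — only the most specific predicate of each
family is written — and the entailed statements (subproperty closure of
``vocab:has_parent`` under CHEMINF_000480 and of the specific identity
predicates under CHEMINF_000462, plus mirroring of the symmetric
predicates) are recovered by a small fixpoint materializer rather than a
general OWL reasoner.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import rdflib
from rdflib import Graph, Literal, RDF, RDFS, URIRef
from rdflib.compare import to_isomorphic
from rdflib.namespace import SKOS, XSD
from rdflib.plugin import register as _register_plugin
from rdflib.plugins.serializers.turtle import TurtleSerializer
from rdflib.serializer import Serializer

from .chem import CompoundRecord, SubstanceRecord
from .descriptors import CheminfCatalog, DescriptorAssertion, DEFAULT_CATALOG
from .identity import CigRelation
from .namespaces import (
    DEFAULT_NAMESPACES,
    NamespaceTable,
    mint_descriptor_iri,
    mint_entity_iri,
    mint_inchikey_iri,
    mint_synonym_iri,
)

__all__ = [
    "TripleGraph",
    "SynonymAssertion",
    "synonym_vote",
    "emit_substance_triples",
    "emit_compound_triples",
    "emit_annotation_triples",
    "descriptor_triples",
    "materialize_inferences",
    "serialize_turtle",
    "parse_turtle",
    "run_example_query",
    "EXAMPLE_QUERIES",
    "SUBDOMAIN_OF_SUBJECT",
]

Triple = tuple[URIRef, URIRef, object]


class _ExactTurtleSerializer(TurtleSerializer):
    """Turtle writer that keeps xsd:double lexical forms intact.

    The stock writer renders doubles as bare numeric tokens via ``%e`` with
    six significant digits, which silently truncates values such as
    558.639803; quoting them as typed literals is equally valid Turtle and
    lossless, so serialize-parse round-trips preserve graph equality.
    """

    def label(self, node, position):
        if isinstance(node, Literal) and node.datatype == XSD.double:
            qname = getattr(self, "get_pname", None) or self.getQName
            return node._literal_n3(use_plain=False, qname_callback=qname)
        return super().label(node, position)


_register_plugin("chemrdf-turtle", Serializer, "chemrdf.graph", "_ExactTurtleSerializer")


class TurtleSyntaxError(ValueError):
    """Malformed Turtle input; message carries the offending line number."""


@dataclass
class TripleGraph:
    """A set of triples with the subdomain namespace table bound.

    Thin wrapper over an rdflib graph: set semantics, prefix header on
    serialization, and isomorphism comparison for round-trip checks.
    """

    graph: Graph = dc_field(default_factory=Graph)
    namespaces: NamespaceTable = dc_field(default_factory=lambda: DEFAULT_NAMESPACES)

    def __post_init__(self) -> None:
        self.namespaces.bind_all(self.graph)

    def add(self, triple: Triple) -> None:
        self.graph.add(triple)

    def update(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.graph.add(t)

    def __len__(self) -> int:
        return len(self.graph)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.graph)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.graph

    def copy(self) -> "TripleGraph":
        out = TripleGraph(namespaces=self.namespaces)
        out.update(self.graph)
        return out

    def isomorphic(self, other: "TripleGraph") -> bool:
        return to_isomorphic(self.graph) == to_isomorphic(other.graph)


# -- entailment ------------------------------------------------------------

_SIO = DEFAULT_NAMESPACES.namespace("sio")
_VOCAB = DEFAULT_NAMESPACES.namespace("vocab")

#: subproperty axioms demonstrated by the data model (specific -> generic)
SUBPROPERTY_AXIOMS: tuple[tuple[URIRef, URIRef], ...] = (
    (_VOCAB["has_parent"], _SIO["CHEMINF_000480"]),
    (_SIO["CHEMINF_000455"], _SIO["CHEMINF_000462"]),
    (_SIO["CHEMINF_000461"], _SIO["CHEMINF_000462"]),
)

#: compound-to-compound predicates declared symmetric
SYMMETRIC_PREDICATES: tuple[URIRef, ...] = (
    _SIO["CHEMINF_000455"],
    _SIO["CHEMINF_000461"],
    _SIO["CHEMINF_000462"],
    _SIO["CHEMINF_000482"],
    _SIO["CHEMINF_000483"],
)


def materialize_inferences(tg: TripleGraph, include_schema: bool = True) -> TripleGraph:
    """Fixpoint closure under the subproperty and symmetry rules.

    Monotone (output contains the input) and idempotent (a second
    application adds nothing).  When ``include_schema`` is set, the
    ``rdfs:subPropertyOf`` axioms themselves are also written so queries
    can inspect the rule set.
    """
    out = tg.copy()
    g = out.graph
    if include_schema:
        for specific, generic in SUBPROPERTY_AXIOMS:
            g.add((specific, RDFS.subPropertyOf, generic))
    sub_map: dict[URIRef, set[URIRef]] = {}
    for specific, generic in SUBPROPERTY_AXIOMS:
        sub_map.setdefault(specific, set()).add(generic)
    symmetric = set(SYMMETRIC_PREDICATES)
    changed = True
    while changed:
        changed = False
        for s, p, o in list(g):
            for generic in sub_map.get(p, ()):
                if (s, generic, o) not in g:
                    g.add((s, generic, o))
                    changed = True
            if p in symmetric and (o, p, s) not in g:
                g.add((o, p, s))
                changed = True
    return out


# -- synonym voting --------------------------------------------------------


@dataclass(frozen=True)
class SynonymAssertion:
    """One depositor-provided name on one substance."""

    text: str
    sid: int
    source_name: str
    type_labels: tuple[str, ...] = ()
    mesh_id: Optional[str] = None
    atc_code: Optional[str] = None

    @property
    def key(self) -> str:
        return self.text.casefold()


def synonym_vote(
    assertions: Sequence[SynonymAssertion],
    normalization: Mapping[int, int],
) -> set[tuple[str, int]]:
    """Name/structure voting: promote a synonym to a compound only when a
    strict majority of distinct sources backs that compound.

    Votes are counted as distinct source names per (synonym, CID); the
    winning CID must strictly out-vote every other CID associated with the
    same (case-folded) name.  Returns ``(synonym text key, cid)`` pairs.
    """
    votes: dict[str, dict[int, set[str]]] = {}
    for a in assertions:
        cid = normalization.get(a.sid)
        if cid is None:
            continue
        votes.setdefault(a.key, {}).setdefault(cid, set()).add(a.source_name)
    promotions: set[tuple[str, int]] = set()
    for key, by_cid in votes.items():
        counts = sorted(((len(srcs), cid) for cid, srcs in by_cid.items()), reverse=True)
        if len(counts) == 1 or counts[0][0] > counts[1][0]:
            promotions.add((key, counts[0][1]))
    return promotions


# -- emission --------------------------------------------------------------

_DATATYPES = {
    "double": XSD.double,
    "integer": XSD.integer,
    "nonNegativeInteger": XSD.nonNegativeInteger,
}


def descriptor_triples(
    assertion: DescriptorAssertion,
    table: NamespaceTable = DEFAULT_NAMESPACES,
    link_software: bool = False,
) -> list[Triple]:
    """Descriptor-subdomain triples for one assertion: type, value, unit.

    The software provenance link is recorded in the assertion but only
    emitted when requested; the exported model shows explicit software
    provenance for similarity scores, not plain descriptors.
    """
    sio = table.namespace("sio")
    obo = table.namespace("obo")
    subject = mint_descriptor_iri(assertion.entity_label, assertion.descriptor_label, table)
    triples: list[Triple] = []
    if assertion.cheminf_type:
        triples.append((subject, RDF.type, sio[assertion.cheminf_type]))
    dtype = _DATATYPES.get(assertion.datatype)
    value = Literal(assertion.value, datatype=dtype) if dtype else Literal(assertion.value)
    triples.append((subject, sio["has-value"], value))
    if assertion.unit:
        triples.append((subject, sio["has-unit"], obo[assertion.unit]))
    if link_software and assertion.software:
        triples.append((subject, sio["is-output-of"], sio[assertion.software]))
    return triples


def emit_substance_triples(
    record: SubstanceRecord,
    cid: Optional[int],
    catalog: CheminfCatalog = DEFAULT_CATALOG,
    table: NamespaceTable = DEFAULT_NAMESPACES,
    chebi_class: Optional[str] = None,
) -> list[Triple]:
    """Substance-subdomain triples for one depositor record.

    Provenance (``dcterms:source``), the normalization link to the
    compound (CHEMINF_000477) when standardization succeeded, version and
    synonym attributes, ChEBI typing (the record's own or one propagated
    from a co-normalized ChEBI deposition), and PDB/ChEMBL/PubMed
    cross-references.
    """
    sio = table.namespace("sio")
    cheminf = table.namespace("cheminf")
    obo = table.namespace("obo")
    dcterms = table.namespace("dcterms")
    cito = table.namespace("cito")
    pdbo = table.namespace("pdbo")

    subject = mint_entity_iri("substance", record.sid, table)
    triples: list[Triple] = [
        (subject, dcterms["source"], mint_entity_iri("source", record.source_name, table)),
    ]
    if cid is not None:
        triples.append((subject, cheminf["CHEMINF_000477"], mint_entity_iri("compound", cid, table)))
    version_node = mint_descriptor_iri(f"SID{record.sid}", "Substance_Version", table)
    triples.append((subject, sio["has-attribute"], version_node))
    for text, _labels in record.synonyms:
        triples.append((subject, sio["has-attribute"], mint_synonym_iri(text, table)))
    effective_chebi = chebi_class or record.chebi_class
    if effective_chebi:
        triples.append((subject, RDF.type, obo[effective_chebi]))
    if record.pdb_id:
        if record.pdb_id.strip() and len(record.pdb_id.strip()) == 4:
            triples.append(
                (subject, pdbo["link_to_pdb"], table.term("pdbr", record.pdb_id.strip()))
            )
    if record.chembl_id:
        chembl_id = record.chembl_id.strip()
        if chembl_id:
            triples.append((subject, SKOS.exactMatch, table.term("chembl", chembl_id)))
            triples.append((subject, SKOS.exactMatch, table.term("linkedchem", chembl_id)))
    for pmid in record.pubmed_ids:
        triples.append((subject, cito["isDiscussedBy"], mint_entity_iri("reference", pmid, table)))
    return triples


def emit_compound_triples(
    record: CompoundRecord,
    descriptor_labels: Sequence[str] = (),
    cig_relations: Sequence[CigRelation] = (),
    table: NamespaceTable = DEFAULT_NAMESPACES,
    chebi_class: Optional[str] = None,
) -> list[Triple]:
    """Compound-subdomain triples: descriptor attribute links, mixture
    composition (CHEMINF_000480 to each non-parent component, or
    ``vocab:has_parent`` for the designated parent), and the most specific
    identity-group predicate per related pair."""
    sio = table.namespace("sio")
    cheminf = table.namespace("cheminf")
    vocab = table.namespace("vocab")
    obo = table.namespace("obo")
    subject = mint_entity_iri("compound", record.cid, table)
    triples: list[Triple] = []
    for label in descriptor_labels:
        triples.append(
            (subject, sio["has-attribute"], mint_descriptor_iri(f"CID{record.cid}", label, table))
        )
    if chebi_class:
        triples.append((subject, RDF.type, obo[chebi_class]))
    for comp_cid in record.component_cids:
        comp = mint_entity_iri("compound", comp_cid, table)
        if record.parent_cid is not None and comp_cid == record.parent_cid:
            triples.append((subject, vocab["has_parent"], comp))
        else:
            triples.append((subject, cheminf["CHEMINF_000480"], comp))
    for rel in cig_relations:
        if record.cid == rel.cid_a:
            other = mint_entity_iri("compound", rel.cid_b, table)
            triples.append((subject, cheminf[rel.predicate], other))
    return triples


def emit_annotation_triples(
    synonym_assertions: Sequence[SynonymAssertion],
    promotions: set[tuple[str, int]],
    inchikeys: Mapping[int, str] = {},
    sources: Mapping[str, Mapping] = {},
    inchikey_mesh: Mapping[str, str] = {},
    catalog: CheminfCatalog = DEFAULT_CATALOG,
    table: NamespaceTable = DEFAULT_NAMESPACES,
    known_cids: Optional[set[int]] = None,
) -> list[Triple]:
    """Synonym, InChIKey and source subdomain triples.

    Synonym nodes are typed per the depositor-identifier catalog
    (unrecognized labels fall back to the depositor-supplied-name class),
    carry their case-folded text, point back to the compound for voted
    promotions, and carry MeSH/ATC subject annotations.  InChIKey nodes
    link to their compound.  Sources become ``dcterms:Dataset`` instances
    categorized by SKOS concepts in the Substance Categorization
    Classification scheme.
    """
    sio = table.namespace("sio")
    dcterms = table.namespace("dcterms")
    triples: list[Triple] = []

    by_key: dict[str, list[SynonymAssertion]] = {}
    for a in synonym_assertions:
        by_key.setdefault(a.key, []).append(a)
    promoted = {key: cid for key, cid in promotions}
    for key, group in by_key.items():
        node = mint_synonym_iri(key, table)
        type_ids = {catalog.synonym_type(lbl) for a in group for lbl in a.type_labels}
        if not type_ids:
            type_ids = {catalog.UNRECOGNIZED_SYNONYM_TYPE}
        for tid in sorted(type_ids):
            triples.append((node, RDF.type, sio[tid]))
        triples.append((node, sio["has-value"], Literal(key)))
        if key in promoted:
            cid = promoted[key]
            if known_cids is not None and cid not in known_cids:
                raise KeyError(f"promotion references unknown CID{cid}")
            triples.append((node, sio["is-attribute-of"], mint_entity_iri("compound", cid, table)))
        for a in group:
            if a.mesh_id:
                triples.append((node, dcterms["subject"], table.term("mesh", a.mesh_id)))
            if a.atc_code:
                triples.append(
                    (node, dcterms["subject"], mint_entity_iri("concept", "ATC_" + a.atc_code, table))
                )

    for cid, key in inchikeys.items():
        node = mint_inchikey_iri(key, table)
        triples.append((node, sio["is-attribute-of"], mint_entity_iri("compound", cid, table)))
        if key in inchikey_mesh:
            triples.append((node, dcterms["subject"], table.term("mesh", inchikey_mesh[key])))

    scheme = mint_entity_iri("concept", "Substance_Categorization_Classification", table)
    for name, meta in sources.items():
        node = mint_entity_iri("source", name, table)
        triples.append((node, RDF.type, dcterms["Dataset"]))
        triples.append((node, dcterms["title"], Literal(meta.get("title", name))))
        if meta.get("alternative"):
            triples.append((node, dcterms["alternative"], Literal(meta["alternative"])))
        for category in meta.get("categories", ()):
            concept = mint_entity_iri("concept", category, table)
            triples.append((node, dcterms["subject"], concept))
            triples.append((concept, RDF.type, SKOS.Concept))
            triples.append((concept, SKOS.inScheme, scheme))
            triples.append((concept, SKOS.prefLabel, Literal(category)))
    return triples


# -- Turtle I/O ------------------------------------------------------------


def serialize_turtle(tg: TripleGraph) -> str:
    return tg.graph.serialize(format="chemrdf-turtle")


def parse_turtle(text: str, table: NamespaceTable = DEFAULT_NAMESPACES) -> TripleGraph:
    tg = TripleGraph(namespaces=table)
    try:
        tg.graph.parse(data=text, format="turtle")
    except rdflib.plugins.parsers.notation3.BadSyntax as exc:
        raise TurtleSyntaxError(f"Turtle syntax error at line {exc.lines + 1}: {exc._why}")
    return tg


#: subdomain name per subject-IRI prefix, for one-file-per-subdomain output
SUBDOMAIN_OF_SUBJECT = (
    ("substance", "substance"),
    ("compound", "compound"),
    ("descr", "descriptor"),
    ("syno", "synonym"),
    ("inchikey", "inchikey"),
    ("nbr", "neighbor"),
    ("source", "source"),
)


def partition_by_subdomain(tg: TripleGraph) -> dict[str, TripleGraph]:
    """Split a graph into one graph per subdomain keyed on the subject IRI;
    triples whose subject is external land in the catch-all 'other'."""
    table = tg.namespaces
    prefixes = [(table.entries[p], name) for p, name in SUBDOMAIN_OF_SUBJECT]
    out: dict[str, TripleGraph] = {}
    for s, p, o in tg:
        name = "other"
        subject_str = str(s)
        for base, candidate in prefixes:
            if subject_str.startswith(base):
                name = candidate
                break
        out.setdefault(name, TripleGraph(namespaces=table)).add((s, p, o))
    return out


# -- example queries -------------------------------------------------------

EXAMPLE_QUERIES = {
    "substances-by-compound": "substances_by_compound.rq",
    "pdb-ligand-roles": "pdb_ligand_roles.rq",
    "nsaid-mw-filter": "nsaid_mw_filter.rq",
    "nsaid-3d-sources": "nsaid_3d_sources.rq",
}


def load_query(name: str) -> str:
    try:
        filename = EXAMPLE_QUERIES[name]
    except KeyError:
        raise KeyError(f"unknown query {name!r}; known: {sorted(EXAMPLE_QUERIES)}")
    return resources.files("chemrdf.queries").joinpath(filename).read_text()


def run_example_query(
    tg: TripleGraph,
    name: str,
    cid: int = 60823,
    pdb_id: str = "1HWK",
) -> list[tuple[str, ...]]:
    """Run one of the shipped SPARQL queries; rows are sorted lexically.

    The query texts are written against the worked example (CID60823,
    PDB 1HWK); ``cid``/``pdb_id`` retarget them at other graphs.
    """
    text = load_query(name)
    text = text.replace("CID60823", f"CID{cid}").replace("1HWK", pdb_id)
    rows = [
        tuple("" if v is None else str(v) for v in row)
        for row in tg.graph.query(text)
    ]
    return sorted(rows)
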