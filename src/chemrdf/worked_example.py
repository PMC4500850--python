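"""The atorvastatin worked example.

Builds, from first principles, the published RDF neighborhood of
atorvastatin (compound accession CID60823): four depositions from ChEMBL,
ChEBI, MMDB and a fourth depositor, the normalization links, the ChEBI
class typing with its two pharmacological-role restrictions, the
PDB/ChEMBL cross-references, MeSH and ATC subject annotations, the
molecular-weight descriptor, the calcium-salt mixture with its parent
designation, the identity-group relations, and the 2-D/3-D n-ary
similarity associations with their published scores (0.98, 0.88, 0.59).

The structure itself is carried as a molfile rebuilt from an isomeric
SMILES and validated at build time against the known InChIKey
(XUKUURHRXDUEBC-KAYWLYCHSA-N), which guards against fixture drift.  The
accession numbers are those of the public archive and serve as fixed
inputs; similarity and 3-D scores are inputs too, since fingerprint
generation and conformer scoring are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import BNode, Literal, RDF, RDFS, URIRef
from rdflib.namespace import OWL

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import (
    CompoundRecord,
    MolecularGraph,
    SubstanceRecord,
    designate_parent,
    neutralize,
    parse_sdf,
    split_covalent_units,
)
from .descriptors import (
    DEFAULT_CATALOG,
    DEFAULT_WEIGHTS,
    adapter_descriptors,
    build_descriptor_assertions,
    compute_native_descriptors,
)
from .graph import (
    SynonymAssertion,
    TripleGraph,
    descriptor_triples,
    emit_annotation_triples,
    emit_compound_triples,
    emit_substance_triples,
    synonym_vote,
)
from .identity import CigRelation, ISOTOPOLOGUE_OF, STEREOISOMER_OF
from .namespaces import DEFAULT_NAMESPACES
from .similarity import NeighborPair, similarity_triples

__all__ = [
    "ATORVASTATIN_SMILES",
    "ATORVASTATIN_INCHIKEY",
    "WorkedExample",
    "atorvastatin_molfile",
    "atorvastatin_calcium_molfile",
    "build_worked_example",
]

ATORVASTATIN_SMILES = (
    "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)"
    "n1CC[C@@H](O)C[C@@H](O)CC(=O)O"
)
ATORVASTATIN_INCHIKEY = "XUKUURHRXDUEBC-KAYWLYCHSA-N"

# the published accessions used as fixed inputs
CID_ATORVASTATIN = 60823
CID_CALCIUM_SALT = 23665101
CID_CALCIUM_ION = 5360545
CID_ISOTOPOLOGUE = 10507504
CID_STEREOISOMER = 21029434
CID_2D_NEIGHBOR = 10030610
CID_3D_NEIGHBOR = 11330946

CHEBI_ATORVASTATIN = "CHEBI_39548"
ROLE_AXIOMS = (
    ("CHEBI_35821", "antilipemic drug"),
    ("CHEBI_35664", "hydroxymethylglutaryl-CoA reductase inhibitor"),
)


class FixtureDriftError(RuntimeError):
    """The rebuilt structure no longer matches the pinned InChIKey."""


def _smiles_to_molfile(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    AllChem.Compute2DCoords(mol)
    return Chem.MolToMolBlock(mol, kekulize=True)


def atorvastatin_molfile() -> str:
    """Atorvastatin free acid as a V2000 molfile (stereo as wedges)."""
    return _smiles_to_molfile(ATORVASTATIN_SMILES)


def atorvastatin_calcium_molfile() -> str:
    """The 2:1 atorvastatin–calcium salt as a single multi-unit molfile."""
    anion = ATORVASTATIN_SMILES.replace("C(=O)O", "C(=O)[O-]")
    return _smiles_to_molfile(f"{anion}.{anion}.[Ca+2]")


@dataclass
class WorkedExample:
    graph: TripleGraph
    substances: list[SubstanceRecord]
    compound: CompoundRecord
    salt: CompoundRecord
    molfile: str
    salt_molfile: str
    structure: MolecularGraph
    role_labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(label for _, label in ROLE_AXIOMS)
    )


def _substance_records() -> list[SubstanceRecord]:
    return [
        SubstanceRecord(
            sid=103554720,
            source_name="ChEMBL",
            synonyms=[
                ("atorvastatin", ["International nonproprietary name"]),
                ("CHEMBL1487", ["ChEMBL identifier"]),
            ],
            chembl_id="CHEMBL1487",
            mesh_id="M0179294",
            atc_code="C10AA05",
        ),
        SubstanceRecord(
            sid=43118161,
            source_name="DrugBank",
            synonyms=[("atorvastatin", [])],
        ),
        SubstanceRecord(
            sid=26697365,
            source_name="ChEBI",
            synonyms=[("atorvastatin", [])],
            chebi_class=CHEBI_ATORVASTATIN,
        ),
        SubstanceRecord(
            sid=822166,
            source_name="MMDB",
            pdb_id="1HWK",
        ),
        SubstanceRecord(
            sid=1950,
            source_name="ChemIDplus",
            pubmed_ids=[11676470],
        ),
    ]


def build_worked_example(table=DEFAULT_NAMESPACES) -> WorkedExample:
    """Assemble the full worked-example graph; see the module docstring."""
    molfile = atorvastatin_molfile()
    (structure, _fields), = parse_sdf(molfile + "$$$$\n")
    adapted = adapter_descriptors(structure)
    if adapted.get("IUPAC_InChIKey") != ATORVASTATIN_INCHIKEY:
        raise FixtureDriftError(
            f"expected {ATORVASTATIN_INCHIKEY}, got {adapted.get('IUPAC_InChIKey')}"
        )

    tg = TripleGraph(namespaces=table)
    sio = table.namespace("sio")
    obo = table.namespace("obo")
    obov = table.namespace("obov")

    records = _substance_records()
    cid_map = {rec.sid: CID_ATORVASTATIN for rec in records}
    for rec in records:
        tg.update(
            emit_substance_triples(
                rec, cid_map[rec.sid], DEFAULT_CATALOG, table,
                chebi_class=CHEBI_ATORVASTATIN,
            )
        )
        for a in build_descriptor_assertions(
            f"SID{rec.sid}", {"Substance_Version": rec.version}
        ):
            tg.update(descriptor_triples(a, table))

    # descriptor block for the compound (native + adapter values)
    native = compute_native_descriptors(structure, DEFAULT_WEIGHTS)
    values = {**native, **adapted}
    assertions = build_descriptor_assertions(f"CID{CID_ATORVASTATIN}", values)
    for a in assertions:
        tg.update(descriptor_triples(a, table))

    # the calcium-salt mixture: components and parent computed, not asserted
    salt_molfile = atorvastatin_calcium_molfile()
    (salt_graph, _), = parse_sdf(salt_molfile + "$$$$\n")
    _units, unique_units = split_covalent_units(salt_graph)
    neutral_units = [(neutralize(u), m) for u, m in unique_units]
    parent_idx = designate_parent(neutral_units)
    if parent_idx is None:
        raise FixtureDriftError("salt fixture lost its parent designation")
    component_cids = [
        CID_ATORVASTATIN if i == parent_idx else CID_CALCIUM_ION
        for i in range(len(unique_units))
    ]
    salt = CompoundRecord(
        cid=CID_CALCIUM_SALT,
        graph=salt_graph,
        canonical_key=salt_graph.canonical_key() or "",
        component_cids=component_cids,
        parent_cid=CID_ATORVASTATIN,
        is_mixture=True,
    )
    tg.update(emit_compound_triples(salt, (), (), table))

    compound = CompoundRecord(
        cid=CID_ATORVASTATIN,
        graph=structure,
        canonical_key=structure.canonical_key() or "",
    )
    cig = [
        CigRelation(*sorted((CID_ATORVASTATIN, CID_ISOTOPOLOGUE)), ISOTOPOLOGUE_OF),
        CigRelation(*sorted((CID_ATORVASTATIN, CID_STEREOISOMER)), STEREOISOMER_OF),
    ]
    tg.update(
        emit_compound_triples(
            compound,
            [a.descriptor_label for a in assertions],
            [r for r in cig if r.cid_a == CID_ATORVASTATIN],
            table,
            chebi_class=CHEBI_ATORVASTATIN,
        )
    )
    # relations whose canonical (lower-CID-first) form starts at the partner
    for rel in cig:
        if rel.cid_a != CID_ATORVASTATIN:
            tg.add((
                table.term("compound", f"CID{rel.cid_a}"),
                sio[rel.predicate],
                table.term("compound", f"CID{rel.cid_b}"),
            ))

    # published similarity neighbors with their scores as inputs
    pairs = [
        NeighborPair(*sorted((CID_ATORVASTATIN, CID_2D_NEIGHBOR)), kind="2D",
                     tanimoto_2d=0.98),
        NeighborPair(*sorted((CID_ATORVASTATIN, CID_3D_NEIGHBOR)), kind="3D",
                     st=0.88, ct=0.59),
    ]
    for pair in pairs:
        tg.update(similarity_triples(pair, table))

    # ChEBI-style role axioms: class subClassOf (restriction on has_role)
    chebi_class = obo[CHEBI_ATORVASTATIN]
    for role_id, label in ROLE_AXIOMS:
        restriction = BNode()
        tg.add((chebi_class, RDFS.subClassOf, restriction))
        tg.add((restriction, RDF.type, OWL.Restriction))
        tg.add((restriction, OWL.onProperty, obov["has_role"]))
        tg.add((restriction, OWL.someValuesFrom, obo[role_id]))
        tg.add((obo[role_id], RDFS.label, Literal(label)))

    # synonym and InChIKey annotations; the vote promotes "atorvastatin"
    synonym_assertions = [
        SynonymAssertion(
            text, rec.sid, rec.source_name, tuple(labels),
            # subject annotations belong to the chemical name, not to the
            # depositor-identifier synonyms
            mesh_id=rec.mesh_id if text.casefold() == "atorvastatin" else None,
            atc_code=rec.atc_code if text.casefold() == "atorvastatin" else None,
        )
        for rec in records
        for text, labels in rec.synonyms
    ]
    promotions = synonym_vote(synonym_assertions, cid_map)
    sources = {
        "ChEMBL": {"title": "ChEMBL", "alternative": "ChEMBL database",
                   "categories": ["Biological_Properties"]},
        "DrugBank": {"title": "DrugBank"},
        "ChEBI": {"title": "ChEBI",
                  "categories": ["Biological_Properties"]},
        "MMDB": {"title": "MMDB", "alternative": "Molecular Modeling Database",
                 "categories": ["Protein_3D_Structures"]},
        "ChemIDplus": {"title": "ChemIDplus", "categories": ["Toxicology"]},
    }
    tg.update(
        emit_annotation_triples(
            synonym_assertions,
            promotions,
            inchikeys={CID_ATORVASTATIN: ATORVASTATIN_INCHIKEY},
            sources=sources,
            inchikey_mesh={ATORVASTATIN_INCHIKEY: "M0179294"},
            table=table,
            known_cids={CID_ATORVASTATIN},
        )
    )

    return WorkedExample(
        graph=tg,
        substances=records,
        compound=compound,
        salt=salt,
        molfile=molfile,
        salt_molfile=salt_molfile,
        structure=structure,
    )
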