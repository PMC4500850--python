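"""End-to-end conversion: depositor records -> subdomain Turtle graphs.

The pipeline mirrors the archive's processing order: parse and validate
each deposition, standardize structures into the compound registry, compute
and type descriptors, derive identity-group and similarity relations, vote
on name/structure associations, and emit the substance, compound,
descriptor, synonym, InChIKey, neighbor and source subdomain graphs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .chem import (
    CompoundRegistry,
    StandardizationConfig,
    SubstanceRecord,
    parse_sdf,
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
    partition_by_subdomain,
    synonym_vote,
)
from .identity import build_cig_relations
from .namespaces import DEFAULT_NAMESPACES, NamespaceTable
from .similarity import (
    SimilarityConfig,
    decode_cactvs_subskeys,
    neighbor_pairs,
    similarity_triples,
)

__all__ = ["ConversionResult", "convert_records", "load_deposition"]

FINGERPRINT_FIELD = "PUBCHEM_CACTVS_SUBSKEYS"
SID_FIELD = "PUBCHEM_SUBSTANCE_ID"


@dataclass
class ConversionResult:
    """Everything one conversion run produced."""

    registry: CompoundRegistry
    sid_to_cid: dict[int, int]
    graph: TripleGraph                       # merged, asserted-only
    pairs: list = field(default_factory=list)
    promotions: set = field(default_factory=set)

    def subdomains(self) -> dict[str, TripleGraph]:
        return partition_by_subdomain(self.graph)


def load_deposition(sdf_text: str, metadata: Mapping | str) -> list[SubstanceRecord]:
    """Join an SDF stream with its depositor metadata into substance records.

    SDF records are matched to metadata entries by the substance-accession
    data field when present, else positionally.  Metadata entries without a
    matching SDF record become structureless substances (names-only
    depositions are legal).
    """
    if isinstance(metadata, str):
        metadata = json.loads(metadata)
    parsed = parse_sdf(sdf_text) if sdf_text.strip() else []
    by_sid: dict[int, tuple] = {}
    leftovers: list[tuple] = []
    for graph, fields in parsed:
        sid_text = fields.get(SID_FIELD, "").strip()
        if sid_text.isdigit():
            by_sid[int(sid_text)] = (graph, fields)
        else:
            leftovers.append((graph, fields))
    records: list[SubstanceRecord] = []
    for entry in metadata["substances"]:
        sid = int(entry["sid"])
        graph, fields = None, {}
        if sid in by_sid:
            graph, fields = by_sid.pop(sid)
        elif leftovers:
            graph, fields = leftovers.pop(0)
        xrefs = entry.get("xrefs", {})
        records.append(
            SubstanceRecord(
                sid=sid,
                source_name=entry["source"],
                version=int(entry.get("version", 1)),
                synonyms=[
                    (s["text"], list(s.get("types", []))) for s in entry.get("synonyms", [])
                ],
                pdb_id=xrefs.get("pdb"),
                chembl_id=xrefs.get("chembl"),
                pubmed_ids=[int(p) for p in xrefs.get("pubmed", [])],
                mesh_id=xrefs.get("mesh"),
                atc_code=xrefs.get("atc"),
                chebi_class=xrefs.get("chebi"),
                structure=graph,
                fingerprint_b64=fields.get(FINGERPRINT_FIELD),
                passthrough=dict(fields),
            )
        )
    return records


def convert_records(
    records: Sequence[SubstanceRecord],
    three_d_scores: Sequence[tuple] | None = None,
    source_meta: Mapping[str, Mapping] | None = None,
    std_config: StandardizationConfig | None = None,
    sim_config: SimilarityConfig | None = None,
    table: NamespaceTable = DEFAULT_NAMESPACES,
    catalog=DEFAULT_CATALOG,
    weights=DEFAULT_WEIGHTS,
) -> ConversionResult:
    """Run the full mapping over in-memory substance records."""
    registry = CompoundRegistry(std_config)
    sid_to_cid: dict[int, int] = {}
    for rec in sorted(records, key=lambda r: r.sid):
        if rec.structure is None:
            continue
        cid = registry.register(rec.structure)
        if cid is not None:
            sid_to_cid[rec.sid] = cid

    # ChEBI typing propagates from any ChEBI-classed deposition to the
    # compound and every co-normalized substance.
    chebi_of_cid: dict[int, str] = {}
    for rec in records:
        if rec.chebi_class and rec.sid in sid_to_cid:
            chebi_of_cid.setdefault(sid_to_cid[rec.sid], rec.chebi_class)

    tg = TripleGraph(namespaces=table)

    # -- descriptors per compound -----------------------------------------
    passthrough_of_cid: dict[int, Mapping[str, str]] = {}
    for rec in records:
        cid = sid_to_cid.get(rec.sid)
        if cid is not None and cid not in passthrough_of_cid and rec.passthrough:
            passthrough_of_cid[cid] = rec.passthrough

    descriptor_labels: dict[int, list[str]] = {}
    hba_of_cid: dict[int, int] = {}
    inchikey_of_cid: dict[int, str] = {}
    for comp in registry:
        native = compute_native_descriptors(comp.graph, weights)
        adapted = adapter_descriptors(comp.graph, passthrough_of_cid.get(comp.cid))
        values = {**native, **adapted}
        hba_of_cid[comp.cid] = int(native["Hydrogen_Bond_Acceptor_Count"])
        if "IUPAC_InChIKey" in adapted:
            inchikey_of_cid[comp.cid] = adapted["IUPAC_InChIKey"]
        assertions = build_descriptor_assertions(f"CID{comp.cid}", values, catalog)
        for assertion in assertions:
            tg.update(descriptor_triples(assertion, table))
        descriptor_labels[comp.cid] = [a.descriptor_label for a in assertions]

    # -- identity and similarity ------------------------------------------
    cig = build_cig_relations({c.cid: c.canonical_key for c in registry})
    cig_by_cid: dict[int, list] = {}
    for rel in cig:
        cig_by_cid.setdefault(rel.cid_a, []).append(rel)

    fingerprints = {}
    for rec in records:
        cid = sid_to_cid.get(rec.sid)
        if cid is not None and rec.fingerprint_b64 and cid not in fingerprints:
            fingerprints[cid] = decode_cactvs_subskeys(rec.fingerprint_b64)
    features = {cid: hba >= 1 for cid, hba in hba_of_cid.items()}
    pairs = neighbor_pairs(
        fingerprints, three_d_scores, sim_config, features,
        known_cids={c.cid for c in registry},
    )
    for pair in pairs:
        tg.update(similarity_triples(pair, table))

    # -- substances --------------------------------------------------------
    synonym_assertions: list[SynonymAssertion] = []
    for rec in records:
        cid = sid_to_cid.get(rec.sid)
        tg.update(
            emit_substance_triples(
                rec, cid, catalog, table,
                chebi_class=chebi_of_cid.get(cid) if cid is not None else rec.chebi_class,
            )
        )
        version_assertions = build_descriptor_assertions(
            f"SID{rec.sid}", {"Substance_Version": rec.version}, catalog
        )
        for assertion in version_assertions:
            tg.update(descriptor_triples(assertion, table))
        for text, labels in rec.synonyms:
            synonym_assertions.append(
                SynonymAssertion(
                    text=text,
                    sid=rec.sid,
                    source_name=rec.source_name,
                    type_labels=tuple(labels),
                    mesh_id=rec.mesh_id,
                    atc_code=rec.atc_code,
                )
            )

    # -- compounds ---------------------------------------------------------
    for comp in registry:
        tg.update(
            emit_compound_triples(
                comp,
                descriptor_labels.get(comp.cid, ()),
                cig_by_cid.get(comp.cid, ()),
                table,
                chebi_class=chebi_of_cid.get(comp.cid),
            )
        )

    # -- annotations -------------------------------------------------------
    promotions = synonym_vote(synonym_assertions, sid_to_cid)
    mesh_of_key: dict[str, str] = {}
    for rec in records:
        cid = sid_to_cid.get(rec.sid)
        if rec.mesh_id and cid is not None and cid in inchikey_of_cid:
            mesh_of_key.setdefault(inchikey_of_cid[cid], rec.mesh_id)
    sources: dict[str, Mapping] = {}
    for rec in records:
        sources.setdefault(rec.source_name, {"title": rec.source_name})
    if source_meta:
        for name, meta in source_meta.items():
            sources[name] = {**sources.get(name, {"title": name}), **meta}
    tg.update(
        emit_annotation_triples(
            synonym_assertions,
            promotions,
            inchikeys=inchikey_of_cid,
            sources=sources,
            inchikey_mesh=mesh_of_key,
            catalog=catalog,
            table=table,
            known_cids={c.cid for c in registry},
        )
    )

    return ConversionResult(
        registry=registry,
        sid_to_cid=sid_to_cid,
        graph=tg,
        pairs=pairs,
        promotions=promotions,
    )
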