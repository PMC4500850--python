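"""Subdomain namespaces and URI minting.

The PubChem RDF data model partitions its resources into *subdomains*
(compound, substance, descriptor, synonym, InChIKey, neighbor, source,
concept, reference) each with its own base namespace, plus a vocabulary
namespace for PubChem-specific classes and properties.  Every subdomain
namespace is a slash (303-style) namespace; only the vocabulary namespace
is a hash namespace.  This module holds the canonical namespace table and
mints the well-known URI shapes:

* entity URIs such as ``compound:CID60823`` and ``substance:SID103554720``
* descriptor URIs such as ``descr:CID60823_Molecular_Weight``
* synonym URIs ``syno:MD5_<hex>`` where the hex digest is the MD5 of the
  case-folded synonym text, so synonym URIs resolve case-insensitively
* InChIKey URIs in a dedicated subdomain
* neighbor-pair URIs ``nbr:CID{a}_CID{b}_2DSimilarity`` with the lower CID
  first so symmetric pairs mint a single canonical URI
"""

from __future__ import annotations

import hashlib
import re
import urllib.parse
from dataclasses import dataclass, field
from typing import Mapping

from rdflib import Namespace, URIRef

__all__ = [
    "NamespaceTable",
    "DEFAULT_NAMESPACES",
    "InvalidIdentifierError",
    "mint_entity_iri",
    "mint_descriptor_iri",
    "mint_synonym_iri",
    "mint_inchikey_iri",
    "mint_neighbor_iri",
    "compact_iri",
    "expand_curie",
]

_PUBCHEM = "http://rdf.ncbi.nlm.nih.gov/pubchem/"

#: Subdomain and ontology prefixes.  The vocabulary namespace is the only
#: hash namespace; all other PubChem subdomains use slash namespaces.
DEFAULT_PREFIXES: dict[str, str] = {
    # PubChem subdomains
    "compound": _PUBCHEM + "compound/",
    "substance": _PUBCHEM + "substance/",
    "descr": _PUBCHEM + "descriptor/",
    "inchikey": _PUBCHEM + "inchikey/",
    "syno": _PUBCHEM + "synonym/",
    "concept": _PUBCHEM + "concept/",
    "reference": _PUBCHEM + "reference/",
    "nbr": _PUBCHEM + "neighbor/",
    "source": _PUBCHEM + "source/",
    "vocab": _PUBCHEM + "vocabulary#",
    # External RDF resources
    "pdbr": "http://rdf.wwpdb.org/pdb/",
    "mesh": "http://id.nlm.nih.gov/mesh/",
    "chembl": "http://rdf.ebi.ac.uk/resource/chembl/molecule/",
    "linkedchem": "http://linkedchemistry.info/chembl/chemblid/",
    # Ontologies and W3C vocabularies
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "obo": "http://purl.obolibrary.org/obo/",
    # OBO-style hash namespace used by the ChEBI role-restriction queries
    "obov": "http://purl.obolibrary.org/obo#",
    "sio": "http://semanticscience.org/resource/",
    "cheminf": "http://semanticscience.org/resource/",
    "cito": "http://purl.org/spar/cito/",
    "pdbo": "http://rdf.wwpdb.org/schema/pdbx-v40.owl#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "dcterms": "http://purl.org/dc/terms/",
}


class InvalidIdentifierError(ValueError):
    """Raised when an identifier violates the minting rules of its kind."""


@dataclass(frozen=True)
class NamespaceTable:
    """Prefix -> base-namespace map with compaction support.

    ``sio`` and ``cheminf`` deliberately share a base URI; compaction of
    URIs in that namespace prefers ``sio``.
    """

    entries: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PREFIXES))

    def __post_init__(self) -> None:
        for prefix, base in self.entries.items():
            if not re.match(r"^[a-z][\w-]*$", prefix, re.IGNORECASE):
                raise ValueError(f"bad prefix {prefix!r}")
            if "://" not in base:
                raise ValueError(f"namespace for {prefix!r} is not absolute: {base!r}")

    def namespace(self, prefix: str) -> Namespace:
        return Namespace(self.entries[prefix])

    def term(self, prefix: str, local: str) -> URIRef:
        return URIRef(self.entries[prefix] + local)

    def bind_all(self, graph) -> None:
        """Bind every prefix on an rdflib graph (for Turtle headers)."""
        seen_bases: set[str] = set()
        for prefix, base in self.entries.items():
            if base in seen_bases:
                continue
            seen_bases.add(base)
            graph.bind(prefix, Namespace(base), replace=True)

    def compact(self, iri: str | URIRef) -> str:
        """Compact an absolute IRI to ``prefix:local`` by longest base match."""
        s = str(iri)
        best: tuple[str, str] | None = None
        for prefix, base in self.entries.items():
            if s.startswith(base) and (best is None or len(base) > len(self.entries[best[0]])):
                best = (prefix, s[len(base):])
        if best is None:
            raise InvalidIdentifierError(f"no known namespace for {s!r}")
        return f"{best[0]}:{best[1]}"

    def expand(self, curie: str) -> URIRef:
        prefix, _, local = curie.partition(":")
        if prefix not in self.entries:
            raise InvalidIdentifierError(f"unknown prefix {prefix!r}")
        return URIRef(self.entries[prefix] + local)


DEFAULT_NAMESPACES = NamespaceTable()

_ENTITY_PATTERNS = {
    "compound": "CID",
    "substance": "SID",
    "reference": "PMID",
}


def _escape_local(name: str) -> str:
    """Local-name escaping for source/concept names: whitespace runs become
    '_' and any remaining reserved characters are percent-encoded."""
    collapsed = re.sub(r"\s+", "_", name.strip())
    return urllib.parse.quote(collapsed, safe="_-.~A-Za-z0-9")


def mint_entity_iri(kind: str, ident, table: NamespaceTable = DEFAULT_NAMESPACES) -> URIRef:
    """Mint a compound/substance/source/reference/concept URI.

    Numeric accessions (CID, SID, PMID) must be positive integers; source
    and concept names are non-empty strings escaped to safe local names.
    """
    if kind in _ENTITY_PATTERNS:
        try:
            num = int(ident)
        except (TypeError, ValueError):
            raise InvalidIdentifierError(f"{kind} id must be an integer, got {ident!r}")
        if num <= 0:
            raise InvalidIdentifierError(f"{kind} id must be positive, got {num}")
        return table.term(kind, _ENTITY_PATTERNS[kind] + str(num))
    if kind in ("source", "concept"):
        name = str(ident)
        if not name.strip():
            raise InvalidIdentifierError(f"{kind} name must be non-empty")
        return table.term(kind, _escape_local(name))
    raise InvalidIdentifierError(f"unknown entity kind {kind!r}")


_ENTITY_LABEL_RE = re.compile(r"^(CID|SID)[1-9]\d*$")


def mint_descriptor_iri(
    entity_label: str, descriptor_label: str, table: NamespaceTable = DEFAULT_NAMESPACES
) -> URIRef:
    """Mint ``descr:<CID|SID accession>_<Descriptor_Label>``."""
    if not _ENTITY_LABEL_RE.match(entity_label):
        raise InvalidIdentifierError(f"bad entity label {entity_label!r}")
    if not descriptor_label or re.search(r"\s", descriptor_label):
        raise InvalidIdentifierError(f"bad descriptor label {descriptor_label!r}")
    return table.term("descr", f"{entity_label}_{descriptor_label}")


def mint_synonym_iri(
    synonym_text: str,
    table: NamespaceTable = DEFAULT_NAMESPACES,
    encoding: str = "utf-8",
) -> URIRef:
    """Mint ``syno:MD5_<hex>`` from the case-folded synonym text.

    Synonym text is case-folded (full Unicode default case folding) before
    hashing, so names differing only in case mint the same URI.  The
    pre-hash byte encoding defaults to UTF-8 and is configurable.
    """
    if not synonym_text:
        raise InvalidIdentifierError("synonym text must be non-empty")
    digest = hashlib.md5(synonym_text.casefold().encode(encoding)).hexdigest()
    return table.term("syno", "MD5_" + digest)


_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def mint_inchikey_iri(key: str, table: NamespaceTable = DEFAULT_NAMESPACES) -> URIRef:
    """Mint an InChIKey subdomain URI; the 14-10-1 key is used verbatim."""
    if not _INCHIKEY_RE.match(key):
        raise InvalidIdentifierError(f"malformed InChIKey {key!r}")
    return table.term("inchikey", key)


_NEIGHBOR_SUFFIXES = {
    ("2D", "Similarity"): "2DSimilarity",
    ("2D", "TanimotoScore"): "2DTanimotoScore",
    ("3D", "Similarity"): "3DSimilarity",
    ("3D", "ShapeTanimotoScore"): "3DShapeTanimotoScore",
    ("3D", "FeatureTanimotoScore"): "3DFeatureTanimotoScore",
}


def mint_neighbor_iri(
    cid_a: int,
    cid_b: int,
    kind: str,
    role: str = "Similarity",
    table: NamespaceTable = DEFAULT_NAMESPACES,
) -> URIRef:
    """Mint a neighbor-pair URI with the lower CID first.

    ``role`` is ``Similarity`` for the association node or one of the score
    labels (``TanimotoScore``, ``ShapeTanimotoScore``, ``FeatureTanimotoScore``).
    """
    if cid_a == cid_b:
        raise InvalidIdentifierError(f"self-pair CID{cid_a}")
    if cid_a <= 0 or cid_b <= 0:
        raise InvalidIdentifierError("CIDs must be positive")
    try:
        suffix = _NEIGHBOR_SUFFIXES[(kind, role)]
    except KeyError:
        raise InvalidIdentifierError(f"unknown neighbor kind/role {kind!r}/{role!r}")
    lo, hi = sorted((cid_a, cid_b))
    return table.term("nbr", f"CID{lo}_CID{hi}_{suffix}")


def compact_iri(iri: str | URIRef, table: NamespaceTable = DEFAULT_NAMESPACES) -> str:
    return table.compact(iri)


def expand_curie(curie: str, table: NamespaceTable = DEFAULT_NAMESPACES) -> URIRef:
    return table.expand(curie)
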