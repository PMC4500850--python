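"""Fingerprint decoding, Tanimoto scoring, and similarity neighboring.

2-D neighbors are computed from 881-bit binary substructure fingerprints
(the PubChem SDF fingerprint field: base64 text whose decoded payload
starts with a 4-byte big-endian bit length, followed by the bits packed
most-significant-bit first).  Two compounds are 2-D neighbors when their
Tanimoto score |a∩b|/|a∪b| is at least 0.90.

3-D neighbors are threshold decisions over externally supplied shape (ST)
and feature/color (CT) Tanimoto scores from conformer superposition —
those scores are consumed, never computed here.  When both compounds have
pharmacophore features the rule is ST >= 0.80 and CT >= 0.50; when neither
has features, ST >= 0.93 alone decides.  The mixed case (exactly one
compound with features) is not covered by either rule and yields no pair.

Each surviving pair is reified as an n-ary RDF association: an association
node typed ``vocab:PC2D_structural_similarity`` (or ``PC3D_...``) that
``sio:refers-to`` both compounds and carries score nodes via
``sio:has-measurement-value``.
"""

from __future__ import annotations

import base64
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from rdflib import RDF, Literal, URIRef
from rdflib.namespace import XSD

from .namespaces import DEFAULT_NAMESPACES, NamespaceTable, mint_entity_iri, mint_neighbor_iri

logger = logging.getLogger(__name__)

__all__ = [
    "FINGERPRINT_BITS",
    "Fingerprint",
    "SimilarityConfig",
    "NeighborPair",
    "FingerprintDialectError",
    "decode_cactvs_subskeys",
    "encode_cactvs_subskeys",
    "tanimoto",
    "neighbor_pairs",
    "similarity_triples",
]

FINGERPRINT_BITS = 881


class FingerprintDialectError(ValueError):
    """The decoded field does not declare the 881-bit dialect."""


@dataclass(frozen=True)
class Fingerprint:
    """An ordered set of set-bit positions in a fixed 881-bit vector."""

    bits: frozenset[int]
    length: int = FINGERPRINT_BITS

    def __post_init__(self) -> None:
        if self.length != FINGERPRINT_BITS:
            raise FingerprintDialectError(f"fingerprint length must be {FINGERPRINT_BITS}")
        bad = [b for b in self.bits if not 0 <= b < self.length]
        if bad:
            raise ValueError(f"bit positions out of range: {sorted(bad)[:5]}")


@dataclass(frozen=True)
class SimilarityConfig:
    """Neighboring thresholds (all scores are Tanimoto values in (0, 1])."""

    tanimoto_2d_threshold: float = 0.90
    st_threshold: float = 0.80
    ct_threshold: float = 0.50
    st_only_threshold: float = 0.93

    def __post_init__(self) -> None:
        for name in ("tanimoto_2d_threshold", "st_threshold", "ct_threshold", "st_only_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class NeighborPair:
    """A scored 2-D or 3-D neighbor association, stored with cid_a < cid_b."""

    cid_a: int
    cid_b: int
    kind: str                       # "2D" | "3D"
    tanimoto_2d: Optional[float] = None
    st: Optional[float] = None
    ct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cid_a >= self.cid_b:
            raise ValueError("NeighborPair stores cid_a < cid_b")
        if self.kind == "2D" and self.tanimoto_2d is None:
            raise ValueError("2D pair requires tanimoto_2d")
        if self.kind == "3D" and self.st is None:
            raise ValueError("3D pair requires st")
        if self.kind not in ("2D", "3D"):
            raise ValueError(f"unknown pair kind {self.kind!r}")


# -- fingerprint codec -----------------------------------------------------


def decode_cactvs_subskeys(field_text: str) -> Fingerprint:
    """Decode a base64 fingerprint field to its bit set.

    The decoded payload is a 4-byte big-endian declared bit length (which
    must equal 881) followed by the bits packed MSB-first; the trailing
    pad bits of the last byte are ignored.
    """
    try:
        raw = base64.b64decode(field_text.strip(), validate=True)
    except Exception as exc:
        raise ValueError(f"fingerprint field is not valid base64: {exc}")
    if len(raw) < 4:
        raise ValueError("fingerprint payload shorter than its 4-byte length header")
    declared = int.from_bytes(raw[:4], "big")
    if declared != FINGERPRINT_BITS:
        raise FingerprintDialectError(
            f"declared bit length {declared}, expected {FINGERPRINT_BITS}"
        )
    body = raw[4:]
    if len(body) * 8 < declared:
        raise ValueError("fingerprint payload shorter than declared bit length")
    bits = set()
    for pos in range(declared):
        byte, offset = divmod(pos, 8)
        if body[byte] & (0x80 >> offset):
            bits.add(pos)
    return Fingerprint(frozenset(bits))


def encode_cactvs_subskeys(fp: Fingerprint) -> str:
    """Inverse of :func:`decode_cactvs_subskeys` (used by the generator)."""
    n_bytes = (fp.length + 7) // 8
    body = bytearray(n_bytes)
    for pos in fp.bits:
        byte, offset = divmod(pos, 8)
        body[byte] |= 0x80 >> offset
    return base64.b64encode(fp.length.to_bytes(4, "big") + bytes(body)).decode("ascii")


# -- scoring ---------------------------------------------------------------


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a∩b| / |a∪b|; defined as 0.0 when both bit sets are empty."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} != {b.length}")
    union = len(a.bits | b.bits)
    if union == 0:
        logger.debug("both fingerprints empty; Tanimoto defined as 0.0")
        return 0.0
    return len(a.bits & b.bits) / union


# -- neighboring -----------------------------------------------------------


def neighbor_pairs(
    fingerprints: Mapping[int, Fingerprint],
    three_d_scores: Iterable[tuple] | None = None,
    config: SimilarityConfig | None = None,
    features: Mapping[int, bool] | None = None,
    known_cids: set[int] | None = None,
) -> list[NeighborPair]:
    """Apply the 2-D and 3-D neighboring thresholds.

    ``fingerprints`` maps cid -> decoded fingerprint; every unordered pair
    is scored and kept when Tanimoto >= the 2-D threshold.  Optional
    ``three_d_scores`` rows are ``(cid_a, cid_b, st, ct)`` tuples;
    ``features`` says whether a compound has pharmacophore features
    (defaults to True for every cid appearing in a 3-D row); a 3-D row
    referencing a CID outside ``known_cids`` (default: the fingerprinted
    set) is an error.
    """
    config = config or SimilarityConfig()
    pairs: list[NeighborPair] = []
    for a, b in itertools.combinations(sorted(fingerprints), 2):
        score = tanimoto(fingerprints[a], fingerprints[b])
        if score >= config.tanimoto_2d_threshold:
            pairs.append(NeighborPair(a, b, "2D", tanimoto_2d=score))
    if three_d_scores is not None:
        known = known_cids if known_cids is not None else set(fingerprints)
        seen: set[tuple[int, int]] = set()
        for row in three_d_scores:
            cid_a, cid_b, st = int(row[0]), int(row[1]), float(row[2])
            ct = float(row[3]) if len(row) > 3 and row[3] is not None else None
            for cid in (cid_a, cid_b):
                if known and cid not in known:
                    raise KeyError(f"3-D score row references unknown CID{cid}")
            lo, hi = sorted((cid_a, cid_b))
            if (lo, hi) in seen:
                continue
            seen.add((lo, hi))
            feat_a = features.get(cid_a, True) if features is not None else True
            feat_b = features.get(cid_b, True) if features is not None else True
            if feat_a and feat_b:
                keep = ct is not None and st >= config.st_threshold and ct >= config.ct_threshold
            elif not feat_a and not feat_b:
                keep = st >= config.st_only_threshold
            else:
                logger.info(
                    "CID%d/CID%d: one compound with features, one without; "
                    "no 3-D neighboring rule applies", cid_a, cid_b,
                )
                keep = False
            if keep:
                pairs.append(NeighborPair(lo, hi, "3D", st=st, ct=ct))
    return pairs


# -- RDF n-ary pattern -----------------------------------------------------

_SOFTWARE_FOR_KIND = {"2D": "CHEMINF_000386", "3D": "CHEMINF_000333"}


def similarity_triples(
    pair: NeighborPair,
    table: NamespaceTable = DEFAULT_NAMESPACES,
    link_software: bool = True,
) -> list[tuple[URIRef, URIRef, object]]:
    """Reify one neighbor pair as the n-ary association/score pattern.

    Also asserts the direct compound-to-compound similarity predicate
    (CHEMINF_000482 for 2-D, CHEMINF_000483 for 3-D) so the association
    node and the plain link stay consistent.
    """
    sio = table.namespace("sio")
    vocab = table.namespace("vocab")
    comp_a = mint_entity_iri("compound", pair.cid_a, table)
    comp_b = mint_entity_iri("compound", pair.cid_b, table)
    assoc = mint_neighbor_iri(pair.cid_a, pair.cid_b, pair.kind, "Similarity", table)
    triples: list[tuple[URIRef, URIRef, object]] = []
    direct = sio["CHEMINF_000482" if pair.kind == "2D" else "CHEMINF_000483"]
    triples.append((comp_a, direct, comp_b))
    triples.append((assoc, RDF.type, vocab[f"PC{pair.kind}_structural_similarity"]))
    triples.append((assoc, sio["refers-to"], comp_a))
    triples.append((assoc, sio["refers-to"], comp_b))

    def score_node(role: str, vocab_class: str, value: float) -> None:
        node = mint_neighbor_iri(pair.cid_a, pair.cid_b, pair.kind, role, table)
        triples.append((assoc, sio["has-measurement-value"], node))
        triples.append((node, RDF.type, vocab[vocab_class]))
        triples.append((node, sio["has-value"], Literal(value, datatype=XSD.double)))
        if link_software:
            triples.append((node, sio["is-output-of"], sio[_SOFTWARE_FOR_KIND[pair.kind]]))

    if pair.kind == "2D":
        if pair.tanimoto_2d is None:
            raise ValueError("2D pair missing Tanimoto score")
        score_node("TanimotoScore", "PC2D_Fingerprint_TanimotoScore", pair.tanimoto_2d)
    else:
        if pair.st is None:
            raise ValueError("3D pair missing shape Tanimoto score")
        score_node("ShapeTanimotoScore", "PC3D_Shape_TanimotoScore", pair.st)
        if pair.ct is not None:
            score_node("FeatureTanimotoScore", "PC3D_Feature_TanimotoScore", pair.ct)
    return triples
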