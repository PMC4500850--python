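"""Compound Identity Group (CIG) relations from layered canonical keys.

Compounds sharing a molecular skeleton are related at three levels of
"sameness", each a symmetric CHEMINF predicate:

* ``CHEMINF_000455`` — isotopologues: same connectivity and stereochemistry,
  different isotopic labelling
* ``CHEMINF_000461`` — stereoisomers: same connectivity and isotope form,
  different stereochemistry
* ``CHEMINF_000462`` — same connectivity: both isotope and stereo form vary

The levels are read off the standard InChI string, whose layers separate
formula+connectivity (``/c``, ``/h``), isotopes (``/i`` and sublayers) and
stereochemistry (``/t``, ``/b``, ``/m``, ``/s``).  Only the most specific
relation is asserted per pair; 000455 and 000461 are subproperties of
000462 and the generic relation is recovered by entailment, not asserted.
"""

from __future__ import annotations

import itertools
import re
from collections import defaultdict
from dataclasses import dataclass

__all__ = [
    "IdentityKeys",
    "CigRelation",
    "ISOTOPOLOGUE_OF",
    "STEREOISOMER_OF",
    "SAME_CONNECTIVITY_AS",
    "identity_keys",
    "classify_pair",
    "build_cig_relations",
]

ISOTOPOLOGUE_OF = "CHEMINF_000455"
STEREOISOMER_OF = "CHEMINF_000461"
SAME_CONNECTIVITY_AS = "CHEMINF_000462"

# Layer membership: connectivity = formula + /c + /h; isotope = /i (with its
# /t.. sublayers); stereo = top-level /t /b /m /s.  The reconnected or
# fixed-H blocks, when present, are folded into the layer they follow.
_STEREO_PREFIXES = ("t", "b", "m", "s")


@dataclass(frozen=True)
class IdentityKeys:
    """The three comparison keys derived from one canonical key."""

    connectivity_key: str
    isotope_key: str = ""
    stereo_key: str = ""


@dataclass(frozen=True, order=True)
class CigRelation:
    cid_a: int
    cid_b: int
    predicate: str

    def __post_init__(self) -> None:
        if self.cid_a >= self.cid_b:
            raise ValueError("CigRelation stores cid_a < cid_b")


def identity_keys(canonical_key: str) -> IdentityKeys:
    """Split a standard InChI string into connectivity/isotope/stereo keys.

    Parsing is purely textual; no chemistry is re-perceived.
    """
    m = re.match(r"^InChI=1S?/([^/]+)(.*)$", canonical_key)
    if not m:
        raise ValueError(f"malformed canonical key {canonical_key!r}")
    formula, rest = m.group(1), m.group(2)
    layers = rest.split("/")[1:] if rest.startswith("/") else []
    connectivity = [formula]
    isotope: list[str] = []
    stereo: list[str] = []
    in_isotope = False
    for layer in layers:
        if not layer:
            continue
        prefix = layer[0]
        if prefix == "i":
            in_isotope = True
            isotope.append(layer)
        elif prefix in _STEREO_PREFIXES:
            # /t inside the isotope block is isotopic stereo, a sublayer of /i
            (isotope if in_isotope else stereo).append(layer)
        elif prefix in ("c", "h"):
            in_isotope = False
            connectivity.append(layer)
        elif prefix in ("q", "p"):
            in_isotope = False
            connectivity.append(layer)  # charge/proton layers: part of identity
        else:
            # unknown layer (r, f, ...): treat as connectivity-level
            in_isotope = False
            connectivity.append(layer)
    return IdentityKeys(
        connectivity_key="/".join(connectivity),
        isotope_key="/".join(isotope),
        stereo_key="/".join(stereo),
    )


def classify_pair(keys_a: IdentityKeys, keys_b: IdentityKeys) -> str | None:
    """Most specific CIG predicate for one unordered pair, or None."""
    if keys_a.connectivity_key != keys_b.connectivity_key:
        return None
    if keys_a == keys_b:
        return None  # identical compounds are not neighbors of themselves
    same_stereo = keys_a.stereo_key == keys_b.stereo_key
    same_isotope = keys_a.isotope_key == keys_b.isotope_key
    if same_stereo and not same_isotope:
        return ISOTOPOLOGUE_OF
    if same_isotope and not same_stereo:
        return STEREOISOMER_OF
    return SAME_CONNECTIVITY_AS


def build_cig_relations(compounds: dict[int, str]) -> list[CigRelation]:
    """CIG relations over a registry mapping cid -> canonical key.

    Compounds are bucketed by connectivity key, so only pairs that can be
    related are compared; each unordered pair yields at most one relation,
    the most specific one.
    """
    keys = {cid: identity_keys(key) for cid, key in compounds.items()}
    buckets: dict[str, list[int]] = defaultdict(list)
    for cid, k in keys.items():
        buckets[k.connectivity_key].append(cid)
    relations: list[CigRelation] = []
    for cids in buckets.values():
        for a, b in itertools.combinations(sorted(cids), 2):
            predicate = classify_pair(keys[a], keys[b])
            if predicate is not None:
                relations.append(CigRelation(a, b, predicate))
    return sorted(relations)
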