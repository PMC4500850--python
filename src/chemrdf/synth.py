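"""Seeded synthetic depositions exercising every mapping rule.

The generator emulates a multi-depositor archive: several sources deposit
overlapping sets of small organic structures (CHNOPS, 3–40 heavy atoms) as
V2000 SDF records with depositor metadata.  Designated fractions of the
base structures additionally appear as salt forms (sodium carboxylate plus
counter-ion — a mixture with a carbon-rich parent), enantiomeric stereo
variants, or isotope-labelled variants, so the compound registry, the
parent rule, and all three identity-group predicates are exercised.
Synonyms are shared across sources, with name/structure conflicts injected
at a configured rate to drive the voting filter.

Fingerprints are seeded random 881-bit sets, not computed from structure
(key generation is out of scope); a variant's fingerprint flips at most
five of its template's bits, so variant pairs are 2-D neighbors (Tanimoto
>= 0.9) by construction while unrelated bases are not.

Equal seeds produce byte-identical SDF and metadata.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import AllChem

from .similarity import FINGERPRINT_BITS, Fingerprint, encode_cactvs_subskeys

__all__ = ["SynthConfig", "generate_synthetic_deposition", "make_three_d_scores"]

_SYNONYM_TYPE_POOL = [
    "CAS registry number",
    "Drug trade name",
    "International nonproprietary name",
    "Validated chemical database identifier",
]

_SOURCE_CATEGORY_POOL = [
    "Biological_Properties",
    "Chemical_Reactions",
    "Physical_Properties",
    "Protein_3D_Structures",
    "Substance_Vendors",
]


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 42
    n_sources: int = 4
    n_base_structures: int = 20
    salt_fraction: float = 0.25
    stereo_variant_fraction: float = 0.25
    isotope_variant_fraction: float = 0.15
    synonym_conflict_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.n_base_structures < 1:
            raise ValueError("n_base_structures must be >= 1")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        for name in ("salt_fraction", "stereo_variant_fraction",
                     "isotope_variant_fraction", "synonym_conflict_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _random_branch(rng: random.Random, budget: int) -> str:
    """A random valence-respecting SMILES subtree with <= budget heavy atoms."""
    element, valence = rng.choice([("C", 4), ("C", 4), ("C", 4), ("N", 3), ("O", 2)])
    if budget <= 1:
        return rng.choice(["C", "O", "N", "F", "Cl"])
    n_children = rng.randint(0, min(valence - 1, 2, budget - 1))
    parts = [element]
    remaining = budget - 1
    for _ in range(n_children):
        share = rng.randint(1, max(1, remaining // 2)) if remaining > 1 else 1
        sub = _random_branch(rng, share)
        remaining -= share
        parts.append(f"({sub})")
    return "".join(parts)


def _base_smiles(rng: random.Random) -> str:
    """A chiral carboxylic acid: ``[C@@H](F)(<branch>)C(=O)O``.

    The fluorine-bearing stereocenter guarantees a defined stereo layer
    (so enantiomeric variants differ only in /m), and the acid group gives
    every base a salt form.
    """
    branch = _random_branch(rng, rng.randint(2, 12))
    return f"[C@@H](F)({branch})C(=O)O"


def _variants(base: str, kinds: list[str]) -> dict[str, str]:
    """Deposited forms for one base structure.

    A salted base is deposited *as* its sodium-salt mixture (the free acid
    then enters the registry only as the neutralized parent component);
    stereo and isotope variants are additional free-acid depositions so
    identity-group pairs exist alongside the base form.
    """
    out = {"base": base}
    if "salt" in kinds:
        out["base"] = base.replace("C(=O)O", "C(=O)[O-]", 1) + ".[Na+]"
    if "stereo" in kinds:
        out["stereo"] = base.replace("[C@@H]", "[C@H]", 1)
    if "isotope" in kinds:
        out["isotope"] = base.replace("C(=O)O", "[13C](=O)O", 1)
    return out


def _molblock(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"generator produced invalid SMILES {smiles!r}")
    AllChem.Compute2DCoords(mol)
    return Chem.MolToMolBlock(mol, kekulize=True)


def _random_fingerprint(rng: random.Random, n_bits: int = 150) -> Fingerprint:
    return Fingerprint(frozenset(rng.sample(range(FINGERPRINT_BITS), n_bits)))


def _flip_bits(fp: Fingerprint, rng: random.Random, max_flips: int = 5) -> Fingerprint:
    bits = set(fp.bits)
    for pos in rng.sample(range(FINGERPRINT_BITS), rng.randint(1, max_flips)):
        bits.symmetric_difference_update({pos})
    return Fingerprint(frozenset(bits))


def generate_synthetic_deposition(config: SynthConfig) -> tuple[str, str]:
    """Generate (SDF text, metadata JSON) for one synthetic archive.

    Each structure (base or variant) is deposited by one or more sources;
    every deposition gets its own SID, version, synonyms with type labels,
    sparse cross-references, and a fingerprint data field.
    """
    rng = random.Random(config.seed)
    n = config.n_base_structures

    picks = {"salt": set(), "stereo": set(), "isotope": set()}
    for kind, frac in (("salt", config.salt_fraction),
                       ("stereo", config.stereo_variant_fraction),
                       ("isotope", config.isotope_variant_fraction)):
        k = round(frac * n)
        picks[kind] = set(rng.sample(range(n), k)) if k else set()

    sdf_chunks: list[str] = []
    substances: list[dict] = []
    sid = 1000
    structures: list[tuple[str, str, int]] = []   # (smiles, variant kind, base index)
    for i in range(n):
        base = _base_smiles(rng)
        kinds = [k for k in ("stereo", "isotope", "salt") if i in picks[k]]
        for kind, smiles in _variants(base, kinds).items():
            structures.append((smiles, kind, i))

    fingerprints: dict[int, Fingerprint] = {}
    base_fp: dict[int, Fingerprint] = {}
    for idx, (smiles, kind, i) in enumerate(structures):
        if i not in base_fp:
            base_fp[i] = _random_fingerprint(rng)
        fingerprints[idx] = base_fp[i] if kind == "base" else _flip_bits(base_fp[i], rng)

    source_names = [f"Source{chr(ord('A') + k)}" for k in range(config.n_sources)]
    for idx, (smiles, kind, i) in enumerate(structures):
        molblock = _molblock(smiles)
        n_depositors = rng.randint(1, config.n_sources) if kind == "base" else 1
        depositors = rng.sample(source_names, n_depositors)
        for source in depositors:
            sid += 1
            name = f"cmpd-{i}" if kind in ("base", "salt") else f"cmpd-{i}-{kind}"
            synonyms = [{"text": name, "types": []}]
            if rng.random() < 0.3:
                synonyms.append({
                    "text": f"{rng.randint(100, 999)}-{rng.randint(10, 99)}-{rng.randint(0, 9)}",
                    "types": [rng.choice(_SYNONYM_TYPE_POOL)],
                })
            if rng.random() < config.synonym_conflict_rate:
                # conflict: this depositor also claims a neighboring base's name
                synonyms.append({"text": f"cmpd-{(i + 1) % n}", "types": []})
            xrefs: dict = {}
            if rng.random() < 0.15:
                xrefs["pubmed"] = [rng.randint(10_000_000, 29_999_999)]
            if rng.random() < 0.10:
                xrefs["chembl"] = f"CHEMBL{rng.randint(1000, 99999)}"
            if rng.random() < 0.05:
                xrefs["mesh"] = f"M{rng.randint(1_000_000, 9_999_999):07d}"
            entry = {
                "sid": sid,
                "source": source,
                "version": rng.randint(1, 3),
                "synonyms": synonyms,
                "xrefs": xrefs,
            }
            substances.append(entry)
            fields = {
                "PUBCHEM_SUBSTANCE_ID": str(sid),
                "PUBCHEM_CACTVS_SUBSKEYS": encode_cactvs_subskeys(fingerprints[idx]),
            }
            if rng.random() < 0.2:
                fields["PUBCHEM_XLOGP3"] = f"{rng.uniform(-2, 6):.1f}"
            chunk = molblock + "".join(
                f"> <{tag}>\n{value}\n\n" for tag, value in fields.items()
            ) + "$$$$\n"
            sdf_chunks.append(chunk)

    sources_meta = {
        name: {
            "title": name,
            "categories": sorted(rng.sample(_SOURCE_CATEGORY_POOL, rng.randint(1, 2))),
        }
        for name in source_names
    }
    metadata = json.dumps(
        {"substances": substances, "sources": sources_meta}, indent=1, sort_keys=True
    )
    return "".join(sdf_chunks), metadata


def make_three_d_scores(
    cids: list[int], seed: int, n_pairs: int | None = None
) -> list[tuple[int, int, float, float]]:
    """Plausible externally-computed 3-D (shape, feature) Tanimoto rows.

    Shape/feature score computation itself is out of scope, so rows are
    drawn around the decision thresholds to exercise both outcomes.
    """
    rng = random.Random(seed)
    pairs: list[tuple[int, int, float, float]] = []
    ordered = sorted(cids)
    n_pairs = n_pairs if n_pairs is not None else max(1, len(ordered) // 2)
    for _ in range(n_pairs):
        if len(ordered) < 2:
            break
        a, b = rng.sample(ordered, 2)
        lo, hi = sorted((a, b))
        st = round(rng.uniform(0.6, 1.0), 2)
        ct = round(rng.uniform(0.3, 0.9), 2)
        pairs.append((lo, hi, st, ct))
    return pairs
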