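"""Chemical descriptors: computation, CHEMINF typing, units, software catalog.

Two routes produce descriptor values.  *Native* descriptors are summed or
counted directly on the molecular graph with a pinned atomic-weight table
(2005/2007 IUPAC standard atomic weights, so mass values are
bit-reproducible across environments): molecular formula in Hill order,
molecular weight, monoisotopic weight, exact mass, formal charge, atom and
stereocenter counts, H-bond donor/acceptor counts, rotatable bonds.
*Adapter* descriptors are delegated to the cheminformatics toolkit
(canonical/isomeric SMILES, InChI, InChIKey) or passed through from
depositor input fields (XLogP3, TPSA, structure complexity, tautomer
count, preferred IUPAC name) — those algorithms are not reimplemented.

Every emitted descriptor is bound to its CHEMINF ontology class, an XSD
datatype, a unit where applicable (UO_0000055, gram per mole, for the
three mass descriptors), and the producing-software catalog entry.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import networkx as nx
from rdkit import Chem
from rdkit.Chem import inchi as rdinchi

from .chem import MolecularGraph

logger = logging.getLogger(__name__)

__all__ = [
    "AtomicWeightTable",
    "CheminfCatalog",
    "DescriptorAssertion",
    "load_atomic_weights",
    "load_catalog",
    "compute_native_descriptors",
    "adapter_descriptors",
    "build_descriptor_assertions",
    "hill_formula",
    "parse_formula",
]

#: Descriptor labels taken from depositor input fields rather than computed.
PASSTHROUGH_LABELS = {
    "XLogP3": "PUBCHEM_XLOGP3",
    "TPSA": "PUBCHEM_CACTVS_TPSA",
    "Structure_Complexity": "PUBCHEM_CACTVS_COMPLEXITY",
    "Tautomer_Count": "PUBCHEM_CACTVS_TAUTO_COUNT",
    "Preferred_IUPAC_Name": "PUBCHEM_IUPAC_NAME",
}


class CatalogError(KeyError):
    """A descriptor or synonym-type label missing from the catalog."""


@dataclass(frozen=True)
class AtomicWeightTable:
    """Element -> (standard atomic weight, principal-isotope exact mass)."""

    weights: Mapping[str, tuple[float, float]]
    isotope_masses: Mapping[tuple[str, int], float]

    def standard_weight(self, element: str) -> float:
        try:
            return self.weights[element][0]
        except KeyError:
            raise KeyError(f"no standard atomic weight for element {element!r}")

    def principal_mass(self, element: str) -> float:
        try:
            return self.weights[element][1]
        except KeyError:
            raise KeyError(f"no principal-isotope mass for element {element!r}")

    def isotope_mass(self, element: str, mass_number: int) -> float:
        # mass-number fallback keeps exotic labels usable, at ~0.1 u error
        return self.isotope_masses.get((element, mass_number), float(mass_number))


@dataclass(frozen=True)
class DescriptorAssertion:
    """A typed, unit-bearing descriptor value bound to a CHEMINF class."""

    entity_label: str          # "CID60823" or "SID43118161"
    descriptor_label: str      # "Molecular_Weight"
    cheminf_type: Optional[str]
    value: str                 # lexical form
    datatype: str              # XSD local name
    unit: Optional[str] = None          # e.g. "UO_0000055"
    software: Optional[str] = None      # CHEMINF id of producing software


@dataclass(frozen=True)
class CheminfCatalog:
    """CHEMINF term catalogs: descriptors, software library, synonym types."""

    descriptors: Mapping[str, dict]          # label -> {id, software, datatype, unit}
    software: Mapping[str, dict]             # name -> {version, id}
    synonym_types: Mapping[str, str]         # type label -> CHEMINF id

    UNRECOGNIZED_SYNONYM_TYPE = "CHEMINF_000339"  # depositor-supplied name

    def descriptor(self, label: str) -> dict:
        try:
            return self.descriptors[label]
        except KeyError:
            raise CatalogError(f"unknown descriptor label {label!r}")

    def synonym_type(self, label: str) -> str:
        return self.synonym_types.get(label, self.UNRECOGNIZED_SYNONYM_TYPE)

    def software_id(self, name: str) -> Optional[str]:
        entry = self.software.get(name)
        return entry["id"] if entry else None


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("chemrdf.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_atomic_weights() -> AtomicWeightTable:
    weights = {r[0]: (float(r[1]), float(r[2])) for r in _read_tsv("atomic_weights.tsv")}
    iso = {(r[0], int(r[1])): float(r[2]) for r in _read_tsv("isotope_masses.tsv")}
    return AtomicWeightTable(weights, iso)


def load_catalog() -> CheminfCatalog:
    desc = {}
    for row in _read_tsv("cheminf_descriptors.tsv"):
        label, cid, software, datatype = row[0], row[1], row[2], row[3]
        unit = row[4] if len(row) > 4 and row[4] else None
        desc[label] = {
            "id": None if cid == "-" else cid,
            "software": software,
            "datatype": datatype,
            "unit": unit,
        }
    software = {r[0]: {"version": r[1], "id": r[2]} for r in _read_tsv("cheminf_software.tsv")}
    syn = {r[0]: r[1] for r in _read_tsv("cheminf_synonym_types.tsv")}
    return CheminfCatalog(desc, software, syn)


DEFAULT_WEIGHTS = load_atomic_weights()
DEFAULT_CATALOG = load_catalog()


# -- formula ---------------------------------------------------------------


def hill_formula(composition: Mapping[str, int]) -> str:
    """Hill-order molecular formula: C, H, then other elements alphabetically;
    without carbon, all elements (H included) sort alphabetically."""
    comp = {el: n for el, n in composition.items() if n > 0}
    parts: list[str] = []
    if "C" in comp:
        order = ["C"] + (["H"] if "H" in comp else []) + sorted(
            el for el in comp if el not in ("C", "H")
        )
    else:
        order = sorted(comp)
    for el in order:
        n = comp[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    comp: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        comp[m.group(1)] = comp.get(m.group(1), 0) + (int(m.group(2) or 1))
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
    return comp


def _composition(graph: MolecularGraph) -> dict[str, int]:
    comp: dict[str, int] = {}
    for atom in graph.atoms:
        comp[atom.element] = comp.get(atom.element, 0) + 1
        if atom.implicit_h:
            comp["H"] = comp.get("H", 0) + atom.implicit_h
    return comp


# -- native descriptors ----------------------------------------------------


def compute_native_descriptors(
    graph: MolecularGraph, weights: AtomicWeightTable = DEFAULT_WEIGHTS
) -> dict[str, object]:
    """Graph-native descriptor values for one (possibly multi-unit) record.

    Monoisotopic weight sums principal-isotope masses throughout; exact
    mass additionally honours explicit isotope labels, so the two coincide
    exactly on unlabelled molecules.
    """
    comp = _composition(graph)
    mw = sum(weights.standard_weight(el) * n for el, n in comp.items())

    mono = 0.0
    exact = 0.0
    isotope_atoms = 0
    for atom in graph.atoms:
        principal = weights.principal_mass(atom.element)
        mono += principal
        if atom.isotope:
            isotope_atoms += 1
            exact += weights.isotope_mass(atom.element, atom.isotope)
        else:
            exact += principal
    h_mass = weights.principal_mass("H")
    n_implicit = sum(a.implicit_h for a in graph.atoms)
    mono += h_mass * n_implicit
    exact += h_mass * n_implicit

    nxg = graph.to_networkx()
    heavy = [i for i, a in enumerate(graph.atoms) if a.element != "H"]
    heavy_set = set(heavy)

    def heavy_degree(i: int) -> int:
        return sum(1 for j in nxg.neighbors(i) if j in heavy_set)

    def h_count(i: int) -> int:
        explicit = sum(1 for j in nxg.neighbors(i) if graph.atoms[j].element == "H")
        return graph.atoms[i].implicit_h + explicit

    donors = sum(1 for i in heavy if graph.atoms[i].element in ("N", "O") and h_count(i) >= 1)
    acceptors = sum(1 for i in heavy if graph.atoms[i].element in ("N", "O"))

    bridges = set(frozenset(e) for e in nx.bridges(nxg))
    bond_by_pair = {frozenset((b.a, b.b)): b for b in graph.bonds}
    amide_n = _amide_nitrogens(graph, nxg)
    rotatable = 0
    for pair, bond in bond_by_pair.items():
        if bond.order != 1 or pair not in bridges:
            continue
        i, j = tuple(pair)
        if i not in heavy_set or j not in heavy_set:
            continue
        if heavy_degree(i) < 2 or heavy_degree(j) < 2:
            continue
        if _is_amide_bond(graph, i, j, amide_n, nxg):
            continue
        rotatable += 1

    defined_at, undef_at, defined_bd, undef_bd = _stereocenter_counts(graph)

    return {
        "Molecular_Formula": hill_formula(comp),
        "Molecular_Weight": mw,
        "Mono_Isotopic_Weight": mono,
        "Exact_Mass": exact,
        "Total_Formal_Charge": sum(a.charge for a in graph.atoms),
        "Heavy_Atom_Count": len(heavy),
        "Isotope_Atom_Count": isotope_atoms,
        "Covalent_Unit_Count": nx.number_connected_components(nxg) if graph.atoms else 0,
        "Defined_Atom_Stereocenter_Count": defined_at,
        "Undefined_Atom_Stereocenter_Count": undef_at,
        "Defined_Bond_Stereocenter_Count": defined_bd,
        "Undefined_Bond_Stereocenter_Count": undef_bd,
        "Hydrogen_Bond_Donor_Count": donors,
        "Hydrogen_Bond_Acceptor_Count": acceptors,
        "Rotatable_Bond_Count": rotatable,
    }


def _amide_nitrogens(graph: MolecularGraph, nxg: nx.Graph) -> set[tuple[int, int]]:
    """(carbon, nitrogen) pairs where the carbon bears a C=O."""
    carbonyl_c = set()
    for b in graph.bonds:
        if b.order == 2:
            for c, o in ((b.a, b.b), (b.b, b.a)):
                if graph.atoms[c].element == "C" and graph.atoms[o].element == "O":
                    carbonyl_c.add(c)
    pairs = set()
    for b in graph.bonds:
        if b.order == 1:
            for c, n in ((b.a, b.b), (b.b, b.a)):
                if c in carbonyl_c and graph.atoms[n].element == "N":
                    pairs.add((c, n))
    return pairs


def _is_amide_bond(graph, i, j, amide_pairs, nxg) -> bool:
    return (i, j) in amide_pairs or (j, i) in amide_pairs


def _stereocenter_counts(graph: MolecularGraph) -> tuple[int, int, int, int]:
    """Potential/defined tetrahedral and double-bond stereocenters via
    toolkit stereo perception; graphs that do not sanitize count only the
    explicitly flagged centers."""
    try:
        mol = graph.to_rdkit()
        found = Chem.FindPotentialStereo(mol)
    except Exception:
        defined_at = sum(1 for a in graph.atoms if a.stereo_parity)
        defined_bd = sum(1 for b in graph.bonds if b.stereo)
        return defined_at, 0, defined_bd, 0
    defined_at = undef_at = defined_bd = undef_bd = 0
    for si in found:
        specified = si.specified == Chem.StereoSpecified.Specified
        if si.type == Chem.StereoType.Atom_Tetrahedral:
            defined_at += specified
            undef_at += not specified
        elif si.type == Chem.StereoType.Bond_Double:
            defined_bd += specified
            undef_bd += not specified
    return defined_at, undef_at, defined_bd, undef_bd


# -- adapter descriptors ---------------------------------------------------


def adapter_descriptors(
    graph: MolecularGraph, passthrough: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Toolkit-delegated identifiers plus depositor passthrough values.

    SMILES/InChI/InChIKey come from the toolkit adapter; XLogP3, TPSA,
    structure complexity, tautomer count and the preferred IUPAC name are
    copied from input fields when supplied and omitted otherwise.  Adapter
    failure drops the affected labels with a warning, never an error.
    """
    out: dict[str, str] = {}
    try:
        mol = graph.to_rdkit()
        iso_smiles = Chem.MolToSmiles(mol)
        out["Isomeric_SMILES"] = iso_smiles
        out["Canonical_SMILES"] = Chem.MolToSmiles(Chem.MolFromSmiles(iso_smiles) or mol,
                                                   isomericSmiles=False)
        inchi_str = rdinchi.MolToInchi(mol)
        if inchi_str:
            out["IUPAC_InChI"] = inchi_str
            key = rdinchi.InchiToInchiKey(inchi_str)
            if key:
                out["IUPAC_InChIKey"] = key
    except Exception as exc:  # noqa: BLE001 - adapter failures are non-fatal
        logger.warning("toolkit adapter failed: %s", exc)
    for label, tag in PASSTHROUGH_LABELS.items():
        if passthrough and tag in passthrough:
            out[label] = str(passthrough[tag]).strip()
        elif passthrough and label in passthrough:
            out[label] = str(passthrough[label]).strip()
    return out


# -- assertions ------------------------------------------------------------


def format_value(value, datatype: str) -> str:
    if isinstance(value, float):
        if datatype == "double":
            # mass-style values print with 6 decimals, trailing zeros trimmed
            text = f"{value:.6f}".rstrip("0").rstrip(".")
            return text if text else "0"
        return repr(value)
    return str(value)


def build_descriptor_assertions(
    entity_label: str,
    values: Mapping[str, object],
    catalog: CheminfCatalog = DEFAULT_CATALOG,
) -> list[DescriptorAssertion]:
    """One typed assertion per descriptor value, subject in the descriptor
    subdomain (``descr:<entity>_<label>``)."""
    assertions = []
    for label in sorted(values):
        entry = catalog.descriptor(label)
        lexical = format_value(values[label], entry["datatype"])
        _check_lexical(lexical, entry["datatype"], label)
        assertions.append(
            DescriptorAssertion(
                entity_label=entity_label,
                descriptor_label=label,
                cheminf_type=entry["id"],
                value=lexical,
                datatype=entry["datatype"],
                unit=entry["unit"],
                software=catalog.software_id(entry["software"]),
            )
        )
    return assertions


def _check_lexical(lexical: str, datatype: str, label: str) -> None:
    try:
        if datatype == "double":
            float(lexical)
        elif datatype == "integer":
            int(lexical)
        elif datatype == "nonNegativeInteger":
            if int(lexical) < 0:
                raise ValueError
    except ValueError:
        raise ValueError(f"{label}: {lexical!r} is not a valid {datatype}")
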