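"""Structure parsing, validation, standardization and compound registry.

Depositor-provided structures arrive as SDF (V2000 molfile blocks plus
tag/value data fields).  Each record is validated (known elements,
reasonable valence), split into covalent units (connected components of the
molecular graph), and standardized to a canonical key — the standard InChI
string — which keys the compound registry: two depositions of the same
structure map to the same compound accession (CID).  Multi-unit records are
mixtures; a component holding a super-majority (>= 70%) of the heavy atoms
across the *unique* components, and containing at least one carbon, is
designated the parent component (the salt/ion aggregation rule).

The canonical key is produced by the standard InChI algorithm (via RDKit),
which stands in for the full archive-internal tautomer/resonance
canonicalization; acid/base neutralization of components is approximated by
formal-charge neutralization on O/N/S centers where valence permits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import inchi as rdinchi

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # InChI emits copious warnings on odd valences

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "SubstanceRecord",
    "CompoundRecord",
    "StandardizationConfig",
    "SdfParseError",
    "Violation",
    "parse_sdf",
    "validate_structure",
    "split_covalent_units",
    "neutralize",
    "designate_parent",
    "CompoundRegistry",
]


@dataclass(frozen=True)
class Atom:
    element: str
    isotope: int = 0          # mass number, 0 = natural abundance
    charge: int = 0
    implicit_h: int = 0
    stereo_parity: int = 0    # 0 = undefined/none


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: int = 1            # 1-3; aromatic input must be Kekulé
    stereo: int = 0           # 0 = none/undefined, nonzero = defined cis/trans


# Allowed valences per element for implicit-H assignment and valence checks.
# Multi-valent S/P pick the smallest allowed valence that covers the explicit
# bond order sum.  Metals and other absent elements get no implicit H and no
# valence check beyond element recognition.
DEFAULT_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,), "B": (3,), "C": (4,), "N": (3,), "O": (2,),
    "F": (1,), "Si": (4,), "P": (3, 5), "S": (2, 4, 6),
    "Cl": (1,), "Br": (1,), "I": (1,),
}

# Elements recognized without a valence model (salt formers, common metals).
KNOWN_ELEMENTS = set(DEFAULT_VALENCES) | {
    "Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba", "Al", "Zn",
    "Fe", "Cu", "Mn", "Co", "Ni", "Ag", "Au", "Pt", "Pd", "Hg", "Sn",
    "Se", "As", "Sb", "Te", "Ti", "Cr", "Mo", "W", "V", "Zr", "Cd",
    "Ga", "Ge", "In", "Tl", "Pb", "Bi",
}


def _allowed_valences(element: str, charge: int) -> tuple[int, ...]:
    base = DEFAULT_VALENCES.get(element)
    if base is None:
        return ()
    if charge == 0:
        return base
    if element in ("C", "B") and charge > 0:
        shift = -charge
    else:
        shift = charge
    return tuple(v + shift for v in base if v + shift >= 0)


@dataclass(frozen=True)
class StandardizationConfig:
    """Validation and parent-designation parameters.

    ``parent_heavy_atom_fraction`` is the super-majority threshold a
    component must reach over the heavy atoms of all *unique* components
    (each counted once, regardless of multiplicity) to be the parent.
    """

    parent_heavy_atom_fraction: float = 0.70
    require_carbon_for_parent: bool = True
    valences: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_VALENCES)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.parent_heavy_atom_fraction <= 1.0:
            raise ValueError("parent_heavy_atom_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Violation:
    rule: str                 # "over-valence" | "unknown-element"
    atom_index: int
    detail: str = ""


class SdfParseError(ValueError):
    """Malformed SDF input; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclass
class MolecularGraph:
    """A molecular graph: typed atoms, integer-order bonds, stereo flags.

    Atom indices are 0-based internally (the molfile boundary is 1-based).
    An optional cached RDKit mol backs toolkit-delegated computations
    (InChI, SMILES, stereo perception); graphs built programmatically are
    converted on demand.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    _rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n) or bond.a == bond.b:
                raise ValueError(f"bad bond endpoints ({bond.a}, {bond.b})")
            key = (min(bond.a, bond.b), max(bond.a, bond.b))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, valences: dict | None = None) -> "MolecularGraph":
        valences = valences or DEFAULT_VALENCES
        atoms: list[Atom] = []
        order_sum = [0.0] * mol.GetNumAtoms()
        bonds: list[Bond] = []
        for bond in mol.GetBonds():
            o = bond.GetBondTypeAsDouble()
            if o not in (1.0, 2.0, 3.0):
                raise ValueError(
                    f"unsupported bond order {o} (aromatic input must be Kekulé)"
                )
            stereo = 0 if bond.GetStereo() == Chem.BondStereo.STEREONONE else 1
            bonds.append(Bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), int(o), stereo))
            order_sum[bond.GetBeginAtomIdx()] += o
            order_sum[bond.GetEndAtomIdx()] += o
        for idx, atom in enumerate(mol.GetAtoms()):
            element = atom.GetSymbol()
            charge = atom.GetFormalCharge()
            explicit_h = atom.GetNumExplicitHs()
            parity = 0 if atom.GetChiralTag() == Chem.ChiralType.CHI_UNSPECIFIED else (
                1 if atom.GetChiralTag() == Chem.ChiralType.CHI_TETRAHEDRAL_CW else 2
            )
            implicit = _implicit_h(element, charge, order_sum[idx] + explicit_h, valences)
            atoms.append(Atom(element, atom.GetIsotope(), charge, implicit + explicit_h, parity))
        return cls(atoms, bonds, _rdmol=mol)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        if self._rdmol is not None:
            return self._rdmol
        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(atom.charge)
            a.SetIsotope(atom.isotope)
            a.SetNumExplicitHs(atom.implicit_h)
            a.SetNoImplicit(True)
            if atom.stereo_parity == 1:
                a.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
            elif atom.stereo_parity == 2:
                a.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            rw.AddAtom(a)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for bond in self.bonds:
            rw.AddBond(bond.a, bond.b, order_map[bond.order])
        mol = rw.GetMol()
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol

    # -- convenience -------------------------------------------------------

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def has_carbon(self) -> bool:
        return any(a.element == "C" for a in self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.a, b.b) for b in self.bonds)
        return g

    def canonical_key(self) -> Optional[str]:
        """Standard InChI of the graph, or None when canonicalization fails."""
        try:
            mol = self.to_rdkit()
            key = rdinchi.MolToInchi(mol, treatWarningAsError=False)
        except Exception:
            return None
        return key or None


def _implicit_h(element: str, charge: int, order_sum: float, valences: dict) -> int:
    allowed = _allowed_valences(element, charge) if element in valences else ()
    for v in sorted(allowed):
        if v >= order_sum:
            return int(v - order_sum)
    return 0


# -- SDF reading -----------------------------------------------------------


def parse_sdf(stream) -> list[tuple[MolecularGraph, dict[str, str]]]:
    """Read concatenated V2000 records; returns (graph, data fields) pairs.

    Data fields (``> <TAG>`` blocks) are captured verbatim, including the
    base64 fingerprint field of the PubChem SDF dialect when present.
    Molfile blocks are parsed by RDKit without sanitization so chemically
    unreasonable depositions still reach the validation step.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    records = _split_records(text)
    out: list[tuple[MolecularGraph, dict[str, str]]] = []
    for idx, record in enumerate(records):
        molblock, fields = _split_fields(record, idx)
        mol = Chem.MolFromMolBlock(molblock, sanitize=False, removeHs=False)
        if mol is None:
            raise SdfParseError("malformed molfile block", idx)
        # Kekulé bond orders come from the unsanitized parse; wedge-derived
        # chiral tags and double-bond geometry from a sanitized parse when
        # the structure admits one (invalid valences keep stereo flags 0 and
        # fail canonicalization later, which is the intended path).
        san = Chem.MolFromMolBlock(molblock, sanitize=True, removeHs=False)
        if san is not None and san.GetNumAtoms() == mol.GetNumAtoms():
            for a_raw, a_san in zip(mol.GetAtoms(), san.GetAtoms()):
                a_raw.SetChiralTag(a_san.GetChiralTag())
            for b_raw, b_san in zip(mol.GetBonds(), san.GetBonds()):
                b_raw.SetStereo(b_san.GetStereo())
        graph = MolecularGraph.from_rdkit(mol)
        graph._rdmol = san  # sanitized mol backs InChI/SMILES when available
        out.append((graph, fields))
    return out


def _split_records(text: str) -> list[str]:
    chunks: list[str] = []
    current: list[str] = []
    terminated = True
    for line in text.splitlines():
        if line.strip() == "$$$$":
            chunks.append("\n".join(current))
            current = []
            terminated = True
        else:
            current.append(line)
            terminated = False
    if not terminated and any(l.strip() for l in current):
        raise SdfParseError("stream truncated before $$$$ terminator", len(chunks))
    return chunks


def _split_fields(record: str, idx: int) -> tuple[str, dict[str, str]]:
    lines = record.split("\n")
    end = next((i for i, l in enumerate(lines) if l.strip() == "M  END"), None)
    if end is None:
        raise SdfParseError("missing M  END (truncated molfile)", idx)
    molblock = "\n".join(lines[: end + 1]) + "\n"
    fields: dict[str, str] = {}
    i = end + 1
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            lo, hi = line.find("<"), line.rfind(">")
            if lo == -1 or hi <= lo:
                raise SdfParseError(f"malformed data header {line!r}", idx)
            tag = line[lo + 1 : hi]
            i += 1
            value_lines: list[str] = []
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            fields[tag] = "\n".join(value_lines)
        i += 1
    return molblock, fields


# -- validation ------------------------------------------------------------


def validate_structure(
    graph: MolecularGraph, config: StandardizationConfig | None = None
) -> list[Violation]:
    """Element and valence checks; an empty list means the structure passes.

    Violations are data, not exceptions: the registry uses them to decide
    whether a deposition gets a normalized compound at all.
    """
    config = config or StandardizationConfig()
    violations: list[Violation] = []
    order_sum = [0.0] * len(graph.atoms)
    for bond in graph.bonds:
        order_sum[bond.a] += bond.order
        order_sum[bond.b] += bond.order
    for idx, atom in enumerate(graph.atoms):
        if atom.element not in KNOWN_ELEMENTS:
            violations.append(Violation("unknown-element", idx, atom.element))
            continue
        allowed = _allowed_valences(atom.element, atom.charge)
        if allowed and order_sum[idx] > max(allowed):
            violations.append(
                Violation(
                    "over-valence",
                    idx,
                    f"{atom.element}{atom.charge:+d} with bond order sum {order_sum[idx]:g}"
                    if atom.charge
                    else f"{atom.element} with bond order sum {order_sum[idx]:g}",
                )
            )
    return violations


# -- covalent units --------------------------------------------------------


def split_covalent_units(
    graph: MolecularGraph,
) -> tuple[list[MolecularGraph], list[tuple[MolecularGraph, int]]]:
    """Connected components of the molecular graph, plus unique units.

    Returns ``(units, unique_units)`` where ``unique_units`` deduplicates
    by canonical key and carries the multiplicity of each distinct unit;
    multiplicities sum to ``len(units)``.
    """
    if not graph.atoms:
        raise ValueError("empty molecular graph")
    components = list(nx.connected_components(graph.to_networkx()))
    units = [_subgraph(graph, sorted(comp)) for comp in components]
    unique: list[tuple[MolecularGraph, int]] = []
    key_index: dict[str, int] = {}
    for unit in units:
        key = unit.canonical_key() or f"__raw__{_raw_key(unit)}"
        if key in key_index:
            g, mult = unique[key_index[key]]
            unique[key_index[key]] = (g, mult + 1)
        else:
            key_index[key] = len(unique)
            unique.append((unit, 1))
    return units, unique


def _raw_key(graph: MolecularGraph) -> str:
    atoms = sorted((a.element, a.isotope, a.charge, a.implicit_h) for a in graph.atoms)
    return repr((atoms, sorted((b.order,) for b in graph.bonds)))


def _subgraph(graph: MolecularGraph, indices: list[int]) -> MolecularGraph:
    remap = {old: new for new, old in enumerate(indices)}
    atoms = [graph.atoms[i] for i in indices]
    bonds = [
        Bond(remap[b.a], remap[b.b], b.order, b.stereo)
        for b in graph.bonds
        if b.a in remap and b.b in remap
    ]
    return MolecularGraph(atoms, bonds)


def neutralize(graph: MolecularGraph) -> MolecularGraph:
    """Formal-charge neutralization of O/N/S centers where valence permits.

    Protonates anionic O/S (charge -1, gains one H) and deprotonates
    cationic N carrying at least one H.  Charges that cannot be neutralized
    this way (e.g. metal cations, quaternary N) are left untouched.
    """
    atoms: list[Atom] = []
    for atom in graph.atoms:
        if atom.charge == -1 and atom.element in ("O", "S"):
            atoms.append(replace(atom, charge=0, implicit_h=atom.implicit_h + 1))
        elif atom.charge == 1 and atom.element == "N" and atom.implicit_h >= 1:
            atoms.append(replace(atom, charge=0, implicit_h=atom.implicit_h - 1))
        else:
            atoms.append(atom)
    return MolecularGraph(atoms, list(graph.bonds))


def designate_parent(
    unique_units: list[tuple[MolecularGraph, int]],
    config: StandardizationConfig | None = None,
) -> Optional[int]:
    """Index of the parent component among the unique units, if any.

    A unit is the parent when its heavy atoms are >= 70% (configurable) of
    the heavy atoms summed over unique units — each unique unit counted
    once, multiplicity ignored — and it contains at least one carbon.  At
    most one unit can reach a super-majority.
    """
    config = config or StandardizationConfig()
    total = sum(unit.heavy_atom_count() for unit, _ in unique_units)
    if total == 0:
        return None
    for idx, (unit, _) in enumerate(unique_units):
        frac = unit.heavy_atom_count() / total
        if frac >= config.parent_heavy_atom_fraction:
            if config.require_carbon_for_parent and not unit.has_carbon():
                return None
            return idx
    return None


# -- depositor and registry records ---------------------------------------


@dataclass
class SubstanceRecord:
    """One depositor assertion: a substance accession with its provenance.

    Every substance is attributed to exactly one source; synonyms carry
    depositor-assigned type labels; cross-references are optional.
    """

    sid: int
    source_name: str
    version: int = 1
    synonyms: list[tuple[str, list[str]]] = field(default_factory=list)
    pdb_id: Optional[str] = None
    chembl_id: Optional[str] = None
    pubmed_ids: list[int] = field(default_factory=list)
    mesh_id: Optional[str] = None
    atc_code: Optional[str] = None
    chebi_class: Optional[str] = None
    structure: Optional[MolecularGraph] = None
    fingerprint_b64: Optional[str] = None
    passthrough: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sid <= 0:
            raise ValueError("sid must be positive")
        if self.version < 1:
            raise ValueError("version must be >= 1")
        if not self.source_name.strip():
            raise ValueError("source_name must be non-empty")


@dataclass
class CompoundRecord:
    cid: int
    graph: MolecularGraph
    canonical_key: str
    component_cids: list[int] = field(default_factory=list)
    parent_cid: Optional[int] = None
    is_mixture: bool = False

    def __post_init__(self) -> None:
        if self.is_mixture and len(self.component_cids) < 2:
            raise ValueError("a mixture must reference >= 2 component CIDs")
        if self.parent_cid is not None and not (
            self.parent_cid == self.cid or self.parent_cid in self.component_cids
        ):
            raise ValueError("parent_cid must be a component or self")


class CompoundRegistry:
    """Canonical-key -> CID registry with sequential, reproducible CIDs.

    Registration is idempotent and a pure function of the canonical key:
    atom-order permutations of the same structure receive the same CID.
    Validation failures and canonicalization failures yield no CID at all
    (the substance then carries no normalization link).  Mixture records
    additionally register each unique *neutralized* component and record
    the parent designation.
    """

    def __init__(self, config: StandardizationConfig | None = None):
        self.config = config or StandardizationConfig()
        self._by_key: dict[str, int] = {}
        self.records: dict[int, CompoundRecord] = {}
        self._next_cid = 1

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records.values())

    def register(self, graph: MolecularGraph) -> Optional[int]:
        if validate_structure(graph, self.config):
            return None
        key = graph.canonical_key()
        if key is None:
            logger.warning("canonical-key computation failed; treating as standardization failure")
            return None
        if key in self._by_key:
            return self._by_key[key]
        cid = self._next_cid
        self._next_cid += 1
        self._by_key[key] = cid

        units, unique_units = split_covalent_units(graph)
        is_mixture = len(units) > 1
        component_cids: list[int] = []
        parent_cid: Optional[int] = None
        if is_mixture:
            neutral_units = [(neutralize(u), m) for u, m in unique_units]
            aligned: list[Optional[int]] = [self.register(u) for u, _ in neutral_units]
            component_cids = [c for c in aligned if c is not None]
            parent_idx = designate_parent(neutral_units, self.config)
            if parent_idx is not None:
                parent_cid = aligned[parent_idx]
        self.records[cid] = CompoundRecord(
            cid=cid,
            graph=graph,
            canonical_key=key,
            component_cids=component_cids,
            parent_cid=parent_cid,
            is_mixture=is_mixture,
        )
        return cid

    def dump_tsv(self) -> str:
        """Registry dump: one ``canonical_key<TAB>cid`` row per compound."""
        rows = [f"{rec.canonical_key}\t{rec.cid}" for rec in self.records.values()]
        return "\n".join(["canonical_key\tcid", *rows]) + "\n"
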