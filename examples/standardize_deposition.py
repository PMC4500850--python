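"""Validate, split and register depositor structures.

A 2:1 atorvastatin-calcium salt is parsed from its molfile, split into
covalent units, and registered: the registry assigns one CID per unique
canonical structure, registers the neutralized components of the mixture,
and designates the carbon-rich super-majority component as the parent.
"""

from chemrdf import CompoundRegistry, parse_sdf, split_covalent_units, validate_structure
from chemrdf.worked_example import atorvastatin_calcium_molfile

(graph, _fields), = parse_sdf(atorvastatin_calcium_molfile() + "$$$$\n")
print("violations:", validate_structure(graph) or "none")

units, unique = split_covalent_units(graph)
print(f"covalent units: {len(units)}  unique: "
      + ", ".join(f"{u.heavy_atom_count()} heavy atoms x{m}" for u, m in unique))

registry = CompoundRegistry()
cid = registry.register(graph)
record = registry.records[cid]
print(f"mixture CID{cid}: components {record.component_cids}, "
      f"parent CID{record.parent_cid}")
print()
print("The atorvastatin component holds 41 of 42 unique-component heavy")
print("atoms (>= 70%) and contains carbon, so it is the designated parent;")
print("the calcium counter-ion is a plain component.")
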