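"""Compute and type the chemical descriptors of atorvastatin.

Native descriptors are summed on the molecular graph with the pinned
2005/2007 IUPAC atomic weights; identifier descriptors come from the
toolkit adapter.  Each value is bound to its CHEMINF ontology class, an
XSD datatype, and (for masses) the gram-per-mole unit.
"""

from chemrdf import (
    adapter_descriptors,
    build_descriptor_assertions,
    compute_native_descriptors,
    parse_sdf,
)
from chemrdf.worked_example import atorvastatin_molfile

(graph, _), = parse_sdf(atorvastatin_molfile() + "$$$$\n")
values = {**compute_native_descriptors(graph), **adapter_descriptors(graph)}

for label in ("Molecular_Formula", "Molecular_Weight", "Mono_Isotopic_Weight",
              "Heavy_Atom_Count", "Hydrogen_Bond_Donor_Count",
              "Hydrogen_Bond_Acceptor_Count", "Rotatable_Bond_Count",
              "Defined_Atom_Stereocenter_Count", "IUPAC_InChIKey"):
    print(f"{label:34s} {values[label]}")

print()
mw = next(a for a in build_descriptor_assertions("CID60823", values)
          if a.descriptor_label == "Molecular_Weight")
print(f"typed assertion: descr:CID60823_Molecular_Weight a sio:{mw.cheminf_type};")
print(f'  sio:has-value "{mw.value}"^^xsd:{mw.datatype}; sio:has-unit obo:{mw.unit} .')
print()
print("558.639803 g/mol is the sum of standard atomic weights over")
print("C33H35FN2O5; the unit obo:UO_0000055 is gram per mole.")
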