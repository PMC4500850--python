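"""Mint subdomain URIs: accessions, descriptors, MD5 synonyms, neighbors.

Every resource lives in its own subdomain namespace; synonym URIs hash the
case-folded name so lookups are case-insensitive, and neighbor URIs put
the lower compound accession first so a symmetric pair has one canonical
name.
"""

from chemrdf import (
    compact_iri,
    mint_descriptor_iri,
    mint_entity_iri,
    mint_inchikey_iri,
    mint_neighbor_iri,
    mint_synonym_iri,
)

print("compound:   ", mint_entity_iri("compound", 60823))
print("substance:  ", mint_entity_iri("substance", 103554720))
print("descriptor: ", mint_descriptor_iri("CID60823", "Molecular_Weight"))
print("inchikey:   ", mint_inchikey_iri("XUKUURHRXDUEBC-KAYWLYCHSA-N"))
for text in ("Atorvastatin", "atorvastatin"):
    print(f"synonym({text!r}):", compact_iri(mint_synonym_iri(text)))
print("neighbor:   ", compact_iri(mint_neighbor_iri(10030610, 60823, "2D")))
print()
print("Both spellings hash to the same MD5 synonym URI, and the neighbor")
print("URI is identical regardless of the argument order.")
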