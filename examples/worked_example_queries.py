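"""The atorvastatin worked example and its SPARQL queries.

Builds the published RDF neighborhood of atorvastatin (CID60823) from
first principles — structure from a molfile verified against its InChIKey,
descriptors computed, similarity scores carried as inputs — then runs the
example queries over the entailed graph.
"""

from chemrdf import materialize_inferences, run_example_query
from chemrdf.worked_example import build_worked_example

example = build_worked_example()
print(f"worked-example graph: {len(example.graph)} asserted triples")

inferred = materialize_inferences(example.graph)
print(f"after entailment:     {len(inferred)} triples")
print()

print("substances and sources of CID60823:")
for substance, source in run_example_query(inferred, "substances-by-compound"):
    print("  ", substance.rsplit("/", 1)[1], "<-", source.rsplit("/", 1)[1])

print()
print("pharmacological roles of the ligand in PDB 1HWK:")
for (label,) in run_example_query(inferred, "pdb-ligand-roles"):
    print("  ", label)

print()
print("NSAID compounds under 200 g/mol:",
      run_example_query(inferred, "nsaid-mw-filter") or "none")
print()
print("The role query walks substance -> PDB link -> ChEBI class ->")
print("role restriction and returns exactly the two published role labels;")
print("the weight filter is empty because atorvastatin is 558.639803 g/mol.")
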