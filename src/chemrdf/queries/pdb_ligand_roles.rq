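# Pharmacological roles (via ChEBI role restrictions) of the chemical bound
# in a given PDB crystal structure.
PREFIX obov: <http://purl.obolibrary.org/obo#>
PREFIX rdf:  <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX owl:  <http://www.w3.org/2002/07/owl#>
PREFIX pdbo: <http://rdf.wwpdb.org/schema/pdbx-v40.owl#>
PREFIX pdbr: <http://rdf.wwpdb.org/pdb/>
SELECT DISTINCT ?rolelabel
WHERE {
  ?substance pdbo:link_to_pdb pdbr:1HWK .
  ?substance rdf:type ?chebi .
  ?chebi rdfs:subClassOf [ a owl:Restriction ;
                           owl:onProperty obov:has_role ;
                           owl:someValuesFrom ?role ] .
  ?role rdfs:label ?rolelabel .
}
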