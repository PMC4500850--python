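# Substances with the NSAID role coming from data sources categorized as
# providers of protein 3-D structures.
PREFIX obov:    <http://purl.obolibrary.org/obo#>
PREFIX obo:     <http://purl.obolibrary.org/obo/>
PREFIX rdf:     <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs:    <http://www.w3.org/2000/01/rdf-schema#>
PREFIX owl:     <http://www.w3.org/2002/07/owl#>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX concept: <http://rdf.ncbi.nlm.nih.gov/pubchem/concept/>
SELECT DISTINCT ?substance ?source
WHERE {
  ?substance dcterms:source ?source .
  ?source dcterms:subject concept:Protein_3D_Structures .
  ?substance rdf:type ?chebi .
  ?chebi rdfs:subClassOf [ a owl:Restriction ;
                           owl:onProperty obov:has_role ;
                           owl:someValuesFrom obo:CHEBI_35475 ] .
}
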