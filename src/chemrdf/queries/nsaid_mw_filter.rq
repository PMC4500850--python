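# Compounds with the NSAID role (ChEBI_35475) and molecular weight < 200.
PREFIX obov: <http://purl.obolibrary.org/obo#>
PREFIX obo:  <http://purl.obolibrary.org/obo/>
PREFIX rdf:  <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX owl:  <http://www.w3.org/2002/07/owl#>
PREFIX sio:  <http://semanticscience.org/resource/>
SELECT DISTINCT ?compound
WHERE {
  ?compound rdf:type ?chebi .
  ?chebi rdfs:subClassOf [ a owl:Restriction ;
                           owl:onProperty obov:has_role ;
                           owl:someValuesFrom obo:CHEBI_35475 ] .
  ?compound sio:has-attribute ?MW .
  ?MW rdf:type sio:CHEMINF_000334 .
  ?MW sio:has-value ?MWValue .
  FILTER ( ?MWValue < 200 )
}
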