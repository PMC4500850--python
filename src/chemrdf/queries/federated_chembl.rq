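# Federated query against the Uppsala ChEMBL endpoint for bioactivities of
# a substance cross-linked via skos:exactMatch.  Shipped as query text only:
# it requires a remote SPARQL SERVICE and is never executed locally.
PREFIX onto:      <http://rdf.farmbio.uu.se/chembl/onto/#>
PREFIX skos:      <http://www.w3.org/2004/02/skos/core#>
PREFIX owl:       <http://www.w3.org/2002/07/owl#>
PREFIX rdfs:      <http://www.w3.org/2000/01/rdf-schema#>
PREFIX substance: <http://rdf.ncbi.nlm.nih.gov/pubchem/substance/>
SELECT DISTINCT ?rel ?value ?unit ?label
WHERE {
  substance:SID103554720 skos:exactMatch ?chembl .
  SERVICE <http://rdf.farmbio.uu.se/chembl/sparql>
  WHERE {
    ?chembl owl:equivalentClass ?mol .
    ?act onto:forMolecule ?mol .
    ?act onto:relation ?rel .
    ?act onto:standardValue ?value .
    ?act onto:standardUnits ?unit .
    ?act onto:type ?type .
    ?act onto:onAssay ?assay .
    ?assay rdfs:label ?label .
  }
}
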