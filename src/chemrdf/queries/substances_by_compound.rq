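# All substances standardized to a given compound, with their data sources.
PREFIX sio:      <http://semanticscience.org/resource/>
PREFIX compound: <http://rdf.ncbi.nlm.nih.gov/pubchem/compound/>
PREFIX dcterms:  <http://purl.org/dc/terms/>
SELECT DISTINCT ?substance ?source
WHERE {
  ?substance sio:CHEMINF_000477 compound:CID60823 .
  ?substance dcterms:source ?source .
}
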