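# chemrdf

`chemrdf` converts depositor-style chemical substance records into the
PubChem RDF data model and serves the result to Semantic Web tooling: it
mints subdomain URIs, standardizes structures into a compound registry,
computes and ontology-types chemical descriptors, derives identity-group
and similarity relations, models provenance, serializes Turtle (one file
per subdomain), materializes the model's entailments, and answers the
canonical SPARQL queries — all offline, on synthetic or fixture data.

It is written for cheminformaticians and knowledge-graph engineers who
want the archive's substance/compound semantics as a reusable,
inspectable engine rather than as a remote endpoint.

## The data model in brief

* **Substances vs compounds.** A *substance* (SID) is one depositor's
  assertion — structure, names, cross-references — attributed to exactly
  one source (`dcterms:source`). Validation (known elements, sane
  valence) plus canonicalization maps it to at most one *compound* (CID),
  linked by `cheminf:CHEMINF_000477`; the canonical key is the standard
  InChI of the structure, so equal structures from different depositors
  share a CID.
* **Mixtures and parents.** A compound with more than one covalent unit
  (connected component) is a mixture, linked to its neutralized
  components by `CHEMINF_000480`. A component holding ≥ 70 % of the heavy
  atoms across the *unique* components and containing carbon is the
  designated parent (`vocab:has_parent`), aggregating salt and ionized
  forms.
* **Identity groups.** Compounds sharing a skeleton are related at three
  levels read off the InChI layers: isotopologues (`CHEMINF_000455`,
  stereo fixed), stereoisomers (`CHEMINF_000461`, isotope fixed), same
  connectivity (`CHEMINF_000462`). Only the most specific predicate is
  asserted; `000455` and `000461` are subproperties of `000462`, and a
  small fixpoint materializer adds the entailed and symmetric-mirror
  statements.
* **Similarity neighboring.** 2-D neighbors satisfy Tanimoto ≥ 0.90 over
  881-bit binary substructure fingerprints (decoded from their base64 SDF
  field, T = |a∩b|/|a∪b|); 3-D neighbors are threshold decisions over
  externally supplied shape/feature Tanimoto scores (ST ≥ 0.80 and
  CT ≥ 0.50 with pharmacophore features, ST ≥ 0.93 without). Each scored
  pair is reified n-ary style: an association node `sio:refers-to` both
  compounds and carries typed score nodes via
  `sio:has-measurement-value`.
* **Descriptors, synonyms, provenance.** Every descriptor is typed by its
  CHEMINF class with an XSD datatype and unit (e.g. molecular weight →
  `CHEMINF_000334`, `xsd:double`, `obo:UO_0000055`). Synonym URIs are
  `syno:MD5_<hex>` over the case-folded name; a voting filter promotes a
  name to a compound only when a strict majority of distinct sources
  agrees. Sources are `dcterms:Dataset` instances categorized by SKOS
  concepts.

## Worked example

`examples/worked_example_queries.py` builds the atorvastatin neighborhood
(compound CID60823) from first principles and queries it:

```text
worked-example graph: 163 asserted triples
after entailment:     175 triples

substances and sources of CID60823:
   SID103554720 <- ChEMBL
   SID1950 <- ChemIDplus
   SID26697365 <- ChEBI
   SID43118161 <- DrugBank
   SID822166 <- MMDB

pharmacological roles of the ligand in PDB 1HWK:
   antilipemic drug
   hydroxymethylglutaryl-CoA reductase inhibitor

NSAID compounds under 200 g/mol: none
```

Five depositions standardize to one compound; the role query walks
substance → PDB cross-reference → ChEBI class → role restriction and
returns the two pharmacological roles; the molecular-weight filter is
empty because atorvastatin weighs 558.639803 g/mol — the exact value the
descriptor module computes from the pinned 2005/2007 IUPAC atomic
weights over C33H35FN2O5.

The other scripts in `examples/` each demonstrate one capability (URI
minting, standardization and the parent rule, descriptor typing, identity
groups, fingerprint neighboring, the full pipeline). A thin CLI wraps the
pipeline:

```bash
chemrdf synth   --seed 42 --n 20 --out deposition/
chemrdf convert --sdf deposition/deposition.sdf \
                --meta deposition/metadata.json --out ttl/ --materialize
chemrdf query   --graph ttl/ --name substances-by-compound --cid 1
```

## Layout

```
src/chemrdf/
  namespaces.py     subdomain namespace table and URI minting
  chem.py           SDF parsing, validation, covalent units, registry
  descriptors.py    descriptor computation + CHEMINF/unit/software catalog
  identity.py       InChI-layer identity keys and CIG relations
  similarity.py     fingerprint codec, Tanimoto, neighboring, n-ary pattern
  graph.py          triple emission, synonym vote, entailment, Turtle, SPARQL
  pipeline.py       end-to-end conversion
  synth.py          seeded synthetic deposition generator
  worked_example.py the atorvastatin fixture
  data/*.tsv        atomic weights, CHEMINF catalogs
  queries/*.rq      the example SPARQL queries (incl. the federated one,
                    shipped as text only)
```

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
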