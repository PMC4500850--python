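# Methods

This note records the model `chemrdf` implements, the parameters that
matter, the numerical and design choices made where the design was open,
and what the synthetic tests do and do not demonstrate.

## Standardization and the compound registry

A depositor structure becomes a compound only if it passes validation:
every element must be recognized, and no atom may exceed its maximum
allowed valence. The valence table is deliberately small and configurable
(C 4; N 3, +1 charged 4; O 2; halogens 1; S 2/4/6; P 3/5; charge shifts
follow the usual electron-count rules, e.g. O⁻ 1, C⁺ 3); metals are
recognized but not valence-checked. Validation failures are data, not
exceptions — a failed record simply carries no normalization link, which
is itself part of the model.

The canonical key is the standard InChI string produced by the toolkit's
InChI adapter. This is an explicit proxy: the archive's own normalization
collapses tautomer and resonance variation with internal machinery that
is not openly specified, while InChI is the one canonicalizer with a
public definition whose layer structure also drives the identity groups.
Consequences: records differing only by tautomer form may receive
distinct CIDs here that the real archive would merge.

CIDs are assigned sequentially in first-seen order over a fixed input
ordering (substances sorted by SID), so runs are reproducible; real
archive accessions are *not* reproduced, except in the worked-example
fixture where the published accessions are fixed inputs.

Mixture handling: covalent units are the connected components of the
molecular graph. Acid/base neutralization of components is reduced to
formal-charge neutralization — anionic O/S gain a proton, cationic N
with an available proton loses one — a simplification that covers the
common carboxylate/ammonium salt forms but not multi-step acid/base
chemistry. The parent rule is applied to the *unique* neutralized
components, each counted once regardless of multiplicity: a component is
the parent iff its heavy atoms are ≥ 70 % of that total and it contains
carbon. At most one component can reach a super-majority, so the rule
needs no tie-break.

## Descriptors

Native descriptors are computed directly on the graph. The atomic-weight
table is pinned to the 2005/2007 IUPAC standard atomic weights (C
12.0107, H 1.00794, N 14.0067, O 15.9994, F 18.9984032, …) because the
reference molecular-weight value 558.639803 g/mol for C33H35FN2O5 is only
bit-reproducible under that revision — later tables shift the fourth
decimal. Monoisotopic weight sums principal-isotope masses; exact mass
additionally honours explicit isotope labels (unknown labels fall back to
the mass number, an ~0.1 u approximation). Mass lexical forms are printed
with six decimals, trailing zeros trimmed.

Hydrogen-bond donors are N/O atoms bearing at least one hydrogen;
acceptors are all N/O atoms; rotatable bonds are acyclic (bridge) single
bonds between heavy atoms of heavy-degree ≥ 2, excluding amide C–N.
These simple Cactvs-style rules are this package's own definitions — the
software that computes the archive's values is named in the catalog but
its exact rule set is proprietary — so counts can differ from archival
values on edge cases (e.g. tautomeric donors).

Stereocenter counts use the toolkit's stereo perception over the
wedge-annotated input (defined vs potential-but-undefined centers) rather
than full CIP analysis; structures that fail sanitization fall back to
counting explicit flags only.

SMILES, InChI and InChIKey are delegated to the toolkit. XLogP3, TPSA,
structure complexity, tautomer count and IUPAC names are passed through
from depositor input fields when present and omitted otherwise — their
algorithms are out of scope. Descriptor software provenance is recorded
in each assertion but emitted as a triple only behind a flag (default
off): the exported model demonstrates explicit `sio:is-output-of` links
for similarity scores, not for plain descriptors, and the default
follows that.

## Identity groups

Identity keys are a purely textual split of the InChI string:
connectivity = formula + `/c` + `/h` (plus charge layers `/q`, `/p`,
which are treated as part of identity); isotope = `/i` with its
sublayers; stereo = top-level `/t`, `/b`, `/m`, `/s`. Pairs sharing a
connectivity key are classified by which of the other two keys differ;
only the most specific predicate is asserted, and the generic
same-connectivity statement plus all symmetric mirrors are produced by
the materializer. Bucketing by connectivity key keeps the scan near-linear
in practice; tests assert equivalence with an all-pairs oracle.

## Similarity

The fingerprint dialect is pinned: base64 text decoding to a 4-byte
big-endian declared bit length that must equal 881, followed by the bits
packed most-significant-bit first; any other declared length is a dialect
error. Tanimoto over two empty bit sets is defined as 0.0 (no shared
evidence), not 1.0. Thresholds: 2-D ≥ 0.90; 3-D ST ≥ 0.80 ∧ CT ≥ 0.50
when both compounds have pharmacophore features, ST ≥ 0.93 when neither
does. "Has pharmacophore features" is operationalized as H-bond acceptor
count ≥ 1 (configurable). The mixed case — exactly one compound with
features — is covered by neither rule; no pair is emitted and the event
is logged. 3-D scores are consumed from an external table, never
computed: conformer generation and shape/feature scoring are out of
scope.

## Graph assembly and entailment

Entailment is restricted to the rules the data model itself exhibits:
`vocab:has_parent ⊑ CHEMINF_000480`, `000455 ⊑ 000462`,
`000461 ⊑ 000462`, and symmetry of `000455/000461/000462/000482/000483`.
The materializer is a monotone, idempotent fixpoint; no general RDFS/OWL
reasoning is attempted, and the subproperty axioms themselves are written
into the output so a downstream reasoner can reproduce the closure.
Symmetric statements are materialized in both directions.

The synonym vote is a documented stand-in for the archive's unpublished
algorithm: votes are distinct source names per (case-folded name, CID),
and a name is promoted to a compound only when its CID strictly out-votes
every other CID carrying that name. Ties promote nothing; a single
source suffices when unopposed.

Turtle serialization binds the full subdomain prefix table. One deviation
from the stock rdflib writer: `xsd:double` literals are emitted as quoted
typed literals because the default bare-token form is rendered at six
significant digits, which would corrupt values like 558.639803 on a
serialize/parse round-trip. Output is partitioned into one file per
subdomain by the subject's namespace.

The four example queries ship as `.rq` files and run through rdflib's
SPARQL engine with rows sorted lexically for determinism. The
molecular-weight filter query corrects an inconsequential variable-name
typo present in its published form (`?comp` for `?compound`), which would
otherwise turn the weight pattern into a cross join. The federated
ChEMBL query ships as text only — it requires a remote SPARQL `SERVICE`
and is never executed.

## Synthetic data

The generator emulates a multi-depositor archive at a scale chosen to
exercise every rule quickly: by default 20 base structures and 4 sources,
with 25 % of bases deposited as sodium-salt mixtures, 25 % accompanied by
an enantiomeric variant, 15 % by a ¹³C-labelled variant, and name
conflicts injected at 10 %. Every base is a chiral fluorinated carboxylic
acid with a random CHNOPS(+F/Cl) substituent tree, which guarantees a
defined stereo layer (so enantiomer pairs are true stereoisomers) and a
salt-formable group (so salted deposits are mixtures with a carbon-rich
parent).

Fingerprints are seeded random 150-of-881-bit sets, not computed from
structure — key generation is out of scope — and a variant flips at most
five of its template's bits, so variant pairs clear the 0.90 Tanimoto
threshold by construction while unrelated bases (independent random
sets) fall far below it. What passing tests therefore show is that the
*mapping rules* behave correctly on inputs with known ground truth; they
say nothing about fingerprint quality or similarity recall on real
chemistry. Likewise the generator's structures are small (3–40 heavy
atoms) and aromatic-free, so aromatic perception and macromolecular edge
cases are untested by design.

Equal seeds give byte-identical SDF/metadata and identical Turtle.

## Worked example

The atorvastatin fixture rebuilds its structure from an isomeric SMILES
and fails loudly if the derived InChIKey stops matching
`XUKUURHRXDUEBC-KAYWLYCHSA-N` (drift guard). Published accession numbers
(CID60823, the four SIDs, the partner CIDs) and the published pairwise
similarity scores (0.98, 0.88, 0.59) are *inputs*: the accessions because
this engine cannot reproduce archive accession assignment, the scores
because fingerprint generation and 3-D scoring are out of scope. The
ChEBI role axioms are encoded locally in the published restriction shape
(`rdfs:subClassOf [ a owl:Restriction; owl:onProperty obov:has_role;
owl:someValuesFrom <role> ]`) rather than importing the full ontology.
Aggregate statistics quoted against the live archive (e.g. result counts
of corpus-wide queries) require the real databases and are out of reach
of fixtures by construction.

## Known limitations

* Tautomer/resonance merging is only as strong as standard InChI.
* Charge-layer placement treats `/q`/`/p` as identity-defining; protomers
  therefore never join an identity group.
* The valence table covers common organic chemistry; exotic oxidation
  states must be configured in.
* Aromatic (order-4) molfile bonds are rejected at the parser boundary —
  all package-produced molfiles are Kekulé.
* The synonym vote, the pharmacophore-feature proxy, and the donor/
  acceptor/rotatable-bond rules are this package's own documented
  definitions of under-specified archive behavior.
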