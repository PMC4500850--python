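"""Identity-group relations between registered compounds.

Compounds sharing a skeleton are related at three levels read off the
layered canonical (InChI) key: isotopologues (stereo fixed), stereoisomers
(isotope fixed), and same-connectivity (both vary).  Only the most
specific relation is asserted; the generic one follows by entailment.
"""

from rdkit import Chem

from chemrdf import MolecularGraph, build_cig_relations, identity_keys


def key_of(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return MolecularGraph.from_rdkit(mol).canonical_key()


compounds = {
    1: key_of("CCO"),                 # ethanol
    2: key_of("[2H]C([2H])(C)O"),     # 1,1-dideuterioethanol
    3: key_of("F[C@H](Cl)Br"),        # (R)-bromochlorofluoromethane
    4: key_of("F[C@@H](Cl)Br"),       # (S)-
    5: key_of("c1ccccc1"),            # unrelated
}

for cid, key in compounds.items():
    k = identity_keys(key)
    print(f"CID{cid}: connectivity={k.connectivity_key!r} "
          f"isotope={k.isotope_key!r} stereo={k.stereo_key!r}")

print()
for rel in build_cig_relations(compounds):
    print(f"compound:CID{rel.cid_a} cheminf:{rel.predicate} compound:CID{rel.cid_b}")
print()
print("CID1/CID2 differ only in the isotope layer (isotopologues, 000455);")
print("CID3/CID4 differ only in the stereo layer (stereoisomers, 000461);")
print("benzene shares no connectivity key and is related to nothing.")
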