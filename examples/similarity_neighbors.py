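"""2-D fingerprint neighboring and the n-ary similarity pattern.

881-bit substructure fingerprints are decoded from their base64 SDF field,
scored with the Tanimoto coefficient, thresholded at 0.90, and each
surviving pair is reified as an association node with refers-to links and
a measurement-value score node.
"""

from chemrdf import (
    Fingerprint,
    decode_cactvs_subskeys,
    encode_cactvs_subskeys,
    neighbor_pairs,
    similarity_triples,
    tanimoto,
)
from chemrdf.namespaces import DEFAULT_NAMESPACES

a = Fingerprint(frozenset(range(0, 150)))
b = Fingerprint(frozenset(range(3, 150)))    # 147/150 shared
c = Fingerprint(frozenset(range(400, 520)))  # disjoint

field = encode_cactvs_subskeys(a)
print("SDF field (base64, 4-byte length header + MSB-first bits):")
print(" ", field[:48] + "...")
print("decoded bits:", len(decode_cactvs_subskeys(field).bits))

print(f"tanimoto(a, b) = {tanimoto(a, b):.4f}  (neighbors, >= 0.90)")
print(f"tanimoto(a, c) = {tanimoto(a, c):.4f}  (not neighbors)")
print()

pairs = neighbor_pairs({60823: a, 10030610: b, 99999: c})
for pair in pairs:
    print(f"pair CID{pair.cid_a}/CID{pair.cid_b}: score {pair.tanimoto_2d:.4f}")
    for s, p, o in similarity_triples(pair):
        table = DEFAULT_NAMESPACES
        print("  ", table.compact(s), table.compact(p) if "://" in str(p) else p,
              o if not str(o).startswith("http") else table.compact(o))
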