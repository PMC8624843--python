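"""Extract sparse features from a toy protein-RNA pair and score a map.

A contact map activates three groups of count features: k-mer contexts
of each binding residue, of each binding base, and paired windows of
each contact.  The model score is the inner product of these counts
with a sparse weight vector, and it always equals the equivalent
per-variable linear form u.x + v.y + w.z used by the decoder.
"""

from ribocontact import (
    ContactMap,
    ModelWeights,
    ProteinRecord,
    RNARecord,
    full_features,
    score,
    score_terms,
)

protein = ProteinRecord("toy_prot", "MKVLR", "HHHEE")
rna = RNARecord.from_dotbracket("toy_rna", "ACGUACG", "((...))")
z = ContactMap(5, 7, frozenset({(2, 3), (2, 4)}))

phi = full_features(protein, rna, z)
print(f"{len(phi)} active feature keys; a few of them:")
for key, count in sorted(phi.items())[:6]:
    print(f"  {key[0]:<24s} {'|'.join(key[1]):<14s} x{count}")

model = ModelWeights({key: 0.1 for key in phi})
terms = score_terms(protein, rna, model)
print(f"\nfeature-space score : {score(protein, rna, z, model):.3f}")
print(f"linear-form score   : {terms.objective(z):.3f}")
print("(identical by construction: every active key weighs 0.1, so the")
print(" score is 0.1 x total feature count)")
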