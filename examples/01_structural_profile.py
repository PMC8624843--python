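"""Annotate an RNA secondary structure with loop-context labels.

Each base of a dot-bracket structure gets one of six states: stack (S)
for paired bases, and external (E), hairpin (H), internal (I), bulge (B)
or multibranch (M) loop for unpaired ones.  These labels are the RNA
side of the model's structural features.
"""

from ribocontact import rna_profile

structures = [
    ".....",                   # fully unpaired
    "(((...)))",               # one stem-loop
    "((.((...))))",            # stem with a bulge
    "((.((...)).))",           # stem with an internal loop
    "((.((...))((...)).))",    # multibranch junction
]

for s in structures:
    print(s)
    print(rna_profile(s))
    print()
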