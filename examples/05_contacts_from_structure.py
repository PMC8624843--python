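"""Derive a contact map from 3D coordinates by the heavy-atom rule.

A residue and a base are in contact when any two of their non-hydrogen
atoms lie within 4.0 Angstrom.  The coordinates below are synthetic
(hand-placed to straddle the cutoff), not from a real structure.
"""

from ribocontact.datasets import Atom, contacts_from_coordinates

protein_atoms = [
    Atom(1, "CA", (0.0, 0.0, 10.0)),   # far from everything
    Atom(2, "CB", (0.0, 0.0, 3.9)),    # 3.9 A from base 1's phosphate
    Atom(3, "CG", (4.1, 0.0, 0.0)),    # 4.1 A: just outside the cutoff
]
rna_atoms = [
    Atom(1, "P", (0.0, 0.0, 0.0)),
    Atom(1, "HO2", (4.0, 0.0, 0.0)),   # hydrogen: never counted
]

z = contacts_from_coordinates(protein_atoms, rna_atoms, cutoff=4.0)
print(f"contact map ({z.n_residues} residues x {z.n_bases} base):")
print(f"contacts: {sorted(z.contacts)}")
print("residue 2 is within 4.0 A of a heavy atom; residue 3 misses by 0.1 A;")
print("the hydrogen 4.0 A from residue 3 is excluded from the rule.")
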