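"""Contact maps from 3D coordinates, and synthetic labelled corpora.

Real training data come from protein--RNA complex structures: a residue
and a base are in contact when any two of their heavy (non-hydrogen)
atoms lie within a distance cutoff (default 4.0 Angstrom, the van der
Waals contact distance; hydrogen-bond-range contacts at 3.5 A are a
subset of this criterion).

The synthetic generator emulates the full input stack -- random protein
sequences with run-favouring 8-state secondary-structure strings, random
RNA sequences with well-formed stem-loop dot-brackets -- and labels each
pair by exact IP decoding under sparse *planted* weights, so every label
is guaranteed realizable by the model family and reproducible from the
seed.  It supports parameter-recovery and end-to-end training tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DataError, ValidationError
from .features import DEFAULT_CONFIG, FeatureConfig, base_strings, residue_strings, window
from .inference import InferenceProblem, predict_ip
from .io import (
    AA_ALPHABET,
    ContactMap,
    FeatureKey,
    ModelWeights,
    ProteinRecord,
    RNARecord,
    write_annotations,
    write_corpus_contacts,
    write_model,
)
from .learning import TrainingInstance

_AA = "".join(sorted(AA_ALPHABET))
_SS8 = "HGIEBTS-"
_BASES = "ACGU"


# ---------------------------------------------------------------------------
# contact maps from coordinates
# ---------------------------------------------------------------------------

class Atom(NamedTuple):
    index: int          # 1-based residue/base index
    name: str           # PDB atom name
    xyz: tuple[float, float, float]


def contacts_from_coordinates(
    protein_atoms: Sequence[Atom | tuple],
    rna_atoms: Sequence[Atom | tuple],
    cutoff: float = 4.0,
) -> ContactMap:
    """Heavy-atom distance contacts: (i, j) is a contact iff some pair of
    non-hydrogen atoms of residue i and base j is within ``cutoff`` A."""
    def heavy(atoms: Sequence) -> list[Atom]:
        return [Atom(*a) for a in atoms if not Atom(*a).name.startswith("H")]

    pa, ra = heavy(protein_atoms), heavy(rna_atoms)
    if not pa or not ra:
        raise DataError("no heavy atoms on one side of the interface")
    n_res = max(a.index for a in pa)
    n_base = max(a.index for a in ra)
    pcoord = np.array([a.xyz for a in pa], dtype=float)
    rcoord = np.array([a.xyz for a in ra], dtype=float)
    dist = cdist(pcoord, rcoord)
    contacts = {
        (pa[ai].index, ra[bi].index)
        for ai, bi in zip(*np.nonzero(dist <= cutoff))
    }
    return ContactMap(n_res, n_base, frozenset(contacts))


# ---------------------------------------------------------------------------
# random sequence / structure samplers
# ---------------------------------------------------------------------------

def random_protein(rng: np.random.Generator, length: int, stay: float = 0.75) -> tuple[str, str]:
    """A uniform random amino-acid sequence and a run-favouring 8-state
    secondary-structure string (first-order Markov chain, stay
    probability ``stay``)."""
    seq = "".join(rng.choice(list(_AA), size=length))
    states = []
    current = rng.integers(len(_SS8))
    for _ in range(length):
        states.append(_SS8[current])
        if rng.random() >= stay:
            current = (current + 1 + rng.integers(len(_SS8) - 1)) % len(_SS8)
    return seq, "".join(states)


def _sample_unit(rng: np.random.Generator, depth: int = 0) -> str:
    """One stem with loop content: hairpin, internal loop, bulge or
    multibranch (recursion bounded)."""
    h = int(rng.integers(3, 6))  # stem length >= 3 bp
    roll = rng.random()
    if depth >= 2 or roll < 0.5:
        inner = "." * int(rng.integers(3, 7))  # hairpin loop >= 3 nt
    elif roll < 0.65:  # internal loop: unpaired on both sides
        inner = (
            "." * int(rng.integers(1, 4))
            + _sample_unit(rng, depth + 1)
            + "." * int(rng.integers(1, 4))
        )
    elif roll < 0.8:  # bulge: unpaired on one side only
        gap = "." * int(rng.integers(1, 4))
        stem = _sample_unit(rng, depth + 1)
        inner = gap + stem if rng.random() < 0.5 else stem + gap
    else:  # multibranch: >= 2 inner stems
        inner = (
            "." * int(rng.integers(0, 3))
            + _sample_unit(rng, depth + 1)
            + "." * int(rng.integers(1, 3))
            + _sample_unit(rng, depth + 1)
            + "." * int(rng.integers(0, 3))
        )
    return "(" * h + inner + ")" * h


def random_dotbracket(
    rng: np.random.Generator, min_len: int, max_len: int, max_tries: int = 200
) -> str:
    """A random well-formed dot-bracket whose length falls in
    [min_len, max_len]; falls back to a single fitted hairpin (or an
    unpaired string) when rejection sampling fails."""
    if min_len < 1 or max_len < min_len:
        raise ValidationError("invalid dot-bracket length range")
    for _ in range(max_tries):
        n_units = 1 + int(rng.random() < 0.4) + int(rng.random() < 0.15)
        parts = ["." * int(rng.integers(0, 4))]
        for _ in range(n_units):
            parts.append(_sample_unit(rng))
            parts.append("." * int(rng.integers(0, 4)))
        s = "".join(parts)
        if min_len <= len(s) <= max_len:
            return s
    target = (min_len + max_len) // 2
    if target >= 9:  # smallest stem-loop: 3 bp + 3 nt loop
        h = min(3 + (target - 9) // 4, (target - 3) // 2)
        loop = target - 2 * h
        return "(" * h + "." * loop + ")" * h
    return "." * target


def random_rna(rng: np.random.Generator, min_len: int, max_len: int) -> tuple[str, str]:
    """A random RNA sequence and dot-bracket of matching length."""
    db = random_dotbracket(rng, min_len, max_len)
    seq = "".join(rng.choice(list(_BASES), size=len(db)))
    return seq, db


# ---------------------------------------------------------------------------
# synthetic labelled corpora
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    RNA lengths default to 20-40 nt so that internal loops, bulges and
    multibranch loops (which need roughly 17+ nt) occur with positive
    probability and all six loop states appear across a corpus.
    """

    n_pairs: int = 10
    protein_length_range: tuple[int, int] = (15, 30)
    rna_length_range: tuple[int, int] = (20, 40)
    planted_sparsity: float = 0.1
    planted_scale: float = 1.0
    seed: int = 0
    x_cap: int | None = 8
    y_cap: int | None = 8

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        for lo, hi in (self.protein_length_range, self.rna_length_range):
            if lo < 3 or hi < lo:
                raise ValidationError("length ranges must be >= 3 and ordered")
        if not (0 < self.planted_sparsity <= 1):
            raise ValidationError("planted_sparsity must be in (0, 1]")


def _realizable_keys(
    pairs: list[tuple[ProteinRecord, RNARecord]], config: FeatureConfig
) -> list[FeatureKey]:
    """All feature keys that can occur in a corpus (sorted)."""
    keys: set[FeatureKey] = set()
    for p, r in pairs:
        rstr, bstr = residue_strings(p), base_strings(r)
        rwins: dict[tuple[str, int], list[str]] = {}
        for tag, src, k in config.residue_rows:
            for i in range(1, len(p) + 1):
                keys.add((tag, (window(rstr[src], i, k, config.pad_char),)))
        for tag, src, k in config.base_rows:
            for j in range(1, len(r) + 1):
                keys.add((tag, (window(bstr[src], j, k, config.pad_char),)))
        for tag, rsrc, bsrc, k in config.contact_rows:
            rw = [window(rstr[rsrc], i, k, config.pad_char) for i in range(1, len(p) + 1)]
            bw = [window(bstr[bsrc], j, k, config.pad_char) for j in range(1, len(r) + 1)]
            for a in rw:
                for b in bw:
                    keys.add((tag, (a, b)))
    return sorted(keys)


def generate_synthetic(
    config: SyntheticConfig,
    feature_config: FeatureConfig = DEFAULT_CONFIG,
    planted: ModelWeights | None = None,
) -> tuple[list[TrainingInstance], ModelWeights]:
    """Generate a labelled corpus from planted sparse weights.

    Sequences and structures are sampled from the seed; planted weights
    (unless supplied) are drawn Normal(0, scale) on a random
    ``planted_sparsity`` fraction of the realizable feature keys; each
    pair is labelled by exact IP decoding under the planted weights and
    the configured caps, so labels are feasible by construction.
    """
    rng = np.random.default_rng(config.seed)
    pairs: list[tuple[ProteinRecord, RNARecord]] = []
    for k in range(config.n_pairs):
        plen = int(rng.integers(*config.protein_length_range, endpoint=True))
        pseq, ss8 = random_protein(rng, plen)
        rseq, db = random_rna(rng, *config.rna_length_range)
        pairs.append(
            (
                ProteinRecord(f"prot{k + 1:03d}", pseq, ss8),
                RNARecord.from_dotbracket(f"rna{k + 1:03d}", rseq, db),
            )
        )

    if planted is None:
        keys = _realizable_keys(pairs, feature_config)
        n_nonzero = int(round(config.planted_sparsity * len(keys)))
        if n_nonzero == 0:
            warnings.warn("no planted weights sampled; all labels will be empty")
            planted = ModelWeights({})
        else:
            chosen = rng.choice(len(keys), size=n_nonzero, replace=False)
            values = rng.normal(0.0, config.planted_scale, size=n_nonzero)
            planted = ModelWeights(
                {keys[int(i)]: float(v) for i, v in zip(chosen, values) if v != 0.0}
            )

    from .features import score_terms  # local import keeps module load light

    instances = []
    for p, r in pairs:
        terms = score_terms(p, r, planted, feature_config)
        z, _ = predict_ip(InferenceProblem(terms, config.x_cap, config.y_cap))
        instances.append(TrainingInstance(p, r, z))
    return instances, planted


def write_corpus(
    directory: str | Path,
    instances: Iterable[TrainingInstance],
    planted: ModelWeights | None = None,
) -> None:
    """Write a corpus as FASTA + annotation files + contact TSV, loadable
    by the I/O layer (and the planted model, when given)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    instances = list(instances)
    with open(directory / "protein.fasta", "w") as fh:
        for inst in instances:
            fh.write(f">{inst.protein.id}\n{inst.protein.sequence}\n")
    with open(directory / "rna.fasta", "w") as fh:
        for inst in instances:
            fh.write(f">{inst.rna.id}\n{inst.rna.sequence}\n")
    write_annotations(
        directory / "ss8.tsv", {i.protein.id: i.protein.ss8 for i in instances}
    )
    write_annotations(
        directory / "dotbracket.tsv", {i.rna.id: i.rna.dotbracket for i in instances}
    )
    write_corpus_contacts(
        directory / "contacts.tsv",
        {(i.protein.id, i.rna.id): i.z_true for i in instances},
    )
    if planted is not None:
        write_model(directory / "planted_model.tsv", planted)


# ---------------------------------------------------------------------------
# PDB extraction
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_RNA_RESNAMES = {"A": "A", "C": "C", "G": "G", "U": "U"}


class InstanceSkeleton(NamedTuple):
    """Sequences and contact map of one PDB protein/RNA chain pair;
    secondary-structure strings are left to external predictors."""

    protein_id: str
    protein_sequence: str
    rna_id: str
    rna_sequence: str
    contact_map: ContactMap


def pdb_to_instances(
    pdb_file: str | Path, protein_chain: str, rna_chain: str, cutoff: float = 4.0
) -> InstanceSkeleton:
    """Extract one protein chain and one RNA chain from a PDB file.

    Sequences follow author residue order; non-standard residues and
    nucleotides are skipped with a warning and indices compacted; the
    contact map uses the heavy-atom distance criterion.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", str(pdb_file))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    for cid in (protein_chain, rna_chain):
        if cid not in chains:
            raise DataError(f"chain {cid!r} not found in {pdb_file}")

    def extract(chain, table: dict[str, str], what: str):
        seq, atoms = [], []
        idx = 0
        for residue in chain:
            het = residue.id[0].strip()
            name = residue.get_resname().strip()
            if het or name not in table:
                if het == "W":
                    continue
                warnings.warn(f"skipping non-standard {what} {name!r} in chain {chain.id}")
                continue
            idx += 1
            seq.append(table[name])
            for atom in residue:
                atoms.append(Atom(idx, atom.get_name(), tuple(atom.coord)))
        return "".join(seq), atoms

    pseq, patoms = extract(chains[protein_chain], _THREE_TO_ONE, "residue")
    rseq, ratoms = extract(chains[rna_chain], _RNA_RESNAMES, "nucleotide")
    if not pseq or not rseq:
        raise DataError("empty protein or RNA chain after filtering")
    heavy_p = [a for a in patoms if not a.name.startswith("H")]
    heavy_r = [a for a in ratoms if not a.name.startswith("H")]
    if not heavy_p or not heavy_r:
        raise DataError("no heavy atoms in one of the chains")
    zmap = contacts_from_coordinates(heavy_p, heavy_r, cutoff)
    # pad dimensions: trailing residues may have no atoms within cutoff
    zmap = ContactMap(len(pseq), len(rseq), zmap.contacts)
    return InstanceSkeleton(protein_chain, pseq, rna_chain, rseq, zmap)
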