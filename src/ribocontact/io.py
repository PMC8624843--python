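"""Domain types and plain-text file I/O.

The unit of prediction is a protein--RNA pair: a protein sequence with a
per-residue 8-state secondary-structure string (as produced by an
SSpro8-class predictor) and an RNA sequence with a dot-bracket structure
(as produced by a CentroidFold-class predictor) from which a 6-state
loop profile is derived.  A contact map is a sparse set of 1-based
(residue, base) index pairs; the binding indicators x_i and y_j are
derived from it (a residue/base is a binding site iff its row/column of
the map is non-empty).

All file formats are plain text: FASTA for sequences, one-line-per-record
``id<TAB>string`` annotation files for secondary structures, two-column
TSV for single contact maps, four-column TSV for corpora, and TSV model
files.  Indices are 1-based in every file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import profiles
from .errors import BoundsError, ParseError, ValidationError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
RNA_ALPHABET = frozenset("ACGU")

#: A feature key: (feature-type tag, tuple of one or two context strings).
FeatureKey = tuple[str, tuple[str, ...]]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its 8-state secondary-structure string."""

    id: str
    sequence: str
    ss8: str

    def __post_init__(self) -> None:
        if len(self.ss8) != len(self.sequence):
            raise ValidationError(
                f"{self.id}: ss8 length {len(self.ss8)} != sequence length "
                f"{len(self.sequence)}"
            )
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in AA_ALPHABET:
                raise ValidationError(
                    f"{self.id}: illegal amino-acid letter {ch!r} at position {pos}"
                )
        profiles.validate_ss8(self.ss8)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RNARecord:
    """An RNA sequence, its dot-bracket structure and derived loop profile."""

    id: str
    sequence: str
    dotbracket: str
    profile: str

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.dotbracket) != n or len(self.profile) != n:
            raise ValidationError(
                f"{self.id}: sequence/structure/profile lengths differ"
            )
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in RNA_ALPHABET:
                raise ValidationError(
                    f"{self.id}: illegal base {ch!r} at position {pos}"
                )
        paired = {i for pair in profiles.parse_dotbracket(self.dotbracket) for i in pair}
        for j in range(1, n + 1):
            if (self.profile[j - 1] == "S") != (j in paired):
                raise ValidationError(
                    f"{self.id}: profile inconsistent with structure at position {j}"
                )

    @classmethod
    def from_dotbracket(cls, id: str, sequence: str, dotbracket: str) -> "RNARecord":
        """Build a record, deriving the loop profile from the structure."""
        return cls(id, sequence, dotbracket, profiles.rna_profile(dotbracket))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ContactMap:
    """A sparse |P|x|R| binary contact map (1-based index pairs)."""

    n_residues: int
    n_bases: int
    contacts: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_bases < 1:
            raise ValidationError("contact map dimensions must be positive")
        for (i, j) in self.contacts:
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_bases):
                raise BoundsError(
                    f"contact ({i},{j}) outside {self.n_residues}x{self.n_bases} map"
                )

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[int, int]], n_residues: int, n_bases: int
    ) -> "ContactMap":
        return cls(n_residues, n_bases, frozenset((int(i), int(j)) for i, j in pairs))

    def indicators(self) -> tuple[np.ndarray, np.ndarray]:
        """Binding indicators (x, y): x_i=1 iff row i non-empty, y_j likewise."""
        x = np.zeros(self.n_residues, dtype=np.int8)
        y = np.zeros(self.n_bases, dtype=np.int8)
        for (i, j) in self.contacts:
            x[i - 1] = 1
            y[j - 1] = 1
        return x, y

    def dense(self) -> np.ndarray:
        z = np.zeros((self.n_residues, self.n_bases), dtype=np.int8)
        for (i, j) in self.contacts:
            z[i - 1, j - 1] = 1
        return z


def derive_indicators(z: ContactMap) -> tuple[np.ndarray, np.ndarray]:
    """Binding indicators of a contact map (module-level convenience)."""
    return z.indicators()


@dataclass
class ModelWeights:
    """Sparse feature-key -> weight mapping; absent keys weigh 0."""

    weights: dict[FeatureKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prune()

    def get(self, key: FeatureKey) -> float:
        return self.weights.get(key, 0.0)

    def prune(self) -> None:
        """Drop keys whose weight is exactly zero (sparsity invariant)."""
        self.weights = {k: w for k, w in self.weights.items() if w != 0.0}

    def l1_norm(self) -> float:
        return sum(abs(w) for w in self.weights.values())

    def __len__(self) -> int:
        return len(self.weights)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelWeights):
            return NotImplemented
        return self.weights == other.weights


@dataclass
class Hyperparameters:
    """Loss penalties, regularization and optimisation settings.

    The false-negative penalties (0.5) and false-positive penalties
    (0.005) trade sensitivity against specificity in the structured
    hinge loss; C weighs the l1 regularizer.  X_cap/Y_cap bound the
    number of contacts per residue/base (default 8; ``None`` = no bound).
    """

    delta_fn_residue: float = 0.5
    delta_fp_residue: float = 0.005
    delta_fn_base: float = 0.5
    delta_fp_base: float = 0.005
    delta_fn_contact: float = 0.5
    delta_fp_contact: float = 0.005
    C: float = 1e-5
    eta: float = 1.0
    epsilon: float = 1e-8
    tol: float = 1e-6
    max_epochs: int = 100
    X_cap: int | None = 8
    Y_cap: int | None = 8

    def __post_init__(self) -> None:
        deltas = (
            self.delta_fn_residue, self.delta_fp_residue,
            self.delta_fn_base, self.delta_fp_base,
            self.delta_fn_contact, self.delta_fp_contact,
        )
        if any(d < 0 or not math.isfinite(d) for d in deltas):
            raise ValidationError("loss penalties must be nonnegative and finite")
        if self.C < 0 or self.eta <= 0 or self.max_epochs < 1:
            raise ValidationError("invalid optimisation hyperparameters")
        for cap in (self.X_cap, self.Y_cap):
            if cap is not None and cap < 1:
                raise ValidationError("contact caps must be >= 1 or None")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, rna: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file, returning (id, sequence) in file order.

    Sequences are upper-cased; in RNA mode T is mapped to U.  Letters
    outside the canonical alphabet raise :class:`ParseError` naming the
    line number.
    """
    alphabet = RNA_ALPHABET if rna else AA_ALPHABET
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is not None:
            records.append((current_id, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if current_id is None:
                    raise ParseError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                seq = line.upper()
                if rna:
                    seq = seq.replace("T", "U")
                for ch in seq:
                    if ch not in alphabet:
                        raise ParseError(
                            f"{path}: illegal character {ch!r} at line {lineno}"
                        )
                chunks.append(seq)
    flush()
    return records


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>string`` annotation file (ss8 or dot-bracket)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: expected 2 columns at line {lineno}")
            out[parts[0]] = parts[1]
    return out


def write_annotations(path: str | Path, items: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for key, value in items.items():
            fh.write(f"{key}\t{value}\n")


def read_contact_map(path: str | Path, n_residues: int, n_bases: int) -> ContactMap:
    """Read a two-column TSV of 1-based (residue, base) contacts."""
    pairs: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: expected 2 columns at line {lineno}")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise ParseError(f"{path}: non-integer index at line {lineno}")
            if not (1 <= i <= n_residues and 1 <= j <= n_bases):
                raise BoundsError(
                    f"{path}: contact ({i},{j}) at line {lineno} outside "
                    f"{n_residues}x{n_bases} map"
                )
            pairs.add((i, j))
    return ContactMap(n_residues, n_bases, frozenset(pairs))


def write_contact_map(path: str | Path, z: ContactMap) -> None:
    with open(path, "w") as fh:
        for (i, j) in sorted(z.contacts):
            fh.write(f"{i}\t{j}\n")


def read_corpus_contacts(path: str | Path) -> dict[tuple[str, str], set[tuple[int, int]]]:
    """Read a four-column corpus TSV: protein id, RNA id, residue, base."""
    out: dict[tuple[str, str], set[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}: expected 4 columns at line {lineno}")
            try:
                i, j = int(parts[2]), int(parts[3])
            except ValueError:
                raise ParseError(f"{path}: non-integer index at line {lineno}")
            out.setdefault((parts[0], parts[1]), set()).add((i, j))
    return out


def write_corpus_contacts(
    path: str | Path,
    maps: Mapping[tuple[str, str], ContactMap],
) -> None:
    with open(path, "w") as fh:
        for (pid, rid), z in maps.items():
            for (i, j) in sorted(z.contacts):
                fh.write(f"{pid}\t{rid}\t{i}\t{j}\n")


def write_model(path: str | Path, model: ModelWeights) -> None:
    """Write model weights as TSV: feature_type, context(s), weight.

    Exact-zero weights are pruned before writing.
    """
    model.prune()
    with open(path, "w") as fh:
        for (ftype, contexts), w in sorted(model.weights.items()):
            fh.write("\t".join([ftype, *contexts, repr(w)]) + "\n")


def read_model(path: str | Path) -> ModelWeights:
    """Read a TSV model file written by :func:`write_model`."""
    from .features import FEATURE_ARITY, FEATURE_K  # deferred: avoids import cycle

    weights: dict[FeatureKey, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            ftype = parts[0]
            if ftype not in FEATURE_ARITY:
                raise ParseError(
                    f"{path}: unknown feature type {ftype!r} at line {lineno}"
                )
            arity = FEATURE_ARITY[ftype]
            if len(parts) != arity + 2:
                raise ParseError(
                    f"{path}: expected {arity + 2} columns at line {lineno}"
                )
            if any(len(ctx) != FEATURE_K[ftype] for ctx in parts[1:-1]):
                raise ParseError(
                    f"{path}: context length != {FEATURE_K[ftype]} at line {lineno}"
                )
            try:
                w = float(parts[-1])
            except ValueError:
                raise ParseError(f"{path}: non-numeric weight at line {lineno}")
            weights[(ftype, tuple(parts[1:-1]))] = w
    return ModelWeights(weights)
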