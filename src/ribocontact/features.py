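"""Sparse k-mer and structural-profile features and linear scoring.

The score of a contact map z for a pair (P, R) is a linear function
f(P,R,z) = <lambda, Phi(P,R,z)> where Phi concatenates three sparse count
vectors:

* residue features: for every binding residue i (x_i = 1), one count per
  configured residue feature row -- k-mers of the amino-acid sequence
  (k=3,5), of its 10-group and 4-group simplified alphabets (k=5,7), and
  of the 8-state secondary-structure string (k=3,5);
* base features: for every binding base j (y_j = 1), k-mers of the RNA
  sequence and of its 6-state loop profile (k=3,5);
* contact features: for every contact (i,j), paired windows combining a
  residue-side string (sequence, simplified alphabets, secondary
  structure) with a base-side string (sequence, loop profile) at k=3,5.

Windows are centred and padded with a sentinel character so every
position yields a full-length context; this makes the per-variable
scores u_i, v_j, w_ij of the IP objective position-independent
precomputations:

    u_i = <lambda_p, phi_p(P, i)>,  v_j = <lambda_r, phi_r(R, j)>,
    w_ij = <lambda_c, phi_c(P, R, i, j)>,

so that f(P,R,z) = sum_i u_i x_i + sum_j v_j y_j + sum_ij w_ij z_ij for
any map z with indicators x, y derived from it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import ContactMap, FeatureKey, ModelWeights, ProteinRecord, RNARecord

# Simplified amino-acid alphabets (BLOSUM50-derived groupings); each
# letter maps to the first letter of its group.
_G10_GROUPS = ["LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H"]
_G4_GROUPS = ["LVIMC", "AGSTP", "FYW", "EDNQKRH"]


def _group_table(groups: list[str]) -> dict[str, str]:
    table: dict[str, str] = {}
    for g in groups:
        for ch in g:
            table[ch] = g[0]
    return table


_G10 = _group_table(_G10_GROUPS)
_G4 = _group_table(_G4_GROUPS)

PAD_CHAR = "^"

# residue-side derived strings: tag -> how to derive from a ProteinRecord
_RESIDUE_SOURCES = ("seq", "sa10", "sa4", "ss8")
# base-side derived strings
_BASE_SOURCES = ("seq", "profile")

#: unary residue feature rows: (feature-type tag, source string, k)
RESIDUE_ROWS: tuple[tuple[str, str, int], ...] = (
    ("residue-3mer", "seq", 3),
    ("residue-5mer", "seq", 5),
    ("sa10-5mer", "sa10", 5),
    ("sa10-7mer", "sa10", 7),
    ("sa4-5mer", "sa4", 5),
    ("sa4-7mer", "sa4", 7),
    ("protss-3mer", "ss8", 3),
    ("protss-5mer", "ss8", 5),
)

#: unary base feature rows
BASE_ROWS: tuple[tuple[str, str, int], ...] = (
    ("base-3mer", "seq", 3),
    ("base-5mer", "seq", 5),
    ("rnass-3mer", "profile", 3),
    ("rnass-5mer", "profile", 5),
)

#: contact feature rows: (tag, residue source, base source, k) -- paired
#: equal-length windows at k in {3,5} for all six source combinations
CONTACT_ROWS: tuple[tuple[str, str, str, int], ...] = tuple(
    (f"contact:{rtag}{k}x{btag}{k}", rsrc, bsrc, k)
    for (rtag, rsrc) in (("res", "seq"), ("protss", "ss8"),
                         ("sa10", "sa10"), ("sa4", "sa4"))
    for (btag, bsrc) in (("base", "seq"), ("rnass", "profile"))
    for k in (3, 5)
    if not (rtag == "protss" and bsrc == "seq")      # SS pairs with SS only
    if not (rtag == "res" and bsrc == "profile")      # seq pairs with seq
) + tuple()

#: number of context strings each feature type carries (1 or 2)
FEATURE_ARITY: dict[str, int] = {tag: 1 for tag, _, _ in RESIDUE_ROWS}
FEATURE_ARITY.update({tag: 1 for tag, _, _ in BASE_ROWS})
FEATURE_ARITY.update({tag: 2 for tag, _, _, _ in CONTACT_ROWS})

#: declared context length of each feature type
FEATURE_K: dict[str, int] = {tag: k for tag, _, k in RESIDUE_ROWS}
FEATURE_K.update({tag: k for tag, _, k in BASE_ROWS})
FEATURE_K.update({tag: k for tag, _, _, k in CONTACT_ROWS})


@dataclass
class FeatureConfig:
    """The set of feature rows in use and the window pad character."""

    residue_rows: tuple[tuple[str, str, int], ...] = RESIDUE_ROWS
    base_rows: tuple[tuple[str, str, int], ...] = BASE_ROWS
    contact_rows: tuple[tuple[str, str, str, int], ...] = CONTACT_ROWS
    pad_char: str = PAD_CHAR

    def __post_init__(self) -> None:
        ks = [k for *_, k in self.residue_rows]
        ks += [k for *_, k in self.base_rows]
        ks += [k for *_, k in self.contact_rows]
        if any(k % 2 == 0 for k in ks):
            raise ValidationError("window sizes must be odd (centred windows)")
        if len(self.pad_char) != 1:
            raise ValidationError("pad_char must be a single character")

    def to_text(self) -> str:
        """Serialize as key/value text (one row per feature line)."""
        lines = [f"pad_char={self.pad_char}"]
        for tag, src, k in self.residue_rows:
            lines.append(f"residue_row={tag},{src},{k}")
        for tag, src, k in self.base_rows:
            lines.append(f"base_row={tag},{src},{k}")
        for tag, rsrc, bsrc, k in self.contact_rows:
            lines.append(f"contact_row={tag},{rsrc},{bsrc},{k}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FeatureConfig":
        pad = PAD_CHAR
        residue_rows: list[tuple[str, str, int]] = []
        base_rows: list[tuple[str, str, int]] = []
        contact_rows: list[tuple[str, str, str, int]] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if key == "pad_char":
                pad = value
            elif key == "residue_row":
                tag, src, k = value.split(",")
                residue_rows.append((tag, src, int(k)))
            elif key == "base_row":
                tag, src, k = value.split(",")
                base_rows.append((tag, src, int(k)))
            elif key == "contact_row":
                tag, rsrc, bsrc, k = value.split(",")
                contact_rows.append((tag, rsrc, bsrc, int(k)))
            else:
                raise ValidationError(f"unknown config key {key!r} at line {lineno}")
        return cls(
            residue_rows=tuple(residue_rows),
            base_rows=tuple(base_rows),
            contact_rows=tuple(contact_rows),
            pad_char=pad,
        )


DEFAULT_CONFIG = FeatureConfig()


def window(s: str, center: int, k: int, pad: str = PAD_CHAR) -> str:
    """The length-k substring of ``s`` centred at 1-based ``center``,
    padded with ``pad`` outside the string."""
    if k % 2 == 0:
        raise ValidationError(f"window size must be odd, got {k}")
    if not (1 <= center <= len(s)):
        raise ValidationError(f"center {center} outside string of length {len(s)}")
    half = (k - 1) // 2
    out = []
    for pos in range(center - half, center + half + 1):
        out.append(s[pos - 1] if 1 <= pos <= len(s) else pad)
    return "".join(out)


def simplify(s: str, scheme: str) -> str:
    """Map an amino-acid string onto a simplified alphabet ('g10' or 'g4')."""
    table = {"g10": _G10, "g4": _G4}.get(scheme)
    if table is None:
        raise ValidationError(f"unknown simplification scheme {scheme!r}")
    try:
        return "".join(table[ch] for ch in s)
    except KeyError as exc:
        raise ValidationError(f"illegal amino-acid letter {exc.args[0]!r}")


def residue_strings(p: ProteinRecord) -> dict[str, str]:
    return {
        "seq": p.sequence,
        "sa10": simplify(p.sequence, "g10"),
        "sa4": simplify(p.sequence, "g4"),
        "ss8": p.ss8,
    }


def base_strings(r: RNARecord) -> dict[str, str]:
    return {"seq": r.sequence, "profile": r.profile}


SparseFeatureVector = Counter  # FeatureKey -> count


def residue_features(
    p: ProteinRecord, x: np.ndarray, config: FeatureConfig = DEFAULT_CONFIG
) -> Counter:
    """Counts of residue features over all binding residues (x_i = 1)."""
    if len(x) != len(p):
        raise ValidationError("indicator length does not match protein length")
    strings = residue_strings(p)
    counts: Counter = Counter()
    for i in range(1, len(p) + 1):
        if not x[i - 1]:
            continue
        for tag, src, k in config.residue_rows:
            counts[(tag, (window(strings[src], i, k, config.pad_char),))] += 1
    return counts


def base_features(
    r: RNARecord, y: np.ndarray, config: FeatureConfig = DEFAULT_CONFIG
) -> Counter:
    """Counts of base features over all binding bases (y_j = 1)."""
    if len(y) != len(r):
        raise ValidationError("indicator length does not match RNA length")
    strings = base_strings(r)
    counts: Counter = Counter()
    for j in range(1, len(r) + 1):
        if not y[j - 1]:
            continue
        for tag, src, k in config.base_rows:
            counts[(tag, (window(strings[src], j, k, config.pad_char),))] += 1
    return counts


def contact_features(
    p: ProteinRecord,
    r: RNARecord,
    z: ContactMap,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> Counter:
    """Counts of paired-window contact features over all contacts of z."""
    rstr = residue_strings(p)
    bstr = base_strings(r)
    counts: Counter = Counter()
    for (i, j) in z.contacts:
        for tag, rsrc, bsrc, k in config.contact_rows:
            key: FeatureKey = (
                tag,
                (window(rstr[rsrc], i, k, config.pad_char),
                 window(bstr[bsrc], j, k, config.pad_char)),
            )
            counts[key] += 1
    return counts


def full_features(
    p: ProteinRecord,
    r: RNARecord,
    z: ContactMap,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> Counter:
    """Phi(P,R,z): residue, base and contact counts (disjoint key spaces)."""
    x, y = z.indicators()
    counts = residue_features(p, x, config)
    counts.update(base_features(r, y, config))
    counts.update(contact_features(p, r, z, config))
    return counts


def score(
    p: ProteinRecord,
    r: RNARecord,
    z: ContactMap,
    model: ModelWeights,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float:
    """Linear score <lambda, Phi(P,R,z)>; absent keys contribute 0."""
    return float(
        sum(model.get(key) * count for key, count in full_features(p, r, z, config).items())
    )


@dataclass
class ScoreTerms:
    """Per-variable scores of the IP objective.

    u[i-1], v[j-1] and w[i-1, j-1] are the gains of setting x_i, y_j and
    z_ij; ``offset`` is a constant added to the objective (zero in plain
    decoding, the constant part of the loss in loss-augmented decoding).
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.u), len(self.v)):
            raise ValidationError("w shape does not match u, v lengths")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))
                and np.all(np.isfinite(self.w))):
            raise ValidationError("score terms must be finite")

    def objective(self, z: ContactMap) -> float:
        """Evaluate the linear objective at a contact map (x, y derived)."""
        x, y = z.indicators()
        total = float(self.u @ x + self.v @ y)
        for (i, j) in z.contacts:
            total += float(self.w[i - 1, j - 1])
        return total + self.offset


def score_terms(
    p: ProteinRecord,
    r: RNARecord,
    model: ModelWeights,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> ScoreTerms:
    """Precompute u, v, w for a pair under a model (offset 0)."""
    rstr = residue_strings(p)
    bstr = base_strings(r)
    np_, nr = len(p), len(r)

    u = np.zeros(np_)
    for i in range(1, np_ + 1):
        for tag, src, k in config.residue_rows:
            u[i - 1] += model.get((tag, (window(rstr[src], i, k, config.pad_char),)))

    v = np.zeros(nr)
    for j in range(1, nr + 1):
        for tag, src, k in config.base_rows:
            v[j - 1] += model.get((tag, (window(bstr[src], j, k, config.pad_char),)))

    # cache per-position windows for each contact row to avoid recomputing
    w = np.zeros((np_, nr))
    for tag, rsrc, bsrc, k in config.contact_rows:
        rwin = [window(rstr[rsrc], i, k, config.pad_char) for i in range(1, np_ + 1)]
        bwin = [window(bstr[bsrc], j, k, config.pad_char) for j in range(1, nr + 1)]
        for i in range(np_):
            for j in range(nr):
                w[i, j] += model.get((tag, (rwin[i], bwin[j])))
    return ScoreTerms(u=u, v=v, w=w, offset=0.0)
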