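"""RNA loop-context profiles and protein secondary-structure validation.

An RNA secondary structure in dot-bracket notation is converted into a
per-base *structural profile* over six states: every paired base is a
stack (S), and every unpaired base is labelled by the kind of loop that
contains it -- external (E), hairpin (H), internal (I), bulge (B) or
multibranch (M).  This is the standard loop taxonomy: a loop is the set
of unpaired positions and inner ("child") helices directly enclosed by
one closing base pair, and its kind is determined by how many child
pairs it has and where its unpaired bases sit relative to them.

Protein secondary structure uses the 8-state alphabet
H, G, I, E, B, T, S, '-' (helices, strand, turn, bend, coil, loop).

Pseudoknotted structures (crossing pairs) are outside the model; only
the characters ``(``, ``)`` and ``.`` are accepted, which makes every
parsable structure non-crossing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError, ValidationError

SS8_ALPHABET = frozenset("HGIEBTS-")
PROFILE_ALPHABET = "EHIBMS"


def parse_dotbracket(s: str) -> frozenset[tuple[int, int]]:
    """Return the set of base pairs (1-based, i<j) of a dot-bracket string.

    Raises :class:`ParseError` on illegal characters or unbalanced
    parentheses, naming the offending 1-based position.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ParseError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise ParseError(f"unmatched '(' at position {stack[-1]}")
    return frozenset(pairs)


@dataclass
class Loop:
    """One loop: its closing pair (None for the exterior), the inner
    (child) pairs it directly encloses, and its unpaired positions."""

    closing: tuple[int, int] | None
    inner_pairs: list[tuple[int, int]] = field(default_factory=list)
    unpaired: list[int] = field(default_factory=list)


@dataclass
class LoopDecomposition:
    """Full decomposition of a structure into pairs and loops."""

    pairs: frozenset[tuple[int, int]]
    loops: list[Loop]


def decompose(s: str) -> LoopDecomposition:
    """Decompose a dot-bracket string into its loops.

    Every position belongs either to some pair or to exactly one loop.
    """
    pairs = parse_dotbracket(s)
    open_at = {i: j for i, j in pairs}
    loops: list[Loop] = []

    def walk(closing: tuple[int, int] | None, lo: int, hi: int) -> None:
        # scan positions lo..hi at this nesting level
        loop = Loop(closing=closing)
        pos = lo
        while pos <= hi:
            if pos in open_at:
                j = open_at[pos]
                loop.inner_pairs.append((pos, j))
                walk((pos, j), pos + 1, j - 1)
                pos = j + 1
            else:
                loop.unpaired.append(pos)
                pos += 1
        # a helix continuation (one child pair, no unpaired bases) is not
        # a loop in its own right but is kept: it labels nothing
        loops.append(loop)

    walk(None, 1, len(s))
    return LoopDecomposition(pairs=pairs, loops=loops)


def _classify(loop: Loop) -> str:
    if loop.closing is None:
        return "E"
    n_inner = len(loop.inner_pairs)
    if n_inner == 0:
        return "H"
    if n_inner >= 2:
        return "M"
    # one inner pair: bulge vs internal loop, decided by whether the
    # 5' gap and the 3' gap around the inner pair are both non-empty
    (a, b) = loop.closing
    (c, d) = loop.inner_pairs[0]
    five_prime = any(a < q < c for q in loop.unpaired)
    three_prime = any(d < q < b for q in loop.unpaired)
    if five_prime and three_prime:
        return "I"
    return "B"


def rna_profile(s: str) -> str:
    """Map a dot-bracket string to its 6-state structural profile.

    Paired positions become S; each unpaired position takes the label of
    the loop enclosing it (E/H/I/B/M).
    """
    decomp = decompose(s)
    out = ["S"] * len(s)
    for loop in decomp.loops:
        if not loop.unpaired:
            continue
        label = _classify(loop)
        for q in loop.unpaired:
            out[q - 1] = label
    return "".join(out)


def validate_ss8(s: str) -> str:
    """Validate an 8-state protein secondary-structure string."""
    for pos, ch in enumerate(s, start=1):
        if ch not in SS8_ALPHABET:
            raise ValidationError(
                f"illegal secondary-structure character {ch!r} at position {pos}"
            )
    return s
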