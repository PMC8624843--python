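"""Three-level evaluation of predicted contact maps.

Accuracy is reported at three levels: individual residue--base contacts,
binding residues (rows of the map) and binding bases (columns), each by
positive predictive value PPV = TP/(TP+FP), sensitivity SEN = TP/(TP+FN)
and their harmonic mean F.  A metric whose denominator is zero is
reported as 0 and flagged undefined.

Datasets aggregate either macro (mean of per-pair metrics, pairs with no
positives on either side excluded per level) or micro (metrics of the
pooled counts); macro is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import ValidationError
from .io import ContactMap

LEVELS = ("contact", "residue", "base")


@dataclass(frozen=True)
class LevelCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "LevelCounts") -> "LevelCounts":
        return LevelCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class ConfusionCounts:
    contact: LevelCounts
    residue: LevelCounts
    base: LevelCounts

    def level(self, name: str) -> LevelCounts:
        return getattr(self, name)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.contact + other.contact,
            self.residue + other.residue,
            self.base + other.base,
        )


@dataclass(frozen=True)
class Metrics:
    ppv: float
    sen: float
    f: float
    ppv_defined: bool = True
    sen_defined: bool = True
    f_defined: bool = True


def confusion(z_true: ContactMap, z_pred: ContactMap) -> ConfusionCounts:
    """Count TP/FP/FN at contact, binding-residue and binding-base level."""
    if (z_true.n_residues, z_true.n_bases) != (z_pred.n_residues, z_pred.n_bases):
        raise ValidationError("contact map dimensions differ")
    ct = LevelCounts(
        tp=len(z_true.contacts & z_pred.contacts),
        fp=len(z_pred.contacts - z_true.contacts),
        fn=len(z_true.contacts - z_pred.contacts),
    )
    xt, yt = z_true.indicators()
    xp, yp = z_pred.indicators()
    res = LevelCounts(
        tp=int(((xt == 1) & (xp == 1)).sum()),
        fp=int(((xt == 0) & (xp == 1)).sum()),
        fn=int(((xt == 1) & (xp == 0)).sum()),
    )
    base = LevelCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )
    return ConfusionCounts(contact=ct, residue=res, base=base)


def ppv_sen_f(counts: LevelCounts) -> Metrics:
    """PPV, SEN and F of one count triple; zero denominators yield 0,
    flagged undefined."""
    ppv_def = counts.tp + counts.fp > 0
    sen_def = counts.tp + counts.fn > 0
    ppv = counts.tp / (counts.tp + counts.fp) if ppv_def else 0.0
    sen = counts.tp / (counts.tp + counts.fn) if sen_def else 0.0
    f_def = ppv_def and sen_def and (ppv + sen) > 0
    f = 2 * ppv * sen / (ppv + sen) if f_def else 0.0
    # F is undefined when either component is, or both are 0
    return Metrics(ppv, sen, f, ppv_def, sen_def, ppv_def and sen_def)


def evaluate_dataset(
    pairs: Iterable[tuple[ContactMap, ContactMap]], mode: str = "macro"
) -> dict[str, Metrics]:
    """Aggregate metrics over (true, predicted) map pairs, per level.

    macro: average of per-pair metrics, excluding at each level the
    pairs with tp=fp=fn=0 there; micro: metrics of summed counts.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("cannot evaluate an empty dataset")
    if mode not in ("macro", "micro"):
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    all_counts = [confusion(t, p) for t, p in pairs]
    out: dict[str, Metrics] = {}
    for level in LEVELS:
        if mode == "micro":
            pooled = LevelCounts()
            for c in all_counts:
                pooled = pooled + c.level(level)
            out[level] = ppv_sen_f(pooled)
        else:
            per_pair = [
                ppv_sen_f(c.level(level))
                for c in all_counts
                if (c.level(level).tp + c.level(level).fp + c.level(level).fn) > 0
            ]
            if not per_pair:
                out[level] = Metrics(0.0, 0.0, 0.0, False, False, False)
                continue
            n = len(per_pair)
            out[level] = Metrics(
                ppv=sum(m.ppv for m in per_pair) / n,
                sen=sum(m.sen for m in per_pair) / n,
                f=sum(m.f for m in per_pair) / n,
            )
    return out


def write_metrics_tsv(
    path: str | Path, metrics: dict[str, Metrics], n_pairs: int, mode: str
) -> None:
    """Emit metrics as TSV: level, ppv, sen, f, n_pairs, mode."""
    with open(path, "w") as fh:
        fh.write("level\tppv\tsen\tf\tn_pairs\tmode\n")
        for level in LEVELS:
            m = metrics[level]
            fh.write(
                f"{level}\t{m.ppv:.6f}\t{m.sen:.6f}\t{m.f:.6f}\t{n_pairs}\t{mode}\n"
            )
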