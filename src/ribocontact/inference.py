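"""Contact-map decoding by integer programming, with an exhaustive oracle.

The decoder maximises

    sum_i u_i x_i + sum_j v_j y_j + sum_ij w_ij z_ij  (+ offset)

over binary x, y, z subject to consistency constraints:

* x_i + y_j >= 2 z_ij              (a contact implies both binding sites)
* x_i <= sum_j z_ij                (a binding residue has some contact)
* y_j <= sum_i z_ij                (a binding base has some contact)
* y_{j-1} + (1 - y_j) + y_{j+1} >= 1   (no isolated binding base;
  out-of-range neighbour terms are 0, so a bound terminal base needs its
  single inward neighbour bound, and a length-1 RNA can never bind)
* sum_j z_ij <= X_i,  sum_i z_ij <= Y_j  (per-residue / per-base caps)

The backend is an exact 0/1 branch-and-cut solver (HiGHS via
scipy.optimize.milp).  ``predict_bruteforce`` enumerates every contact
map on small instances and serves as an independent oracle; the two
must agree in objective value (contact sets may differ among co-optimal
solutions; the oracle breaks ties by lexicographically smallest set).

Loss-augmented decoding shifts each score by the per-variable loss
terms so that the same solver maximises f(z_hat) + Delta(z, z_hat),
which is what structured-SVM training needs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, milp

from .errors import SolverError, ValidationError
from .io import ContactMap, Hyperparameters
from .features import ScoreTerms

_BRUTE_LIMIT = 20  # max |P|*|R| for exhaustive enumeration

KNOWN_SOLVERS = ("highs",)


@dataclass
class InferenceProblem:
    """Score terms plus per-residue (X) and per-base (Y) contact caps;
    ``None`` means unbounded."""

    terms: ScoreTerms
    x_cap: int | None = 8
    y_cap: int | None = 8

    def __post_init__(self) -> None:
        for cap in (self.x_cap, self.y_cap):
            if cap is not None and cap < 1:
                raise ValidationError("caps must be >= 1 or None")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.terms.u), len(self.terms.v))


def predict_ip(
    problem: InferenceProblem, solver: str = "highs"
) -> tuple[ContactMap, float]:
    """Solve the decoding IP exactly; returns (map, objective).

    The returned indicators are re-derived from z, and the objective is
    evaluated on the returned map (including the offset).
    """
    if solver not in KNOWN_SOLVERS:
        raise SolverError(f"unknown solver {solver!r}; available: {KNOWN_SOLVERS}")
    terms = problem.terms
    P, R = problem.shape
    n = P + R + P * R  # variables: x (P), y (R), z (P*R, row-major)

    def zvar(i: int, j: int) -> int:  # 0-based i, j
        return P + R + i * R + j

    c = np.concatenate([terms.u, terms.v, terms.w.ravel()])

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    nrow = 0

    def add_row(entries: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal nrow
        for col, val in entries:
            rows.append(nrow)
            cols.append(col)
            vals.append(val)
        lb.append(lo)
        ub.append(hi)
        nrow += 1

    inf = np.inf
    for i in range(P):
        for j in range(R):
            # x_i + y_j - 2 z_ij >= 0
            add_row([(i, 1.0), (P + j, 1.0), (zvar(i, j), -2.0)], 0.0, inf)
    for i in range(P):
        # x_i - sum_j z_ij <= 0
        add_row([(i, 1.0)] + [(zvar(i, j), -1.0) for j in range(R)], -inf, 0.0)
    for j in range(R):
        # y_j - sum_i z_ij <= 0
        add_row([(P + j, 1.0)] + [(zvar(i, j), -1.0) for i in range(P)], -inf, 0.0)
    for j in range(R):
        # y_{j-1} - y_j + y_{j+1} >= 0, out-of-range terms absent
        entries = [(P + j, -1.0)]
        if j - 1 >= 0:
            entries.append((P + j - 1, 1.0))
        if j + 1 < R:
            entries.append((P + j + 1, 1.0))
        add_row(entries, 0.0, inf)
    if problem.x_cap is not None:
        for i in range(P):
            add_row([(zvar(i, j), 1.0) for j in range(R)], -inf, float(problem.x_cap))
    if problem.y_cap is not None:
        for j in range(R):
            add_row([(zvar(i, j), 1.0) for i in range(P)], -inf, float(problem.y_cap))

    A = sp.csr_matrix((vals, (rows, cols)), shape=(nrow, n))
    res = milp(
        c=-c,  # milp minimises
        constraints=LinearConstraint(A, np.array(lb), np.array(ub)),
        integrality=np.ones(n),
        bounds=(0, 1),
        options={"mip_rel_gap": 0.0},  # prove optimality, no early gap stop
    )
    if res.status != 0 or res.x is None:
        raise SolverError(f"IP solver failed: status {res.status} ({res.message})")

    zsol = res.x[P + R:].reshape(P, R) > 0.5
    contacts = frozenset(
        (i + 1, j + 1) for i in range(P) for j in range(R) if zsol[i, j]
    )
    zmap = ContactMap(P, R, contacts)
    return zmap, terms.objective(zmap)


def predict_bruteforce(problem: InferenceProblem) -> tuple[ContactMap, float]:
    """Exhaustively enumerate all 2^(|P||R|) maps; independent oracle.

    Keeps feasible maps only (the indicator-consistency constraints hold
    by derivation) and returns the maximiser, breaking ties by the
    lexicographically smallest sorted contact set.
    """
    terms = problem.terms
    P, R = problem.shape
    ncell = P * R
    if ncell > _BRUTE_LIMIT:
        raise ValidationError(
            f"instance too large for enumeration: {P}x{R} > {_BRUTE_LIMIT} cells"
        )
    m = 1 << ncell
    # bit b of pattern p is cell (b // R, b % R)
    patterns = np.arange(m, dtype=np.int64)
    z = ((patterns[:, None] >> np.arange(ncell)) & 1).astype(np.int8)
    z = z.reshape(m, P, R)
    x = z.any(axis=2)
    y = z.any(axis=1)

    feasible = np.ones(m, dtype=bool)
    for j in range(R):
        left = y[:, j - 1] if j - 1 >= 0 else np.zeros(m, dtype=bool)
        right = y[:, j + 1] if j + 1 < R else np.zeros(m, dtype=bool)
        feasible &= ~(y[:, j] & ~left & ~right)  # no isolated binding base
    if problem.x_cap is not None:
        feasible &= (z.sum(axis=2) <= problem.x_cap).all(axis=1)
    if problem.y_cap is not None:
        feasible &= (z.sum(axis=1) <= problem.y_cap).all(axis=1)

    obj = (
        x @ terms.u + y @ terms.v + z.reshape(m, ncell) @ terms.w.ravel()
    ) + terms.offset
    obj[~feasible] = -np.inf
    best = obj.max()

    def contact_set(pattern: int) -> tuple[tuple[int, int], ...]:
        return tuple(
            sorted((b // R + 1, b % R + 1) for b in range(ncell) if (pattern >> b) & 1)
        )

    candidates = np.flatnonzero(obj == best)
    winner = min(contact_set(int(p)) for p in candidates)
    zmap = ContactMap(P, R, frozenset(winner))
    return zmap, float(best)


def check_constraints(z: ContactMap, x_cap: int | None, y_cap: int | None) -> bool:
    """True iff a map satisfies the no-isolated-base and cap constraints
    (the indicator constraints hold by derivation)."""
    zm = z.dense()
    x, y = z.indicators()
    for j in range(z.n_bases):
        left = y[j - 1] if j - 1 >= 0 else 0
        right = y[j + 1] if j + 1 < z.n_bases else 0
        if y[j] and not left and not right:
            return False
    if x_cap is not None and (zm.sum(axis=1) > x_cap).any():
        return False
    if y_cap is not None and (zm.sum(axis=0) > y_cap).any():
        return False
    return True


def enumerate_feasible(
    shape: tuple[int, int], x_cap: int | None, y_cap: int | None
) -> list[ContactMap]:
    """All feasible contact maps on a small instance (test helper)."""
    P, R = shape
    if P * R > _BRUTE_LIMIT:
        raise ValidationError("instance too large for enumeration")
    cells = list(itertools.product(range(1, P + 1), range(1, R + 1)))
    out = []
    for mask in range(1 << len(cells)):
        zmap = ContactMap(
            P, R, frozenset(c for b, c in enumerate(cells) if (mask >> b) & 1)
        )
        if check_constraints(zmap, x_cap, y_cap):
            out.append(zmap)
    return out


def loss(z_true: ContactMap, z_pred: ContactMap, h: Hyperparameters) -> float:
    """Weighted Hamming-style loss Delta(z, z_hat).

    Counts false-negative / false-positive binding residues, binding
    bases and contacts (indicators derived on both sides), each weighted
    by its penalty.
    """
    if (z_true.n_residues, z_true.n_bases) != (z_pred.n_residues, z_pred.n_bases):
        raise ValidationError("contact map dimensions differ")
    xt, yt = z_true.indicators()
    xp, yp = z_pred.indicators()
    fn_res = int(((xt == 1) & (xp == 0)).sum())
    fp_res = int(((xt == 0) & (xp == 1)).sum())
    fn_base = int(((yt == 1) & (yp == 0)).sum())
    fp_base = int(((yt == 0) & (yp == 1)).sum())
    fn_con = len(z_true.contacts - z_pred.contacts)
    fp_con = len(z_pred.contacts - z_true.contacts)
    return (
        h.delta_fn_residue * fn_res
        + h.delta_fp_residue * fp_res
        + h.delta_fn_base * fn_base
        + h.delta_fp_base * fp_base
        + h.delta_fn_contact * fn_con
        + h.delta_fp_contact * fp_con
    )


def loss_augment(
    terms: ScoreTerms, z_true: ContactMap, h: Hyperparameters
) -> ScoreTerms:
    """Shift scores so the augmented objective of any map z_hat equals
    f(z_hat) + Delta(z_true, z_hat).

    Each variable's score moves by -delta_FN where the true variable is 1
    (a zero prediction there forfeits the FN penalty carried in the
    constant offset) and by +delta_FP where it is 0.
    """
    P, R = len(terms.u), len(terms.v)
    if (z_true.n_residues, z_true.n_bases) != (P, R):
        raise ValidationError("true map dimensions do not match score terms")
    x, y = z_true.indicators()
    u = terms.u + np.where(x == 1, -h.delta_fn_residue, h.delta_fp_residue)
    v = terms.v + np.where(y == 1, -h.delta_fn_base, h.delta_fp_base)
    w = terms.w + h.delta_fp_contact
    for (i, j) in z_true.contacts:
        w[i - 1, j - 1] = terms.w[i - 1, j - 1] - h.delta_fn_contact
    offset = (
        terms.offset
        + h.delta_fn_residue * int(x.sum())
        + h.delta_fn_base * int(y.sum())
        + h.delta_fn_contact * len(z_true.contacts)
    )
    return ScoreTerms(u=u, v=v, w=w, offset=offset)
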