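"""Structured-SVM training by stochastic subgradient descent.

The trained objective is the structured hinge with l1 regularization:

    L(lambda) = sum_{(P,R,z) in D} [ max_zhat ( f(zhat) + Delta(z, zhat) )
                                     - f(z) ]  +  C ||lambda||_1 .

The inner max is computed exactly by loss-augmented IP decoding, so the
per-instance subgradient in the weight of feature k is
phi_k(zhat) - phi_k(z) plus C sgn(lambda_k).  Steps are scaled per key
by AdaGrad: lambda_k <- lambda_k - eta / sqrt(G_k + eps) * g_k with G_k
the running sum of squared subgradients.  The l1 subgradient (sgn(0)=0)
is applied lazily, to keys touched by the current instance only; an
exact dense l1 step over the unbounded key space is not defined for a
sparse model.

Training visits instances in a per-epoch shuffled order drawn from the
given seed, so a run is bit-for-bit reproducible.  It stops when the
largest per-epoch weight change drops below ``tol`` or after
``max_epochs`` epochs; exact-zero weights are pruned from the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .features import FeatureConfig, DEFAULT_CONFIG, full_features, score_terms
from .inference import (
    InferenceProblem,
    check_constraints,
    loss_augment,
    predict_ip,
)
from .io import ContactMap, FeatureKey, Hyperparameters, ModelWeights, ProteinRecord, RNARecord


@dataclass
class TrainingInstance:
    """One labelled protein--RNA pair."""

    protein: ProteinRecord
    rna: RNARecord
    z_true: ContactMap

    def __post_init__(self) -> None:
        if (self.z_true.n_residues, self.z_true.n_bases) != (
            len(self.protein),
            len(self.rna),
        ):
            raise DataError(
                f"instance {self.protein.id}/{self.rna.id}: contact map "
                "dimensions do not match sequences"
            )


@dataclass
class TrainState:
    """Mutable optimiser state: weights, AdaGrad accumulator, history."""

    weights: dict[FeatureKey, float] = field(default_factory=dict)
    grad_sq_accum: dict[FeatureKey, float] = field(default_factory=dict)
    epoch: int = 0
    objective_history: list[float] = field(default_factory=list)


def adagrad_step(
    key: FeatureKey, grad: float, state: TrainState, h: Hyperparameters
) -> None:
    """One AdaGrad update of a single weight; grad=0 leaves it untouched."""
    if grad == 0.0:
        return
    g2 = state.grad_sq_accum.get(key, 0.0) + grad * grad
    state.grad_sq_accum[key] = g2
    step = h.eta / math.sqrt(g2 + h.epsilon)
    state.weights[key] = state.weights.get(key, 0.0) - step * grad


def objective(
    data: list[TrainingInstance],
    model: ModelWeights,
    h: Hyperparameters,
    config: FeatureConfig = DEFAULT_CONFIG,
    solver: str = "highs",
    relax_caps_in_augment: bool = False,
) -> float:
    """The regularized structured hinge objective L(lambda).

    ``relax_caps_in_augment`` drops the contact caps during the inner
    max only, for gold maps that exceed them.
    """
    x_cap = None if relax_caps_in_augment else h.X_cap
    y_cap = None if relax_caps_in_augment else h.Y_cap
    total = h.C * model.l1_norm()
    for inst in data:
        terms = score_terms(inst.protein, inst.rna, model, config)
        aug = loss_augment(terms, inst.z_true, h)
        _, aug_opt = predict_ip(InferenceProblem(aug, x_cap, y_cap), solver=solver)
        total += aug_opt - terms.objective(inst.z_true)
    return float(total)


def _validate_feasible(data: list[TrainingInstance], h: Hyperparameters) -> None:
    for inst in data:
        if not check_constraints(inst.z_true, h.X_cap, h.Y_cap):
            raise DataError(
                f"instance {inst.protein.id}/{inst.rna.id}: true contact map "
                "violates the decoding constraints (isolated binding base or "
                "cap exceeded)"
            )


def train(
    data: list[TrainingInstance],
    h: Hyperparameters | None = None,
    seed: int = 0,
    config: FeatureConfig = DEFAULT_CONFIG,
    solver: str = "highs",
    shuffle: bool = True,
    track_objective: bool = True,
    relax_caps_in_augment: bool = False,
    state: TrainState | None = None,
) -> tuple[ModelWeights, TrainState]:
    """Train model weights on labelled pairs; deterministic given seed.

    Returns the pruned weights and the final optimiser state (whose
    ``objective_history`` holds the true objective at the end of each
    epoch when ``track_objective`` is on).  ``relax_caps_in_augment``
    drops the contact caps inside the loss-augmented max, allowing gold
    maps that exceed them (the no-isolated-base constraint still holds).
    """
    if not data:
        raise DataError("training dataset is empty")
    h = h if h is not None else Hyperparameters()
    aug_x_cap = None if relax_caps_in_augment else h.X_cap
    aug_y_cap = None if relax_caps_in_augment else h.Y_cap
    _validate_feasible(data, Hyperparameters(X_cap=aug_x_cap, Y_cap=aug_y_cap))
    state = state if state is not None else TrainState()
    rng = np.random.default_rng(seed)

    # Phi(z_true) is constant per instance
    true_counts = [
        full_features(inst.protein, inst.rna, inst.z_true, config) for inst in data
    ]

    for _ in range(h.max_epochs):
        before = dict(state.weights)
        order = np.arange(len(data))
        if shuffle:
            rng.shuffle(order)
        for idx in order:
            inst = data[idx]
            model = ModelWeights(dict(state.weights))
            terms = score_terms(inst.protein, inst.rna, model, config)
            aug = loss_augment(terms, inst.z_true, h)
            z_hat, _ = predict_ip(
                InferenceProblem(aug, aug_x_cap, aug_y_cap), solver=solver
            )
            pred_counts = full_features(inst.protein, inst.rna, z_hat, config)
            touched = set(pred_counts) | set(true_counts[idx])
            for key in touched:
                lam = state.weights.get(key, 0.0)
                sgn = (lam > 0) - (lam < 0)
                grad = (
                    pred_counts.get(key, 0)
                    - true_counts[idx].get(key, 0)
                    + h.C * sgn
                )
                adagrad_step(key, grad, state, h)
        state.epoch += 1
        if track_objective:
            state.objective_history.append(
                objective(
                    data, ModelWeights(dict(state.weights)), h, config, solver,
                    relax_caps_in_augment,
                )
            )
        delta = max(
            (
                abs(state.weights.get(k, 0.0) - before.get(k, 0.0))
                for k in set(state.weights) | set(before)
            ),
            default=0.0,
        )
        if delta < h.tol:
            break

    final = ModelWeights(dict(state.weights))
    final.prune()
    return final, state
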