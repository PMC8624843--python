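"""Structured-SVM training: AdaGrad algebra, subgradients, convergence."""

import math

import numpy as np
import pytest

from ribocontact import (
    ContactMap,
    DataError,
    Hyperparameters,
    ModelWeights,
    ProteinRecord,
    RNARecord,
    adagrad_step,
    objective,
    train,
)
from ribocontact.features import full_features, score_terms
from ribocontact.inference import InferenceProblem, loss_augment, predict_ip
from ribocontact.learning import TrainState, TrainingInstance  # noqa: F401


def _tiny_instance(contacts=frozenset()):
    p = ProteinRecord("p", "MKVA", "HHEE")
    r = RNARecord.from_dotbracket("r", "ACGUA", ".....")
    return TrainingInstance(p, r, ContactMap(4, 5, frozenset(contacts)))


class TestAdagradStep:
    def test_zero_grad_is_noop(self):
        state = TrainState(weights={("residue-3mer", ("MKV",)): 1.0})
        adagrad_step(("residue-3mer", ("MKV",)), 0.0, state, Hyperparameters())
        assert state.weights[("residue-3mer", ("MKV",))] == 1.0
        assert state.grad_sq_accum == {}

    def test_first_step_magnitude(self):
        # first update: |step| = eta * |g| / sqrt(g^2 + eps) ~ eta
        h = Hyperparameters(eta=1.0, epsilon=1e-12)
        state = TrainState()
        adagrad_step(("base-3mer", ("ACG",)), 3.0, state, h)
        assert state.weights[("base-3mer", ("ACG",))] == pytest.approx(-1.0, abs=1e-9)

    def test_repeated_grads_shrink_by_sqrt2(self):
        h = Hyperparameters(eta=1.0, epsilon=0.0)
        state = TrainState()
        key = ("base-3mer", ("ACG",))
        adagrad_step(key, 2.0, state, h)
        first = state.weights[key]
        adagrad_step(key, 2.0, state, h)
        second = state.weights[key] - first
        assert second == pytest.approx(first / math.sqrt(2))


class TestObjective:
    def test_empty_dataset_is_pure_regularizer(self):
        model = ModelWeights({("residue-3mer", ("MKV",)): 2.0,
                              ("base-3mer", ("ACG",)): -1.0})
        h = Hyperparameters(C=0.5)
        assert objective([], model, h) == pytest.approx(0.5 * 3.0)

    def test_nonnegative_at_zero_weights(self):
        inst = _tiny_instance()
        h = Hyperparameters()
        value = objective([inst], ModelWeights({}), h)
        # the hinge max includes z_hat = z_true, so the term is >= 0
        assert value >= 0.0

    def test_zero_weights_value_is_max_loss_over_feasible(self):
        """With lambda=0, f vanishes and the objective equals the largest
        attainable loss against the (empty) truth."""
        from ribocontact.inference import enumerate_feasible, loss as loss_fn

        h = Hyperparameters()
        small = TrainingInstance(
            ProteinRecord("p", "MK", "HH"),
            RNARecord.from_dotbracket("r", "ACG", "..."),
            ContactMap(2, 3, frozenset()),
        )
        expected = max(
            loss_fn(small.z_true, zh, h)
            for zh in enumerate_feasible((2, 3), h.X_cap, h.Y_cap)
        )
        assert objective([small], ModelWeights({}), h) == pytest.approx(expected)


class TestSubgradient:
    def test_matches_finite_difference(self):
        """Phi(z_hat) - Phi(z_true) is the exact subgradient of the hinge
        term: directional finite differences of the (unregularized)
        objective agree along random directions."""
        rng = np.random.default_rng(21)
        inst = _tiny_instance({(2, 2), (2, 3)})
        h = Hyperparameters(C=0.0)
        keys = sorted(full_features(inst.protein, inst.rna,
                                    ContactMap(4, 5, frozenset(
                                        {(i, j) for i in range(1, 5) for j in range(1, 6)}
                                    ))))
        lam = {k: float(rng.normal(scale=0.3)) for k in keys}
        model = ModelWeights(dict(lam))

        terms = score_terms(inst.protein, inst.rna, model)
        aug = loss_augment(terms, inst.z_true, h)
        z_hat, _ = predict_ip(InferenceProblem(aug, h.X_cap, h.Y_cap))
        g = full_features(inst.protein, inst.rna, z_hat)
        g.subtract(full_features(inst.protein, inst.rna, inst.z_true))

        eps = 1e-6
        for _ in range(3):
            direction = {k: float(rng.normal()) for k in keys}
            shifted = ModelWeights(
                {k: lam.get(k, 0.0) + eps * direction[k] for k in keys}
            )
            fd = (objective([inst], shifted, h) - objective([inst], model, h)) / eps
            analytic = sum(g.get(k, 0) * direction[k] for k in keys)
            assert fd == pytest.approx(analytic, abs=1e-3)


class TestTrain:
    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train([], Hyperparameters(), seed=0)

    def test_infeasible_truth_rejected(self):
        # base 3 bound alone between unbound neighbours: isolated
        inst = _tiny_instance({(1, 3)})
        with pytest.raises(DataError, match="isolated"):
            train([inst], Hyperparameters(), seed=0)

    def test_cap_violating_truth_rejected(self):
        contacts = {(1, j) for j in range(1, 6)}
        inst = _tiny_instance(contacts)
        with pytest.raises(DataError):
            train([inst], Hyperparameters(X_cap=2), seed=0)

    def test_relaxed_augment_caps_accept_overfull_truth(self):
        """With caps relaxed inside the loss-augmented max, a gold map
        exceeding the caps is trainable instead of rejected."""
        contacts = {(1, j) for j in range(1, 6)}
        inst = _tiny_instance(contacts)
        h = Hyperparameters(X_cap=2, max_epochs=2)
        model, state = train(
            [inst], h, seed=0, relax_caps_in_augment=True, track_objective=True
        )
        assert len(model) > 0 and len(state.objective_history) == 2

    def test_deterministic_given_seed(self, tiny_corpus):
        instances, _ = tiny_corpus
        h = Hyperparameters(max_epochs=3)
        m1, _ = train(instances, h, seed=5, track_objective=False)
        m2, _ = train(instances, h, seed=5, track_objective=False)
        assert m1.weights == m2.weights

    def test_seed_changes_trajectory(self, tiny_corpus):
        instances, _ = tiny_corpus
        h = Hyperparameters(max_epochs=2)
        m1, _ = train(instances, h, seed=5, track_objective=False)
        m2, _ = train(instances, h, seed=6, track_objective=False)
        assert m1.weights != m2.weights

    def test_objective_improves_on_tiny_corpus(self, tiny_corpus):
        instances, _ = tiny_corpus
        h = Hyperparameters(max_epochs=10)
        model, state = train(instances, h, seed=1)
        initial = objective(instances, ModelWeights({}), h)
        assert state.objective_history[-1] < initial

    def test_empty_truth_learns_to_predict_empty(self):
        """With an all-empty truth the learner pushes feature weights
        negative until the loss-augmented argmax is the empty map; the
        hinge then vanishes and only the l1 term remains."""
        inst = _tiny_instance()
        h = Hyperparameters(max_epochs=5)
        model, state = train([inst], h, seed=0)
        terms = score_terms(inst.protein, inst.rna, model)
        z, _ = predict_ip(InferenceProblem(terms, h.X_cap, h.Y_cap))
        assert z.contacts == frozenset()
        assert state.objective_history[-1] == pytest.approx(
            h.C * model.l1_norm(), abs=1e-9
        )

    def test_huge_l1_suppresses_weights(self, tiny_corpus):
        """Extreme l1 strength pins actively-trained weights near zero:
        the regularizer subgradient dominates the count subgradients, so
        the keys the hinge keeps touching (the true-map features)
        oscillate in a shrinking AdaGrad band instead of growing as they
        do under the default C."""
        instances, _ = tiny_corpus
        h_big = Hyperparameters(max_epochs=20, C=1e4)
        big, _ = train(instances, h_big, seed=2, track_objective=False)
        small, _ = train(
            instances, Hyperparameters(max_epochs=20), seed=2, track_objective=False
        )
        true_keys = set()
        for inst in instances:
            true_keys |= set(full_features(inst.protein, inst.rna, inst.z_true))
        mean_big = sum(abs(big.get(k)) for k in true_keys) / len(true_keys)
        mean_small = sum(abs(small.get(k)) for k in true_keys) / len(true_keys)
        assert max(abs(w) for w in big.weights.values()) <= 2 * h_big.eta
        assert mean_big < 0.2 * mean_small
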