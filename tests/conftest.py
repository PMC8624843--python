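"""Shared fixtures: tiny instances, random structure generators, and the
session-scoped trained model used by the end-to-end learning checks."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ribocontact import (
    ContactMap,
    Hyperparameters,
    ProteinRecord,
    RNARecord,
    SyntheticConfig,
    generate_synthetic,
)
from ribocontact.learning import train


def random_wellformed_dotbracket(rng: np.random.Generator, n: int) -> str:
    """A uniform-ish random balanced dot-bracket of exact length n,
    built by a guarded push/pop walk (independent of the package's
    stem-loop sampler)."""
    out = []
    depth = 0
    for pos in range(n):
        remaining = n - pos
        if depth > 0 and remaining <= depth:
            out.append(")")
            depth -= 1
            continue
        r = rng.random()
        if r < 0.3 and remaining > depth + 1:
            out.append("(")
            depth += 1
        elif r < 0.55 and depth > 0:
            out.append(")")
            depth -= 1
        else:
            out.append(".")
    return "".join(out)


def random_contact_map(
    rng: np.random.Generator, n_res: int, n_base: int, density: float = 0.3
) -> ContactMap:
    """A random (not necessarily decoding-feasible) contact map."""
    cells = [
        (i, j)
        for i, j in itertools.product(range(1, n_res + 1), range(1, n_base + 1))
        if rng.random() < density
    ]
    return ContactMap(n_res, n_base, frozenset(cells))


def all_maps(n_res: int, n_base: int):
    """Every contact map on a small grid."""
    cells = list(itertools.product(range(1, n_res + 1), range(1, n_base + 1)))
    for mask in range(1 << len(cells)):
        yield ContactMap(
            n_res, n_base, frozenset(c for b, c in enumerate(cells) if (mask >> b) & 1)
        )


@pytest.fixture
def mkv_protein() -> ProteinRecord:
    return ProteinRecord("p1", "MKV", "HHH")


@pytest.fixture
def acg_rna() -> RNARecord:
    return RNARecord.from_dotbracket("r1", "ACG", "...")


@pytest.fixture(scope="session")
def synthetic_corpus():
    """The default 10-pair planted-weight corpus (fixed seed)."""
    return generate_synthetic(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def trained_model(synthetic_corpus):
    """Weights trained for up to 50 epochs on the synthetic corpus."""
    instances, _ = synthetic_corpus
    h = Hyperparameters(max_epochs=50)
    model, state = train(instances, h, seed=1)
    return model, state, h


@pytest.fixture(scope="session")
def tiny_corpus():
    """A smaller, faster corpus for optimiser unit tests."""
    config = SyntheticConfig(
        n_pairs=3,
        protein_length_range=(6, 9),
        rna_length_range=(9, 14),
        seed=3,
    )
    return generate_synthetic(config)
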