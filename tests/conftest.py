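import numpy as np
import pytest

from hmmtutor import (
    Alphabet,
    HiddenStates,
    ObservedSequence,
    build_model,
)


def make_model(prior, transitions, emissions, symbols="ab", labels=None):
    """Small custom-alphabet model from explicit rows."""
    K = len(prior)
    labels = labels or tuple(f"S{i + 1}" for i in range(K))
    return build_model(
        Alphabet.custom(symbols),
        HiddenStates(tuple(labels)),
        np.asarray(prior, float),
        np.asarray(transitions, float),
        np.asarray(emissions, float),
    )


def random_instance(rng, n_states, n_symbols, length):
    """A random (model, sequence) pair over a custom alphabet."""
    symbols = "abcdefgh"[:n_symbols]

    def rows(n, m):
        raw = rng.uniform(size=(n, m))
        return raw / raw.sum(axis=1, keepdims=True)

    model = make_model(
        rows(1, n_states)[0],
        rows(n_states, n_states),
        rows(n_states, n_symbols),
        symbols=symbols,
    )
    seq = ObservedSequence.from_string(
        "".join(rng.choice(list(symbols), size=length))
    )
    return model, seq


@pytest.fixture
def one_state_model():
    """Single state, alphabet {a, b}, e(a) = e(b) = 0.5, self-transition 1."""
    return make_model([1.0], [[1.0]], [[0.5, 0.5]], labels=("S",))


@pytest.fixture
def two_state_model():
    """A fixed, asymmetric 2-state 2-symbol model used across tests."""
    return make_model(
        [0.6, 0.4],
        [[0.7, 0.3], [0.4, 0.6]],
        [[0.9, 0.1], [0.2, 0.8]],
        labels=("P", "Q"),
    )
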