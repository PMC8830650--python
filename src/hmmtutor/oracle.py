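"""Brute-force reference results by exhaustive hidden-path enumeration.

For a K-state model and a length-L sequence there are K^L hidden paths;
summing their joint probabilities gives P(O) exactly, the best of them is
the Viterbi path, and restricting the sum to paths with state k at
position j gives the posterior numerator.  This is the independent test
bed for every dynamic-programming result — deliberately naive, plain
probability space only, no optimization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .algorithms import PosteriorMatrix, joint_probability
from .model import HMMModel, ObservedSequence

__all__ = ["PathEnumeration", "enumerate_paths", "posterior_by_enumeration"]

DEFAULT_CAP = 10**6


@dataclass(frozen=True)
class PathEnumeration:
    """All K^L (path, joint probability) pairs plus their aggregate P(O).

    Pairs are sorted by descending probability; equal probabilities are
    ordered by the path's state indices lexicographically, matching the
    Viterbi tie-break (earliest declared state wins).
    """

    pairs: tuple[tuple[tuple[str, ...], float], ...]
    aggregate: float

    @property
    def best_path(self) -> tuple[str, ...]:
        return self.pairs[0][0]

    @property
    def best_probability(self) -> float:
        return self.pairs[0][1]


def enumerate_paths(
    model: HMMModel, seq: ObservedSequence, cap: int = DEFAULT_CAP
) -> PathEnumeration:
    """Enumerate every hidden path with its exact joint probability."""
    K, L = model.n_states, len(seq)
    n_paths = K**L
    if n_paths > cap:
        raise ValueError(
            f"{n_paths} paths exceed the enumeration cap ({cap}); "
            "use the dynamic-programming algorithms instead"
        )
    labels = model.states.labels
    scored = []
    for combo in itertools.product(range(K), repeat=L):
        path = tuple(labels[k] for k in combo)
        p = joint_probability(model, seq, path, mode="plain")
        scored.append((combo, path, p))
    # descending probability, ties by state-index lexicographic order
    scored.sort(key=lambda t: (-t[2], t[0]))
    pairs = tuple((path, p) for _, path, p in scored)
    aggregate = float(sum(p for _, p in pairs))
    return PathEnumeration(pairs, aggregate)


def posterior_by_enumeration(
    model: HMMModel, seq: ObservedSequence, cap: int = DEFAULT_CAP
) -> PosteriorMatrix:
    """Posterior gamma[j, k] from the enumeration: sum over paths with
    state k at position j of P(path, O), divided by P(O)."""
    enum = enumerate_paths(model, seq, cap=cap)
    if enum.aggregate == 0.0:
        raise ValueError("P(O) is zero under this model; the posterior is undefined")
    L, K = len(seq), model.n_states
    index = {label: k for k, label in enumerate(model.states.labels)}
    gamma = np.zeros((L, K))
    for path, p in enum.pairs:
        if p == 0.0:
            continue
        for j, q in enumerate(path):
            gamma[j, index[q]] += p
    gamma /= enum.aggregate
    argmax = tuple(model.states.labels[k] for k in np.argmax(gamma, axis=1))
    return PosteriorMatrix(gamma, argmax, model.states.labels)
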