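"""Forward, Backward and Viterbi dynamic programming, plus posterior decoding.

The three algorithms answer the three classic questions about an observed
sequence O of length L under a K-state model:

* Forward  — what is P(O), the probability of the observed sequence,
  summed over all K^L hidden paths?
* Viterbi  — which single hidden path Q* maximizes the joint P(Q, O)?
* Backward — what is the probability that hidden state k produced the
  symbol at position j?  Combined with Forward it yields the per-position
  posterior gamma[j, k] = P(q_j = k | O), the posterior-decoding chart.

Recursions (1-based positions, as reported to users):

    alpha[1, k] = prior(k) * e(k, o_1)
    alpha[j, l] = e(l, o_j) * sum_k alpha[j-1, k] * a(k -> l)
    P(O)        = sum_k alpha[L, k]

    beta[L, k]  = 1
    beta[j, k]  = sum_l a(k -> l) * e(l, o_{j+1}) * beta[j+1, l]

    delta[1, k] = prior(k) * e(k, o_1)
    delta[j, l] = e(l, o_j) * max_k delta[j-1, k] * a(k -> l)

Two numeric modes are supported.  ``log`` (the default) stores log
probabilities with ``-inf`` for impossible events and uses log-sum-exp for
the Forward/Backward sums; it is required for realistic sequence lengths,
where P(O) underflows double precision (a 100-residue protein already sits
near 1e-127).  ``plain`` works directly in probability space and is kept
for short classroom examples whose intermediate values are readable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .model import HMMModel, ModelValidationError, ObservedSequence

__all__ = [
    "Mode",
    "ForwardResult",
    "BackwardResult",
    "ViterbiResult",
    "PosteriorMatrix",
    "forward",
    "backward",
    "viterbi",
    "posterior_decoding",
    "joint_probability",
    "InfeasibleSequenceError",
]

Mode = Literal["plain", "log"]


class InfeasibleSequenceError(ValueError):
    """The model assigns probability zero to every hidden path for this sequence."""


def _check_mode(mode: str) -> None:
    if mode not in ("plain", "log"):
        raise ValueError(f"mode must be 'plain' or 'log', got {mode!r}")


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


@dataclass(frozen=True)
class ForwardResult:
    """Filled alpha table (L x K) and the sequence probability P(O).

    In log mode ``table`` and ``total`` hold log probabilities; the
    ``probability`` / ``log_probability`` properties convert either way.
    """

    table: np.ndarray
    total: float
    mode: Mode
    state_labels: tuple[str, ...]

    @property
    def probability(self) -> float:
        return float(np.exp(self.total)) if self.mode == "log" else self.total

    @property
    def log_probability(self) -> float:
        if self.mode == "log":
            return self.total
        return float(np.log(self.total)) if self.total > 0 else float("-inf")


@dataclass(frozen=True)
class BackwardResult:
    """Filled beta table (L x K) and P(O) recomputed from position 1."""

    table: np.ndarray
    total: float
    mode: Mode
    state_labels: tuple[str, ...]

    @property
    def probability(self) -> float:
        return float(np.exp(self.total)) if self.mode == "log" else self.total

    @property
    def log_probability(self) -> float:
        if self.mode == "log":
            return self.total
        return float(np.log(self.total)) if self.total > 0 else float("-inf")


@dataclass(frozen=True)
class ViterbiResult:
    """Optimal hidden path with its joint and conditional probabilities.

    ``joint`` is P(Q*, O) in the mode's space; ``conditional`` is always
    the plain probability P(Q* | O) = exp(log P(Q*, O) - log P(O)), the
    quantity a user compares across runs.
    """

    path: tuple[str, ...]
    joint: float
    conditional: float
    table: np.ndarray
    pointers: np.ndarray
    mode: Mode
    state_labels: tuple[str, ...]

    @property
    def log_joint(self) -> float:
        if self.mode == "log":
            return self.joint
        return float(np.log(self.joint)) if self.joint > 0 else float("-inf")

    def path_string(self) -> str:
        return "".join(self.path)


@dataclass(frozen=True)
class PosteriorMatrix:
    """Per-position state posteriors gamma (L x K, plain probabilities).

    ``argmax_path`` is the per-position most probable state — the curve a
    posterior-decoding chart is read from.  It need not be a legal path
    under the transition matrix; Viterbi answers the best-path question.
    """

    gamma: np.ndarray
    argmax_path: tuple[str, ...]
    state_labels: tuple[str, ...]

    def __len__(self) -> int:
        return self.gamma.shape[0]


def _prepare(model: HMMModel, seq: ObservedSequence) -> np.ndarray:
    violations_obs = seq.indices(model.alphabet)  # raises on foreign symbols
    return violations_obs


def forward(model: HMMModel, seq: ObservedSequence, mode: Mode = "log") -> ForwardResult:
    """Run the Forward algorithm; ``total`` is P(O) (or its log)."""
    _check_mode(mode)
    obs = _prepare(model, seq)
    L, K = len(obs), model.n_states

    if mode == "plain":
        alpha = np.zeros((L, K))
        alpha[0] = model.prior * model.emissions[:, obs[0]]
        for j in range(1, L):
            alpha[j] = model.emissions[:, obs[j]] * (alpha[j - 1] @ model.transitions)
        total = float(alpha[-1].sum())
    else:
        lp, lt, le = _log(model.prior), _log(model.transitions), _log(model.emissions)
        alpha = np.full((L, K), -np.inf)
        alpha[0] = lp + le[:, obs[0]]
        for j in range(1, L):
            alpha[j] = le[:, obs[j]] + logsumexp(alpha[j - 1][:, None] + lt, axis=0)
        total = float(logsumexp(alpha[-1]))
    return ForwardResult(alpha, total, mode, model.states.labels)


def backward(model: HMMModel, seq: ObservedSequence, mode: Mode = "log") -> BackwardResult:
    """Run the Backward algorithm; ``total`` recomputes P(O) from position 1."""
    _check_mode(mode)
    obs = _prepare(model, seq)
    L, K = len(obs), model.n_states

    if mode == "plain":
        beta = np.zeros((L, K))
        beta[-1] = 1.0
        for j in range(L - 2, -1, -1):
            beta[j] = model.transitions @ (model.emissions[:, obs[j + 1]] * beta[j + 1])
        total = float((model.prior * model.emissions[:, obs[0]] * beta[0]).sum())
    else:
        lp, lt, le = _log(model.prior), _log(model.transitions), _log(model.emissions)
        beta = np.full((L, K), -np.inf)
        beta[-1] = 0.0
        for j in range(L - 2, -1, -1):
            beta[j] = logsumexp(lt + (le[:, obs[j + 1]] + beta[j + 1])[None, :], axis=1)
        total = float(logsumexp(lp + le[:, obs[0]] + beta[0]))
    return BackwardResult(beta, total, mode, model.states.labels)


def viterbi(model: HMMModel, seq: ObservedSequence, mode: Mode = "log") -> ViterbiResult:
    """Find the single most probable hidden path Q* and P(Q* | O).

    Ties in the max and in the final argmax are broken toward the state
    earliest in the declared state order, so output is deterministic.
    Raises :class:`InfeasibleSequenceError` when no path has nonzero
    probability.
    """
    _check_mode(mode)
    obs = _prepare(model, seq)
    L, K = len(obs), model.n_states
    pointers = np.zeros((L, K), dtype=np.intp)

    if mode == "plain":
        delta = np.zeros((L, K))
        delta[0] = model.prior * model.emissions[:, obs[0]]
        for j in range(1, L):
            cand = delta[j - 1][:, None] * model.transitions  # cand[k, l]
            pointers[j] = np.argmax(cand, axis=0)  # first max: earliest state wins
            delta[j] = model.emissions[:, obs[j]] * cand[pointers[j], np.arange(K)]
        best_last = int(np.argmax(delta[-1]))
        joint = float(delta[-1, best_last])
        infeasible = joint <= 0.0
    else:
        lp, lt, le = _log(model.prior), _log(model.transitions), _log(model.emissions)
        delta = np.full((L, K), -np.inf)
        delta[0] = lp + le[:, obs[0]]
        for j in range(1, L):
            cand = delta[j - 1][:, None] + lt
            pointers[j] = np.argmax(cand, axis=0)
            delta[j] = le[:, obs[j]] + cand[pointers[j], np.arange(K)]
        best_last = int(np.argmax(delta[-1]))
        joint = float(delta[-1, best_last])
        infeasible = joint == -np.inf

    if infeasible:
        raise InfeasibleSequenceError(
            "every hidden path has probability zero: the model cannot emit "
            "this sequence (check for zero emission/transition entries)"
        )

    idx = np.empty(L, dtype=np.intp)
    idx[-1] = best_last
    for j in range(L - 1, 0, -1):
        idx[j - 1] = pointers[j, idx[j]]
    path = tuple(model.states.labels[k] for k in idx)

    log_total = forward(model, seq, mode="log").total
    log_joint = joint if mode == "log" else float(np.log(joint))
    conditional = float(np.exp(log_joint - log_total))
    return ViterbiResult(path, joint, conditional, delta, pointers, mode, model.states.labels)


def posterior_decoding(model: HMMModel, seq: ObservedSequence) -> PosteriorMatrix:
    """Per-position posteriors gamma[j, k] = alpha[j, k] * beta[j, k] / P(O).

    Computed in log space for stability and returned as plain
    probabilities; each position's row sums to 1.  Raises
    :class:`InfeasibleSequenceError` when P(O) = 0 (posterior undefined).
    """
    fwd = forward(model, seq, mode="log")
    if fwd.total == -np.inf:
        raise InfeasibleSequenceError(
            "P(O) is zero under this model; the posterior is undefined"
        )
    bwd = backward(model, seq, mode="log")
    gamma = np.exp(fwd.table + bwd.table - fwd.total)
    # guard against tiny drift; rows are mathematically normalized already
    argmax = tuple(model.states.labels[k] for k in np.argmax(gamma, axis=1))
    return PosteriorMatrix(gamma, argmax, model.states.labels)


def joint_probability(
    model: HMMModel,
    seq: ObservedSequence,
    path: Sequence[str],
    mode: Mode = "plain",
) -> float:
    """P(Q, O) for an explicit hidden path Q:

    prior(q_1) * e(q_1, o_1) * prod_{j>=2} a(q_{j-1} -> q_j) * e(q_j, o_j).

    The log-mode variant returns the log (``-inf`` for impossible paths).
    """
    _check_mode(mode)
    obs = _prepare(model, seq)
    if len(path) != len(obs):
        raise ModelValidationError(
            f"path length {len(path)} does not match sequence length {len(obs)}"
        )
    idx = np.array([model.states.index(q) for q in path], dtype=np.intp)
    terms = np.empty(2 * len(obs) - 1)
    terms[0] = model.prior[idx[0]]
    terms[1::2] = model.transitions[idx[:-1], idx[1:]] if len(obs) > 1 else []
    terms[0::2][1:] = model.emissions[idx[1:], obs[1:]]
    emis0 = model.emissions[idx[0], obs[0]]
    if mode == "plain":
        return float(emis0 * np.prod(terms))
    with np.errstate(divide="ignore"):
        return float(np.log(emis0) + np.sum(np.log(terms)))
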