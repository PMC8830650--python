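"""Domain types for discrete first-order hidden Markov models.

A model is defined by six elements: an alphabet of observed symbols, an
observed sequence drawn from it, a set of hidden states, a prior (initial)
probability vector over the hidden states, a transition probability matrix
between hidden states, and an emission probability matrix from hidden
states to observed symbols.

All probability rows must sum to 1 within ``NORM_TOL``; violations are
surfaced rather than silently renormalized, because spotting a bad row is
half the point when the numbers are typed in by hand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NORM_TOL",
    "AlphabetKind",
    "Alphabet",
    "ObservedSequence",
    "HiddenStates",
    "HMMModel",
    "ModelValidationError",
    "build_model",
    "validate_model",
    "random_model",
]

#: Maximum allowed |row sum - 1| for any probability vector or matrix row.
NORM_TOL = 1e-9

_DNA = "ACGT"
_RNA = "ACGU"
_PROTEIN = "ACDEFGHIKLMNPQRSTVWY"  # standard 20 amino acids, alphabetical


class AlphabetKind(str, enum.Enum):
    DNA = "dna"
    RNA = "rna"
    PROTEIN = "protein"
    CUSTOM = "custom"


class ModelValidationError(ValueError):
    """Raised when a model fails structural or normalization checks."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of distinct single-character observed symbols."""

    kind: AlphabetKind
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ModelValidationError("alphabet must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ModelValidationError("alphabet symbols must be pairwise distinct")
        for s in self.symbols:
            if len(s) != 1:
                raise ModelValidationError(
                    f"alphabet symbols must be single characters, got {s!r}"
                )

    @classmethod
    def dna(cls) -> "Alphabet":
        return cls(AlphabetKind.DNA, tuple(_DNA))

    @classmethod
    def rna(cls) -> "Alphabet":
        return cls(AlphabetKind.RNA, tuple(_RNA))

    @classmethod
    def protein(cls) -> "Alphabet":
        return cls(AlphabetKind.PROTEIN, tuple(_PROTEIN))

    @classmethod
    def custom(cls, symbols) -> "Alphabet":
        return cls(AlphabetKind.CUSTOM, tuple(str(s).upper() for s in symbols))

    @classmethod
    def from_kind(cls, kind, symbols=None) -> "Alphabet":
        """Build a standard alphabet by kind name, or a custom one from symbols."""
        kind = AlphabetKind(str(kind).lower())
        if kind is AlphabetKind.CUSTOM:
            if not symbols:
                raise ModelValidationError("custom alphabet requires explicit symbols")
            return cls.custom(symbols)
        return {
            AlphabetKind.DNA: cls.dna,
            AlphabetKind.RNA: cls.rna,
            AlphabetKind.PROTEIN: cls.protein,
        }[kind]()

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass(frozen=True)
class ObservedSequence:
    """The query O: an ordered list of observed symbols, positions 1-based.

    Symbols are uppercased on ingestion.  Membership in a concrete model
    alphabet is checked when the sequence is bound to a model (at algorithm
    time), not at construction.
    """

    symbols: tuple[str, ...]
    identifier: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ModelValidationError("observed sequence must be non-empty")
        object.__setattr__(self, "symbols", tuple(s.upper() for s in self.symbols))

    @classmethod
    def from_string(cls, s: str, identifier: str = "") -> "ObservedSequence":
        return cls(tuple(s.strip()), identifier=identifier)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)

    def indices(self, alphabet: Alphabet) -> np.ndarray:
        """Map symbols to alphabet column indices, rejecting foreign symbols.

        Error messages report 1-based positions.
        """
        lookup = {s: i for i, s in enumerate(alphabet.symbols)}
        out = np.empty(len(self.symbols), dtype=np.intp)
        for j, s in enumerate(self.symbols):
            try:
                out[j] = lookup[s]
            except KeyError:
                raise ModelValidationError(
                    f"symbol {s!r} at position {j + 1} is not in the alphabet"
                ) from None
        return out


@dataclass(frozen=True)
class HiddenStates:
    """Ordered distinct hidden-state labels (e.g. I, M, O).

    Labels may collide with observed-symbol characters; the two live in
    separate namespaces (a transmembrane model legitimately uses 'O' both
    as the Outside state and via the alphabet's amino acids).
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ModelValidationError("at least one hidden state is required")
        if len(set(self.labels)) != len(self.labels):
            raise ModelValidationError("hidden-state labels must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ModelValidationError(f"unknown hidden-state label {label!r}") from None


@dataclass(frozen=True)
class HMMModel:
    """A fully specified discrete HMM.

    ``prior`` has shape (K,), ``transitions`` (K, K) with rows indexed by
    the source state, ``emissions`` (K, |alphabet|).  Instances built via
    :func:`build_model` or :func:`random_model` are validated; direct
    construction skips validation (used by readers that validate
    afterwards).
    """

    alphabet: Alphabet
    states: HiddenStates
    prior: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray
    name: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "prior", np.asarray(self.prior, dtype=float))
        object.__setattr__(self, "transitions", np.asarray(self.transitions, dtype=float))
        object.__setattr__(self, "emissions", np.asarray(self.emissions, dtype=float))

    @property
    def n_states(self) -> int:
        return len(self.states)

    def emission_column(self, symbol: str) -> np.ndarray:
        return self.emissions[:, self.alphabet.index(symbol)]


def _check_distribution(vec: np.ndarray, what: str, violations: list[str]) -> None:
    vec = np.asarray(vec, dtype=float)
    if np.any(vec < -0.0) or np.any(vec > 1.0 + NORM_TOL):
        violations.append(f"{what}: entries must lie in [0, 1]")
    s = float(vec.sum())
    if abs(s - 1.0) > NORM_TOL:
        violations.append(f"{what}: sums to {s!r}, deviation {s - 1.0:+.3e} exceeds tolerance")


def validate_model(model: HMMModel) -> list[str]:
    """Return a list of violations; an empty list means the model is valid.

    Every dimension mismatch and every probability row whose sum deviates
    from 1 beyond ``NORM_TOL`` is reported; nothing is raised.
    """
    violations: list[str] = []
    K = len(model.states)
    A = len(model.alphabet)

    if model.prior.shape != (K,):
        violations.append(
            f"prior vector: expected shape ({K},) for {K} states, got {model.prior.shape}"
        )
    if model.transitions.shape != (K, K):
        violations.append(
            f"transition matrix: expected shape ({K}, {K}), got {model.transitions.shape}"
        )
    if model.emissions.shape != (K, A):
        violations.append(
            f"emission matrix: expected shape ({K}, {A}) for {K} states x "
            f"{A} symbols, got {model.emissions.shape}"
        )
    if violations:
        return violations  # row checks are meaningless on wrong shapes

    _check_distribution(model.prior, "prior vector", violations)
    for k, label in enumerate(model.states.labels):
        _check_distribution(
            model.transitions[k], f"transition row for state {label!r}", violations
        )
        _check_distribution(
            model.emissions[k], f"emission row for state {label!r}", violations
        )
    return violations


def build_model(
    alphabet: Alphabet,
    states: HiddenStates,
    prior,
    transitions,
    emissions,
    *,
    name: str = "",
    notes: str = "",
    renormalize: bool = False,
) -> HMMModel:
    """Assemble and validate an :class:`HMMModel` from its five components.

    With ``renormalize=True`` each probability row is divided by its sum
    before validation (an explicit opt-in; by default deviations are
    rejected so that data-entry mistakes surface).
    """
    prior = np.asarray(prior, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    emissions = np.asarray(emissions, dtype=float)
    if renormalize:
        prior = prior / prior.sum()
        transitions = transitions / transitions.sum(axis=1, keepdims=True)
        emissions = emissions / emissions.sum(axis=1, keepdims=True)
    model = HMMModel(alphabet, states, prior, transitions, emissions, name=name, notes=notes)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError("invalid model: " + "; ".join(violations))
    return model


def random_model(n_states: int, alphabet: Alphabet, seed: int) -> HMMModel:
    """Generate a model with random parameters, reproducible from *seed*.

    Each probability row is drawn as independent uniform(0, 1) variates and
    normalized to sum to 1 (equivalent to a flat Dirichlet).  The generator
    is numpy's PCG64 via ``numpy.random.default_rng``; identical arguments
    reproduce identical parameters bit-for-bit.

    State labels are S1..Sn unless n_states == 3 and the alphabet is
    protein, in which case the conventional membrane-topology labels
    I, M, O are used.
    """
    if n_states < 1:
        raise ModelValidationError(f"n_states must be >= 1, got {n_states}")
    rng = np.random.default_rng(seed)

    def rows(n_rows: int, n_cols: int) -> np.ndarray:
        raw = rng.uniform(size=(n_rows, n_cols))
        return raw / raw.sum(axis=1, keepdims=True)

    prior = rows(1, n_states)[0]
    transitions = rows(n_states, n_states)
    emissions = rows(n_states, len(alphabet))
    if n_states == 3 and alphabet.kind is AlphabetKind.PROTEIN:
        labels = ("I", "M", "O")
    else:
        labels = tuple(f"S{i + 1}" for i in range(n_states))
    return build_model(
        alphabet,
        HiddenStates(labels),
        prior,
        transitions,
        emissions,
        name=f"random(n_states={n_states}, seed={seed})",
    )
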