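"""Readers and writers for sequences and models, plus bundled fixtures.

Sequences come in as FASTA (via Biopython) or plain strings.  Models are
stored as a single YAML document carrying the alphabet kind (with explicit
symbols for custom alphabets), the ordered state labels, the prior vector,
and the transition and emission matrices keyed by state label.  Numbers
are written as full-precision decimal text so that write -> read is an
exact round-trip.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from importlib import resources
from typing import TextIO

import numpy as np
import yaml
from Bio import SeqIO

from .model import (
    Alphabet,
    AlphabetKind,
    HiddenStates,
    HMMModel,
    ModelValidationError,
    ObservedSequence,
    build_model,
)

__all__ = [
    "read_fasta",
    "read_model",
    "write_model",
    "matrix_from_tsv",
    "FixtureBundle",
    "load_fixture",
    "available_fixtures",
]


class ModelFileError(ValueError):
    """Raised when a model document is malformed."""


def _as_stream(source: str | TextIO) -> TextIO:
    return _io.StringIO(source) if isinstance(source, str) else source


def read_fasta(source: str | TextIO) -> list[tuple[str, ObservedSequence]]:
    """Parse FASTA records into (identifier, sequence) pairs, in file order.

    Sequence bodies are uppercased with whitespace and line breaks
    stripped; identifiers are everything after ``>`` up to the first
    whitespace, preserved verbatim.  Alphabet membership is not checked
    here — it is deferred until the sequence is bound to a model.
    """
    records = list(SeqIO.parse(_as_stream(source), "fasta"))
    if not records:
        raise ModelFileError("no FASTA records found in input")
    out = []
    for rec in records:
        body = str(rec.seq).strip()
        if not body:
            raise ModelFileError(f"FASTA record {rec.id!r} has an empty sequence")
        out.append((rec.id, ObservedSequence.from_string(body, identifier=rec.id)))
    return out


def _matrix_from_mapping(
    mapping, labels: tuple[str, ...], n_cols: int, what: str
) -> np.ndarray:
    if not isinstance(mapping, dict):
        raise ModelFileError(f"{what}: expected a mapping keyed by state label")
    unknown = set(mapping) - set(labels)
    if unknown:
        raise ModelFileError(f"{what}: unknown state label(s) {sorted(unknown)}")
    rows = []
    for label in labels:
        if label not in mapping:
            raise ModelFileError(f"{what}: missing row for state {label!r}")
        row = mapping[label]
        if not isinstance(row, (list, tuple)) or len(row) != n_cols:
            raise ModelFileError(
                f"{what}: row for state {label!r} must have {n_cols} entries, "
                f"got {len(row) if isinstance(row, (list, tuple)) else type(row).__name__}"
            )
        rows.append([float(x) for x in row])
    return np.array(rows)


def read_model(source: str | TextIO) -> HMMModel:
    """Read a model document; the result passes full validation."""
    doc = yaml.safe_load(_as_stream(source).read())
    if not isinstance(doc, dict):
        raise ModelFileError("model document must be a mapping")
    for field in ("alphabet", "states", "prior", "transitions", "emissions"):
        if field not in doc:
            raise ModelFileError(f"model document missing required field {field!r}")

    alpha_doc = doc["alphabet"]
    if not isinstance(alpha_doc, dict) or "kind" not in alpha_doc:
        raise ModelFileError("field 'alphabet' must be a mapping with a 'kind'")
    try:
        alphabet = Alphabet.from_kind(alpha_doc["kind"], alpha_doc.get("symbols"))
    except (ValueError, KeyError) as exc:
        raise ModelFileError(f"field 'alphabet': {exc}") from exc

    labels = tuple(str(s) for s in doc["states"])
    states = HiddenStates(labels)
    K = len(labels)

    prior = doc["prior"]
    if not isinstance(prior, (list, tuple)) or len(prior) != K:
        raise ModelFileError(f"field 'prior' must list {K} probabilities")
    transitions = _matrix_from_mapping(doc["transitions"], labels, K, "field 'transitions'")
    emissions = _matrix_from_mapping(
        doc["emissions"], labels, len(alphabet), "field 'emissions'"
    )
    try:
        return build_model(
            alphabet,
            states,
            np.array([float(x) for x in prior]),
            transitions,
            emissions,
            name=str(doc.get("name", "")),
            notes=str(doc.get("notes", "")),
        )
    except ModelValidationError as exc:
        raise ModelFileError(str(exc)) from exc


def write_model(model: HMMModel) -> str:
    """Serialize a model to YAML text; ``read_model(write_model(m))`` is
    entrywise exact (PyYAML emits floats via ``repr``, preserving all 53
    bits)."""
    doc: dict = {}
    if model.name:
        doc["name"] = model.name
    if model.notes:
        doc["notes"] = model.notes
    alpha: dict = {"kind": model.alphabet.kind.value}
    if model.alphabet.kind is AlphabetKind.CUSTOM:
        alpha["symbols"] = list(model.alphabet.symbols)
    doc["alphabet"] = alpha
    doc["states"] = list(model.states.labels)
    doc["prior"] = [float(x) for x in model.prior]
    doc["transitions"] = {
        label: [float(x) for x in model.transitions[k]]
        for k, label in enumerate(model.states.labels)
    }
    doc["emissions"] = {
        label: [float(x) for x in model.emissions[k]]
        for k, label in enumerate(model.states.labels)
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None, width=100)


def matrix_from_tsv(source: str | TextIO) -> np.ndarray:
    """Read a bare numeric matrix from tab-separated text (classroom import)."""
    rows = []
    for lineno, line in enumerate(_as_stream(source), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(x) for x in line.split("\t")])
        except ValueError as exc:
            raise ModelFileError(f"TSV line {lineno}: {exc}") from exc
    if not rows:
        raise ModelFileError("TSV input contains no rows")
    width = len(rows[0])
    for i, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ModelFileError(f"TSV row {i} has {len(r)} columns, expected {width}")
    return np.array(rows)


@dataclass(frozen=True)
class FixtureBundle:
    """A named, ready-to-run example: sequence + model + provenance notes."""

    name: str
    sequence: ObservedSequence
    model: HMMModel
    provenance: str


_FIXTURES = {
    "tm_p18599": (
        "tm_p18599.fasta",
        "tm_p18599_synthetic_model.yaml",
        "100-residue N-terminal fragment of the 5-hydroxytryptamine receptor "
        "2A (UniProtKB P18599) with SYNTHETIC surrogate model parameters: "
        "hydropathy-derived emissions and transitions with a(I->O) = "
        "a(O->I) = 0. The parameters are constructed, not transcribed from "
        "any published set.",
    ),
}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> FixtureBundle:
    """Load a bundled example by registered name.

    The only bundled fixture is ``tm_p18599``, the transmembrane-topology
    worked example: a 3-state (I/M/O) model over the protein alphabet and
    a 100-residue receptor fragment.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    fasta_name, model_name, provenance = _FIXTURES[name]
    pkg = resources.files(__package__) / "fixtures"
    records = read_fasta((pkg / fasta_name).read_text())
    model = read_model((pkg / model_name).read_text())
    return FixtureBundle(name, records[0][1], model, provenance)
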