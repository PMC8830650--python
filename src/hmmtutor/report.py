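"""Step-by-step educational rendering of the algorithms and their results.

A report echoes the model parameters, then adds one section per computed
result: the recursion formula, the per-position calculation table (with
the arithmetic expanded operand-by-operand for short sequences), and the
final answer — P(O) for Forward, the optimal state string with P(Q|O) for
Viterbi, and the posterior-decoding table for Backward.

Displayed numbers are rounded copies (4 significant digits, scientific
notation below 1e-4); the full-precision values live in the result
objects and every printed probability can be re-derived from them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .algorithms import (
    BackwardResult,
    ForwardResult,
    PosteriorMatrix,
    ViterbiResult,
)
from .model import HMMModel, ObservedSequence

__all__ = [
    "render_report",
    "posterior_chart_data",
    "posterior_table",
    "plot_posterior",
]

#: positions with fully expanded arithmetic when the sequence is longer
_HEAD, _TAIL = 3, 2
#: sequences up to this length get every cell's arithmetic expanded
_FULL_EXPANSION_MAX_L = 15
_BLOCK = 60  # fixed-width block size for sequence/path alignment


def _fmt(x: float) -> str:
    """4 significant digits; scientific notation below 1e-4."""
    if x == 0:
        return "0"
    if not math.isfinite(x):
        return str(x)
    return f"{x:.4g}" if abs(x) >= 1e-4 else f"{x:.3e}"


def _sci_from_log(logp: float) -> str:
    """Scientific-notation string from a natural-log probability.

    Works below the double-precision underflow threshold (a 1000-residue
    query can push P(O) under 1e-308)."""
    if logp == -np.inf:
        return "0"
    log10 = logp / math.log(10.0)
    exp10 = math.floor(log10)
    mantissa = 10.0 ** (log10 - exp10)
    return f"{mantissa:.4g}e{exp10:+03d}"


@dataclass
class _Section:
    title: str
    paragraphs: list[str] = field(default_factory=list)
    tables: list[tuple[list[str], list[list[str]]]] = field(default_factory=list)
    preformatted: list[str] = field(default_factory=list)

    def table(self, header: list[str], rows: list[list[str]]) -> None:
        self.tables.append((header, rows))


def _check_provenance(model: HMMModel, seq: ObservedSequence, results) -> None:
    L = len(seq)
    for r in results:
        labels = r.state_labels
        if tuple(labels) != tuple(model.states.labels):
            raise ValueError(
                "result was computed on a different model (state labels "
                f"{labels} vs {model.states.labels})"
            )
        n = r.gamma.shape[0] if isinstance(r, PosteriorMatrix) else r.table.shape[0]
        if n != L:
            raise ValueError(
                f"result covers {n} positions but the sequence has {L}"
            )


def _header_section(model: HMMModel, seq: ObservedSequence) -> _Section:
    sec = _Section("Model parameters")
    sec.paragraphs.append(
        f"Hidden states: {', '.join(model.states.labels)}  |  "
        f"Alphabet ({model.alphabet.kind.value}): "
        f"{''.join(model.alphabet.symbols)}  |  "
        f"Sequence length L = {len(seq)}"
    )
    if model.name:
        sec.paragraphs.append(f"Model: {model.name}")
    sec.table(
        ["state", "prior"],
        [[lab, _fmt(p)] for lab, p in zip(model.states.labels, model.prior)],
    )
    sec.table(
        ["from \\ to"] + list(model.states.labels),
        [
            [lab] + [_fmt(x) for x in model.transitions[k]]
            for k, lab in enumerate(model.states.labels)
        ],
    )
    sec.table(
        ["state"] + list(model.alphabet.symbols),
        [
            [lab] + [_fmt(x) for x in model.emissions[k]]
            for k, lab in enumerate(model.states.labels)
        ],
    )
    return sec


def _expanded_positions(L: int) -> list[int]:
    if L <= _FULL_EXPANSION_MAX_L:
        return list(range(L))
    return list(range(_HEAD)) + list(range(L - _TAIL, L))


def _value_table(sec: _Section, name: str, table: np.ndarray, labels, mode: str) -> None:
    vals = np.exp(table) if mode == "log" else table
    header = ["pos"] + [f"{name}[j,{lab}]" for lab in labels]
    rows = [
        [str(j + 1)] + [_fmt(v) for v in vals[j]] for j in range(table.shape[0])
    ]
    sec.table(header, rows)


def _expand_forward(sec, model, seq, table, mode) -> None:
    vals = np.exp(table) if mode == "log" else table
    labels = model.states.labels
    lines = []
    for j in _expanded_positions(len(seq)):
        o = seq.symbols[j]
        for l, lab in enumerate(labels):
            if j == 0:
                lines.append(
                    f"alpha[1,{lab}] = prior({lab}) * e({lab},{o}) = "
                    f"{_fmt(model.prior[l])} * {_fmt(model.emission_column(o)[l])} "
                    f"= {_fmt(vals[0, l])}"
                )
            else:
                terms = " + ".join(
                    f"{_fmt(vals[j - 1, k])}*{_fmt(model.transitions[k, l])}"
                    for k in range(len(labels))
                )
                lines.append(
                    f"alpha[{j + 1},{lab}] = e({lab},{o}) * ({terms}) = {_fmt(vals[j, l])}"
                )
    sec.preformatted.extend(lines)


def _forward_section(model, seq, res: ForwardResult) -> _Section:
    sec = _Section("Forward algorithm")
    sec.paragraphs.append(
        "Question: what is the probability of the observed sequence under "
        "the model, P(O), summed over all hidden paths?"
    )
    sec.paragraphs.append(
        "Recursion: alpha[1,k] = prior(k)*e(k,o_1); "
        "alpha[j,l] = e(l,o_j) * sum_k alpha[j-1,k]*a(k->l); "
        "P(O) = sum_k alpha[L,k]."
    )
    _expand_forward(sec, model, seq, res.table, res.mode)
    _value_table(sec, "alpha", res.table, res.state_labels, res.mode)
    sec.paragraphs.append(f"Result: P(O) = {_sci_from_log(res.log_probability)}")
    return sec


def _viterbi_section(model, seq, res: ViterbiResult) -> _Section:
    sec = _Section("Viterbi algorithm")
    sec.paragraphs.append(
        "Question: which single sequence of hidden states Q* most probably "
        "emitted the observed sequence?"
    )
    sec.paragraphs.append(
        "Recursion: delta[1,k] = prior(k)*e(k,o_1); "
        "delta[j,l] = e(l,o_j) * max_k delta[j-1,k]*a(k->l); "
        "traceback from argmax_k delta[L,k]."
    )
    _value_table(sec, "delta", res.table, res.state_labels, res.mode)
    obs, path = str(seq), res.path_string()
    for start in range(0, len(obs), _BLOCK):
        end = min(start + _BLOCK, len(obs))
        left, right = str(start + 1), str(end)
        gap = end - start - len(left) - len(right)
        ruler = left + " " * gap + right if gap >= 1 else f"{left}..{right}"
        sec.preformatted.append(f"pos   {ruler}")
        sec.preformatted.append(f"seq   {obs[start:end]}")
        sec.preformatted.append(f"Q*    {path[start:end]}")
        sec.preformatted.append("")
    sec.paragraphs.append(
        f"Result: P(Q*,O) = {_sci_from_log(res.log_joint)}; "
        f"P(Q*|O) = {_fmt(res.conditional)}"
    )
    return sec


def _backward_section(model, seq, res: BackwardResult, post: PosteriorMatrix | None) -> _Section:
    sec = _Section("Backward algorithm and posterior decoding")
    sec.paragraphs.append(
        "Question: what is the probability that hidden state k emitted the "
        "observed symbol at position j, given the whole sequence?"
    )
    sec.paragraphs.append(
        "Recursion: beta[L,k] = 1; "
        "beta[j,k] = sum_l a(k->l)*e(l,o_{j+1})*beta[j+1,l]; "
        "gamma[j,k] = alpha[j,k]*beta[j,k] / P(O)."
    )
    _value_table(sec, "beta", res.table, res.state_labels, res.mode)
    sec.paragraphs.append(
        f"Check: P(O) recomputed from position 1 = {_sci_from_log(res.log_probability)}"
    )
    if post is not None:
        df = posterior_table(post)
        sec.table(
            ["pos"] + list(df.columns),
            [
                [str(idx)] + [v if isinstance(v, str) else _fmt(v) for v in row]
                for idx, row in zip(df.index, df.itertuples(index=False))
            ],
        )
    return sec


def _posterior_only_section(post: PosteriorMatrix) -> _Section:
    sec = _Section("Posterior decoding")
    df = posterior_table(post)
    sec.table(
        ["pos"] + list(df.columns),
        [
            [str(idx)] + [v if isinstance(v, str) else _fmt(v) for v in row]
            for idx, row in zip(df.index, df.itertuples(index=False))
        ],
    )
    return sec


def render_report(
    model: HMMModel,
    seq: ObservedSequence,
    results=(),
    format: str = "text",
) -> str:
    """Render a report for any subset of computed results.

    ``results`` may contain a :class:`ForwardResult`, a
    :class:`BackwardResult`, a :class:`ViterbiResult` and/or a
    :class:`PosteriorMatrix`, in any order; sections appear in the
    canonical order Forward, Viterbi, Backward/posterior.  ``format`` is
    ``text``, ``markdown`` or ``html``.  Results computed on a different
    model or sequence are rejected.
    """
    if format not in ("text", "plain-text", "markdown", "html"):
        raise ValueError(f"unknown report format {format!r}")
    results = list(results)
    _check_provenance(model, seq, results)

    by_type = {type(r): r for r in results}
    fwd = by_type.get(ForwardResult)
    vit = by_type.get(ViterbiResult)
    bwd = by_type.get(BackwardResult)
    post = by_type.get(PosteriorMatrix)

    sections = [_header_section(model, seq)]
    if fwd is not None:
        sections.append(_forward_section(model, seq, fwd))
    if vit is not None:
        sections.append(_viterbi_section(model, seq, vit))
    if bwd is not None:
        sections.append(_backward_section(model, seq, bwd, post))
    elif post is not None:
        sections.append(_posterior_only_section(post))

    if format in ("text", "plain-text"):
        return _emit_text(sections)
    if format == "markdown":
        return _emit_markdown(sections)
    return _emit_html(sections)


def _emit_text(sections: list[_Section]) -> str:
    out: list[str] = []
    for sec in sections:
        out.append(sec.title)
        out.append("=" * len(sec.title))
        for p in sec.paragraphs:
            out.append(p)
        for header, rows in sec.tables:
            widths = [
                max(len(header[c]), *(len(r[c]) for r in rows)) if rows else len(header[c])
                for c in range(len(header))
            ]
            out.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
            for r in rows:
                out.append("  ".join(v.ljust(w) for v, w in zip(r, widths)))
        out.extend(sec.preformatted)
        out.append("")
    return "\n".join(out)


def _emit_markdown(sections: list[_Section]) -> str:
    out: list[str] = []
    for sec in sections:
        out.append(f"## {sec.title}")
        out.append("")
        for p in sec.paragraphs:
            out.append(p)
            out.append("")
        for header, rows in sec.tables:
            out.append("| " + " | ".join(header) + " |")
            out.append("|" + "|".join("---" for _ in header) + "|")
            for r in rows:
                out.append("| " + " | ".join(r) + " |")
            out.append("")
        if sec.preformatted:
            out.append("```")
            out.extend(sec.preformatted)
            out.append("```")
            out.append("")
    return "\n".join(out)


def _emit_html(sections: list[_Section]) -> str:
    from html import escape

    out = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>HMM report</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:"
        "collapse}td,th{border:1px solid #999;padding:2px 6px;font-family:"
        "monospace}pre{background:#f5f5f5;padding:0.5em}</style></head><body>",
    ]
    for sec in sections:
        out.append(f"<h2>{escape(sec.title)}</h2>")
        for p in sec.paragraphs:
            out.append(f"<p>{escape(p)}</p>")
        for header, rows in sec.tables:
            out.append("<table><tr>" + "".join(f"<th>{escape(h)}</th>" for h in header) + "</tr>")
            for r in rows:
                out.append("<tr>" + "".join(f"<td>{escape(v)}</td>" for v in r) + "</tr>")
            out.append("</table>")
        if sec.preformatted:
            out.append("<pre>" + escape("\n".join(sec.preformatted)) + "</pre>")
    out.append("</body></html>")
    return "\n".join(out)


def posterior_chart_data(gamma: PosteriorMatrix) -> dict[str, np.ndarray]:
    """One probability series per hidden state over positions 1..L —
    the data behind a posterior-decoding chart."""
    return {
        lab: gamma.gamma[:, k].copy() for k, lab in enumerate(gamma.state_labels)
    }


def posterior_table(gamma: PosteriorMatrix) -> pd.DataFrame:
    """Posterior matrix as a DataFrame: 1-based position index, one column
    per hidden state, plus the per-position argmax state."""
    df = pd.DataFrame(
        gamma.gamma,
        columns=list(gamma.state_labels),
        index=pd.RangeIndex(1, gamma.gamma.shape[0] + 1, name="position"),
    )
    df["argmax"] = list(gamma.argmax_path)
    return df


def plot_posterior(gamma: PosteriorMatrix, ax=None):
    """Plot the posterior-decoding chart (state probability vs position)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    for lab, series in posterior_chart_data(gamma).items():
        ax.plot(np.arange(1, len(series) + 1), series, label=lab)
    ax.set_xlabel("sequence position")
    ax.set_ylabel("posterior probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(title="hidden state")
    return ax
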