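# Methods

## Model

`hmmtutor` implements discrete first-order hidden Markov models. A model is
the tuple (Σ, S, π, A, E): an alphabet Σ of observed symbols, K hidden
states S, a prior vector π over the first hidden state, a K×K transition
matrix A with a(k→l) = P(q_{j+1}=l | q_j=k), and a K×|Σ| emission matrix E
with e(k, b) = P(o_j=b | q_j=k). The hidden chain is homogeneous and
first-order; there are no Begin/End states, no tied parameters, and
emissions are categorical. Positions are reported 1-based everywhere a user
sees them.

Given an observed sequence O of length L, three questions are answered:

* **Forward** — P(O) = Σ_Q P(Q, O), via
  α[1,k] = π(k)·e(k,o₁), α[j,l] = e(l,o_j)·Σ_k α[j−1,k]·a(k→l),
  P(O) = Σ_k α[L,k].
* **Backward** — β[L,k] = 1, β[j,k] = Σ_l a(k→l)·e(l,o_{j+1})·β[j+1,l];
  recomputing P(O) = Σ_k π(k)·e(k,o₁)·β[1,k] from position 1 is a built-in
  consistency check.
* **Viterbi** — the single best path via the same recursion with max in
  place of sum, with traceback pointers. The reported headline number is
  the conditional P(Q*|O) = exp(log P(Q*,O) − log P(O)), which is
  comparable across runs, alongside the joint.

Posterior decoding combines the two tables:
γ[j,k] = α[j,k]·β[j,k] / P(O), the probability that state k produced
position j given the whole sequence. The per-position argmax of γ is
reported as a curve summary; it is not in general a legal path under A —
Viterbi answers the best-path question.

## Numerics

* **Log space is the default.** Plain probability space underflows double
  precision for realistic lengths (the bundled 100-residue example already
  sits near 10⁻¹²³); log mode stores log probabilities with −∞ as the exact
  sentinel for impossible events and uses `scipy.special.logsumexp` for the
  Forward/Backward sums. Plain mode is kept because its intermediate values
  are readable in classroom reports. On instances where plain mode does not
  underflow the two modes agree to ≲1e−9 relative (measured ~1e−15).
* **Normalization tolerance** |Σ − 1| ≤ 1e−9 for the prior and every matrix
  row. Violations are reported with the offending row and deviation, never
  silently renormalized; `build_model(..., renormalize=True)` is an
  explicit opt-in.
* **Zero probabilities are legal anywhere** — the membrane example requires
  a(I→O) = a(O→I) = 0. A (model, sequence) pair with P(O) = 0 raises a
  diagnostic in Viterbi and posterior decoding rather than returning NaNs.
* **Viterbi ties** are broken toward the state earliest in the declared
  state order, both in the max and the traceback (`argmax` takes the first
  maximum), so output is deterministic even for fully symmetric parameters.
  The enumeration oracle sorts ties by state-index lexicographic order,
  which is the same rule, so the two routes agree exactly under ties.
* **Random models** draw each probability row as independent uniform(0,1)
  variates normalized to sum 1 (a flat Dirichlet) from numpy's PCG64
  (`default_rng(seed)`); identical seeds reproduce parameters bit-for-bit,
  and model files round-trip exactly because floats are serialized at full
  `repr` precision.

## Verification strategy

The independent reference is a brute-force oracle (`hmmtutor.oracle`) that
enumerates all K^L hidden paths and scores each with the closed-form joint
probability. Forward/Backward totals, the Viterbi path and joint, and every
posterior entry are compared against it at 1e−9 relative tolerance over
hundreds of random instances with K ≤ 3, |Σ| ≤ 4, L ≤ 6 (hypothesis,
derandomized, plus a fixed 200-instance sweep). Additional invariants:
probability conservation (Σ over all |Σ|^L observable sequences of P(O) = 1
for K=2, |Σ|=2, L=4), forward–backward agreement with
Σ_k α[j,k]·β[j,k] = P(O) at every position, Viterbi dominance
P(Q*,O) ≤ P(O), and posterior row normalization. One test cross-checks the
forward log-likelihood against hmmlearn's `CategoricalHMM.score` as an
external implementation. These sizes keep the whole suite under ~10 s on
one CPU while covering the recursion's base case, single-state and
single-position degeneracies, and zero-probability structure.

## The bundled transmembrane example

The fixture `tm_p18599` models membrane-protein topology with three hidden
states — Inside (I), Membrane (M), Outside (O) — over the protein alphabet,
applied to the 100-residue N-terminal fragment of the 5-hydroxytryptamine
receptor 2A (UniProtKB P18599). Its parameters are **synthetic surrogates**
(the fixture file says so in its header): they were constructed once from
first principles rather than transcribed from any published parameter set,
which is not redistributed here.

* Transitions: a(I→O) = a(O→I) = 0 exactly — a chain cannot cross the
  membrane without traversing it — with self-transitions 0.98 (I), 0.90 (M),
  0.97 (O), so segments are long relative to single residues.
* Emissions: the M row is a Kyte–Doolittle hydropathy-weighted composition
  (background · exp(KD/2), normalized), giving the membrane state its
  hydrophobic bias; the I row boosts K/R 1.6× over Swiss-Prot background
  (positive-inside rule); the O row boosts polar residues.
* Prior (0.5, 0.1, 0.4): a chain rarely starts mid-membrane.

Under these parameters the toolkit computes log₁₀ P(O) ≈ −123.3, a Viterbi
path with no I↔O adjacency ending in a terminal membrane run from position
79 (the fragment's C-terminal hydrophobic helix), and a posterior chart in
which M is the argmax state throughout that tail. These are honest outputs
of the surrogate parameters; with a differently trained parameter set the
exact magnitude of P(O) and the exact segment boundary would differ, which
is precisely the pedagogical point — the parameters are the heart of the
model. What the passing tests show is that the machinery is exact
(oracle-verified) and that the structural zero-transition constraint
propagates correctly; they do not certify any particular biological
parameterization.

## What the synthetic data does and does not emulate

Random models (flat Dirichlet rows) exercise the full simplex, including
near-zero entries, but are unlike trained biological parameter sets, which
are sparse and strongly diagonal. The fixture adds the structural-zero and
near-diagonal regime. Not emulated: higher-order dependencies, ambiguity
codes (a symbol outside the alphabet is an error by default; an opt-in maps
unknowns to a uniform emission column), position-specific emissions, and
the sliding-window posterior smoothing some production topology predictors
apply.

## Report rendering

Reports echo the model parameters, then show each algorithm's recursion,
its value table, and the final result. Displayed numbers are rounded copies
(4 significant digits; scientific notation below 1e−4; P(O) always in
scientific notation, computed from the log so it renders even below the
double-precision underflow threshold). For L ≤ 15 every cell's arithmetic
is expanded operand-by-operand; longer sequences expand the first 3 and
last 2 positions around the full value table. The Viterbi string is
rendered in 60-column blocks with position rulers, aligned under the
observed sequence. Output formats: plain text, Markdown, and a
self-contained HTML file.

## Known limitations

Plain mode underflows near L ≈ 1000; the enumeration oracle is capped at
10⁶ paths by design; no Baum–Welch/Viterbi training, no N-best paths, no
banded DP, no Begin/End states.
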