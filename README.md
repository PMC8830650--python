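# hmmtutor

A discrete first-order hidden Markov model (HMM) toolkit built for
teaching and for small, fully inspectable models: define the six model
elements, validate them, run the three classic inference algorithms, and
get a step-by-step report of every calculation.

It is aimed at students and instructors working through HMM modeling by
hand — for example the classic exercise of predicting transmembrane
topology in a protein sequence with three hidden states, Inside (I),
Membrane (M) and Outside (O) — and at anyone who wants a small, exact,
well-tested discrete HMM library with a brute-force oracle to check
against.

## The model and its questions

A discrete HMM is (Σ, S, π, A, E): an alphabet Σ of observed symbols
(DNA, RNA, protein, or custom), hidden states S, a prior vector π, a
transition matrix A with a(k→l) = P(q_{j+1}=l | q_j=k), and an emission
matrix E with e(k,b) = P(o_j=b | q_j=k). For an observed sequence O of
length L the package answers:

* **Forward** — P(O) = Σ_Q P(Q,O): how probable is the sequence under the
  model? (α recursion, log-space by default.)
* **Viterbi** — argmax_Q P(Q,O): the single most probable hidden path,
  reported with P(Q\*|O) = exp(log P(Q\*,O) − log P(O)).
* **Backward / posterior decoding** — γ[j,k] = α[j,k]·β[j,k]/P(O): the
  probability that state k produced position j, plotted per position as
  the posterior-decoding chart.

Every dynamic-programming result is verified against an exhaustive
path-enumeration oracle (`hmmtutor.oracle`) at 1e−9 relative tolerance on
hundreds of random small instances.

## Worked example

The bundled fixture `tm_p18599` is a 3-state membrane-topology model over
the protein alphabet applied to the 100-residue N-terminal fragment of
the 5-hydroxytryptamine receptor 2A (UniProtKB P18599). Its parameters
are clearly labeled **synthetic surrogates** — hydropathy-derived
emissions and transitions with a(I→O) = a(O→I) = 0 — constructed from
first principles, not transcribed from a trained predictor.

```python
import hmmtutor as ht

bundle = ht.load_fixture("tm_p18599")
fwd = ht.forward(bundle.model, bundle.sequence)
vit = ht.viterbi(bundle.model, bundle.sequence)
print(ht.render_report(bundle.model, bundle.sequence, [fwd, vit]))
```

The report ends with (excerpt):

```
Result: P(O) = 4.608e-124
Result: P(Q*,O) = 1.596e-125; P(Q*|O) = 0.03463
pos   1                                                         60
seq   MEILCEDNTSLSSIPNSLMQVDGDSGLYRNDFNSRDANSSDASNWTIDGENRTNLSFEGY
Q*    OOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOOO
pos   61                                   100
seq   LPPTCLSILHLQEKNWSALLTAVVIILTIAGNILVIMAVS
Q*    OOOOOOOOOOOOOOOOOOMMMMMMMMMMMMMMMMMMMMMM
```

Reading the numbers: P(O) ≈ 4.6·10⁻¹²⁴ is the total probability of the
100-residue sequence summed over all 3¹⁰⁰ hidden paths — tiny in absolute
terms, as any long sequence's probability is, and meaningful only
compared across models or sequences. The best single path carries about
3.5% of that mass (P(Q\*|O) = 0.0346) and assigns the C-terminal
hydrophobic stretch to the membrane state from position 79 onward, with
no I↔O adjacency anywhere — impossible by construction, since those
transitions are zero. The same run from the shell:

```sh
hmmtutor fixture tm_p18599 --posterior-out posterior.tsv
hmmtutor random -k 3 -a protein --seed 7 -o model.yaml
hmmtutor run -m model.yaml -s MEILCEDNTSL
hmmtutor validate model.yaml
```

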