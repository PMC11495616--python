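# mdlmotifs

Compression-based inference of network motif sets in directed graphs.

## The problem

Network motifs — small subgraphs that recur more often than chance — are a
central object in systems biology, from transcription networks to
synapse-resolution connectomes. The classical way to find them is to count
each *graphlet* (an isomorphism class of small weakly connected directed
subgraphs) and compare the count against randomized graphs under a chosen
null model. That procedure cannot compare the significance of different
motifs, struggles with multiple testing across the ~10⁴ five-node
graphlets, and its output depends strongly on an essentially arbitrary
null-model choice.

`mdlmotifs` instead treats motif mining as lossless compression. A set of
motifs is good exactly when contracting its occurrences lets the graph be
described in fewer bits. This yields a single scale (bits) on which motif
sets, degree structure and edge reciprocity compete, a built-in control of
multiple testing and correlations through the minimum description length
(MDL) principle, and a significance bound with no null-model simulations.

## The model

The observed simple digraph `G` is described by a reduced multigraph `H`
obtained by contracting node-disjoint induced subgraphs into *supernodes*,
each colored by the graphlet it stands for. The total description length
of the state θ = (H, φ, S, V, Γ) is

```
L(G, θ) = L(Γ, S) + L(H, φ) + L(V | H, S) + L(G | H, V, S, Γ)
```

* `L(Γ, S)` — identities and multiplicities of the motif multiset `S`
  within the dictionary Γ (all 9 576 graphlets on 3–5 nodes by default);
* `L(H, φ) = S_φ(H) + L(φ)` — a two-part code for the reduced multigraph
  under one of four microcanonical base models: Erdős–Rényi (ER), the
  directed configuration model (CM), and their reciprocal variants (RER,
  RCM) which additionally fix the reciprocated-edge structure;
* `L(V | H, S)` — which nodes of `H` are supernodes and their colors;
* `L(G | H, V, S, Γ)` — recovering node labels, each contracted
  subgraph's orientation (`log₂ n!/|Aut|` bits), and how every multiedge
  of `H` wires into the contracted subgraphs (binomial rewiring costs).

Motif-free *reference* codes encode `G` directly with the matching
simple-graph ensembles; a motif set is significant only if it beats the
best of these dyadic descriptions. The no-hypercompression inequality
turns the margin `K` in bits into a p-value bound `p ≤ 2⁻ᴷ`.

Because exhaustively searching motif sets is hopeless, a stochastic greedy
algorithm samples a minibatch of up to `B` surviving census occurrences
per graphlet at each step, contracts the one with the largest codelength
gain (evaluated incrementally and validated against full recomputation),
and returns the trajectory minimum; the search is repeated over seeds and
base models and the overall shortest description wins.

The package also ships the validation machinery: an exhaustive ESU
subgraph census with a canonical-form dictionary, exact null-model
samplers (edge throws for ER/RER, degree-preserving edge-swap chains with
3-cycle reversals for CM/RCM), a planted-motif generator that inverts the
compression scheme, the classical hypothesis-testing baseline, and
topological summaries of inferred motif sets.

## Worked example

`examples/infer_planted_clique.py` plants 12 five-node cliques in a sparse
300-node background and runs the full selection:

```
$ python examples/infer_planted_clique.py
generated graph: N=300, E=2242, 12 planted copies of d5-fffff

selected model: ER+Motifs
motif multiset m_alpha: {'d5-fffff': 12}
compressibility Delta L* = 1316.4 bits
margin over best motif-free model Delta L_motifs = 707.9 bits
no-hypercompression p-value bound: 7.79e-214
```

All 12 planted cliques are recovered (`d5-fffff` is the canonical id of
the complete 5-node digraph). `ΔL*` is the saving relative to encoding
each edge independently; `ΔL_motifs = 707.9` bits is the part attributable
to the motif structure itself, so the probability that a motif-free graph
would compress this well is at most `2⁻⁷⁰⁸ ≈ 8·10⁻²¹⁴`.

The other scripts in `examples/` are one capability each: the graphlet
dictionary, the four-part codelength decomposition, stringency on
motif-free null networks versus the hypothesis-testing baseline, and
motif-set topology statistics.

For shell use there is a thin CLI:

```
mdlmotifs infer connectome.tsv --sizes 3 4 --runs 100 --seed 1 -o report.json
mdlmotifs census connectome.tsv --sizes 3 4 -o counts.json
mdlmotifs ht connectome.tsv --null rcm --n-null 20 -o ht.json
```

Reports are JSON with a schema version and a full configuration echo; node
labels from the input edge list are preserved in all outputs.

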