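# Methods

## Model

`mdlmotifs` scores a candidate motif set for a simple directed graph `G`
(no self-loops, nodes labeled) by the number of bits needed to describe
`G` losslessly through a reduced representation. The state
θ = (H, φ, S, V, Γ) consists of a reduced multigraph `H` obtained by
contracting node-disjoint induced subgraphs of `G` into supernodes, the
multiset `S` of graphlets those subgraphs belong to, the supernode set
`V`, the base-model features φ of `H`, and the graphlet dictionary Γ.
The total description length decomposes as

```
L(G, θ) = L(Γ, S) + L(H, φ) + L(V | H, S) + L(G | H, V, S, Γ)
```

* **Motif set.** `L(Γ, S) = |A| log₂|Γ| + L_N(|Γ|) + |A| log₂ m_max +
  L_N(m_max)`, where `A` is the set of distinct motifs, `m_max` the
  largest multiplicity, and `L_N(n) = log₂[n(n+1)]` the universal integer
  code. An empty motif set costs nothing, which makes the optimizer's
  start state well defined.
* **Reduced multigraph.** `L(H, φ) = S_φ(H) + L(φ)`, a two-part code
  under one of four dyadic ensembles: Erdős–Rényi (φ = (N, E)), the
  directed configuration model (φ = (k⁺, k⁻)), the reciprocal
  Erdős–Rényi model (φ = (N, E_m, E_d), fixing the reciprocated-pair and
  single-edge counts, with a multiedge's reciprocal part defined as
  min(A_ij, A_ji)), and the reciprocal configuration model
  (φ = (κᵐ, κ⁺, κ⁻), fixing per-node reciprocal and non-reciprocated
  degrees).
* **Supernode labels.** `L(V|H,S) = log₂ C(N(H), |S|) +
  log₂(|S|!/∏ m_α!)`: which nodes of `H` are supernodes and which
  graphlet colors they carry.
* **Reconstruction.** `log₂[N(G)!/N(H)!]` to recover node labels, plus
  `log₂(n_α!/|Aut(α)|)` per contracted subgraph for its orientation, plus
  a rewiring cost per supernode: a multiedge of multiplicity `a` to a
  plain neighbor costs `log₂ C(n_s, a)` per direction (which of the `n_s`
  internal nodes carry the edges) and a multiedge towards another
  supernode costs `log₂ C(n_s n_s', a)`.

Motif-free *reference* codes encode `G` directly with the matching
simple-graph ensembles; a motif set is only reported when its best
motif-based description beats the best reference. The compressibility
ΔL\* is measured against the simple Erdős–Rényi reference (encode each
edge independently), and the motif margin ΔL_motifs against the best
motif-free model; by the no-hypercompression inequality the probability
that a motif-free graph compresses ΔL_motifs bits better than its true
description is at most 2^(−ΔL_motifs).

## Entropy formulas and their conventions

The multigraph entropies are the negative log-probabilities of uniform
stub-matching/edge-throw constructions:

* ER: `E log₂[N(N−1)] − log₂ E! + Σ log₂ A_ij!` (multinomial edge throw;
  exact, Kraft sum = 1).
* CM: `log₂ E! − Σᵢ log₂ k⁺ᵢ! k⁻ᵢ! + Σ log₂ A_ij!` (out-stub/in-stub
  matching). The sign of the multiplicity term follows the stub-matching
  probability — the ensemble that contains a single multigraph (e.g. two
  nodes joined by a double edge) must cost zero bits, and the Kraft sums
  over brute-force-enumerable ensembles must not exceed one. Both
  conditions are tested.
* RER: reciprocal pairs thrown over unordered node pairs,
  `(2E_m)!! = 2^{E_m} E_m!`, single edges over ordered pairs.
* RCM: reciprocal stubs matched pairwise (`(2E_m−1)!!` matchings) and
  directed stubs separately (`E_d!`).

The simple-graph ER and RER entropies are exact binomial/multinomial
counts; the simple CM and RCM entropies use the standard asymptotic
counts with a second-order correction term and may be slightly negative
on tiny degenerate graphs (moments in the corrections are plain averages
over nodes; any correction fraction with a zero denominator is taken as
zero). The parametric complexities are shared between multigraph and
simple variants; degree sequences are encoded with the best of a uniform
per-symbol code and two Dirichlet-multinomial prequential codes
(concentration λ ∈ {1, ½}) over the observed integer support, plus the
code identity (log₂ 3) and the sequence length. For λ → ∞ the
Dirichlet-multinomial code approaches the uniform code, which is tested.

Two numerical conventions are deliberate choices:

* **Zeros under the integer code.** `L_N` is undefined at 0, but encoded
  quantities such as E_m, E_d, the minimum of a degree sequence, or the
  edge count of a fully contracted graph can be 0. Zeros are charged
  `L_N(1) = 1` bit. Any alternative (e.g. shifting every zero-capable
  integer by one) changes totals by a few bits at most and never changes
  a model comparison at the scales involved.
* **Entropy hierarchy caveat.** Constraining more features can only
  shrink a microcanonical ensemble, so ideally S_RCM ≤ S_RER ≤ S_ER and
  S_RCM ≤ S_CM ≤ S_ER. The closed-form codes realize this hierarchy in
  the sparse regime (E² ≪ N(N−1)); at higher densities the reciprocal
  codes pay an interleaving penalty of roughly `E_m log₂[E²/(N(N−1))]`
  bits, because they encode the reciprocal and single-edge streams
  separately, and can then exceed the ER multinomial code. This does not
  affect correctness — all four are valid (Kraft-satisfying) codes and
  model selection compares them directly — but the hierarchy property
  test is restricted to the sparse regime where it provably holds.

All codelengths use base-2 logarithms, log-factorials via lgamma, double
precision throughout; unit tests compare exact expressions at 1e-9 and
cross-implementation checks at 1e-6 bits.

## Search

Exhaustively optimizing over motif sets is infeasible (the 3–5-node
dictionary alone has 9 576 classes, enumerated by orbit-marking over all
labeled digraphs; canonical forms are minimum adjacency bitstrings over
all node permutations, memoized, with no external isomorphism library).
The search is stochastic greedy:

1. An exhaustive ESU census lists every connected induced subgraph of
   the requested sizes exactly once, classified by canonical form.
   Occurrence lists are held in memory with a configurable warning
   threshold and hard cap; when a size's requested graphlets reduce to
   the complete digraph, occurrences are found by clique search in the
   reciprocal-edge graph instead of full enumeration.
2. Each iteration samples up to B occurrences per graphlet uniformly
   without replacement from the surviving census (default B = 25;
   results are insensitive across roughly 10–100), discards sampled
   occurrences that overlap an existing supernode permanently, contracts
   the batch candidate with the largest codelength gain (ties broken by
   smallest graphlet, then smallest node subset), and returns the other
   batched candidates that still avoid all supernodes to the pool.
   Discarding batched-but-uncontracted candidates permanently would cap
   a motif's attainable multiplicity at roughly |C_α|/B per run, which
   would make repeated planted motifs unrecoverable; re-insertion keeps
   the inferred multiplicities tracking the true repetition counts.
3. The run continues past codelength increases until no non-overlapping
   occurrence remains, and returns the trajectory minimum. Gains are
   evaluated incrementally from running summaries (edge counts,
   reciprocity decomposition, per-value degree tallies, log-factorial
   sums, rewiring and orientation totals); the incremental evaluation is
   validated against full recomputation to 1e-6 bits on hundreds of
   random contractions.
4. Model selection runs `n_runs` seeded greedy runs per base family
   (each run gets an independent substream spawned from the master
   seed; the census is computed once and shared read-only) and compares
   the best run codelengths against the four motif-free references; the
   overall minimum wins.

## Synthetic data

The **planted-motif generator** inverts the compression scheme: draw a
latent Erdős–Rényi multigraph (edges thrown uniformly over ordered
pairs), mark random latent nodes as supernodes carrying prescribed
graphlets, then expand — internal edges take a uniformly random
distinguishable orientation (uniform over the n!/|Aut| distinct labeled
patterns) and each incident latent multiedge is wired uniformly over the
configurations the rewiring code counts. A latent edge landing on a
saturated pair (a plain-plain pair already carrying an edge, or a
supernode pair at its binomial capacity) is re-thrown individually;
whole-draw rejection has vanishing acceptance probability already at
moderate densities, so the latent law is an ER throw conditioned on
feasibility edge by edge. Node and edge counts of the generated graph
are exact: N = N_latent + Σ m(n_α−1), E = E_latent + Σ m e_α.

The **null randomizers** preserve each family's features exactly: ER and
RER place edges directly (exactly uniform); CM and RCM run Markov chains
of directed double-edge swaps augmented with 3-cycle reversals (double
swaps alone are not ergodic for fixed in/out-degrees), with undirected
swaps on the reciprocal-pair subgraph for RCM and rejection of any move
that would create duplicate or reciprocity-changing edges. Chains run
for a fixed number of proposals (default 40 per edge) rather than a
fixed number of accepted moves: rejections act as self-loops, keeping
the chain aperiodic, whereas conditioning on an exact accepted count can
land in a parity class of small ensembles. A uniformity smoke test
checks visit frequencies against a brute-force ensemble.

The **degree-heterogeneous reciprocal generator** (`connectome_like`)
produces a stand-in for microcircuit wiring diagrams: lognormal in/out
propensities (σ = 1) and a target fraction of reciprocated edges
(default 0.35), matched to the broad degree distributions and high
feedback-connection counts typical of synapse-resolution neural wiring.
It reproduces those two aggregate features only — no spatial embedding,
no cell types, no block structure — so validation results on it speak to
the statistical behavior of the method (false-positive control given
heavy degrees and reciprocity), not to any particular biological
network.

## Hypothesis-testing baseline

The classical comparator counts each graphlet in the observed graph and
in `n_null` randomized samples, forms z = (N_obs − mean)/sd (z = 0 when
the null is degenerate), takes the one-sided Gaussian upper-tail
p-value, and flags a graphlet as a motif when p·|Γ| < α (default
α = 0.01) and the graphlet occurs at all. The Gaussian approximation is
the standard practical choice; exact empirical p-values at
Bonferroni-corrected thresholds would need on the order of a million
null samples. Counts-only censuses go through igraph's motif counter for
sizes 3–4 when available (verified against the in-package enumeration),
since the baseline never needs occurrence lists.

## Validation scales

The test suite runs the full protocol at sizes chosen to finish in
minutes on one core; the statements it verifies are stated at those
sizes:

* Null-model stringency: five graphs per family randomized from one
  degree-heterogeneous reciprocal base graph with N = 198, E = 6 499;
  selection over all four families with one greedy run each on the
  3-node dictionary; the hypothesis-testing comparison uses the
  Erdős–Rényi null on the 3-node dictionary with five null samples.
* Planted recovery: 5-cliques planted at 2, 10 and 20 copies in
  300-node backgrounds of density 0.025, one greedy run per graph under
  the ER base with a dictionary of all 3-node graphlets plus the
  5-clique (a reduced dictionary; the full 3–5-node census of many
  replicates is a cluster-scale computation).
* Oracle checks: 200 random contractions across all four families;
  census versus subset scan on 20-node graphs; Kraft sums on 3-node
  ensembles with up to three edges.

## Known limitations

* Codelengths only — the package never builds an actual bitstream.
* Contractions are node-disjoint; overlapping or nested motifs are out
  of scope, as is MCMC uncertainty quantification around the optimum.
* The exhaustive census holds occurrence lists in memory; a full 5-node
  census of a dense graph with hundreds of nodes exceeds desk-scale
  memory and time budgets (restrict the dictionary or sizes instead).
* The 3-cycle-reversal-augmented swap chains are uniform on their
  reachable class; for the RCM chain, whose state space is constrained
  by both subgraphs simultaneously, full connectivity is not guaranteed
  in pathological cases (the sampler then still preserves φ exactly).
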