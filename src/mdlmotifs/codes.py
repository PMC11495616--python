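"""Exact codelengths for graphs, multigraphs and motif sets.

All codelengths are in bits (base-2 logarithms).  The total description
length of a graph G under a reduction state theta = (H, phi, S, V, Gamma)
decomposes into four parts:

    L(G, theta) = L(Gamma, S) + L(H, phi) + L(V | H, S) + L(G | H, V, S, Gamma)

where L(H, phi) = S_phi(H) + L(phi) is a two-part code for the reduced
multigraph under one of four microcanonical base models (Erdos-Renyi,
configuration model, and their reciprocal variants), L(V|H,S) labels the
supernodes, and the last term pays for recovering node labels, graphlet
orientations, and the wiring of multiedges into the contracted subgraphs.

Motif-free *reference* codes encode the observed simple graph directly
with the corresponding simple-graph ensembles; those are the dyadic null
models the motif-based codes must beat.

Numerical conventions
---------------------
* log-factorials via lgamma; double factorials (2m)!! = 2^m m! and
  (2m-1)!! = (2m)!/(2^m m!), with 0!! = (-1)!! = 1.
* The universal integer code L_N(n) = log2[n(n+1)] is defined for n >= 1;
  quantities that can legitimately be zero (edge counts of a fully
  contracted graph, minima of degree sequences, ...) are charged
  L_N(max(n, 1)), i.e. zeros cost the same one bit as ones.
* The asymptotically corrected simple-graph CM/RCM entropies may be
  slightly negative on tiny degenerate graphs; all other codes are exact
  and nonnegative.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
from scipy.special import gammaln

from .graphs import DirectedGraph, Graphlet, Multigraph

LOG2 = math.log(2.0)

FAMILIES = ("ER", "CM", "RER", "RCM")

__all__ = [
    "FAMILIES",
    "MotifSet",
    "integer_code_length",
    "integer_code_length0",
    "sequence_code_length",
    "base_entropy",
    "simple_entropy",
    "model_complexity",
    "simple_model_complexity",
    "motif_set_code_length",
    "supernode_label_code_length",
    "rewiring_cost",
    "reconstruction_code_length",
    "total_code_length",
    "reference_code_length",
]


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------

def log2_factorial(n: int) -> float:
    if n < 0:
        raise ValueError("factorial of negative integer")
    return math.lgamma(n + 1) / LOG2


def log2_binomial(n: int, k: int) -> float:
    if k < 0 or k > n:
        raise ValueError(f"binomial C({n},{k}) undefined")
    return log2_factorial(n) - log2_factorial(k) - log2_factorial(n - k)


def log2_even_double_factorial(m: int) -> float:
    """log2 (2m)!! = m + log2 m!  (0!! = 1)."""
    if m < 0:
        raise ValueError("negative argument")
    return m + log2_factorial(m)


def log2_odd_double_factorial(m: int) -> float:
    """log2 (2m-1)!! = log2 (2m)! - m - log2 m!  ((-1)!! = 1)."""
    if m < 0:
        raise ValueError("negative argument")
    return log2_factorial(2 * m) - m - log2_factorial(m)


def integer_code_length(n: int) -> float:
    """Universal code for a positive integer, L_N(n) = log2[n(n+1)]."""
    if n < 1:
        raise ValueError(f"integer code requires n >= 1, got {n}")
    return math.log2(n) + math.log2(n + 1)


def integer_code_length0(n: int) -> float:
    """Integer code extended to n = 0 (charged as 1, costing 1 bit)."""
    if n < 0:
        raise ValueError("negative integer")
    return integer_code_length(max(n, 1))


# ---------------------------------------------------------------------------
# Sequence code: min over a uniform code and two Dirichlet-multinomial codes
# ---------------------------------------------------------------------------

def _seq_candidates(counts: np.ndarray, n: int, lo: int, hi: int) -> float:
    """Minimum over the three candidate codes for a sequence with value
    counts ``counts`` over the integer support [lo, hi]."""
    support = hi - lo + 1
    uniform = (
        n * math.log2(support)
        + integer_code_length0(hi)
        + integer_code_length0(lo)
    )
    best = uniform
    for lam in (1.0, 0.5):
        cap_lambda = support * lam
        code = (
            (math.lgamma(n + cap_lambda) - math.lgamma(cap_lambda)) / LOG2
            + support * (math.lgamma(lam) / LOG2)
            - float(np.sum(gammaln(counts + lam))) / LOG2
        )
        best = min(best, code)
    return best


def sequence_code_length(x: Sequence[int]) -> float:
    """Parametric code for a sequence of nonnegative integers.

    L_seq(x) = min{L_U, L_{lambda=1}, L_{lambda=1/2}} + log2(3) + L_N(n):
    the best of a uniform per-symbol code and two prequential
    Dirichlet-multinomial codes over the observed support, plus the code
    identity and the sequence length.  Depends only on the multiset of
    values.
    """
    arr = np.asarray(x, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty sequence")
    if np.any(arr < 0):
        raise ValueError("sequence entries must be nonnegative")
    lo = int(arr.min())
    hi = int(arr.max())
    counts = np.bincount(arr - lo, minlength=hi - lo + 1).astype(np.float64)
    n = int(arr.size)
    return (
        _seq_candidates(counts, n, lo, hi)
        + math.log2(3.0)
        + integer_code_length(n)
    )


def sequence_code_from_counts(counts: np.ndarray) -> float:
    """Same code evaluated from an array of value counts indexed by value
    (index 0 = count of zeros).  Used on hot paths where the counts are
    maintained incrementally."""
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        raise ValueError("empty sequence")
    lo, hi = int(nz[0]), int(nz[-1])
    n = int(counts.sum())
    return (
        _seq_candidates(counts[lo : hi + 1].astype(np.float64), n, lo, hi)
        + math.log2(3.0)
        + integer_code_length(n)
    )


# ---------------------------------------------------------------------------
# Motif set
# ---------------------------------------------------------------------------

@dataclass
class MotifSet:
    """A multiset S of graphlets with multiplicities m_alpha."""

    counts: Counter = field(default_factory=Counter)  # Graphlet -> m_alpha

    @classmethod
    def from_graphlets(cls, graphlets: Iterable[Graphlet]) -> "MotifSet":
        return cls(Counter(graphlets))

    @property
    def size(self) -> int:
        """|S| = total number of contracted subgraphs."""
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def m_max(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    def __bool__(self) -> bool:
        return bool(self.counts)


def motif_set_code_length(ms: MotifSet, gamma_size: int) -> float:
    """L(Gamma, S): identity of each unique motif (log|Gamma| each), the
    number |Gamma|, the multiplicity of each motif (log m_max each) and
    m_max itself.  An empty motif set costs nothing by convention."""
    if gamma_size < 1:
        raise ValueError("gamma_size must be >= 1")
    if not ms:
        return 0.0
    a = ms.n_unique
    m_max = ms.m_max
    return (
        a * math.log2(gamma_size)
        + integer_code_length(gamma_size)
        + a * math.log2(m_max)
        + integer_code_length(m_max)
    )


def supernode_label_code_length(n_h: int, ms: MotifSet) -> float:
    """L(V|H,S): choosing which |S| of the N(H) nodes are supernodes and
    which graphlet each one carries."""
    s = ms.size
    if s > n_h:
        raise ValueError("more supernodes than nodes in H")
    if s == 0:
        return 0.0
    return (
        log2_binomial(n_h, s)
        + log2_factorial(s)
        - sum(log2_factorial(m) for m in ms.counts.values())
    )


# ---------------------------------------------------------------------------
# Base-model entropies (multigraph) and simple-graph entropies
# ---------------------------------------------------------------------------

def _check_family(family: str) -> str:
    family = family.upper()
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    return family


def base_entropy(h: Multigraph, family: str) -> float:
    """Microcanonical entropy S_phi of the multigraph H under the given
    base family, i.e. -log2 of the probability of H under the matching
    uniform stub/throw ensemble.

    ER throws E edges uniformly over ordered node pairs; CM matches
    out-stubs to in-stubs; RER throws E_m reciprocal pairs and E_d single
    edges; RCM matches reciprocal stubs pairwise and directed stubs
    separately.  Parallel edges divide the probability by prod A_ij!.
    """
    family = _check_family(family)
    n = h.n
    pairs = n * (n - 1)
    sum_lf_a = sum(log2_factorial(m) for _, m in h.items() if m > 1)
    if family == "ER":
        e = h.n_edges
        if e == 0:
            return 0.0
        return e * math.log2(pairs) - log2_factorial(e) + sum_lf_a
    if family == "CM":
        e = h.n_edges
        kout = h.out_degrees()
        kin = h.in_degrees()
        return (
            log2_factorial(e)
            - sum(log2_factorial(k) for k in kout)
            - sum(log2_factorial(k) for k in kin)
            + sum_lf_a
        )
    em, ed = h.reciprocity_stats()
    sum_lf_pairs = sum(
        log2_factorial(sym) + log2_factorial(aij) + log2_factorial(aji)
        for _, sym, aij, aji in h._pair_stats()
    )
    if family == "RER":
        if em + ed == 0:
            return 0.0
        return (
            (em + ed) * math.log2(pairs)
            - log2_even_double_factorial(em)
            - log2_factorial(ed)
            + sum_lf_pairs
        )
    # RCM
    km, kp, kq = h.reciprocal_degrees()
    return (
        log2_odd_double_factorial(em)
        + log2_factorial(ed)
        - sum(log2_factorial(k) for k in km)
        - sum(log2_factorial(k) for k in kp)
        - sum(log2_factorial(k) for k in kq)
        + sum_lf_pairs
    )


def _moment(values: Sequence[int], other: Sequence[int] | None = None) -> float:
    v = np.asarray(values, dtype=np.float64)
    if other is None:
        return float(v.mean())
    return float((v * np.asarray(other, dtype=np.float64)).mean())


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def simple_entropy(g: DirectedGraph, family: str) -> float:
    """Entropy of the motif-free simple-graph ensemble for the family.

    ER and RER are exact (log of the number of simple graphs with the
    constrained counts); CM and RCM use the standard asymptotic
    expressions with a second-order correction term.
    """
    family = _check_family(family)
    n = g.n
    e = g.n_edges
    pairs = n * (n - 1)
    if family == "ER":
        return log2_binomial(pairs, e)
    h = Multigraph.from_simple(g)
    em, ed = h.reciprocity_stats()
    if family == "RER":
        half = pairs // 2
        return (
            log2_factorial(half)
            - log2_factorial(half - em - ed)
            - log2_factorial(em)
            - log2_factorial(ed)
            + ed
        )
    if family == "CM":
        kout = g_out = h.out_degrees()
        kin = h.in_degrees()
        correction = _ratio(
            _moment(g_out, g_out) * _moment(kin, kin),
            _moment(kout) * _moment(kin),
        )
        return (
            log2_factorial(e)
            - sum(log2_factorial(k) for k in kout)
            - sum(log2_factorial(k) for k in kin)
            - correction / (2 * LOG2)
        )
    # RCM
    km, kp, kq = h.reciprocal_degrees()
    correction = (
        0.5 * _ratio(_moment(km, km) ** 2, _moment(km) ** 2)
        + _ratio(_moment(kp, kp) * _moment(kq, kq), _moment(kp) * _moment(kq))
        + _ratio(_moment(kp, kq) ** 2, _moment(kp) * _moment(kq))
        + _ratio(_moment(km, kp) * _moment(km, kq), _moment(km) * _moment(kp))
    )
    return (
        log2_even_double_factorial(em)
        - sum(log2_factorial(k) for k in km)
        + log2_factorial(ed)
        - sum(log2_factorial(k) for k in kp)
        - sum(log2_factorial(k) for k in kq)
        - correction / (2 * LOG2)
    )


def model_complexity(h: Multigraph, family: str) -> float:
    """Parametric codelength L(phi) of the base-model features of H.
    Identical expressions apply to multigraphs and simple graphs."""
    family = _check_family(family)
    if family == "ER":
        return integer_code_length(h.n) + integer_code_length0(h.n_edges)
    if family == "CM":
        return sequence_code_length(h.out_degrees()) + sequence_code_length(
            h.in_degrees()
        )
    em, ed = h.reciprocity_stats()
    if family == "RER":
        return (
            integer_code_length(h.n)
            + integer_code_length0(em)
            + integer_code_length0(ed)
        )
    km, kp, kq = h.reciprocal_degrees()
    return (
        sequence_code_length(km)
        + sequence_code_length(kp)
        + sequence_code_length(kq)
    )


def simple_model_complexity(g: DirectedGraph, family: str) -> float:
    return model_complexity(Multigraph.from_simple(g), family)


# ---------------------------------------------------------------------------
# Reconstruction terms
# ---------------------------------------------------------------------------

def rewiring_cost(
    i_s: int, h: Multigraph, supernode_sizes: Mapping[int, int]
) -> float:
    """Bits to specify how the multiedges incident to supernode ``i_s``
    attach to the n_s internal nodes of the subgraph it replaces.

    Plain neighbors j cost log2[C(n_s, A_{i_s j}) * C(n_s, A_{j i_s})];
    edges towards an adjacent supernode j' cost log2 C(n_s n_s', A_{i_s j'})
    (the reverse direction is charged to j').
    """
    ns = supernode_sizes[i_s]
    cost = 0.0
    neighbors = set(h.A.get(i_s, {}))
    for j, row in h.A.items():
        if i_s in row:
            neighbors.add(j)
    for j in neighbors:
        a_out = h.mult(i_s, j)
        a_in = h.mult(j, i_s)
        if j in supernode_sizes:
            cap = ns * supernode_sizes[j]
            if a_out > cap:
                raise ValueError(
                    f"multiplicity {a_out} exceeds supernode-pair capacity {cap}"
                )
            if a_out:
                cost += log2_binomial(cap, a_out)
        else:
            if a_out > ns or a_in > ns:
                raise ValueError(
                    f"multiplicity exceeds supernode capacity {ns}"
                )
            cost += log2_binomial(ns, a_out) + log2_binomial(ns, a_in)
    return cost


class ReductionLike(Protocol):
    """Duck-typed view of a reduction state (see contraction module)."""

    n_g: int

    def to_multigraph(self) -> tuple[Multigraph, dict[int, int]]: ...

    def supernode_info(self) -> list[tuple[int, Graphlet]]: ...

    def motif_set(self) -> MotifSet: ...

    @property
    def gamma_size(self) -> int: ...

    @property
    def family(self) -> str: ...

    @property
    def graph(self) -> DirectedGraph: ...


def reconstruction_code_length(state: ReductionLike) -> float:
    """L(G | H, V, S, Gamma): recovering the original node labeling, each
    contracted subgraph's orientation, and the wiring of all supernode
    multiedges."""
    h, relabel = state.to_multigraph()
    supers = state.supernode_info()
    n_h = h.n
    cost = log2_factorial(state.n_g) - log2_factorial(n_h)
    sizes = {relabel[i]: gl.n for i, gl in supers}
    for i, gl in supers:
        cost += math.log2(gl.orientations)
        cost += rewiring_cost(relabel[i], h, sizes)
    return cost


def total_code_length(state: ReductionLike) -> float:
    """Full four-part codelength L(G, theta) of a reduction state under
    its multigraph base model.  This is the reference (non-incremental)
    evaluation; the optimizer maintains it incrementally."""
    h, _ = state.to_multigraph()
    ms = state.motif_set()
    return (
        motif_set_code_length(ms, state.gamma_size)
        + base_entropy(h, state.family)
        + model_complexity(h, state.family)
        + supernode_label_code_length(h.n, ms)
        + reconstruction_code_length(state)
    )


def reference_code_length(g: DirectedGraph, family: str) -> float:
    """Motif-free dyadic reference: the simple-graph two-part code
    L(G, phi) = S_phi(G) + L(phi(G))."""
    return simple_entropy(g, family) + simple_model_complexity(g, family)
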