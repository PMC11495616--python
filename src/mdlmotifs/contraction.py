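"""Reduction states and subgraph contractions.

A :class:`ReductionState` tracks the reduced multigraph H obtained from the
observed graph G by contracting node-disjoint induced subgraphs into
supernodes, together with the accumulated motif multiset and everything
needed to evaluate the total codelength.

Codelengths are maintained *incrementally*: the state keeps running
summary statistics (edge counts, reciprocity decomposition, degree
tallies, log-factorial sums, rewiring and orientation totals) so that the
putative codelength after contracting a candidate subgraph can be
evaluated from a boundary scan alone, without touching the rest of H.
The non-incremental evaluation in :mod:`mdlmotifs.codes` is the reference
against which this bookkeeping is tested.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .codes import (
    MotifSet,
    integer_code_length,
    integer_code_length0,
    log2_binomial,
    log2_even_double_factorial,
    log2_factorial,
    log2_odd_double_factorial,
    sequence_code_from_counts,
)
from .graphs import DirectedGraph, Graphlet, Multigraph, canonical_form

__all__ = ["ReductionState", "Supernode"]

# Lookup tables for the hot path of the boundary scan: multiplicities in H
# are bounded by the largest supernode-pair capacity (5 * 5 = 25), and the
# binomials of the rewiring cost never exceed C(25, k).
_LF = [log2_factorial(v) for v in range(64)]
_LB = [[log2_binomial(n, k) for k in range(n + 1)] for n in range(26)]


def _lf(v: int) -> float:
    return _LF[v] if v < 64 else log2_factorial(v)


class _DegreeTally:
    """Counts of a degree value across nodes, with the running sum of
    log2-factorials of the values (the entropy term Sum_i log2 k_i!)."""

    __slots__ = ("counts", "sum_lf")

    def __init__(self, values: Iterable[int] = ()):
        values = list(values)
        size = max(values) + 1 if values else 1
        self.counts = np.zeros(max(size, 8), dtype=np.int64)
        self.sum_lf = 0.0
        for v in values:
            self.counts[v] += 1
            self.sum_lf += log2_factorial(v)

    def add(self, v: int) -> None:
        if v >= self.counts.size:
            grown = np.zeros(max(v + 1, 2 * self.counts.size), dtype=np.int64)
            grown[: self.counts.size] = self.counts
            self.counts = grown
        self.counts[v] += 1
        self.sum_lf += _lf(v)

    def remove(self, v: int) -> None:
        if v >= self.counts.size or self.counts[v] <= 0:
            raise ValueError(f"removing absent degree value {v}")
        self.counts[v] -= 1
        self.sum_lf -= _lf(v)

    def copy(self) -> "_DegreeTally":
        out = _DegreeTally.__new__(_DegreeTally)
        out.counts = self.counts.copy()
        out.sum_lf = self.sum_lf
        return out

    def seq_code(self) -> float:
        return sequence_code_from_counts(self.counts)


@dataclass(frozen=True)
class Supernode:
    """A supernode of H: the graphlet it is colored with and the G-nodes
    of the subgraph it replaced."""

    node: int
    graphlet: Graphlet
    members: tuple[int, ...]


_ALL_TALLIES = ("kout", "kin", "km", "kp", "kq")


class _Summary:
    """Scalar summaries from which the total codelength is evaluated."""

    __slots__ = (
        "n_h", "e_h", "e_m", "e_d", "sum_lf_a", "sum_lf_pairs",
        "rew", "orient", "s_size", "a_unique", "m_max", "sum_lf_m",
        "kout", "kin", "km", "kp", "kq",
    )

    def copy(self, tally_names: tuple[str, ...] = _ALL_TALLIES) -> "_Summary":
        """Copy with deep copies of the named degree tallies; the others
        are aliased (callers must not mutate them through the copy)."""
        out = _Summary.__new__(_Summary)
        for name in ("n_h", "e_h", "e_m", "e_d", "sum_lf_a", "sum_lf_pairs",
                     "rew", "orient", "s_size", "a_unique", "m_max", "sum_lf_m"):
            setattr(out, name, getattr(self, name))
        for name in _ALL_TALLIES:
            t = getattr(self, name)
            setattr(out, name, t.copy() if name in tally_names else t)
        return out


class _Boundary:
    """Result of scanning a candidate subset's boundary in H."""

    __slots__ = (
        "subset", "graphlet", "e_int", "m_int", "merged",
        "d_e_m", "d_e_d", "d_lf_a", "d_lf_pairs", "d_rew",
        "kappa_updates", "s_degrees",
    )


class ReductionState:
    """The model state theta = (H, phi, S, V, Gamma) for one base family.

    Supernode ids are allocated above ``g.n`` so the ids of plain nodes
    never change during a run.
    """

    def __init__(self, g: DirectedGraph, family: str, gamma_size: int):
        if gamma_size < 1:
            raise ValueError("gamma_size must be >= 1")
        self.g = g
        self._family = family.upper()
        self._gamma_size = gamma_size

        # H starts as a copy of G (multiplicity 1 everywhere).
        self.succ: dict[int, dict[int, int]] = {v: {} for v in range(g.n)}
        self.pred: dict[int, set[int]] = {v: set() for v in range(g.n)}
        for i, j in g.edges:
            self.succ[i][j] = 1
            self.pred[j].add(i)

        self.plain: set[int] = set(range(g.n))
        self.supernodes: dict[int, Supernode] = {}
        self._next_id = g.n
        self.ms_counts: Counter = Counter()
        self._lf_ng = log2_factorial(g.n)

        sm = _Summary()
        sm.n_h = g.n
        sm.e_h = g.n_edges
        sm.sum_lf_a = 0.0
        sm.sum_lf_pairs = 0.0
        sm.rew = 0.0
        sm.orient = 0.0
        sm.s_size = 0
        sm.a_unique = 0
        sm.m_max = 0
        sm.sum_lf_m = 0.0
        kout, kin = [0] * g.n, [0] * g.n
        km, kp, kq = [0] * g.n, [0] * g.n, [0] * g.n
        em = 0
        for i, j in g.edges:
            kout[i] += 1
            kin[j] += 1
            if (j, i) in g.edges:
                km[i] += 1
                if i < j:
                    em += 1
            else:
                kp[i] += 1
                kq[j] += 1
        sm.e_m = em
        sm.e_d = g.n_edges - 2 * em
        sm.kout = _DegreeTally(kout)
        sm.kin = _DegreeTally(kin)
        sm.km = _DegreeTally(km)
        sm.kp = _DegreeTally(kp)
        sm.kq = _DegreeTally(kq)
        self.summ = sm
        self._cl_cache: float | None = None
        # degree tallies the codelength of this family actually reads;
        # the gain path only simulates these, contract() maintains all
        self._gain_tallies: tuple[str, ...] = {
            "ER": (), "RER": (), "CM": ("kout", "kin"),
            "RCM": ("km", "kp", "kq"),
        }[self._family]
        # per-node degrees of H (kept as dicts so supernodes fit in)
        self.kout = {v: kout[v] for v in range(g.n)}
        self.kin = {v: kin[v] for v in range(g.n)}
        self.km = {v: km[v] for v in range(g.n)}
        self.kp = {v: kp[v] for v in range(g.n)}
        self.kq = {v: kq[v] for v in range(g.n)}

    # ------------------------------------------------------------------
    # public accessors
    # ------------------------------------------------------------------
    @property
    def family(self) -> str:
        return self._family

    @property
    def gamma_size(self) -> int:
        return self._gamma_size

    @property
    def graph(self) -> DirectedGraph:
        return self.g

    @property
    def n_g(self) -> int:
        return self.g.n

    @property
    def n_h(self) -> int:
        return self.summ.n_h

    def motif_set(self) -> MotifSet:
        return MotifSet(Counter(self.ms_counts))

    def supernode_info(self) -> list[tuple[int, Graphlet]]:
        return [(s.node, s.graphlet) for s in self.supernodes.values()]

    def mult(self, i: int, j: int) -> int:
        return self.succ[i].get(j, 0)

    def to_multigraph(self) -> tuple[Multigraph, dict[int, int]]:
        """H as a dense-labeled Multigraph plus the id relabeling map."""
        nodes = sorted(self.succ)
        relabel = {v: q for q, v in enumerate(nodes)}
        mults = {
            (relabel[i], relabel[j]): m
            for i, row in self.succ.items()
            for j, m in row.items()
        }
        return Multigraph(len(nodes), mults), relabel

    # ------------------------------------------------------------------
    # codelength
    # ------------------------------------------------------------------
    def codelength(self) -> float:
        if self._cl_cache is None:
            self._cl_cache = self._codelength(self.summ)
        return self._cl_cache

    def _codelength(self, sm: _Summary) -> float:
        fam = self._family
        n_h = sm.n_h
        pairs = n_h * (n_h - 1)
        total = 0.0
        # L(Gamma, S)
        if sm.s_size:
            total += (
                sm.a_unique * math.log2(self._gamma_size)
                + integer_code_length(self._gamma_size)
                + sm.a_unique * math.log2(sm.m_max)
                + integer_code_length(sm.m_max)
            )
        # S_phi(H)
        if fam == "ER":
            if sm.e_h:
                total += (
                    sm.e_h * math.log2(pairs)
                    - log2_factorial(sm.e_h)
                    + sm.sum_lf_a
                )
        elif fam == "CM":
            total += (
                log2_factorial(sm.e_h)
                - sm.kout.sum_lf
                - sm.kin.sum_lf
                + sm.sum_lf_a
            )
        elif fam == "RER":
            if sm.e_m + sm.e_d:
                total += (
                    (sm.e_m + sm.e_d) * math.log2(pairs)
                    - log2_even_double_factorial(sm.e_m)
                    - log2_factorial(sm.e_d)
                    + sm.sum_lf_pairs
                )
        else:  # RCM
            total += (
                log2_odd_double_factorial(sm.e_m)
                + log2_factorial(sm.e_d)
                - sm.km.sum_lf
                - sm.kp.sum_lf
                - sm.kq.sum_lf
                + sm.sum_lf_pairs
            )
        # L(phi)
        if fam == "ER":
            total += integer_code_length(n_h) + integer_code_length0(sm.e_h)
        elif fam == "CM":
            total += sm.kout.seq_code() + sm.kin.seq_code()
        elif fam == "RER":
            total += (
                integer_code_length(n_h)
                + integer_code_length0(sm.e_m)
                + integer_code_length0(sm.e_d)
            )
        else:
            total += sm.km.seq_code() + sm.kp.seq_code() + sm.kq.seq_code()
        # L(V | H, S)
        if sm.s_size:
            total += (
                log2_binomial(n_h, sm.s_size)
                + log2_factorial(sm.s_size)
                - sm.sum_lf_m
            )
        # L(G | H, V, S, Gamma)
        total += self._lf_ng - log2_factorial(n_h) + sm.orient + sm.rew
        return total

    # ------------------------------------------------------------------
    # contraction machinery
    # ------------------------------------------------------------------
    def non_overlapping(self, subset: Sequence[int]) -> bool:
        """True iff every node of ``subset`` is still a plain node of H."""
        plain = self.plain
        return all(v in plain for v in subset)

    def _check_candidate(self, subset: Sequence[int], graphlet: Graphlet) -> tuple[int, ...]:
        subset = tuple(sorted(subset))
        if len(subset) != graphlet.n:
            raise ValueError("subset size does not match graphlet size")
        if not self.non_overlapping(subset):
            raise ValueError(f"subset {subset} overlaps an existing supernode")
        bits = self.g.induced_bits(subset)
        cbits, _ = canonical_form(graphlet.n, bits)
        if cbits != graphlet.bits:
            raise ValueError(
                f"induced subgraph of {subset} is not isomorphic to {graphlet.id}"
            )
        return subset

    def _scan(self, subset: tuple[int, ...], graphlet: Graphlet) -> _Boundary:
        """Boundary scan: everything that changes if ``subset`` is
        contracted, without mutating the state."""
        bd = _Boundary()
        bd.subset = subset
        bd.graphlet = graphlet
        sub = set(subset)
        succ, pred = self.succ, self.pred
        g_edges = self.g.edges

        e_int = m_int = 0
        for idx, a in enumerate(subset):
            for b in subset[idx + 1 :]:
                ab = (a, b) in g_edges
                ba = (b, a) in g_edges
                e_int += ab + ba
                m_int += ab and ba
        bd.e_int = e_int
        bd.m_int = m_int

        merged: dict[int, list[int]] = {}
        for j in subset:
            for x in succ[j]:
                if x not in sub:
                    merged.setdefault(x, [0, 0])
            for x in pred[j]:
                if x not in sub:
                    merged.setdefault(x, [0, 0])

        ns = graphlet.n
        supernodes = self.supernodes
        d_lf_a = 0.0
        d_lf_pairs = 0.0
        d_rew = 0.0
        d_e_m = -m_int
        d_e_d = -(e_int - 2 * m_int)
        kappa_updates: list[tuple[int, int, int, int]] = []
        s_out_total = s_in_total = 0
        s_km = s_kp = s_kq = 0

        lf = _LF
        lb = _LB
        for x in sorted(merged):
            s_out = s_in = 0
            sym_old = a_out_old = a_in_old = 0  # a_out: asym j->x, a_in: asym x->j
            is_super = x in supernodes
            nx = supernodes[x].graphlet.n if is_super else 1
            row_x = succ[x]
            for j in subset:
                ajx = succ[j].get(x, 0)
                axj = row_x.get(j, 0)
                if ajx <= 1 and axj <= 1:
                    # multiplicity-free fast path: all log-factorials vanish
                    if ajx or axj:
                        s_out += ajx
                        s_in += axj
                        sym = ajx & axj
                        sym_old += sym
                        a_out_old += ajx - sym
                        a_in_old += axj - sym
                        if is_super:
                            d_rew -= lb[nx][axj] + lb[nx][ajx]
                    continue
                s_out += ajx
                s_in += axj
                sym = min(ajx, axj)
                sym_old += sym
                a_out_old += ajx - sym
                a_in_old += axj - sym
                d_lf_a -= lf[ajx] + lf[axj]
                d_lf_pairs -= lf[sym] + lf[ajx - sym] + lf[axj - sym]
                if is_super:
                    # x's old wiring charges for the plain neighbor j
                    d_rew -= lb[nx][axj] + lb[nx][ajx]
            merged[x][0] = s_out
            merged[x][1] = s_in
            sym_new = min(s_out, s_in)
            a_out_new = s_out - sym_new  # asym s->x
            a_in_new = s_in - sym_new    # asym x->s
            d_lf_a += lf[s_out] + lf[s_in]
            d_lf_pairs += lf[sym_new] + lf[a_out_new] + lf[a_in_new]
            d_e_m += sym_new - sym_old
            d_e_d += (a_out_new + a_in_new) - (a_out_old + a_in_old)
            kappa_updates.append(
                (x, sym_new - sym_old, a_in_new - a_in_old, a_out_new - a_out_old)
            )
            if is_super:
                d_rew += lb[ns * nx][s_out]  # charged to new supernode
                d_rew += lb[nx * ns][s_in]   # charged to x
            else:
                d_rew += lb[ns][s_out] + lb[ns][s_in]
            s_out_total += s_out
            s_in_total += s_in
            s_km += sym_new
            s_kp += a_out_new
            s_kq += a_in_new

        bd.merged = merged
        bd.d_e_m = d_e_m
        bd.d_e_d = d_e_d
        bd.d_lf_a = d_lf_a
        bd.d_lf_pairs = d_lf_pairs
        bd.d_rew = d_rew
        bd.kappa_updates = kappa_updates
        bd.s_degrees = (s_out_total, s_in_total, s_km, s_kp, s_kq)
        return bd

    def _summary_after(
        self, bd: _Boundary, tally_names: tuple[str, ...] = _ALL_TALLIES
    ) -> _Summary:
        sm = self.summ.copy(tally_names)
        gl = bd.graphlet
        sm.n_h -= gl.n - 1
        sm.e_h -= bd.e_int
        sm.e_m += bd.d_e_m
        sm.e_d += bd.d_e_d
        sm.sum_lf_a += bd.d_lf_a
        sm.sum_lf_pairs += bd.d_lf_pairs
        sm.rew += bd.d_rew
        sm.orient += math.log2(gl.orientations)
        m_new = self.ms_counts[gl] + 1
        sm.s_size += 1
        if m_new == 1:
            sm.a_unique += 1
        sm.m_max = max(sm.m_max, m_new)
        sm.sum_lf_m += log2_factorial(m_new) - log2_factorial(m_new - 1)
        # degree tallies (only the ones requested)
        do_deg = "kout" in tally_names
        do_rec = "km" in tally_names
        for j in bd.subset:
            if do_deg:
                sm.kout.remove(self.kout[j])
                sm.kin.remove(self.kin[j])
            if do_rec:
                sm.km.remove(self.km[j])
                sm.kp.remove(self.kp[j])
                sm.kq.remove(self.kq[j])
        if do_rec:
            for x, d_km, d_kp, d_kq in bd.kappa_updates:
                if d_km:
                    sm.km.remove(self.km[x])
                    sm.km.add(self.km[x] + d_km)
                if d_kp:
                    sm.kp.remove(self.kp[x])
                    sm.kp.add(self.kp[x] + d_kp)
                if d_kq:
                    sm.kq.remove(self.kq[x])
                    sm.kq.add(self.kq[x] + d_kq)
        s_out, s_in, s_km, s_kp, s_kq = bd.s_degrees
        if do_deg:
            sm.kout.add(s_out)
            sm.kin.add(s_in)
        if do_rec:
            sm.km.add(s_km)
            sm.kp.add(s_kp)
            sm.kq.add(s_kq)
        return sm

    def contraction_gain(self, subset: Sequence[int], graphlet: Graphlet) -> float:
        """Codelength gain Delta L = L(theta) - L(theta after contracting
        ``subset``).  Positive means the contraction compresses.  Side
        effect free."""
        subset = self._check_candidate(subset, graphlet)
        bd = self._scan(subset, graphlet)
        after = self._summary_after(bd, self._gain_tallies)
        return self.codelength() - self._codelength(after)

    def contract(self, subset: Sequence[int], graphlet: Graphlet) -> int:
        """Contract the induced subgraph on ``subset`` into a new
        supernode; returns the supernode id."""
        subset = self._check_candidate(subset, graphlet)
        bd = self._scan(subset, graphlet)
        self.summ = self._summary_after(bd)
        self._cl_cache = None

        # per-node degree dict updates
        for x, d_km, d_kp, d_kq in bd.kappa_updates:
            self.km[x] += d_km
            self.kp[x] += d_kp
            self.kq[x] += d_kq
        for j in subset:
            for d in (self.kout, self.kin, self.km, self.kp, self.kq):
                del d[j]
        s = self._next_id
        self._next_id += 1
        s_out, s_in, s_km, s_kp, s_kq = bd.s_degrees
        self.kout[s] = s_out
        self.kin[s] = s_in
        self.km[s] = s_km
        self.kp[s] = s_kp
        self.kq[s] = s_kq

        # adjacency rewrite
        succ, pred = self.succ, self.pred
        sub = set(subset)
        for j in subset:
            for x in succ[j]:
                if x not in sub:
                    pred[x].discard(j)
            for x in pred[j]:
                if x not in sub:
                    del succ[x][j]
            del succ[j]
            del pred[j]
        succ[s] = {}
        pred[s] = set()
        for x, (out, inn) in bd.merged.items():
            if out:
                succ[s][x] = out
                pred[x].add(s)
            if inn:
                succ[x][s] = inn
                pred[s].add(x)

        self.plain -= sub
        self.supernodes[s] = Supernode(node=s, graphlet=graphlet, members=subset)
        self.ms_counts[graphlet] += 1
        return s

    # ------------------------------------------------------------------
    # consistency checking (used in tests / debug)
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Recompute every summary from scratch and compare."""
        h, relabel = self.to_multigraph()
        sm = self.summ
        assert h.n == sm.n_h
        assert h.n_edges == sm.e_h
        em, ed = h.reciprocity_stats()
        assert (em, ed) == (sm.e_m, sm.e_d)
        n_members = sum(len(s.members) for s in self.supernodes.values())
        assert sm.n_h == self.g.n - n_members + len(self.supernodes)
        internal = sum(
            1
            for s in self.supernodes.values()
            for i in s.members
            for j in s.members
            if (i, j) in self.g.edges
        )
        assert sm.e_h == self.g.n_edges - internal
        lf_a = sum(log2_factorial(m) for _, m in h.items())
        assert abs(lf_a - sm.sum_lf_a) < 1e-8
        kout = h.out_degrees()
        assert sorted(kout) == sorted(self.kout.values())
        from .codes import rewiring_cost

        sizes = {relabel[s.node]: s.graphlet.n for s in self.supernodes.values()}
        rew = sum(rewiring_cost(relabel[s.node], h, sizes) for s in self.supernodes.values())
        assert abs(rew - sm.rew) < 1e-8
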