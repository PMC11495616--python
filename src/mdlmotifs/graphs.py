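"""Core graph types and canonical forms for directed graphlets.

A *graphlet* is an isomorphism class of small weakly connected directed
graphs without self-loops.  Isomorphism classes are represented by a
canonical adjacency bitstring: the off-diagonal adjacency entries are read
row-major over ordered pairs (i, j), i != j, packed into an integer, and
the canonical form is the minimal encoding over all node permutations.
Brute
force over the n! permutations is exact and fast for the sizes used in
motif mining (n <= 6); results are memoized.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

MAX_GRAPHLET_NODES = 6

__all__ = [
    "DirectedGraph",
    "Multigraph",
    "Graphlet",
    "canonical_form",
    "automorphism_count",
    "orientation_count",
    "weakly_connected",
    "bits_from_edges",
    "edges_from_bits",
]


# ---------------------------------------------------------------------------
# Bitstring encoding of small digraphs
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def pair_positions(n: int) -> tuple[tuple[int, int], ...]:
    """Ordered pairs (i, j), i != j, in row-major order."""
    return tuple((i, j) for i in range(n) for j in range(n) if i != j)


@lru_cache(maxsize=None)
def _pair_index(n: int) -> dict[tuple[int, int], int]:
    return {pair: p for p, pair in enumerate(pair_positions(n))}


def _nbits(n: int) -> int:
    return n * (n - 1)


def bits_from_edges(n: int, edges: Iterable[tuple[int, int]]) -> int:
    """Encode an edge set as an integer: bit p of the integer is the
    adjacency entry of the p-th ordered pair in row-major order (the
    first pair is the least significant bit, so the canonical minimum
    integer reads "10" for a single edge on two nodes)."""
    index = _pair_index(n)
    bits = 0
    for e in edges:
        i, j = e
        if i == j:
            raise ValueError(f"self-loop ({i},{i}) not allowed")
        bits |= 1 << index[(i, j)]
    return bits


def edges_from_bits(n: int, bits: int) -> tuple[tuple[int, int], ...]:
    pairs = pair_positions(n)
    return tuple(pairs[p] for p in range(_nbits(n)) if bits >> p & 1)


@lru_cache(maxsize=None)
def _perm_tables(n: int) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """All permutations of range(n) with, for each, the induced map on
    bit positions (bit p of the input goes to bit table[p] of the
    output)."""
    index = _pair_index(n)
    length = _nbits(n)
    pairs = pair_positions(n)
    tables = []
    for perm in itertools.permutations(range(n)):
        shift_map = [0] * length
        for p, (i, j) in enumerate(pairs):
            shift_map[p] = index[(perm[i], perm[j])]
        tables.append((perm, tuple(shift_map)))
    return tuple(tables)


def _apply_bit_map(bits: int, shift_map: Sequence[int]) -> int:
    out = 0
    x = bits
    while x:
        low = x & -x
        out |= 1 << shift_map[low.bit_length() - 1]
        x ^= low
    return out


def _check_size(n: int) -> None:
    if n < 1:
        raise ValueError("graphlet must have at least one node")
    if n > MAX_GRAPHLET_NODES:
        raise ValueError(
            f"canonicalization supports up to {MAX_GRAPHLET_NODES} nodes, got {n}"
        )


_canonical_cache: dict[tuple[int, int], tuple[int, tuple[int, ...]]] = {}


def canonical_form(n: int, bits: int) -> tuple[int, tuple[int, ...]]:
    """Canonical (minimal) adjacency bitstring of an n-node digraph,
    plus one permutation achieving it.

    Two digraphs are isomorphic iff their canonical bitstrings are equal.
    The returned permutation ``sigma`` maps node i of the input to node
    ``sigma[i]`` of the canonical layout.
    """
    _check_size(n)
    key = (n, bits)
    hit = _canonical_cache.get(key)
    if hit is not None:
        return hit
    best = None
    best_perm = None
    for perm, shift_map in _perm_tables(n):
        cand = _apply_bit_map(bits, shift_map)
        if best is None or cand < best:
            best, best_perm = cand, perm
    result = (best, best_perm)
    _canonical_cache[key] = result
    return result


def automorphism_count(n: int, bits: int) -> int:
    """Size of the automorphism group, |{sigma : sigma(g) = g}|, by brute
    force over all n! permutations."""
    _check_size(n)
    count = 0
    for _, shift_map in _perm_tables(n):
        if _apply_bit_map(bits, shift_map) == bits:
            count += 1
    return count


def orientation_count(n: int, bits: int) -> int:
    """Number of distinguishable orientations, n!/|Aut|: the number of
    distinct labeled digraphs in the isomorphism class."""
    return math.factorial(n) // automorphism_count(n, bits)


def weakly_connected(n: int, edges: Iterable[tuple[int, int]]) -> bool:
    """True iff the graph obtained by ignoring edge directions is
    connected.  A single node is connected."""
    if n < 1:
        raise ValueError("empty node set")
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n
    stack = [0]
    seen[0] = True
    found = 1
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if not seen[u]:
                seen[u] = True
                found += 1
                stack.append(u)
    return found == n


def weakly_connected_bits(n: int, bits: int) -> bool:
    return weakly_connected(n, edges_from_bits(n, bits))


# ---------------------------------------------------------------------------
# Graphlet: a canonical isomorphism class
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Graphlet:
    """An isomorphism class of weakly connected digraphs, keyed by its
    canonical bitstring.  Ordering is (n, bits), the deterministic
    dictionary order used throughout the package."""

    n: int
    bits: int
    aut: int = field(compare=False)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("graphlets have at least two nodes")

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "Graphlet":
        edges = tuple(edges)
        if not weakly_connected(n, edges):
            raise ValueError("graphlet must be weakly connected")
        bits, _ = canonical_form(n, bits_from_edges(n, edges))
        return cls(n=n, bits=bits, aut=automorphism_count(n, bits))

    @classmethod
    def from_bits(cls, n: int, bits: int) -> "Graphlet":
        cbits, _ = canonical_form(n, bits)
        if not weakly_connected_bits(n, cbits):
            raise ValueError("graphlet must be weakly connected")
        return cls(n=n, bits=cbits, aut=automorphism_count(n, cbits))

    @classmethod
    def from_id(cls, gid: str) -> "Graphlet":
        if not gid.startswith("d"):
            raise ValueError(f"malformed graphlet id {gid!r}")
        head, _, hexpart = gid[1:].partition("-")
        n = int(head)
        bits = int(hexpart, 16)
        g = cls.from_bits(n, bits)
        if g.bits != bits:
            raise ValueError(f"graphlet id {gid!r} is not in canonical form")
        return g

    @property
    def id(self) -> str:
        ndigits = max(1, -(-_nbits(self.n) // 4))
        return f"d{self.n}-{self.bits:0{ndigits}x}"

    @property
    def orientations(self) -> int:
        return math.factorial(self.n) // self.aut

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return edges_from_bits(self.n, self.bits)

    @property
    def n_edges(self) -> int:
        return self.bits.bit_count()

    @property
    def density(self) -> float:
        return self.n_edges / _nbits(self.n)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.id


def clique_graphlet(n: int) -> Graphlet:
    """The complete digraph on n nodes (all n(n-1) directed edges)."""
    return Graphlet(n=n, bits=(1 << _nbits(n)) - 1, aut=math.factorial(n))


# ---------------------------------------------------------------------------
# DirectedGraph: the observed simple digraph G
# ---------------------------------------------------------------------------

class DirectedGraph:
    """A simple directed graph without self-loops.

    Nodes are dense integers 0..N-1; ``labels`` optionally maps them back
    to the original string labels of an input file.
    """

    __slots__ = ("n", "edges", "labels", "_succ", "_pred", "_und")

    def __init__(
        self,
        n: int,
        edges: Iterable[tuple[int, int]],
        labels: Sequence[str] | None = None,
    ):
        if n < 1:
            raise ValueError("graph must have at least one node")
        edge_set = set()
        for e in edges:
            i, j = int(e[0]), int(e[1])
            if i == j:
                raise ValueError(f"self-loop ({i},{i}) not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) out of range for n={n}")
            edge_set.add((i, j))
        self.n = n
        self.edges = frozenset(edge_set)
        if labels is not None:
            labels = tuple(labels)
            if len(labels) != n:
                raise ValueError("labels must have one entry per node")
        self.labels = labels
        succ: list[set[int]] = [set() for _ in range(n)]
        pred: list[set[int]] = [set() for _ in range(n)]
        for i, j in edge_set:
            succ[i].add(j)
            pred[j].add(i)
        self._succ = succ
        self._pred = pred
        self._und = [succ[v] | pred[v] for v in range(n)]

    # -- basic accessors ----------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        return self.n_edges / (self.n * (self.n - 1)) if self.n > 1 else 0.0

    def successors(self, v: int) -> set[int]:
        return self._succ[v]

    def predecessors(self, v: int) -> set[int]:
        return self._pred[v]

    def neighbors(self, v: int) -> set[int]:
        """Undirected (weak) neighborhood."""
        return self._und[v]

    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self.edges

    def label(self, v: int) -> str:
        return self.labels[v] if self.labels is not None else str(v)

    # -- derived forms ------------------------------------------------------
    def induced_bits(self, subset: Sequence[int]) -> int:
        """Adjacency bitstring of the induced subgraph on ``subset``
        (nodes taken in the given order)."""
        bits = 0
        p = 0
        edges = self.edges
        for a in subset:
            for b in subset:
                if a == b:
                    continue
                if (a, b) in edges:
                    bits |= 1 << p
                p += 1
        return bits

    def reciprocal_edge_count(self) -> int:
        return sum(1 for (i, j) in self.edges if i < j and (j, i) in self.edges)

    def relabeled(self, perm: Sequence[int]) -> "DirectedGraph":
        """Graph with node i renamed perm[i] (labels permuted along)."""
        labels = None
        if self.labels is not None:
            labels = [""] * self.n
            for i, q in enumerate(perm):
                labels[q] = self.labels[i]
        return DirectedGraph(
            self.n, ((perm[i], perm[j]) for i, j in self.edges), labels
        )

    @classmethod
    def from_labeled_edges(
        cls, pairs: Iterable[tuple[str, str]]
    ) -> "DirectedGraph":
        """Build from (source, target) label pairs; labels are mapped to
        dense ids in first-appearance order."""
        ids: dict[str, int] = {}
        edges = []
        for a, b in pairs:
            for x in (a, b):
                if x not in ids:
                    ids[x] = len(ids)
            edges.append((ids[a], ids[b]))
        if not ids:
            raise ValueError("no edges given")
        return cls(len(ids), edges, labels=tuple(ids))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DirectedGraph(n={self.n}, E={self.n_edges})"


# ---------------------------------------------------------------------------
# Multigraph: the reduced latent graph H
# ---------------------------------------------------------------------------

class Multigraph:
    """A directed multigraph with integer edge multiplicities and no
    self-loops, with the degree and reciprocity statistics used by the
    microcanonical base codes.

    The reciprocal part of a multiedge is ``min(A_ij, A_ji)`` and the
    non-reciprocated part is the remainder.
    """

    __slots__ = ("n", "A")

    def __init__(self, n: int, multiplicities: Mapping[tuple[int, int], int]):
        if n < 1:
            raise ValueError("multigraph must have at least one node")
        A: dict[int, dict[int, int]] = {}
        for (i, j), m in multiplicities.items():
            m = int(m)
            if m < 0:
                raise ValueError("negative multiplicity")
            if m == 0:
                continue
            if i == j:
                raise ValueError("self-loops not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"pair ({i},{j}) out of range")
            A.setdefault(i, {})[j] = m
        self.n = n
        self.A = A

    @classmethod
    def from_simple(cls, g: DirectedGraph) -> "Multigraph":
        return cls(g.n, {e: 1 for e in g.edges})

    def mult(self, i: int, j: int) -> int:
        return self.A.get(i, {}).get(j, 0)

    def items(self):
        for i, row in self.A.items():
            for j, m in row.items():
                yield (i, j), m

    # -- aggregate statistics ------------------------------------------------
    @property
    def n_edges(self) -> int:
        """Total edge count including multiplicities, E = E_d + 2 E_m."""
        return sum(m for _, m in self.items())

    def out_degrees(self) -> list[int]:
        k = [0] * self.n
        for (i, _), m in self.items():
            k[i] += m
        return k

    def in_degrees(self) -> list[int]:
        k = [0] * self.n
        for (_, j), m in self.items():
            k[j] += m
        return k

    def _pair_stats(self):
        """Iterate unordered pairs {i<j} with (sym, asym_ij, asym_ji)."""
        seen = set()
        for (i, j), _ in list(self.items()):
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            mij = self.mult(a, b)
            mji = self.mult(b, a)
            sym = min(mij, mji)
            yield (a, b), sym, mij - sym, mji - sym

    def reciprocity_stats(self) -> tuple[int, int]:
        """(E_m, E_d): reciprocated pair count and non-reciprocated count."""
        em = ed = 0
        for _, sym, aij, aji in self._pair_stats():
            em += sym
            ed += aij + aji
        return em, ed

    def reciprocal_degrees(self) -> tuple[list[int], list[int], list[int]]:
        """(kappa_m, kappa_plus, kappa_minus) per node."""
        km = [0] * self.n
        kp = [0] * self.n
        kq = [0] * self.n
        for (i, j), sym, aij, aji in self._pair_stats():
            km[i] += sym
            km[j] += sym
            kp[i] += aij
            kq[j] += aij
            kp[j] += aji
            kq[i] += aji
        return km, kp, kq

    def __repr__(self) -> str:  # pragma: no cover
        return f"Multigraph(n={self.n}, E={self.n_edges})"
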