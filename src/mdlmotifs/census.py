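"""Graphlet dictionary enumeration and exhaustive subgraph census.

``enumerate_graphlets`` lists all isomorphism classes of weakly connected
digraphs of given sizes by scanning every labeled digraph once and marking
whole isomorphism orbits.  ``subgraph_census`` enumerates every connected
induced subgraph of the input graph exactly once using Wernicke's ESU
recursion and classifies each occurrence by canonical form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .graphs import (
    DirectedGraph,
    Graphlet,
    _apply_bit_map,
    _nbits,
    _perm_tables,
    canonical_form,
    clique_graphlet,
    weakly_connected_bits,
)

logger = logging.getLogger(__name__)

__all__ = ["CensusTable", "enumerate_graphlets", "subgraph_census", "graphlet_counts"]


# ---------------------------------------------------------------------------
# Graphlet dictionary
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _isomorphism_classes(n: int) -> tuple[Graphlet, ...]:
    """All weakly connected digraph isomorphism classes on n nodes.

    Scans the 2^(n(n-1)) labeled digraphs; the canonical form of each orbit
    is its numerically smallest member, computed for all graphs at once by
    applying every bit permutation with two half-word lookup tables.
    """
    length = _nbits(n)
    total = 1 << length
    half = length // 2
    lo_mask = (1 << half) - 1

    arr = np.arange(total, dtype=np.uint32)
    lo = arr & lo_mask
    hi = arr >> half
    canon = arr.copy()
    tables = _perm_tables(n)
    for _, shift_map in tables[1:]:  # identity permutation maps x to x
        t_lo = np.empty(1 << half, dtype=np.uint32)
        for x in range(1 << half):
            t_lo[x] = _apply_bit_map(x, shift_map)
        t_hi = np.empty(total >> half, dtype=np.uint32)
        for x in range(total >> half):
            t_hi[x] = _apply_bit_map(x << half, shift_map)
        np.minimum(canon, t_lo[lo] | t_hi[hi], out=canon)

    reps = np.unique(canon)
    out = []
    for rep in reps.tolist():
        if not weakly_connected_bits(n, rep):
            continue
        aut = sum(1 for _, m in tables if _apply_bit_map(rep, m) == rep)
        out.append(Graphlet(n=n, bits=rep, aut=aut))
    return tuple(sorted(out))


@lru_cache(maxsize=None)
def enumerate_graphlets(n_min: int, n_max: int) -> tuple[Graphlet, ...]:
    """The graphlet dictionary: all weakly connected digraph isomorphism
    classes with n_min..n_max nodes, ordered by (size, canonical bits)."""
    if not (2 <= n_min <= n_max <= 5):
        raise ValueError("graphlet sizes must satisfy 2 <= n_min <= n_max <= 5")
    gamma: list[Graphlet] = []
    for n in range(n_min, n_max + 1):
        gamma.extend(_isomorphism_classes(n))
    return tuple(gamma)


# ---------------------------------------------------------------------------
# Census of graphlet occurrences
# ---------------------------------------------------------------------------

@dataclass
class CensusTable:
    """Occurrence lists of every graphlet of the dictionary in a graph.

    ``occurrences`` maps graphlet id to the list of node subsets (sorted
    tuples) whose induced subgraph belongs to that class.  Graphlets with
    no occurrence are omitted from the mapping.
    """

    gamma: tuple[Graphlet, ...]
    occurrences: dict[str, list[tuple[int, ...]]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {gid: len(subs) for gid, subs in self.occurrences.items()}

    @property
    def total(self) -> int:
        return sum(len(subs) for subs in self.occurrences.values())

    def copy_occurrences(self) -> dict[str, list[tuple[int, ...]]]:
        return {gid: list(subs) for gid, subs in self.occurrences.items()}


def _esu_connected_subsets(g: DirectedGraph, k: int):
    """Yield every connected induced k-subset of g exactly once (ESU:
    extend by exclusive neighbors with id greater than the root, visited
    in ascending order)."""
    neighbors = g.neighbors
    for v in range(g.n):
        ext = sorted(u for u in neighbors(v) if u > v)
        if k == 1:
            yield (v,)
            continue
        # stack entries: (subgraph tuple, extension list, closed neighborhood)
        stack = [((v,), ext, set(neighbors(v)) | {v})]
        while stack:
            sub, extension, closed = stack.pop()
            while extension:
                w = extension[0]
                extension = extension[1:]
                new_sub = sub + (w,)
                if len(new_sub) == k:
                    yield tuple(sorted(new_sub))
                    continue
                excl = [u for u in neighbors(w) if u > v and u not in closed]
                new_ext = sorted(set(extension) | set(excl))
                stack.append((new_sub, new_ext, closed | set(neighbors(w)) | {w}))


def _mutual_cliques(g: DirectedGraph, k: int) -> list[tuple[int, ...]]:
    """All k-subsets inducing the complete digraph (cliques of the
    reciprocal-edge graph)."""
    mutual = [
        {u for u in g.successors(v) if g.has_edge(u, v)} for v in range(g.n)
    ]
    out: list[tuple[int, ...]] = []

    def extend(clique: tuple[int, ...], cand: set[int]) -> None:
        if len(clique) == k:
            out.append(clique)
            return
        for u in sorted(cand):
            if u > clique[-1]:
                extend(clique + (u,), cand & mutual[u])

    for v in range(g.n):
        extend((v,), {u for u in mutual[v] if u > v})
    return out


def subgraph_census(
    g: DirectedGraph,
    gamma: Sequence[Graphlet],
    warn_threshold: int = 5_000_000,
    hard_limit: int = 100_000_000,
) -> CensusTable:
    """Exhaustive induced-subgraph census of ``g`` over the dictionary
    ``gamma``.

    Every connected induced subgraph of each requested size is enumerated
    exactly once and classified by canonical form; subsets whose class is
    not in ``gamma`` are discarded.  When all requested graphlets of a size
    are the complete digraph, occurrences are found by clique search in the
    reciprocal-edge graph instead of full enumeration.
    """
    by_size: dict[int, dict[int, str]] = {}
    for gl in gamma:
        by_size.setdefault(gl.n, {})[gl.bits] = gl.id

    table = CensusTable(gamma=tuple(gamma))
    occ = table.occurrences
    total = 0
    warned = False
    for k in sorted(by_size):
        wanted = by_size[k]
        clique = clique_graphlet(k)
        if set(wanted) == {clique.bits}:
            for subset in _mutual_cliques(g, k):
                occ.setdefault(clique.id, []).append(subset)
                total += 1
            continue
        classify: dict[int, str | None] = {}
        for subset in _esu_connected_subsets(g, k):
            bits = g.induced_bits(subset)
            gid = classify.get(bits, "")
            if gid == "":
                cbits, _ = canonical_form(k, bits)
                gid = wanted.get(cbits)
                classify[bits] = gid
            if gid is not None:
                occ.setdefault(gid, []).append(subset)
                total += 1
                if total > hard_limit:
                    raise MemoryError(
                        f"census exceeded hard occurrence limit ({hard_limit}); "
                        "reduce the graphlet sizes or restrict the dictionary"
                    )
                if total > warn_threshold and not warned:
                    logger.warning(
                        "census holds %d occurrences (threshold %d)",
                        total,
                        warn_threshold,
                    )
                    warned = True
    return table


# ---------------------------------------------------------------------------
# Counts-only census (used by the hypothesis-testing baseline)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _igraph_class_map(size: int) -> tuple[str | None, ...]:
    """Map igraph directed isomorphism-class index -> graphlet id (None
    for disconnected classes)."""
    import igraph as ig

    n_classes = {3: 16, 4: 218}[size]
    out: list[str | None] = []
    for c in range(n_classes):
        h = ig.Graph.Isoclass(size, c, directed=True)
        edges = [tuple(e.tuple) for e in h.es]
        try:
            gl = Graphlet.from_edges(size, edges)
        except ValueError:
            out.append(None)
            continue
        out.append(gl.id)
    return tuple(out)


def graphlet_counts(
    g: DirectedGraph, sizes: Iterable[int], backend: str = "auto"
) -> dict[str, int]:
    """Per-graphlet occurrence counts (no subsets stored).

    ``backend='igraph'`` uses igraph's ESU-based motif counter for sizes 3
    and 4 (identical counts, much faster); ``'esu'`` forces the in-package
    enumeration; ``'auto'`` prefers igraph when available.
    """
    sizes = sorted(set(sizes))
    use_igraph = False
    if backend in ("auto", "igraph") and all(k in (3, 4) for k in sizes):
        try:
            import igraph  # noqa: F401

            use_igraph = True
        except ImportError:
            if backend == "igraph":
                raise
    counts: dict[str, int] = {}
    if use_igraph:
        import igraph as ig

        h = ig.Graph(n=g.n, edges=sorted(g.edges), directed=True)
        for k in sizes:
            raw = h.motifs_randesu(size=k)
            cmap = _igraph_class_map(k)
            for c, value in enumerate(raw):
                gid = cmap[c]
                if gid is None or math.isnan(value):
                    continue
                counts[gid] = counts.get(gid, 0) + int(value)
        return counts
    gamma = [gl for k in sizes for gl in _isomorphism_classes(k)]
    table = subgraph_census(g, gamma)
    return table.counts()
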