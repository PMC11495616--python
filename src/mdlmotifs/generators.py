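"""Synthetic inputs: the planted-motif model and null-model randomizers.

The planted-motif model inverts the compression scheme: draw a latent
Erdos-Renyi multigraph, designate random nodes as supernodes carrying
prescribed graphlets, then expand each supernode into a uniformly oriented
copy of its graphlet whose incident multiedges are wired uniformly over
the configurations the rewiring code counts.

The randomizers produce samples from the four microcanonical null
ensembles (exactly preserving the family's constrained features) either by
direct placement (ER, RER) or by Markov-chain edge swaps (CM, RCM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .graphs import (
    DirectedGraph,
    Graphlet,
    Multigraph,
    _nbits,
    _apply_bit_map,
    _perm_tables,
    edges_from_bits,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedSpec",
    "PlantedGraph",
    "plant_motifs",
    "planted_motif_benchmark",
    "connectome_like",
    "randomize",
]


# ---------------------------------------------------------------------------
# Planted motif model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the planted-motif model: a latent ER multigraph of
    ``n_latent`` nodes and ``e_latent`` thrown edges, with ``m`` latent
    nodes per (graphlet, m) placement expanded into motif copies."""

    n_latent: int
    e_latent: int
    placements: tuple[tuple[Graphlet, int], ...]

    def __post_init__(self):
        total = sum(m for _, m in self.placements)
        if total > self.n_latent:
            raise ValueError("more supernodes than latent nodes")
        if self.n_latent < 1 or self.e_latent < 0:
            raise ValueError("invalid latent graph size")

    @property
    def n_supernodes(self) -> int:
        return sum(m for _, m in self.placements)

    @property
    def n_expanded(self) -> int:
        """Number of nodes of the generated graph."""
        return self.n_latent + sum(m * (gl.n - 1) for gl, m in self.placements)

    @property
    def e_expanded(self) -> int:
        """Number of edges of the generated graph."""
        return self.e_latent + sum(m * gl.n_edges for gl, m in self.placements)


@dataclass
class PlantedGraph:
    """A generated graph together with its ground truth."""

    graph: DirectedGraph
    spec: PlantedSpec
    # (graphlet, member node ids in G, orientation bits relative to the
    # sorted member order)
    ground_truth: list[tuple[Graphlet, tuple[int, ...], int]]
    latent: Multigraph
    # latent node id -> tuple of G node ids it expanded into
    expansion: dict[int, tuple[int, ...]] = field(default_factory=dict)


@lru_cache(maxsize=None)
def _orientation_orbit(n: int, bits: int) -> tuple[int, ...]:
    """All distinct labeled adjacency patterns of the isomorphism class
    (the n!/|Aut| distinguishable orientations)."""
    return tuple(sorted({_apply_bit_map(bits, m) for _, m in _perm_tables(n)}))


def plant_motifs(
    spec: PlantedSpec, rng: np.random.Generator, max_retries: int = 200
) -> PlantedGraph:
    """Generate a simple directed graph with planted motifs.

    The latent multigraph is resampled as a whole whenever a multiedge
    exceeds the wiring capacity of its endpoints (a plain-plain pair can
    carry one edge, a supernode pair (s, s') up to n_s * n_s').
    """
    n_l = spec.n_latent
    m_total = spec.n_supernodes
    pair_of = [(i, j) for i in range(n_l) for j in range(n_l) if i != j]

    chosen = rng.choice(n_l, size=m_total, replace=False)
    graphlet_of: dict[int, Graphlet] = {}
    pos = 0
    for gl, m in spec.placements:
        for _ in range(m):
            graphlet_of[int(chosen[pos])] = gl
            pos += 1
    size = {v: graphlet_of[v].n if v in graphlet_of else 1 for v in range(n_l)}

    # Latent ER throw conditioned on wiring feasibility: each edge landing
    # on a saturated pair (a plain-plain pair already carrying an edge, or
    # a supernode pair at its binomial capacity n_s * n_s') is re-thrown.
    mult: dict[tuple[int, int], int] = {}
    budget = max_retries * max(spec.e_latent, 1)
    placed = 0
    while placed < spec.e_latent:
        if budget <= 0:
            raise RuntimeError(
                "could not place the latent edges within the retry budget; "
                "reduce the density or the motif load"
            )
        budget -= 1
        i, j = pair_of[int(rng.integers(len(pair_of)))]
        if mult.get((i, j), 0) >= size[i] * size[j]:
            continue
        mult[(i, j)] = mult.get((i, j), 0) + 1
        placed += 1

    # expand: allocate G node ids
    expansion: dict[int, tuple[int, ...]] = {}
    next_id = 0
    for v in range(n_l):
        k = size[v]
        expansion[v] = tuple(range(next_id, next_id + k))
        next_id += k

    edges: list[tuple[int, int]] = []
    ground_truth: list[tuple[Graphlet, tuple[int, ...], int]] = []
    for v, gl in sorted(graphlet_of.items()):
        orbit = _orientation_orbit(gl.n, gl.bits)
        bits = int(orbit[rng.integers(len(orbit))])
        members = expansion[v]
        for a, b in edges_from_bits(gl.n, bits):
            edges.append((members[a], members[b]))
        ground_truth.append((gl, members, bits))

    for (u, v), a in sorted(mult.items()):
        src, dst = expansion[u], expansion[v]
        nu, nv = len(src), len(dst)
        if nu == 1 and nv == 1:
            edges.append((src[0], dst[0]))
        elif nv == 1:
            for i in rng.choice(nu, size=a, replace=False):
                edges.append((src[int(i)], dst[0]))
        elif nu == 1:
            for j in rng.choice(nv, size=a, replace=False):
                edges.append((src[0], dst[int(j)]))
        else:
            for p in rng.choice(nu * nv, size=a, replace=False):
                edges.append((src[int(p) // nv], dst[int(p) % nv]))

    graph = DirectedGraph(next_id, edges)
    assert graph.n_edges == spec.e_expanded
    return PlantedGraph(
        graph=graph,
        spec=spec,
        ground_truth=ground_truth,
        latent=Multigraph(n_l, mult),
        expansion=expansion,
    )


def planted_motif_benchmark(
    graphlet: Graphlet,
    copies: int,
    rng: np.random.Generator,
    n_total: int = 300,
    density: float = 0.025,
) -> PlantedGraph:
    """Planted-motif benchmark graph: ``copies`` copies of ``graphlet``
    planted so that the generated graph has ``n_total`` nodes and overall
    edge density ``density`` (background plus motif edges)."""
    n_latent = n_total - copies * (graphlet.n - 1)
    e_total = round(density * n_total * (n_total - 1))
    e_latent = e_total - copies * graphlet.n_edges
    if n_latent <= graphlet.n or e_latent < 0:
        raise ValueError("motif load incompatible with the requested size/density")
    spec = PlantedSpec(
        n_latent=n_latent,
        e_latent=e_latent,
        placements=((graphlet, copies),),
    )
    return plant_motifs(spec, rng)


def connectome_like(
    n: int,
    e: int,
    rng: np.random.Generator,
    reciprocity: float = 0.35,
    degree_sigma: float = 1.0,
) -> DirectedGraph:
    """A synthetic stand-in for a microcircuit wiring diagram: a simple
    directed graph with lognormal in/out degree propensities and a
    prescribed fraction of reciprocated edges.

    Used to set the features phi (degrees, reciprocity counts) that the
    null-model ensembles then preserve exactly; it is not a model of any
    particular connectome.
    """
    if e > n * (n - 1):
        raise ValueError("too many edges")
    w_out = rng.lognormal(0.0, degree_sigma, size=n)
    w_in = rng.lognormal(0.0, degree_sigma, size=n)
    p_out = w_out / w_out.sum()
    p_in = w_in / w_in.sum()
    # fraction q of drawn pairs also receives the reverse edge, so the
    # edge reciprocity is about 2q / (1 + q)
    q = reciprocity / (2.0 - reciprocity)
    edges: set[tuple[int, int]] = set()
    budget = 500 * e
    while len(edges) < e and budget > 0:
        budget -= 1
        i = int(rng.choice(n, p=p_out))
        j = int(rng.choice(n, p=p_in))
        if i == j:
            continue
        edges.add((i, j))
        if len(edges) < e and rng.random() < q:
            edges.add((j, i))
    if len(edges) < e:
        raise RuntimeError("could not reach the requested edge count")
    return DirectedGraph(n, edges)


# ---------------------------------------------------------------------------
# Null-model randomizers
# ---------------------------------------------------------------------------

def _sample_pairs(n: int, k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """k distinct ordered pairs (i, j), i != j, uniformly."""
    idx = rng.choice(n * (n - 1), size=k, replace=False)
    out = []
    for p in idx:
        i, r = divmod(int(p), n - 1)
        j = r if r < i else r + 1
        out.append((i, j))
    return out


def _directed_swaps(
    edges: list[tuple[int, int]],
    forbidden: set[tuple[int, int]],
    n_steps: int,
    rng: np.random.Generator,
    no_reciprocal: bool,
    triangle_prob: float = 0.25,
) -> list[tuple[int, int]]:
    """Degree-preserving Markov chain on a directed edge list: double-edge
    swaps plus 3-cycle reversals, run for a fixed number of proposals.

    Double-edge swaps alone are not ergodic on the set of digraphs with
    fixed in- and out-degrees; reversing directed triangles restores
    ergodicity.  Both move types are involutive with symmetric proposals
    and rejected proposals are self-loops, so the fixed-proposal-count
    chain is aperiodic with a uniform stationary distribution (stopping
    after a fixed number of *accepted* moves instead can condition on a
    parity invariant of small ensembles).
    ``forbidden`` holds ordered pairs that may not be created (existing
    edges, including the list itself); with ``no_reciprocal`` a new edge
    may not close a reciprocal pair either (preserves reciprocal degrees).
    """
    m = len(edges)
    if m < 2:
        return edges
    pos = {e: i for i, e in enumerate(edges)}
    accepted = 0
    for _ in range(n_steps):
        i1, i2 = rng.integers(0, m, size=2)
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        if rng.random() < triangle_prob:
            # try to reverse the directed triangle a -> b -> c -> a formed
            # by e1 = (a, b) and e2 = (c, d) with d == a plus the edge (b, c)
            if d != a or c == b or c == a:
                continue
            i3 = pos.get((b, c))
            if i3 is None:
                continue
            new1, new2, new3 = (b, a), (a, c), (c, b)
            if new1 in forbidden or new2 in forbidden or new3 in forbidden:
                continue
            for old, new, idx in (
                ((a, b), new1, i1), ((c, a), new2, i2), ((b, c), new3, i3)
            ):
                forbidden.discard(old)
                del pos[old]
                forbidden.add(new)
                pos[new] = idx
                edges[idx] = new
            accepted += 1
            continue
        if a == d or c == b:
            continue
        e1, e2 = (a, d), (c, b)
        if e1 in forbidden or e2 in forbidden:
            continue
        if no_reciprocal and ((d, a) in forbidden or (b, c) in forbidden):
            continue
        for old, new, idx in (((a, b), e1, i1), ((c, d), e2, i2)):
            forbidden.discard(old)
            del pos[old]
            forbidden.add(new)
            pos[new] = idx
            edges[idx] = new
        accepted += 1
    if n_steps and accepted == 0 and m >= 2:
        logger.warning("edge-swap chain accepted no moves in %d proposals", n_steps)
    return edges


def _undirected_swaps(
    pairs: list[tuple[int, int]],
    blocked: set[tuple[int, int]],
    n_steps: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Double-edge swaps on undirected pairs (stored as (min, max)), run
    for a fixed number of proposals; ``blocked`` holds unordered pairs
    that may not be created."""
    m = len(pairs)
    if m < 2:
        return pairs
    accepted = 0
    for _ in range(n_steps):
        i1, i2 = rng.integers(0, m, size=2)
        if i1 == i2:
            continue
        a, b = pairs[i1]
        c, d = pairs[i2]
        if rng.integers(2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        p1 = (a, c) if a < c else (c, a)
        p2 = (b, d) if b < d else (d, b)
        if p1 in blocked or p2 in blocked:
            continue
        blocked.discard(pairs[i1])
        blocked.discard(pairs[i2])
        blocked.add(p1)
        blocked.add(p2)
        pairs[i1] = p1
        pairs[i2] = p2
        accepted += 1
    if n_steps and accepted == 0 and m >= 2:
        logger.warning(
            "undirected swap chain accepted no moves in %d proposals", n_steps
        )
    return pairs


def randomize(
    g: DirectedGraph,
    family: str,
    rng: np.random.Generator,
    n_swaps: int | None = None,
) -> DirectedGraph:
    """Sample from the null ensemble of ``family`` seeded at ``g``,
    exactly preserving the family's constrained features phi.

    ER and RER are resampled directly (exactly uniform); CM and RCM use
    Markov-chain edge swaps with ``n_swaps`` proposal attempts per edge
    subset (default 40 * E, which accepts on the order of 10 swaps per
    edge on sparse graphs).
    """
    family = family.upper()
    n = g.n
    if family == "ER":
        return DirectedGraph(n, _sample_pairs(n, g.n_edges, rng))
    if family == "RER":
        h = Multigraph.from_simple(g)
        em, ed = h.reciprocity_stats()
        half_pairs = n * (n - 1) // 2
        idx = rng.choice(half_pairs, size=em + ed, replace=False)

        def offset(i: int) -> int:
            return i * (2 * n - i - 1) // 2

        unordered = []
        for p in idx:
            p = int(p)
            # unrank an unordered pair {i < j} in lexicographic order
            i = (2 * n - 1 - math.isqrt((2 * n - 1) ** 2 - 8 * p)) // 2
            while offset(i + 1) <= p:
                i += 1
            while offset(i) > p:
                i -= 1
            j = i + 1 + (p - offset(i))
            unordered.append((i, j))
        edges = []
        for k, (i, j) in enumerate(unordered):
            if k < em:
                edges.append((i, j))
                edges.append((j, i))
            else:
                edges.append((i, j) if rng.integers(2) else (j, i))
        return DirectedGraph(n, edges)
    if family == "CM":
        edges = sorted(g.edges)
        steps = n_swaps if n_swaps is not None else 40 * len(edges)
        forbidden = set(edges)
        edges = _directed_swaps(edges, forbidden, steps, rng, no_reciprocal=False)
        return DirectedGraph(n, edges)
    if family == "RCM":
        mutual = sorted(
            (i, j) for (i, j) in g.edges if i < j and (j, i) in g.edges
        )
        singles = sorted(
            (i, j) for (i, j) in g.edges if (j, i) not in g.edges
        )
        t_mut = n_swaps if n_swaps is not None else 40 * len(mutual)
        t_sin = n_swaps if n_swaps is not None else 40 * len(singles)
        # a mutual pair may not coincide with any other pair carrying edges
        blocked = set(mutual) | {(min(i, j), max(i, j)) for i, j in singles}
        mutual = _undirected_swaps(mutual, blocked, t_mut, rng)
        forbidden = set(singles)
        for i, j in mutual:
            forbidden.add((i, j))
            forbidden.add((j, i))
        singles = _directed_swaps(
            singles, forbidden, t_sin, rng, no_reciprocal=True
        )
        edges = list(singles)
        for i, j in mutual:
            edges.append((i, j))
            edges.append((j, i))
        return DirectedGraph(n, edges)
    raise ValueError(f"unknown family {family!r}")
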