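"""Topological summaries of inferred motif sets.

Per-graphlet measures (density, reciprocity, number of simple directed
cycles) are averaged over the motif multiset and compared against
fixed-density baselines obtained from random graphlets with the same
number of nodes and edges.  Across graphs, motif prevalence and
concentration summarize which graphlets recur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import Graphlet

__all__ = [
    "MotifSummary",
    "graphlet_density",
    "graphlet_reciprocity",
    "graphlet_cycle_count",
    "motif_summary",
    "motif_prevalence",
]


def graphlet_density(gl: Graphlet) -> float:
    return gl.density


def _edge_reciprocity(edges: Sequence[tuple[int, int]]) -> float:
    edge_set = set(edges)
    if not edge_set:
        return 0.0
    recip = sum(1 for (i, j) in edge_set if (j, i) in edge_set)
    return recip / len(edge_set)


def graphlet_reciprocity(gl: Graphlet) -> float:
    """Fraction of the graphlet's edges that are reciprocated."""
    return _edge_reciprocity(gl.edges)


def _cycle_count(edges: Sequence[tuple[int, int]]) -> int:
    dg = nx.DiGraph(list(edges))
    return sum(1 for c in nx.simple_cycles(dg) if len(c) >= 2)


def graphlet_cycle_count(gl: Graphlet) -> int:
    """Number of simple directed cycles of length >= 2 (exhaustive
    enumeration; graphlets have at most five nodes)."""
    return _cycle_count(gl.edges)


@dataclass
class MotifSummary:
    """Multiset-weighted means of the graphlet measures, with
    fixed-density random baselines."""

    per_graphlet: pd.DataFrame  # index: graphlet id
    mean_density: float
    mean_reciprocity: float
    mean_cycles: float
    baseline_reciprocity: float
    baseline_cycles: float
    n_random: int


def _random_same_density(
    n: int, e: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    idx = rng.choice(len(pairs), size=e, replace=False)
    return [pairs[int(p)] for p in idx]


def motif_summary(
    motifs: Mapping[Graphlet, int] | Sequence[Graphlet],
    rng: np.random.Generator | None = None,
    n_random: int = 100,
) -> MotifSummary:
    """Topological profile of a motif multiset.

    ``motifs`` maps graphlets to multiplicities (or is a plain sequence).
    Baselines average each measure over ``n_random`` random digraphs per
    motif with the motif's node and edge count (density conserved by
    construction).
    """
    if not isinstance(motifs, Mapping):
        counts: dict[Graphlet, int] = {}
        for gl in motifs:
            counts[gl] = counts.get(gl, 0) + 1
        motifs = counts
    if not motifs:
        raise ValueError("empty motif set")
    if rng is None:
        rng = np.random.default_rng(0)

    rows = []
    total = sum(motifs.values())
    mean_density = mean_recip = mean_cycles = 0.0
    base_recip = base_cycles = 0.0
    for gl, m in sorted(motifs.items()):
        dens = gl.density
        recip = graphlet_reciprocity(gl)
        cycles = graphlet_cycle_count(gl)
        b_recip = b_cycles = 0.0
        for _ in range(n_random):
            edges = _random_same_density(gl.n, gl.n_edges, rng)
            b_recip += _edge_reciprocity(edges)
            b_cycles += _cycle_count(edges)
        b_recip /= n_random
        b_cycles /= n_random
        rows.append(
            {
                "graphlet": gl.id,
                "m": m,
                "density": dens,
                "reciprocity": recip,
                "cycles": cycles,
                "baseline_reciprocity": b_recip,
                "baseline_cycles": b_cycles,
            }
        )
        w = m / total
        mean_density += w * dens
        mean_recip += w * recip
        mean_cycles += w * cycles
        base_recip += w * b_recip
        base_cycles += w * b_cycles
    frame = pd.DataFrame(rows).set_index("graphlet")
    return MotifSummary(
        per_graphlet=frame,
        mean_density=mean_density,
        mean_reciprocity=mean_recip,
        mean_cycles=mean_cycles,
        baseline_reciprocity=base_recip,
        baseline_cycles=base_cycles,
        n_random=n_random,
    )


def motif_prevalence(
    motif_sets: Sequence[Mapping[str, int]]
) -> pd.DataFrame:
    """Cross-graph motif statistics.

    For each graphlet id: prevalence p = fraction of graphs whose motif
    set contains it, and concentration c = mean (over graphs with a
    nonempty motif set) of its share m_alpha / sum_beta m_beta.
    """
    if not motif_sets:
        raise ValueError("need at least one motif set")
    n_graphs = len(motif_sets)
    nonempty = [ms for ms in motif_sets if sum(ms.values()) > 0]
    ids = sorted({gid for ms in motif_sets for gid in ms})
    if not ids:
        return pd.DataFrame(
            columns=["prevalence", "concentration"],
            index=pd.Index([], name="graphlet"),
        )
    rows = []
    for gid in ids:
        p = sum(1 for ms in motif_sets if ms.get(gid, 0) > 0) / n_graphs
        if nonempty:
            c = float(
                np.mean([ms.get(gid, 0) / sum(ms.values()) for ms in nonempty])
            )
        else:
            c = 0.0
        rows.append({"graphlet": gid, "prevalence": p, "concentration": c})
    return pd.DataFrame(rows).set_index("graphlet")
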