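"""Hypothesis-testing motif mining (the classical comparator).

Each graphlet's count in the observed graph is compared against its count
distribution in graphs randomized under a prescribed null model; a
graphlet is flagged as a motif when it is significantly over-represented
after Bonferroni correction over the whole dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .census import graphlet_counts
from .generators import randomize
from .graphs import DirectedGraph, Graphlet

__all__ = ["HTResult", "ht_motif_mining"]


@dataclass
class HTResult:
    """Per-graphlet test results and the settings that produced them."""

    table: pd.DataFrame  # index: graphlet id
    null_family: str
    n_null: int
    alpha: float
    bonferroni_m: int

    @property
    def motifs(self) -> list[str]:
        return list(self.table.index[self.table["is_motif"]])

    @property
    def n_motifs(self) -> int:
        return int(self.table["is_motif"].sum())


def ht_motif_mining(
    g: DirectedGraph,
    gamma: tuple[Graphlet, ...],
    null_family: str,
    rng: np.random.Generator,
    n_null: int = 10,
    alpha: float = 0.01,
    bonferroni_m: int | None = None,
    backend: str = "auto",
) -> HTResult:
    """Classic motif mining against one null model.

    For each graphlet: z = (N_obs - mean_null) / sd_null (0 when the null
    is degenerate), one-sided Gaussian p-value for over-representation,
    Bonferroni correction by the dictionary size.  A graphlet absent from
    the observed graph is never flagged.
    """
    if n_null < 2:
        raise ValueError("need at least two null samples")
    sizes = sorted({gl.n for gl in gamma})
    ids = [gl.id for gl in gamma]
    m = bonferroni_m if bonferroni_m is not None else len(gamma)

    obs_counts = graphlet_counts(g, sizes, backend=backend)
    obs = np.array([obs_counts.get(gid, 0) for gid in ids], dtype=float)
    null = np.zeros((n_null, len(ids)))
    for r in range(n_null):
        sample = randomize(g, null_family, rng)
        counts = graphlet_counts(sample, sizes, backend=backend)
        null[r] = [counts.get(gid, 0) for gid in ids]

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    p_raw = stats.norm.sf(z)
    p_corr = np.minimum(1.0, p_raw * m)
    is_motif = (p_raw * m < alpha) & (obs > 0)

    table = pd.DataFrame(
        {
            "count": obs.astype(int),
            "null_mean": mean,
            "null_sd": sd,
            "z": z,
            "p_raw": p_raw,
            "p_corrected": p_corr,
            "is_motif": is_motif,
        },
        index=pd.Index(ids, name="graphlet"),
    )
    return HTResult(
        table=table,
        null_family=null_family.upper(),
        n_null=n_null,
        alpha=alpha,
        bonferroni_m=m,
    )
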