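"""Topological profile of an inferred motif set.

Summarizes a motif multiset by density, edge reciprocity and simple-cycle
count, compares against fixed-density random baselines, and aggregates
motif prevalence and concentration across several graphs' motif sets.
"""

import numpy as np

from mdlmotifs import Graphlet, clique_graphlet, motif_prevalence, motif_summary

k5 = clique_graphlet(5)
triangle = Graphlet.from_edges(3, [(0, 1), (1, 2), (2, 0)])
ffl = Graphlet.from_edges(3, [(0, 1), (0, 2), (1, 2)])  # feed-forward loop

summary = motif_summary({k5: 4, triangle: 2, ffl: 1}, np.random.default_rng(0))
print("per-graphlet measures:")
print(summary.per_graphlet.round(3).to_string())
print(f"\nmultiset means: density={summary.mean_density:.3f} "
      f"reciprocity={summary.mean_reciprocity:.3f} cycles={summary.mean_cycles:.2f}")
print(f"fixed-density baselines: reciprocity={summary.baseline_reciprocity:.3f} "
      f"cycles={summary.baseline_cycles:.2f}")

# prevalence / concentration across three graphs' inferred sets
sets = [
    {k5.id: 3, triangle.id: 1},
    {k5.id: 1},
    {ffl.id: 2, triangle.id: 2},
]
print("\ncross-graph prevalence and concentration:")
print(motif_prevalence(sets).round(3).to_string())

# A reciprocity far above its fixed-density baseline indicates that the
# motifs' feedback structure is not a mere consequence of their density.
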