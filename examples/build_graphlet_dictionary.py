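"""Enumerate the directed graphlet dictionary.

Builds the isomorphism classes of weakly connected digraphs for each size
and prints the class counts plus a few example graphlets with their
automorphism structure.  The total over sizes 3-5 is the dictionary size
|Gamma| used to price motif identities in the codelength.
"""

from mdlmotifs import enumerate_graphlets

for n in (2, 3, 4):
    gamma = enumerate_graphlets(n, n)
    print(f"{n}-node weakly connected digraph classes: {len(gamma)}")

gamma35 = enumerate_graphlets(3, 5)
print(f"dictionary size |Gamma| for sizes 3-5: {len(gamma35)}")

print("\nsome 3-node graphlets (id, edges, |Aut|, orientations):")
for gl in enumerate_graphlets(3, 3)[:5]:
    print(f"  {gl.id}  {gl.edges}  aut={gl.aut}  orientations={gl.orientations}")

# The number of distinguishable orientations n!/|Aut| is the price (in
# log2 units) of recovering how a contracted subgraph was oriented.
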