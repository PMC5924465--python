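"""Compare circular gene orders: breakpoint distances and synteny blocks.

Starts from one 13-gene order, applies known numbers of random single-gene
transpositions, and prints the pairwise BD/BDn matrix (BD above the diagonal,
BDn below, as the field's summary tables are laid out) plus the conserved
synteny blocks for one pair.
"""

from ctenomito.rearrange import (
    GeneOrder,
    distance_matrix,
    render_distance_table,
    synteny_blocks,
)
from ctenomito.simulate import rearrange_order

base = GeneOrder(
    "ancestor",
    ("cox1", "cox2", "nad4", "nad4L", "nad1", "nad2", "nad5",
     "nad6", "cob", "cox3", "nad3", "rnl", "rns"),
)
few, _ = rearrange_order(base, k_moves=2, seed=1)
many, _ = rearrange_order(base, k_moves=20, seed=2)
few = GeneOrder("few_moves", few.order)
many = GeneOrder("many_moves", many.order)

print(render_distance_table(distance_matrix([base, few, many])))
print()
blocks = synteny_blocks(base, few)
print(f"synteny blocks conserved between ancestor and few_moves ({len(blocks)}):")
for b in blocks:
    print("  " + "-".join(b.genes))
# BDn near 1 (13/13) means the orders share almost no adjacencies -
# rearrangement close to random; BD 0 means identical circular orders.
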