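"""Reconstruct and date a clone genealogy from shared mutations.

Two SS clones sharing a mutation plus one unrelated SS clone: the shared
mutation forces a cherry, the loner attaches at the ancestral root, and
every mutation is dated to the midpoint between the sample where it first
appears and the previous sample.
"""

import pandas as pd

from fossilrecord import (
    CloneGenotype,
    FrequencySeries,
    GenerationScale,
    build_genealogy,
    count_independent_origins,
    date_tree,
    day_to_generation,
    to_newick,
)
from fossilrecord.genealogy import dating_table

days = [0, 61, 72, 138, 156]
alt = pd.DataFrame(
    {0: [0, 0, 0], 61: [0, 0, 0], 72: [12, 10, 0], 138: [55, 30, 20], 156: [60, 35, 25]},
    index=["spoT-454", "nadR-290", "rbs-del"],
)
total = alt * 0 + 100
series = FrequencySeries("p19", alt, total, GenerationScale())

clones = [
    CloneGenotype("SS1", "p19", "SS", frozenset({"spoT-454", "nadR-290"}), 156),
    CloneGenotype("SS2", "p19", "SS", frozenset({"spoT-454"}), 156),
    CloneGenotype("SS3", "p19", "SS", frozenset({"rbs-del"}), 156),
]

tree = build_genealogy(clones, series)
date_tree(tree, series, extraction_gen=day_to_generation(156))

print("newick:", to_newick(tree))
print()
print(dating_table(tree).to_string(index=False))
print()
print("independent SS origins:", count_independent_origins(clones, "SS"))
print()
print(
    "spoT-454 and nadR-290 first appear at day 72 (generation 482), so both\n"
    "are dated to (408 + 482) / 2 = 445; SS3 shares nothing with SS1/SS2 and\n"
    "therefore counts as a second, independent origin of the SS phenotype."
)
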