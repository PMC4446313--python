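"""Expand a genus-level backbone into a species tree and compute ED.

A tiny dated backbone carries one representative tip per genus.  Grafting
replaces each representative with a polytomy of all its congeners, placed at
min(half the pendant-branch age, the 80th quantile of genus ages), keeping
the tree dated.  Fair-proportion ED then splits every branch's length
equally among its descendant species.
"""

import edam
from edam.phylo import GenusExpansionTable, graft_congeners, write_tree

backbone = edam.read_tree("((Isoetes_rep:1,Selaginella_rep:1):1,Pinus_rep:2);")
table = GenusExpansionTable(
    {
        "Isoetes": ["Isoetes_echinospora", "Isoetes_lacustris"],
        "Selaginella": ["Selaginella_selaginoides"],
        "Pinus": ["Pinus_sylvestris"],
    }
)

grafted = graft_congeners(backbone, table, quantile=0.8)
print("grafted tree:", write_tree(grafted))

ed = edam.ed_table(grafted)
print(ed.round(4))
print(f"sum of ED = {ed['ed'].sum():.4f} (total branch length conserved)")
# The two Isoetes species split their genus branch, so each is less
# distinctive than the lone Selaginella; Pinus keeps the longest branch.
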