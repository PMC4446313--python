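"""Relative change index (RCI) from two-period atlas occupancy.

RCI is the residual of a regression of logit occupancy in the later period
on logit occupancy in the earlier one, negated so larger = steeper decline
relative to the assemblage.  A species that lost range while similar-sized
species held steady gets a high RCI.
"""

import pandas as pd

from edam import OccupancyTable, relative_change_index

occ = OccupancyTable(
    pd.DataFrame(
        {
            "occupied_t1": [700, 420, 150, 70, 300],
            "occupied_t2": [690, 400, 60, 72, 295],
            "total_cells": 1000,
        },
        index=pd.Index(
            ["steady_wide", "steady_mid", "collapsing", "steady_rare", "mild"],
            name="species",
        ),
    )
)

rci = relative_change_index(occ)
print(rci.round(3).sort_values(ascending=False))
# 'collapsing' lost over half its cells and tops the index; the residuals
# sum to zero because decline is measured relative to the assemblage trend.
print(f"sum of residuals = {rci.sum():.2e}")
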