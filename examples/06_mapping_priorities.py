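"""Map priority species onto a grid: top-k counts and mean scores per cell.

Conservation action happens in places, not lists: counting how many of the
top-k ranked species occur in each grid cell shows where priorities
concentrate.  Ties at the rank-k boundary are included.
"""

import edam

study = edam.simulate_study(
    edam.SimulationConfig(n_species=30, n_genera=12, n_cells=60, seed=8)
)
comp = edam.study_components(study)
scored = edam.compose_measure("EDAM", comp)

counts = edam.topk_cell_counts(scored, study.grid, k=10)
means = edam.mean_cell_score(scored, study.grid)

print("cells richest in top-10 priority species:")
print(counts.sort_values(ascending=False).head(5))
print("\nmean priority score in those cells:")
print(means[counts.sort_values(ascending=False).head(5).index].round(3))
# A cell can hold many top-priority species yet have a modest mean score if
# it is also rich in low-priority species.
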