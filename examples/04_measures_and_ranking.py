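"""Compose the EDGE / EDM / EDAM measure family and rank a synthetic flora.

Each EDAM-family measure sums z-scaled components: ln(ED), magnitude of
decline M (reversed RCI), and accuracy A (Acc_TV, negated so poorly
predicted declines rank higher).  EDGE is the classic unscaled
ln(ED) + Red List code.
"""

import edam

study = edam.simulate_study(
    edam.SimulationConfig(n_species=40, n_genera=15, seed=11)
)
comp = edam.study_components(study, include_gain=True)

for measure in ("EDGE", "EDM", "EDAM", "EDAM'", "ED(AM)max"):
    scored = edam.compose_measure(measure, comp)
    top = scored.sort_values("rank").head(3)
    names = ", ".join(top.index)
    print(f"{measure:<10} ties={scored.attrs['tie_count']:>2}  top 3: {names}")

edge = edam.compose_measure("EDGE", comp)
edm = edam.compose_measure("EDM", comp)
print("EDGE vs EDM:", edam.compare_scores(edge, edm))
# EDGE produces tied scores whenever congeners share ED and Red List code;
# EDM discriminates every species because RCI is continuous.
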