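"""End-to-end convenience: raw study inputs -> component table -> measures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import accuracy, decline, distinctiveness, measures, phylo

__all__ = ["accuracy_by_species", "study_components", "score_study"]


def accuracy_by_species(
    predictions: dict, direction: str = "both", df: int = 3
) -> pd.Series:
    """Acc_TV per species from a dict of TemporalPrediction objects.

    Species whose masked site subset is degenerate (too few distinct
    predicted changes to fit the spline, or no predicted change at all)
    get NaN and are later dropped listwise by the component join.
    """
    out = {}
    for sp, pred in predictions.items():
        try:
            out[sp] = accuracy.directional_acc(pred, direction=direction, df=df).acc_tv
        except ValueError:
            out[sp] = np.nan
    return pd.Series(out, name=f"acc_{direction}")


def study_components(
    study,
    quantile: float = 0.8,
    spline_df: int = 3,
    adjust_occupancy: bool = False,
    include_gain: bool = False,
) -> pd.DataFrame:
    """Component table (log ED, M, A, GE + z-twins) for a study.

    Grafts congeners onto the backbone, normalises the root age to 1,
    computes fair-proportion ED, the reversed relative change index, the
    Acc_TV accuracy, and Red List codes, then inner-joins them per species.

    The headline A component pools gains and losses (direction "both"): the
    calibration identity behind the ideal TV line holds exactly there, and
    the pooled score is the least noisy.  ``include_gain=True`` adds the
    gain-direction Acc_TV column needed by the EDAM' preset; species whose
    gain subset is degenerate (e.g. steep decline everywhere) are then
    dropped listwise from the join.
    """
    tree = phylo.graft_congeners(study.tree, study.genera, quantile=quantile)
    tree = phylo.scale_root_age(tree, 1.0, force=True)
    led = distinctiveness.log_ed(distinctiveness.fair_proportion(tree))
    m = decline.relative_change_index(study.occupancy, adjust=adjust_occupancy)
    a = accuracy_by_species(study.predictions, "both", df=spline_df)
    a_gain = (
        accuracy_by_species(study.predictions, "gain", df=spline_df)
        if include_gain
        else None
    )
    ge = study.threat.map(decline.red_list_code)
    return measures.build_component_table(
        log_ed=led, m=m, a=a, a_gain=a_gain, ge=ge
    )


def score_study(study, measure="EDAM", **kwargs) -> pd.DataFrame:
    """Ranked score table for one measure on a (synthetic or real) study."""
    comp = study_components(study, **kwargs)
    return measures.compose_measure(measure, comp)
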