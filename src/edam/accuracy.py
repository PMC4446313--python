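"""Temporal-validation accuracy (Acc_TV) of distribution-model predictions.

A temporal-validation (TV) plot regresses observed site-level change in
occupancy (-1 lost, 0 unchanged, +1 gained) on the change in modelled
probability of presence between two periods, using a natural-spline smooth.
A perfectly calibrated model traces the ideal curve y = x: sites predicted
to gain probability 0.3 should, on average, show a 0.3 excess of gains.

Acc_TV summarises a TV plot as one minus the weighted mean distance between
the fitted and the ideal curve,

    Acc_TV = 1 - sum_q w_q |yhat(x_q) - x_q| / sum_q w_q,   w_q = |x_q|,

so that sites whose modelled probability barely changes contribute little,
focusing the score on the parts of the range observed or predicted to
change.  Acc_TV <= 1, with 1 attained exactly when the fitted curve matches
the ideal line at every weighted site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix

__all__ = [
    "TemporalPrediction",
    "TVCurve",
    "AccResult",
    "site_changes",
    "fit_tv_curve",
    "acc_tv",
    "directional_acc",
]

Direction = Literal["both", "loss", "gain"]


@dataclass
class TemporalPrediction:
    """Per-site modelled probabilities and observed presence at two periods."""

    p1_model: np.ndarray
    p2_model: np.ndarray
    obs1: np.ndarray
    obs2: np.ndarray

    def __post_init__(self) -> None:
        self.p1_model = np.asarray(self.p1_model, dtype=float)
        self.p2_model = np.asarray(self.p2_model, dtype=float)
        self.obs1 = np.asarray(self.obs1, dtype=bool)
        self.obs2 = np.asarray(self.obs2, dtype=bool)
        n = self.p1_model.size
        if not (self.p2_model.size == self.obs1.size == self.obs2.size == n):
            raise ValueError("all site vectors must have equal length")
        for p in (self.p1_model, self.p2_model):
            if ((p < 0) | (p > 1)).any():
                raise ValueError("modelled probabilities must lie in [0, 1]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemporalPrediction":
        return cls(
            df["p1_model"].to_numpy(),
            df["p2_model"].to_numpy(),
            df["obs1"].to_numpy(),
            df["obs2"].to_numpy(),
        )

    def __len__(self) -> int:
        return self.p1_model.size


@dataclass
class TVCurve:
    """Natural-spline least-squares fit of observed change on predicted change."""

    x: np.ndarray
    fitted: np.ndarray
    coef: np.ndarray
    design_info: object
    df: int

    def predict(self, x_new) -> np.ndarray:
        (mat,) = build_design_matrices([self.design_info], {"x": np.asarray(x_new)})
        return np.asarray(mat) @ self.coef


@dataclass
class AccResult:
    acc_tv: float
    weights: np.ndarray = field(repr=False)
    direction: Direction = "both"
    n: int = 0


def site_changes(pred: TemporalPrediction):
    """Per-site predicted change x, observed change o, and direction masks.

    x_q = p2_model - p1_model; o_q = +1 for a gain (absent -> present), -1
    for a loss, 0 otherwise.  The loss (gain) mask keeps sites whose
    modelled probability is predicted to fall (rise).  Masking on predicted
    change alone preserves the calibration identity E[o | x] = x that the
    ideal TV line expresses; conditioning on the *observed* initial state
    instead would shift the conditional mean (on occupied sites
    E[o | x] = x - (1 - p1)) and bias the directional scores by occupancy
    level.  Sites with x = 0 fall in neither mask; they carry zero weight
    in Acc_TV regardless.
    """
    x = pred.p2_model - pred.p1_model
    o = pred.obs2.astype(int) - pred.obs1.astype(int)
    loss_mask = x < 0
    gain_mask = x > 0
    return x, o, loss_mask, gain_mask


def fit_tv_curve(x, o, df: int = 3) -> TVCurve:
    """Least-squares natural-spline fit of observed change ``o`` on ``x``.

    Deterministic given its inputs and invariant to site order.  Requires
    at least ``df + 2`` distinct x values.
    """
    x = np.asarray(x, dtype=float)
    o = np.asarray(o, dtype=float)
    if x.size != o.size:
        raise ValueError("x and o must have equal length")
    n_distinct = np.unique(x).size
    if n_distinct < df + 2:
        raise ValueError(
            f"need >= {df + 2} distinct predicted-change values, got {n_distinct}"
        )
    design = dmatrix("cr(x, df=df)", {"x": x, "df": df}, return_type="matrix")
    coef, *_ = np.linalg.lstsq(np.asarray(design), o, rcond=None)
    fitted = np.asarray(design) @ coef
    return TVCurve(x=x, fitted=fitted, coef=coef,
                   design_info=design.design_info, df=df)


def acc_tv(curve: TVCurve, x=None, direction: Direction = "both") -> AccResult:
    """Acc_TV of a fitted TV curve, weighting each site by |x_q|."""
    x = curve.x if x is None else np.asarray(x, dtype=float)
    yhat = curve.fitted if x is curve.x else curve.predict(x)
    weights = np.abs(x)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no predicted change to validate (all x_q = 0)")
    score = 1.0 - float(np.sum(weights * np.abs(yhat - x)) / total)
    return AccResult(acc_tv=score, weights=weights, direction=direction, n=x.size)


def directional_acc(
    pred: TemporalPrediction, direction: Direction = "both", df: int = 3
) -> AccResult:
    """Acc_TV over all sites, or restricted to loss- or gain-eligible sites.

    The loss direction scores how well decline is predicted (the A term of
    EDAM); the gain direction scores range expansion (EDAM-prime).
    """
    x, o, loss_mask, gain_mask = site_changes(pred)
    if direction == "both":
        mask = np.ones_like(x, dtype=bool)
    elif direction == "loss":
        mask = loss_mask
    elif direction == "gain":
        mask = gain_mask
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not mask.any():
        raise ValueError(f"no sites eligible for direction {direction!r}")
    curve = fit_tv_curve(x[mask], o[mask], df=df)
    return acc_tv(curve, direction=direction)
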