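"""Magnitude of decline: Telfer relative change index and Red List coding.

The relative change index (RCI) of a species is its residual from an OLS
regression of logit occupancy proportion in the later period on logit
occupancy in the earlier period, across all species.  It measures decline
*relative to the assemblage*: a species on the fitted line changed exactly as
expected given its earlier range size.  By convention the residuals are
negated so that larger values mean steeper relative decline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "OccupancyTable",
    "logit",
    "ols_residuals",
    "relative_change_index",
    "red_list_code",
    "RED_LIST_CODES",
]

log = logging.getLogger(__name__)


@dataclass
class OccupancyTable:
    """Per-species occupied-cell counts for two atlas periods.

    ``data`` columns: occupied_t1, occupied_t2, total_cells_t1,
    total_cells_t2 (a single ``total_cells`` column is accepted and applied
    to both periods).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "total_cells" in df.columns and "total_cells_t1" not in df.columns:
            df = df.assign(
                total_cells_t1=df["total_cells"], total_cells_t2=df["total_cells"]
            )
        required = {"occupied_t1", "occupied_t2", "total_cells_t1", "total_cells_t2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"occupancy table missing columns {sorted(missing)}")
        if (df[list(required)] < 0).any().any():
            raise ValueError("negative counts in occupancy table")
        if (df["occupied_t1"] > df["total_cells_t1"]).any() or (
            df["occupied_t2"] > df["total_cells_t2"]
        ).any():
            raise ValueError("occupied cells exceed total cells")
        if (df["total_cells_t1"] != df["total_cells_t2"]).any():
            log.warning("total cell counts differ between periods")
        self.data = df

    @classmethod
    def from_csv(cls, path) -> "OccupancyTable":
        return cls(pd.read_csv(path, index_col="species"))

    def proportions(self, adjust: bool = False) -> tuple[pd.Series, pd.Series]:
        """Occupancy proportions (p1, p2); ``adjust`` applies the empirical
        correction p* = (k + 0.5) / (N + 1), keeping boundary species usable."""
        df = self.data
        if adjust:
            p1 = (df["occupied_t1"] + 0.5) / (df["total_cells_t1"] + 1.0)
            p2 = (df["occupied_t2"] + 0.5) / (df["total_cells_t2"] + 1.0)
        else:
            p1 = df["occupied_t1"] / df["total_cells_t1"]
            p2 = df["occupied_t2"] / df["total_cells_t2"]
        return p1, p2


def logit(p, species=None):
    """ln(p / (1 - p)) for proportions strictly inside (0, 1)."""
    arr = np.asarray(p, dtype=float)
    bad = (arr <= 0) | (arr >= 1)
    if bad.any():
        if species is not None:
            names = list(np.asarray(species)[bad])
        elif isinstance(p, pd.Series):
            names = list(p.index[bad])
        else:
            names = list(np.flatnonzero(bad))
        raise ValueError(
            f"proportion on the boundary for {names}; use the empirical "
            "adjustment (adjust=True) to handle 0/1 occupancy"
        )
    out = np.log(arr / (1.0 - arr))
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out if arr.ndim else float(out)


def ols_residuals(x, y) -> np.ndarray:
    """Residuals of the ordinary least squares fit y = a + b x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points for the regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(fit.resid)


def relative_change_index(
    occ: OccupancyTable, reverse: bool = True, adjust: bool = False
) -> pd.Series:
    """Telfer relative change index per species.

    Residuals of logit(p2) regressed on logit(p1), negated when ``reverse``
    (the default) so that larger values indicate steeper relative decline.
    """
    p1, p2 = occ.proportions(adjust=adjust)
    resid = ols_residuals(logit(p1), logit(p2))
    if reverse:
        resid = -resid
    return pd.Series(resid, index=occ.data.index, name="rci")


#: IUCN 2001 categories on the coarse integer scale used by EDGE scoring.
RED_LIST_CODES = {
    "LC": 0, "LEAST CONCERN": 0,
    "NT": 1, "NEAR THREATENED": 1,
    "CD": 1, "CONSERVATION DEPENDENT": 1, "LR/CD": 1,
    "VU": 2, "VULNERABLE": 2,
    "EN": 3, "ENDANGERED": 3,
    "CR": 4, "CRITICALLY ENDANGERED": 4,
}


def red_list_code(category: str) -> int:
    """Integer code of a Red List category: LC=0, NT/CD=1, VU=2, EN=3, CR=4."""
    key = str(category).strip().upper()
    try:
        return RED_LIST_CODES[key]
    except KeyError:
        accepted = sorted(set(RED_LIST_CODES))
        raise ValueError(
            f"unknown Red List category {category!r}; accepted: {accepted}"
        ) from None
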