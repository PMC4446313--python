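"""Composite prioritisation measures: EDGE, EDM, EDAM, EDAM', ED(AM)_max.

Each measure sums per-species components — log evolutionary distinctiveness
(ED), magnitude of decline (M, the reversed relative change index), accuracy
of decline prediction (A, Acc_TV), and the Red List integer code (GE).  In
the EDAM family every component is z-scaled (mean 0, s.d. 1) before being
combined, so each contributes equally unless an explicit weight says
otherwise; EDGE keeps the traditional unscaled ln(ED) + GE.  Sign
conventions: M is already reversed so decline is positive, and A enters
negated in the decline-focused measures so that *poorly understood* declines
raise priority.  A "prime" negates a term (EDAM' prioritises expanding
ranges with poorly predicted gains); the max-combiner of ED(AM)_max is
precautionary, taking the worse of the M and negated-A terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Term",
    "MeasureSpec",
    "PRESETS",
    "zscale",
    "build_component_table",
    "compose_measure",
    "edge_score",
    "rank_scores",
    "compare_scores",
]

Component = Literal["ED", "M", "A", "A_GAIN", "GE"]

#: component keyword -> raw column of the component table
_RAW_COLUMN = {
    "ED": "log_ed",
    "M": "m",
    "A": "a",
    "A_GAIN": "a_gain",
    "GE": "ge",
}


@dataclass(frozen=True)
class Term:
    component: Component
    sign: int = 1
    weight: float = 1.0
    scaled: bool = True

    def __post_init__(self) -> None:
        if self.component not in _RAW_COLUMN:
            raise ValueError(f"unknown component {self.component!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError("weight must be finite and >= 0")


@dataclass(frozen=True)
class MeasureSpec:
    """Declarative recipe for one measure: signed, weighted terms plus a
    combiner (plain sum, or ED plus the max of the remaining terms)."""

    name: str
    terms: tuple[Term, ...]
    combiner: Literal["sum", "ed_plus_max_of_rest"] = "sum"

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ValueError("a measure needs at least one term")
        if self.combiner not in ("sum", "ed_plus_max_of_rest"):
            raise ValueError(f"unknown combiner {self.combiner!r}")


PRESETS: dict[str, MeasureSpec] = {
    "EDGE": MeasureSpec(
        "EDGE",
        (Term("ED", scaled=False), Term("GE", scaled=False)),
    ),
    "EDM": MeasureSpec("EDM", (Term("ED"), Term("M"))),
    "EDAM": MeasureSpec("EDAM", (Term("ED"), Term("M"), Term("A", sign=-1))),
    "EDAM'": MeasureSpec(
        "EDAM'",
        (Term("ED"), Term("M", sign=-1), Term("A_GAIN", sign=-1)),
    ),
    "ED(AM)max": MeasureSpec(
        "ED(AM)max",
        (Term("ED"), Term("M"), Term("A", sign=-1)),
        combiner="ed_plus_max_of_rest",
    ),
}


def zscale(values) -> np.ndarray:
    """Centre to mean 0 and scale to s.d. 1 (sample, n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to z-scale")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-scale a constant vector")
    out = (arr - arr.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def build_component_table(
    log_ed: pd.Series,
    m: pd.Series | None = None,
    a: pd.Series | None = None,
    a_gain: pd.Series | None = None,
    ge: pd.Series | None = None,
) -> pd.DataFrame:
    """Inner-join components on species and add z-scaled twins.

    Species missing any supplied component are dropped listwise (reported
    via a ``dropped`` attribute on the returned frame), never imputed.
    """
    pieces = {"log_ed": log_ed, "m": m, "a": a, "a_gain": a_gain, "ge": ge}
    cols = {k: v for k, v in pieces.items() if v is not None}
    table = pd.DataFrame(cols).dropna()
    union = set().union(*(set(v.index) for v in cols.values()))
    dropped = sorted(union - set(table.index))
    for col in ("log_ed", "m", "a", "a_gain"):
        if col in table.columns:
            table[f"z_{col}"] = zscale(table[col])
    table.attrs["dropped"] = dropped
    return table


def _term_values(term: Term, comp: pd.DataFrame) -> pd.Series:
    raw = _RAW_COLUMN[term.component]
    col = f"z_{raw}" if term.scaled and term.component != "GE" else raw
    if col not in comp.columns:
        raise ValueError(
            f"component table lacks column {col!r} needed by term "
            f"{term.component}"
        )
    return term.weight * term.sign * comp[col]


def compose_measure(spec: MeasureSpec | str, comp: pd.DataFrame) -> pd.DataFrame:
    """Score every species under a measure; returns a ranked score table.

    ``spec`` may be a preset name (EDGE, EDM, EDAM, EDAM', ED(AM)max) or a
    custom :class:`MeasureSpec`.
    """
    if isinstance(spec, str):
        try:
            spec = PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown preset {spec!r}; available: {sorted(PRESETS)}"
            ) from None
    values = [_term_values(t, comp) for t in spec.terms]
    if spec.combiner == "sum":
        score = sum(values)
    else:  # ED term plus the max over the remaining signed, weighted terms
        ed_terms = [v for t, v in zip(spec.terms, values) if t.component == "ED"]
        rest = [v for t, v in zip(spec.terms, values) if t.component != "ED"]
        if not rest:
            raise ValueError("ed_plus_max_of_rest needs at least one non-ED term")
        score = sum(ed_terms) + pd.concat(rest, axis=1).max(axis=1)
    out = pd.DataFrame({"score": score})
    out.attrs["measure"] = spec.name
    return rank_scores(out)


def edge_score(log_ed: pd.Series, ge: pd.Series) -> pd.DataFrame:
    """Classic EDGE: unscaled ln(ED) + Red List code, ranked."""
    ge = pd.Series(ge)
    if not ge.isin([0, 1, 2, 3, 4]).all():
        raise ValueError("GE codes must be integers 0-4")
    comp = build_component_table(log_ed=log_ed, ge=ge)
    return compose_measure("EDGE", comp)


def rank_scores(scores: pd.DataFrame, decimals: int = 12) -> pd.DataFrame:
    """Attach descending min-ranks and a tie flag to a score table.

    Ties are exact equalities after rounding to ``decimals`` places; the
    tie count (species sharing a score with at least one other) is stored
    in ``attrs['tie_count']``.
    """
    s = scores["score"].round(decimals)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    out = scores.copy()
    out["rank"] = stats.rankdata(-s, method="min").astype(int)
    counts = s.value_counts()
    out["tied"] = s.map(counts) > 1
    out.attrs.update(scores.attrs)
    out.attrs["tie_count"] = int(out["tied"].sum())
    return out


def compare_scores(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Pearson r and r^2 of two score tables over their shared species."""
    joined = a[["score"]].join(b[["score"]], how="inner", lsuffix="_a", rsuffix="_b")
    if len(joined) < 3:
        raise ValueError("need at least 3 shared species")
    x, y = joined["score_a"], joined["score_b"]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in scores")
    r = float(np.corrcoef(x, y)[0, 1])
    return {"r": r, "r2": r * r, "n": len(joined)}
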