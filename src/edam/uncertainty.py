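"""Phylogenetic uncertainty and spatial summaries of priority scores.

Scores depend on the tree through ED, so the whole grafting -> ED -> measure
pipeline is recomputed on every credible (e.g. bootstrap) tree; the spread of
each species' rank across trees measures how robust its priority is to
phylogenetic uncertainty.  When per-tree log-likelihoods are available, a
likelihood-weighted mean score uses softmax weights exp(logL - max logL).

The spatial summaries project a ranked score table onto a species x grid-cell
presence matrix: counts of top-k species per cell (k = 50 in national
prioritisation practice) and mean score of the species present in each cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import distinctiveness, measures, phylo

__all__ = [
    "TreeSet",
    "PresenceGrid",
    "scores_over_trees",
    "summarize_uncertainty",
    "topk_cell_counts",
    "mean_cell_score",
]

log = logging.getLogger(__name__)


@dataclass
class TreeSet:
    """A collection of credible trees, optionally with log-likelihoods."""

    trees: list
    log_likelihoods: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.log_likelihoods is not None:
            self.log_likelihoods = np.asarray(self.log_likelihoods, dtype=float)
            if self.log_likelihoods.size != len(self.trees):
                raise ValueError("one log-likelihood per tree required")
            if not np.isfinite(self.log_likelihoods).all():
                raise ValueError("log-likelihoods must be finite")

    def __len__(self) -> int:
        return len(self.trees)


@dataclass
class PresenceGrid:
    """Boolean species x cell presence, stored long-format internally."""

    data: pd.DataFrame  # columns: species, cell [, x, y]

    def __post_init__(self) -> None:
        if not {"species", "cell"}.issubset(self.data.columns):
            raise ValueError("presence grid needs columns species,cell")
        self.data = self.data.drop_duplicates(subset=["species", "cell"])

    @classmethod
    def from_csv(cls, path) -> "PresenceGrid":
        return cls(pd.read_csv(path))

    @property
    def species(self) -> pd.Index:
        return pd.Index(self.data["species"].unique())

    @property
    def cells(self) -> pd.Index:
        return pd.Index(self.data["cell"].unique())


def scores_over_trees(
    trees: TreeSet,
    table: phylo.GenusExpansionTable | None,
    components: pd.DataFrame | None,
    measure: measures.MeasureSpec | str = "EDM",
    quantile: float = 0.8,
    root_age: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute a measure on every tree; return score and rank matrices.

    For each tree: graft congeners (if a table is given), normalise the root
    age, compute ED, rebuild the component table with the tree's log-ED and
    the tree-independent columns of ``components``, compose the measure and
    rank.  Returns (scores, ranks) DataFrames indexed by species with one
    column per tree.
    """
    score_cols, rank_cols = {}, {}
    species_universe: pd.Index | None = None
    static = None
    if components is not None:
        static = components[
            [c for c in ("m", "a", "a_gain", "ge") if c in components.columns]
        ]
    for i, tree in enumerate(trees.trees):
        t = tree
        if table is not None and len(table):
            t = phylo.graft_congeners(t, table, quantile=quantile)
        t = phylo.scale_root_age(t, root_age, force=True)
        led = distinctiveness.log_ed(distinctiveness.fair_proportion(t))
        kwargs = dict(static) if static is not None else {}
        comp = measures.build_component_table(log_ed=led, **kwargs)
        scored = measures.compose_measure(measure, comp)
        if species_universe is None:
            species_universe = scored.index
        elif not species_universe.sort_values().equals(
            scored.index.sort_values()
        ):
            raise ValueError(
                f"tree {i} yields a different species set after grafting"
            )
        score_cols[i] = scored["score"]
        rank_cols[i] = scored["rank"]
    return pd.DataFrame(score_cols), pd.DataFrame(rank_cols)


def summarize_uncertainty(
    scores: pd.DataFrame,
    ranks: pd.DataFrame,
    log_likelihoods: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-species summaries of score/rank distributions across trees.

    Always reports median_rank, rank_sd, mean_score, score_sd; adds
    weighted_mean_score with weights proportional to exp(logL - max logL)
    when log-likelihoods are supplied.
    """
    out = pd.DataFrame(
        {
            "median_rank": ranks.median(axis=1),
            "rank_sd": ranks.std(axis=1, ddof=1) if ranks.shape[1] > 1 else 0.0,
            "mean_score": scores.mean(axis=1),
            "score_sd": scores.std(axis=1, ddof=1) if scores.shape[1] > 1 else 0.0,
        }
    )
    if log_likelihoods is not None:
        ll = np.asarray(log_likelihoods, dtype=float)
        if ll.size != scores.shape[1]:
            raise ValueError("one log-likelihood per tree required")
        w = np.exp(ll - ll.max())
        w /= w.sum()
        out["weighted_mean_score"] = scores.to_numpy() @ w
    return out


def topk_cell_counts(
    scores: pd.DataFrame, grid: PresenceGrid, k: int = 50
) -> pd.Series:
    """Count of the top-k ranked species present in each grid cell.

    Species tied with the rank-k species are all included, so the retained
    set can exceed k (logged when it does).  Cells never occupied by a
    retained species get a count of 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(grid.data) == 0:
        raise ValueError("empty presence grid")
    missing = set(scores.index) - set(grid.species)
    if missing:
        log.warning("%d scored species absent from the grid", len(missing))
    ranked = scores.sort_values("rank")
    if len(ranked) > k:
        cutoff = ranked["rank"].iloc[k - 1]
        top = ranked[ranked["rank"] <= cutoff]
        if len(top) > k:
            log.info("rank-%d ties extend the top-%d set to %d species",
                     cutoff, k, len(top))
    else:
        top = ranked
    present = grid.data[grid.data["species"].isin(top.index)]
    counts = present.groupby("cell").size()
    return counts.reindex(grid.cells, fill_value=0).rename("topk_count")


def mean_cell_score(scores: pd.DataFrame, grid: PresenceGrid) -> pd.Series:
    """Arithmetic mean score of the scored species present in each cell;
    cells containing no scored species are NaN."""
    joined = grid.data.merge(
        scores[["score"]], left_on="species", right_index=True, how="left"
    )
    means = joined.groupby("cell")["score"].mean()
    return means.reindex(grid.cells).rename("mean_score")
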