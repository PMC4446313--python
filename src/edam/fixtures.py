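"""Synthetic study generator with known ground truth.

Emulates the data shapes of a national prioritisation exercise: a dated
genus-level backbone phylogeny, a genus -> species expansion table, two-period
atlas occupancy counts, per-site distribution-model predictions with
controllable noise, Red List labels derived from the true decline, and a
species x grid-cell presence matrix.  Every quantity is driven by one seed,
and the true per-species decline (delta, on the logit scale) and prediction
noise (sigma, on the probability scale) are returned so that parameter
recovery can be tested end to end.

The generator is deliberately simple where realism does not matter for the
measures: ranges are spatially unstructured (no autocorrelation), sites are
exchangeable, and observation is perfect.  What it does emulate faithfully
is the causal chain the measures exploit: decline shifts occupancy between
periods on the logit scale, and prediction noise corrupts the modelled
probabilities that the temporal-validation accuracy score consumes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import expit, logit as _logit

from .accuracy import TemporalPrediction
from .decline import OccupancyTable
from .phylo import GenusExpansionTable, node_ages, scale_root_age
from .uncertainty import PresenceGrid, TreeSet

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_tree",
    "simulate_study",
    "jitter_trees",
    "write_study",
]


def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) dated tree with ``n_tips`` extant tips, root depth 1.

    Reproducible per seed; exactly ultrametric (tip depths are snapped to
    the maximum depth before rescaling).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    # The simulator stops exactly at the n-th birth, leaving a zero-length
    # cherry; run the clock on by the Exp(n * lambda) waiting time to the
    # next (unobserved) split so the present falls strictly between events.
    extra = float(np.random.default_rng(seed).exponential(1.0 / n_tips))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # Snap away float drift so the tree is exactly ultrametric.
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (depths[parent] if parent else 0.0) + (node.edge.length or 0.0)
    max_depth = max(depths[l] for l in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += max_depth - depths[leaf]
    tree = scale_root_age(tree, 1.0, force=True)
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    ):
        leaf.taxon.label = f"T{i + 1}"
    return tree


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_study`.

    decline_effects: per-species logit-scale change in occupancy between
    periods (negative = decline); drawn N(0, 1) when omitted.
    prediction_noise: s.d. of Gaussian noise added to the modelled
    second-period probability of presence (probability scale); a scalar
    applies to all species, a vector gives per-species noise.
    """

    n_species: int = 50
    n_genera: int = 20
    n_cells: int = 500
    seed: int = 0
    decline_effects: np.ndarray | None = None
    prediction_noise: float | np.ndarray = 0.1
    tree_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not (2 <= self.n_genera <= self.n_species):
            raise ValueError("need 2 <= n_genera <= n_species")
        if self.n_cells < 10:
            raise ValueError("need at least 10 grid cells")
        sigma = np.broadcast_to(
            np.asarray(self.prediction_noise, dtype=float), (self.n_species,)
        )
        if (sigma < 0).any():
            raise ValueError("prediction noise must be >= 0")


@dataclass
class StudyData:
    tree: dendropy.Tree
    genera: GenusExpansionTable
    occupancy: OccupancyTable
    predictions: dict[str, TemporalPrediction]
    threat: pd.Series  # species -> Red List label
    grid: PresenceGrid
    truth: pd.DataFrame = field(repr=False)  # delta, sigma per species


#: Decline-severity percentiles mapped to Red List labels (rest are LC).
_THREAT_QUANTILES = [(99, "CR"), (95, "EN"), (90, "VU"), (80, "NT")]


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate one synthetic study; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    n_sp, n_gen, n_cells = config.n_species, config.n_genera, config.n_cells

    genus_names = [f"G{i + 1:03d}" for i in range(n_gen)]
    # every genus gets one species; the rest are assigned at random
    assignment = list(range(n_gen)) + list(
        rng.integers(0, n_gen, size=n_sp - n_gen)
    )
    genera: dict[str, list[str]] = {g: [] for g in genus_names}
    for i, g_idx in enumerate(assignment):
        g = genus_names[g_idx]
        genera[g].append(f"{g}_sp{len(genera[g]) + 1}")
    species = [s for g in genus_names for s in genera[g]]

    tree = simulate_tree(n_gen, seed=int(rng.integers(2**31 - 1)))
    for leaf, genus in zip(
        sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label), genus_names
    ):
        leaf.taxon.label = f"{genus}_rep"

    delta = (
        np.asarray(config.decline_effects, dtype=float)
        if config.decline_effects is not None
        else rng.normal(0.0, 1.0, size=n_sp)
    )
    if delta.size != n_sp:
        raise ValueError("decline_effects must have one entry per species")
    sigma = np.broadcast_to(
        np.asarray(config.prediction_noise, dtype=float), (n_sp,)
    ).copy()

    # Occupancy model: logit p2 = logit p1 + delta, heterogeneous sites.
    base = rng.normal(-0.5, 0.8, size=n_sp)          # species-level logit p1
    site_effect = rng.normal(0.0, 1.0, size=n_cells)  # cell suitability
    eta1 = base[:, None] + site_effect[None, :]
    eta2 = eta1 + delta[:, None]
    pi1, pi2 = expit(eta1), expit(eta2)
    obs1 = rng.random((n_sp, n_cells)) < pi1
    obs2 = rng.random((n_sp, n_cells)) < pi2
    # guarantee every species stays strictly inside the occupancy boundary
    for obs in (obs1, obs2):
        for i in range(n_sp):
            if obs[i].sum() == 0:
                obs[i, rng.integers(n_cells)] = True
            elif obs[i].sum() == n_cells:
                obs[i, rng.integers(n_cells)] = False

    occupancy = OccupancyTable(
        pd.DataFrame(
            {
                "occupied_t1": obs1.sum(axis=1),
                "occupied_t2": obs2.sum(axis=1),
                "total_cells": n_cells,
            },
            index=pd.Index(species, name="species"),
        )
    )

    # SDM predictions: first-period model is the truth; the second-period
    # model is the truth corrupted by per-species Gaussian noise.
    noise = rng.normal(0.0, 1.0, size=(n_sp, n_cells)) * sigma[:, None]
    p2_model = np.clip(pi2 + noise, 0.0, 1.0)
    predictions = {
        sp: TemporalPrediction(pi1[i], p2_model[i], obs1[i], obs2[i])
        for i, sp in enumerate(species)
    }

    # Red List labels from the true decline severity (-delta).
    severity = -delta
    labels = np.array(["LC"] * n_sp, dtype=object)
    for pct, label in sorted(_THREAT_QUANTILES):  # ascending so worst wins
        labels[severity >= np.percentile(severity, pct)] = label
    threat = pd.Series(labels, index=pd.Index(species, name="species"),
                       name="category")

    cells = [f"C{j + 1:04d}" for j in range(n_cells)]
    sp_idx, cell_idx = np.nonzero(obs2)
    grid = PresenceGrid(
        pd.DataFrame(
            {
                "species": [species[i] for i in sp_idx],
                "cell": [cells[j] for j in cell_idx],
            }
        )
    )

    truth = pd.DataFrame(
        {"delta": delta, "sigma": sigma},
        index=pd.Index(species, name="species"),
    )
    return StudyData(
        tree=tree,
        genera=GenusExpansionTable(genera),
        occupancy=occupancy,
        predictions=predictions,
        threat=threat,
        grid=grid,
        truth=truth,
    )


def jitter_trees(
    tree: dendropy.Tree, n: int, epsilon: float, seed: int
) -> TreeSet:
    """Stand-in for a set of credible dated trees: ``n`` copies whose
    internal-node ages carry multiplicative log-normal noise of scale
    ``epsilon``, re-normalised to root age 1.

    Ages are perturbed rather than raw branch lengths so every replicate
    stays dated (ultrametric), as rate-smoothed bootstrap trees are; a
    child's age is capped at its parent's.  ``epsilon = 0`` returns exact
    copies.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = tree.clone(depth=1)
        if epsilon > 0:
            ages = node_ages(t)
            new_age = {
                node: (0.0 if node.is_leaf()
                       else ages[node] * float(np.exp(rng.normal(0, epsilon))))
                for node in t.preorder_node_iter()
            }
            for node in t.preorder_node_iter():  # parent before child: cap
                parent = node.parent_node
                if parent is not None and new_age[node] > new_age[parent]:
                    new_age[node] = new_age[parent]
            for node in t.preorder_node_iter():
                if node.parent_node is not None:
                    node.edge.length = new_age[node.parent_node] - new_age[node]
            t = scale_root_age(t, 1.0)
        out.append(t)
    return TreeSet(trees=out)


def write_study(study: StudyData, outdir) -> dict[str, str]:
    """Write every study table in the package's interchange formats."""
    import os

    from .phylo import write_tree

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_tree(study.tree, _p("tree.nwk"))
    pd.DataFrame(
        [(g, s) for g, sps in study.genera for s in sps],
        columns=["genus", "species"],
    ).to_csv(_p("genera.csv"), index=False)
    study.occupancy.data.to_csv(_p("occupancy.csv"))
    rows = []
    for sp, pred in study.predictions.items():
        for q in range(len(pred)):
            rows.append(
                (sp, q, pred.p1_model[q], pred.p2_model[q],
                 int(pred.obs1[q]), int(pred.obs2[q]))
            )
    pd.DataFrame(
        rows, columns=["species", "site", "p1_model", "p2_model", "obs1", "obs2"]
    ).to_csv(_p("predictions.csv"), index=False)
    study.threat.to_csv(_p("redlist.csv"))
    study.grid.data.to_csv(_p("grid.csv"), index=False)
    study.truth.to_csv(_p("truth.csv"))
    return paths
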