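"""Dated-tree handling: Newick I/O, root-age normalisation, polytomy grafting.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
Backbone phylogenies in national prioritisation studies typically carry one
representative tip per genus; :func:`graft_congeners` expands each such tip
into a polytomy carrying every congeneric species, placed at

    min(half the age of the pendant branch, the q-th quantile of genus ages),

which keeps the tree dated (ultrametric) while avoiding artificially deep
splits inside genera whose representatives sit on unusually long branches.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "GenusExpansionTable",
    "TreeError",
    "read_tree",
    "read_trees",
    "write_tree",
    "root_depth",
    "node_ages",
    "assert_ultrametric",
    "scale_root_age",
    "graft_congeners",
    "genus_of",
]

#: Relative ultrametricity tolerance: inputs whose root-to-tip depths differ
#: by more than DEFAULT_TOL * depth are rejected as undated.
DEFAULT_TOL = 1e-9
#: Relaxed tolerance selected by ``force=True`` for slightly sloppy inputs.
FORCED_TOL = 1e-6

#: "Genus_species" convention: genus is the label prefix up to the first
#: underscore (or whitespace, which Newick readers may substitute).
GENUS_PATTERN = r"^([^_\s]+)"


class TreeError(ValueError):
    """Raised for malformed, undated, or otherwise unusable trees."""


def genus_of(label: str, pattern: str = GENUS_PATTERN) -> str:
    """Genus prefix of a tip label (``'Quercus_robur'`` -> ``'Quercus'``)."""
    m = re.match(pattern, label)
    if not m:
        raise TreeError(f"cannot extract genus from tip label {label!r}")
    return m.group(1)


@dataclass
class GenusExpansionTable:
    """Mapping genus -> list of species labels (the representative's
    congeners, including itself).  Species labels must be globally unique."""

    genera: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for genus, species in self.genera.items():
            if len(species) == 0:
                raise TreeError(f"genus {genus!r} has an empty species list")
            for s in species:
                if s in seen:
                    raise TreeError(f"species label {s!r} listed twice")
                seen.add(s)

    @classmethod
    def from_csv(cls, path) -> "GenusExpansionTable":
        import pandas as pd

        df = pd.read_csv(path)
        if not {"genus", "species"}.issubset(df.columns):
            raise TreeError("genus expansion CSV needs columns genus,species")
        genera = {
            genus: list(group["species"])
            for genus, group in df.groupby("genus", sort=False)
        }
        return cls(genera)

    def __iter__(self):
        return iter(self.genera.items())

    def __len__(self) -> int:
        return len(self.genera)

    def total_species(self) -> int:
        return sum(len(v) for v in self.genera.values())


# ---------------------------------------------------------------------------
# I/O


def read_tree(source: str) -> dendropy.Tree:
    """Parse a single Newick tree from a string or a file path.

    Branch lengths are preserved exactly; underscores in labels are kept
    verbatim.  Raises :class:`TreeError` on malformed input or duplicate
    tip labels.
    """
    text = source
    if "(" not in source and ";" not in source:  # looks like a path
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def read_trees(source: str) -> list[dendropy.Tree]:
    """Parse a multi-Newick file (one tree per line) into a list of trees."""
    text = source
    if "(" not in source and ";" not in source:
        with open(source) as fh:
            text = fh.read()
    tl = dendropy.TreeList.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return list(tl)


def write_tree(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialise a tree to Newick with full-precision branch lengths."""
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ---------------------------------------------------------------------------
# Ages and ultrametricity


def _leaf_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depths[node] = (depths[parent] if parent is not None else 0.0) + edge
    return {leaf: depths[leaf] for leaf in tree.leaf_node_iter()}


def root_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (the tree's age for a dated tree)."""
    return max(_leaf_depths(tree).values())


def assert_ultrametric(tree: dendropy.Tree, tol: float = DEFAULT_TOL) -> float:
    """Check all root-to-tip depths agree within ``tol * depth``; return depth."""
    depths = np.array(list(_leaf_depths(tree).values()))
    depth = depths.max()
    if depth <= 0:
        raise TreeError("tree has zero depth")
    if (depth - depths.min()) > tol * depth:
        raise TreeError(
            f"tree is not ultrametric: root-to-tip depths span "
            f"[{depths.min():.6g}, {depth:.6g}] (tolerance {tol:g} relative)"
        )
    return float(depth)


def node_ages(tree: dendropy.Tree) -> dict:
    """Age (time before present) of every node of a dated tree.

    The age of a node is the tree depth minus its distance from the root;
    tips of an ultrametric tree have age ~0.
    """
    depth = assert_ultrametric(tree, tol=FORCED_TOL)
    ages = {}
    cum = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        cum[node] = (cum[parent] if parent is not None else 0.0) + edge
        ages[node] = depth - cum[node]
    return ages


# ---------------------------------------------------------------------------
# Operations


def scale_root_age(
    tree: dendropy.Tree,
    target_age: float = 1.0,
    tol: float = DEFAULT_TOL,
    force: bool = False,
) -> dendropy.Tree:
    """Rescale all branch lengths so the root-to-tip depth equals ``target_age``.

    The tree must be dated (ultrametric within ``tol``); ``force=True``
    relaxes the tolerance to 1e-6.  Returns a new tree; the input is left
    untouched.
    """
    if target_age <= 0:
        raise TreeError("target_age must be positive")
    tree = tree.clone(depth=1)
    depth = assert_ultrametric(tree, tol=FORCED_TOL if force else tol)
    factor = target_age / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def graft_congeners(
    tree: dendropy.Tree,
    table: GenusExpansionTable,
    quantile: float = 0.8,
    genus_pattern: str = GENUS_PATTERN,
    tol: float = FORCED_TOL,
) -> dendropy.Tree:
    """Expand genus-representative tips into dated polytomies of congeners.

    Each genus key of ``table`` must match exactly one tip by genus prefix.
    A genus listing k > 1 species has its representative tip replaced by a
    polytomy node of age

        min(attachment_age / 2, quantile-th quantile of genus ages),

    where a tip's *genus age* is the age of the node its pendant branch
    attaches to, and the quantile (type-7 linear interpolation) is taken
    over the genus ages of **all** tips of the input tree.  Genera listing a
    single species have their tip relabelled only.  The output is ultrametric
    with one tip per listed species plus all untouched tips.
    """
    if not (0.0 < quantile < 1.0):
        raise TreeError("quantile must lie strictly between 0 and 1")
    tree = tree.clone(depth=1)
    ages = node_ages(tree)

    tips_by_genus: dict[str, list] = {}
    for leaf in tree.leaf_node_iter():
        tips_by_genus.setdefault(
            genus_of(leaf.taxon.label, genus_pattern), []
        ).append(leaf)

    # Genus age of every tip = age of its attachment node, on the input tree.
    genus_ages = np.array(
        [ages[leaf.parent_node] for leaf in tree.leaf_node_iter()
         if leaf.parent_node is not None]
    )
    if genus_ages.size == 0:
        raise TreeError("tree has no internal structure to graft onto")
    age_cut = float(np.quantile(genus_ages, quantile))  # type-7 default

    taxon_ns = tree.taxon_namespace
    for genus, species in table:
        leaves = tips_by_genus.get(genus, [])
        if len(leaves) != 1:
            raise TreeError(
                f"genus {genus!r} matches {len(leaves)} tips; need exactly one"
            )
        leaf = leaves[0]
        species = list(species)
        if len(species) == 1:
            leaf.taxon = taxon_ns.new_taxon(label=species[0])
            continue
        attach_age = ages[leaf.parent_node]
        poly_age = min(attach_age / 2.0, age_cut)
        if poly_age <= 0:
            raise TreeError(
                f"polytomy age for genus {genus!r} is {poly_age:.6g}; "
                "the representative attaches at age "
                f"{attach_age:.6g} and the quantile cut is {age_cut:.6g}"
            )
        # Reuse the representative's node as the polytomy node.
        leaf.taxon = None
        leaf.edge.length = attach_age - poly_age
        for label in species:
            child = dendropy.Node(edge_length=poly_age)
            child.taxon = taxon_ns.new_taxon(label=label)
            leaf.add_child(child)

    assert_ultrametric(tree, tol=tol)
    return tree
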