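"""Evolutionary distinctiveness by the fair-proportion rule.

Fair proportion apportions each branch's length equally among the tips that
descend from it; a tip's ED is the sum of its shares along the root-to-tip
path.  Summed over tips this recovers the total branch length of the tree
(the conservation identity), making ED a per-species partition of the tree's
phylogenetic diversity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["fair_proportion", "log_ed", "ed_table"]


def fair_proportion(
    tree,
    include_root: bool = False,
    isaac_correction: bool = False,
) -> pd.Series:
    """Per-tip evolutionary distinctiveness of a rooted tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with non-negative branch lengths and at least two tips.
    include_root : bool
        Include a length on the root edge, if present, in the apportionment.
        Off by default: the root edge subtends every tip and shifts all ED
        values by the same constant share.
    isaac_correction : bool
        Hook for a multiplicative polytomy correction.  Not implemented;
        plain fair proportion handles multifurcating trees directly.

    Returns
    -------
    pandas.Series
        ED per tip label, strictly positive, summing to the total branch
        length included in the apportionment.
    """
    if isaac_correction:
        raise NotImplementedError(
            "no published closed form for the polytomy correction is "
            "implemented; plain fair proportion supports polytomies directly"
        )
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("fair proportion needs a rooted tree with >= 2 tips")

    # Single postorder pass: count descendant tips per node, then a preorder
    # pass accumulating length/num_tips shares down to the leaves.
    n_desc = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_desc[node] = 1
        else:
            n_desc[node] = sum(n_desc[c] for c in node.child_nodes())

    shares = {}
    ed = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        length = node.edge.length or 0.0
        if parent is None and not include_root:
            length = 0.0
        if length < 0:
            raise ValueError("negative branch length")
        acc = (shares[parent] if parent is not None else 0.0)
        acc += length / n_desc[node]
        shares[node] = acc
        if node.is_leaf():
            ed[node.taxon.label] = acc
    return pd.Series(ed, name="ed")


def log_ed(ed: pd.Series, add_one: bool = False) -> pd.Series:
    """Natural log of ED values, optionally ln(1 + ED).

    ``add_one`` guards against zero ED; it is off by default because on
    dated trees with root age ~1 it badly skews the distribution.
    """
    values = np.asarray(ed, dtype=float)
    if add_one:
        if (values < 0).any():
            raise ValueError("ED values must be >= 0 with add_one")
        out = np.log1p(values)
    else:
        if (values <= 0).any():
            bad = pd.Series(ed)[values <= 0].index.tolist()
            raise ValueError(f"non-positive ED for {bad}; consider add_one")
        out = np.log(values)
    return pd.Series(out, index=pd.Series(ed).index, name="log_ed")


def ed_table(tree, add_one: bool = False, **kwargs) -> pd.DataFrame:
    """Convenience: DataFrame with columns ``ed`` and ``log_ed`` per species."""
    ed = fair_proportion(tree, **kwargs)
    return pd.DataFrame({"ed": ed, "log_ed": log_ed(ed, add_one=add_one)})
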