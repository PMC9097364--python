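"""Plot helpers: phylomorphospace scatter with ancestral branch overlay.

Ancestral states at internal nodes are reconstructed by squared-change
minimisation (each internal state is the 1/branch-length weighted average of
its neighbours), then parent-child segments are drawn under the tip scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo import TimeTree

__all__ = ["ancestral_states", "plot_phylomorphospace"]


def ancestral_states(tree: TimeTree, tip_values: pd.DataFrame) -> pd.DataFrame:
    """Weighted-average (squared-change) ancestral reconstruction.

    Minimises sum over edges of (state change)^2 / branch length with tip
    states fixed, i.e. solves the linear system in which every internal state
    equals the inverse-branch-length weighted mean of its neighbours.
    Zero-length edges are floored at 1e-8 of tree depth.  Returns a frame
    indexed by internal node ids (preorder position).
    """
    dt = tree._tree
    internal = [nd for nd in dt.preorder_node_iter() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(internal)}
    floor = 1e-8 * max(tree.max_depth(), 1.0)
    Y = tip_values.reindex(tree.tip_labels).to_numpy(dtype=float)
    tip_state = dict(zip(tree.tip_labels, Y))
    p = Y.shape[1]
    n = len(internal)
    A = np.zeros((n, n))
    b = np.zeros((n, p))
    for nd in internal:
        i = index[nd]
        neighbours = list(nd.child_nodes())
        if nd.parent_node is not None:
            neighbours.append(nd.parent_node)
        for nb in neighbours:
            edge = nb.edge if nb in nd.child_nodes() else nd.edge
            w = 1.0 / max(edge.length or 0.0, floor)
            A[i, i] += w
            if nb.is_leaf():
                b[i] += w * tip_state[nb.taxon.label]
            else:
                A[i, index[nb]] -= w
    states = np.linalg.solve(A, b)
    return pd.DataFrame(states, index=[f"node_{i}" for i in range(n)],
                        columns=tip_values.columns)


def plot_phylomorphospace(tree: TimeTree, scores: pd.DataFrame, path,
                          groups: pd.Series | None = None,
                          axes: tuple[str, str] | None = None) -> None:
    """Scatter tip scores on two axes with phylogenetic branches underlaid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cols = list(axes) if axes else list(scores.columns[:2])
    anc = ancestral_states(tree, scores[cols])
    dt = tree._tree
    internal = [nd for nd in dt.preorder_node_iter() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(internal)}

    def node_xy(nd):
        if nd.is_leaf():
            return scores.loc[nd.taxon.label, cols].to_numpy(dtype=float)
        return anc.iloc[index[nd]].to_numpy()

    fig, ax = plt.subplots(figsize=(7, 6))
    for nd in dt.preorder_node_iter():
        if nd.parent_node is None:
            continue
        a = node_xy(nd.parent_node)
        c = node_xy(nd)
        ax.plot([a[0], c[0]], [a[1], c[1]], color="0.7", lw=0.8, zorder=1)
    tip_xy = scores.loc[tree.tip_labels, cols]
    if groups is not None:
        for name, sub in tip_xy.groupby(groups.reindex(tip_xy.index)):
            ax.scatter(sub[cols[0]], sub[cols[1]], label=str(name), zorder=2)
        ax.legend(fontsize=8)
    else:
        ax.scatter(tip_xy[cols[0]], tip_xy[cols[1]], zorder=2)
    ax.set_xlabel(cols[0])
    ax.set_ylabel(cols[1])
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
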