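"""Time-scaled phylogenies and phylogenetic comparative statistics.

Trees are wrapped :class:`TimeTree` objects (dendropy-backed) with branch
lengths in Ma.  The module provides fossil grafting and linear time-scaling,
the Brownian-motion covariance matrix, univariate and multivariate
phylogenetic-signal statistics (K and its multivariate generalisation), and a
permutation-based pairwise comparison of group means under phylogenetic
covariance ("phylogenetic HSD", an RRPP scheme).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    DegenerateDataError,
    GroupError,
    NewickParseError,
    SingularMatrixError,
    TreeError,
)

__all__ = [
    "TimeTree",
    "PhyloCov",
    "TraitMatrix",
    "SignalResult",
    "PairwiseResult",
    "read_newick",
    "write_newick",
    "scale_tree_depth",
    "graft_clade",
    "phylo_vcv",
    "phylo_gls_mean",
    "blomberg_k",
    "k_mult",
    "phylo_hsd",
]

_EIG_FLOOR = 1e-12


class TimeTree:
    """A rooted tree with non-negative branch lengths (Ma).

    Thin wrapper around :class:`dendropy.Tree` enforcing the invariants used
    throughout: single root, unique tip labels, branch lengths >= 0.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            elif edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if len(labels) == 0:
            raise TreeError("tree has no tips")

    # -- basic accessors ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label if lf.taxon else (lf.label or "")
                for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _node_depths(self) -> dict:
        depths = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = nd.edge.length or 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        return depths

    def max_depth(self) -> float:
        depths = self._node_depths()
        return max(depths[lf] for lf in self._tree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        depths = self._node_depths()
        return {lf.taxon.label: depths[lf] for lf in self._tree.leaf_node_iter()}

    def copy(self) -> "TimeTree":
        return read_newick(write_newick(self))

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips}, depth={self.max_depth():.4g})"


def read_newick(text: str) -> TimeTree:
    """Parse a Newick string (branch lengths required) into a :class:`TimeTree`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        pos = getattr(exc, "col_num", None)
        raise NewickParseError(str(exc), position=pos) from exc
    return TimeTree(tree)


def write_newick(tree: TimeTree) -> str:
    """Serialise with full float precision; round-trips through read_newick."""
    s = tree._tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
        unquoted_underscores=True,
    )
    return s.strip()


def scale_tree_depth(tree: TimeTree, target_depth: float) -> TimeTree:
    """Multiply every branch by one constant so max root-to-tip depth = target."""
    depth = tree.max_depth()
    if depth <= 0:
        raise TreeError("cannot scale a zero-depth tree")
    factor = target_depth / depth
    out = tree.copy()
    for edge in out._tree.preorder_edge_iter():
        if edge.length:
            edge.length *= factor
    return out


def _subtree_ages(node, tip_ages: dict, spacing: float) -> dict:
    """Node -> age (Ma before present) using the fixed divergence spacing rule."""
    ages = {}

    def rec(nd):
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else nd.label
            ages[nd] = float(tip_ages.get(label, 0.0))
        else:
            for c in nd.child_nodes():
                rec(c)
            ages[nd] = max(ages[c] for c in nd.child_nodes()) + spacing
        return ages[nd]

    rec(node)
    return ages


def graft_clade(
    host: TimeTree,
    attach_at: str,
    subtree: TimeTree,
    stem_age: float,
    tip_ages: dict[str, float] | None = None,
    spacing: float = 0.01,
) -> TimeTree:
    """Graft ``subtree`` onto ``host`` with its stem diverging at ``stem_age``.

    ``attach_at`` is a tip label, an internal node label, or ``"root"``.  Tips
    of the grafted clade terminate at their ``tip_ages`` (Ma before present,
    default 0); unspecified divergence times are resolved by placing each
    internal node ``spacing`` Ma (default 0.01, i.e. 10 kyr) above its oldest
    child, recursing in input order.  Raises :class:`TreeError` if the
    requested ages imply a negative branch length.
    """
    tip_ages = dict(tip_ages or {})
    out = host.copy()
    dt = out._tree
    depths = out._node_depths()
    root_age = max(depths[lf] for lf in dt.leaf_node_iter())

    sub_ages = _subtree_ages(subtree._tree.seed_node, tip_ages, spacing)
    sub_root_age = sub_ages[subtree._tree.seed_node]
    if sub_root_age > stem_age:
        raise TreeError(
            f"stem age {stem_age} younger than grafted clade root age {sub_root_age}"
        )

    if attach_at == "root":
        if stem_age < root_age:
            raise TreeError(
                f"stem age {stem_age} younger than host root age {root_age}; "
                "cannot attach above the root"
            )
        old_root = dt.seed_node
        new_root = dendropy.Node()
        dt.seed_node = new_root
        new_root.add_child(old_root)
        old_root.edge.length = stem_age - root_age
        attach_parent = new_root
    else:
        node = None
        for nd in dt.preorder_node_iter():
            label = nd.taxon.label if nd.taxon else nd.label
            if label == attach_at:
                node = nd
                break
        if node is None:
            raise TreeError(f"attach point {attach_at!r} not found in host tree")
        if node.parent_node is None:
            raise TreeError("use attach_at='root' to attach above the root")
        node_age = root_age - depths[node]
        parent_age = node_age + (node.edge.length or 0.0)
        if not (node_age <= stem_age <= parent_age):
            raise TreeError(
                f"stem age {stem_age} outside edge above {attach_at!r} "
                f"(ages {node_age:.6g}..{parent_age:.6g})"
            )
        parent = node.parent_node
        mid = dendropy.Node()
        parent.add_child(mid)
        mid.edge.length = parent_age - stem_age
        parent.remove_child(node)
        mid.add_child(node)
        node.edge.length = stem_age - node_age
        attach_parent = mid

    ns = dt.taxon_namespace

    def build(src, parent_age, parent_dnode):
        age = sub_ages[src]
        nd = dendropy.Node()
        parent_dnode.add_child(nd)
        nd.edge.length = parent_age - age
        if nd.edge.length < 0:
            raise TreeError("grafting produced a negative branch length")
        if src.is_leaf():
            label = src.taxon.label if src.taxon else src.label
            nd.taxon = ns.require_taxon(label=label)
        else:
            nd.label = src.label
            for c in src.child_nodes():
                build(c, age, nd)

    build(subtree._tree.seed_node, stem_age, attach_parent)
    return TimeTree(dt)


# ---------------------------------------------------------------------------
# Brownian covariance


@dataclass(frozen=True)
class PhyloCov:
    """Brownian-motion covariance: shared root-to-MRCA path length per tip pair."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix/label shape mismatch")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    def subset(self, labels) -> "PhyloCov":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCov(self.matrix[np.ix_(idx, idx)], tuple(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def phylo_vcv(tree: TimeTree) -> PhyloCov:
    """Tip x tip shared-path-length matrix under Brownian motion."""
    dt = tree._tree
    depths = tree._node_depths()
    leaves = list(dt.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    # postorder sweep: tips below each child subtree; cross-pairs share the
    # parent node's depth as their MRCA depth
    below: dict = {}
    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = [index[nd]]
            C[index[nd], index[nd]] = depths[nd]
        else:
            kids = [below[c] for c in nd.child_nodes()]
            d = depths[nd]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        C[i, kids[b]] = d
                        C[kids[b], i] = d
            merged = [i for k in kids for i in k]
            below[nd] = merged
    return PhyloCov(C, tuple(labels))


# ---------------------------------------------------------------------------
# Trait containers


@dataclass
class TraitMatrix:
    """Taxon-by-trait table with optional group labels and fossil flags."""

    data: pd.DataFrame
    groups: pd.Series | None = None
    fossil: pd.Series | None = None

    def __post_init__(self):
        if self.groups is not None:
            self.groups = self.groups.reindex(self.data.index)
        if self.fossil is not None:
            self.fossil = self.fossil.reindex(self.data.index).fillna(False)
            if self.groups is not None:
                bad = self.data.index[self.fossil.astype(bool) & self.groups.notna()]
                if len(bad):
                    raise ValueError(f"fossil rows must not carry group labels: {list(bad)}")
        extant = self.data if self.fossil is None else self.data.loc[~self.fossil.astype(bool)]
        if extant.isna().any().any():
            raise ValueError("missing cells in rows used for fitting")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class SignalResult:
    """Phylogenetic-signal statistic with its permutation p-value."""

    statistic: float
    p: float
    nperm: int
    seed: int

    def to_record(self) -> dict:
        return {"statistic": self.statistic, "p": self.p,
                "nperm": self.nperm, "seed": self.seed}


@dataclass(frozen=True)
class PairwiseResult:
    """Pairwise permutation comparison of group means."""

    groups: tuple[str, ...]
    p_values: np.ndarray
    distances: np.ndarray
    nperm: int
    seed: int

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.groups, columns=self.groups)

    def distance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.groups, columns=self.groups)


# ---------------------------------------------------------------------------
# GLS mean, K, K_mult


def _chol(C: np.ndarray):
    try:
        factor = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        cond = float(np.linalg.cond(C))
        raise SingularMatrixError("phylogenetic covariance not positive definite",
                                  condition_number=cond) from exc
    cond = float(np.linalg.cond(C))
    if cond > 1e14:
        raise SingularMatrixError("phylogenetic covariance ill-conditioned",
                                  condition_number=cond)
    return factor


def phylo_gls_mean(C: PhyloCov | np.ndarray, Y: np.ndarray | pd.DataFrame) -> np.ndarray:
    """GLS intercept a = (1' C^-1 1)^-1 1' C^-1 Y, one value per trait column."""
    Cm = C.matrix if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    Ym = np.asarray(Y, dtype=float)
    if Ym.ndim == 1:
        Ym = Ym[:, None]
    factor = _chol(Cm)
    ones = np.ones(Cm.shape[0])
    Ci1 = cho_solve(factor, ones)
    CiY = cho_solve(factor, Ym)
    return (ones @ CiY) / (ones @ Ci1)


def _align_trait(tree: TimeTree, y) -> np.ndarray:
    if isinstance(y, pd.Series):
        y = y.reindex(tree.tip_labels)
        if y.isna().any():
            missing = list(y.index[y.isna()])
            raise ValueError(f"trait missing for tips: {missing}")
        return y.to_numpy(dtype=float)
    arr = np.asarray(y, dtype=float)
    if arr.shape[0] != tree.n_tips:
        raise ValueError("trait length does not match number of tips")
    return arr


def _align_traits(tree: TimeTree, Y) -> np.ndarray:
    if isinstance(Y, pd.DataFrame):
        Y = Y.reindex(tree.tip_labels)
        if Y.isna().any().any():
            raise ValueError("trait matrix missing rows for some tips")
        return Y.to_numpy(dtype=float)
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != tree.n_tips:
        raise ValueError("trait matrix rows do not match number of tips")
    return arr


def _k_statistic(C: np.ndarray, factor, Y: np.ndarray) -> float:
    """Shared kernel of K and its multivariate generalisation."""
    n = C.shape[0]
    ones = np.ones(n)
    Ci1 = cho_solve(factor, ones)
    denom_a = ones @ Ci1
    a = (ones @ cho_solve(factor, Y)) / denom_a
    R = Y - a  # deviations from the phylogenetic mean, raw space
    num = float(np.sum(R * R))
    den = float(np.sum(R * cho_solve(factor, R)))
    if den <= 0 or num <= 0:
        raise DegenerateDataError("trait variance degenerate for K computation")
    expected = (np.trace(C) - n / denom_a) / (n - 1)
    return (num / den) / expected


def k_mult(tree: TimeTree, Y, nperm: int = 999, seed: int = 0) -> SignalResult:
    """Multivariate phylogenetic signal; equals the univariate K for one column.

    The statistic is 1.0 in expectation when traits evolve by Brownian motion
    on the tree.  The p-value is the tip-shuffling permutation proportion of
    replicates with a statistic >= observed, with (count+1)/(nperm+1)
    smoothing, so the minimum reportable p is 1/(nperm+1).
    """
    Ym = _align_traits(tree, Y)
    if Ym.shape[0] < 4:
        raise ValueError("need at least 4 tips")
    if np.allclose(Ym.std(axis=0), 0):
        raise DegenerateDataError("all trait columns constant")
    C = phylo_vcv(tree).matrix
    factor = _chol(C)
    obs = _k_statistic(C, factor, Ym)
    rng = np.random.default_rng(seed)
    count = 0
    n = Ym.shape[0]
    for _ in range(nperm):
        perm = rng.permutation(n)
        if _k_statistic(C, factor, Ym[perm]) >= obs:
            count += 1
    p = (count + 1) / (nperm + 1)
    return SignalResult(statistic=obs, p=p, nperm=nperm, seed=seed)


def blomberg_k(tree: TimeTree, y, nperm: int = 999, seed: int = 0) -> SignalResult:
    """Univariate phylogenetic signal K with tip-shuffling permutation test."""
    arr = _align_trait(tree, y)
    if np.allclose(arr.std(), 0):
        raise DegenerateDataError("trait is constant")
    return k_mult(tree, arr[:, None], nperm=nperm, seed=seed)


# ---------------------------------------------------------------------------
# Phylogenetic HSD (RRPP pairwise comparison)


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    """Matrix inverse square root via eigendecomposition with eigenvalue floor."""
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, _EIG_FLOOR)
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def _pairwise_dist(M: np.ndarray) -> np.ndarray:
    diff = M[:, None, :] - M[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def phylo_hsd(
    tree: TimeTree,
    Y,
    groups,
    nperm: int = 1000,
    seed: int = 0,
) -> PairwiseResult:
    """Pairwise comparison of group means under phylogenetic covariance.

    Data are transformed by the inverse matrix square root of the Brownian
    covariance; observed statistics are Euclidean distances between group
    least-squares means in the transformed space; the null distribution
    randomises intercept-only residuals and refits (RRPP).
    """
    if isinstance(Y, pd.DataFrame):
        labels = list(Y.index)
        Ym = Y.to_numpy(dtype=float)
    else:
        labels = tree.tip_labels
        Ym = np.asarray(Y, dtype=float)
    if Ym.ndim == 1:
        Ym = Ym[:, None]
    g = pd.Series(groups)
    if isinstance(groups, pd.Series):
        g = groups.reindex(labels)
    keep = g.notna().to_numpy()
    labels = [l for l, k in zip(labels, keep) if k]
    Ym = Ym[keep]
    g = g[keep]

    counts = g.value_counts()
    single = sorted(counts.index[counts < 2])
    if single:
        raise GroupError(f"groups with fewer than 2 members: {single}")

    C = phylo_vcv(tree).subset(labels).matrix
    P = _inv_sqrt(C)
    Yt = P @ Ym
    names = tuple(sorted(counts.index))
    X = np.column_stack([(g == name).to_numpy(dtype=float) for name in names])
    Xt = P @ X
    ones_t = P @ np.ones((len(labels), 1))

    pinvX = np.linalg.pinv(Xt)
    beta_obs = pinvX @ Yt
    d_obs = _pairwise_dist(beta_obs)

    # reduced model: intercept only
    b0 = np.linalg.pinv(ones_t) @ Yt
    fitted0 = ones_t @ b0
    resid0 = Yt - fitted0

    rng = np.random.default_rng(seed)
    n = Yt.shape[0]
    count_ge = np.zeros_like(d_obs)
    for _ in range(nperm):
        Ystar = fitted0 + resid0[rng.permutation(n)]
        d_star = _pairwise_dist(pinvX @ Ystar)
        count_ge += (d_star >= d_obs - 1e-15)
    p = (count_ge + 1) / (nperm + 1)
    np.fill_diagonal(p, 1.0)
    return PairwiseResult(groups=names, p_values=p, distances=d_obs,
                          nperm=nperm, seed=seed)
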