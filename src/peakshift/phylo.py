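"""Phylogenetic trees, regime paintings, contrasts and ancestral states.

The :class:`Phylogeny` container stores a rooted binary tree with branch
lengths as flat arrays (tips first), which is the indexing the numerical
routines need.  Newick reading/writing is delegated to dendropy.

Ancestral estimation supports the two flavours used when mapping traits and
diets onto a tree:

* continuous characters under Brownian motion, where the maximum-likelihood
  node values solve a weighted-Laplacian linear system (each node value is a
  branch-length-weighted average of its neighbours);
* discrete characters under an equal-rates Mk model, with the transition
  rate fitted by maximum likelihood (Felsenstein pruning) and marginal node
  probabilities obtained by the standard down-pass/up-pass recursion.

A :class:`RegimePainting` assigns one selective regime to every branch; the
convention throughout the package is that a branch carries the regime of its
child node (evolution along a branch is attributed to the regime it evolves
toward).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import (
    DegenerateBranchError,
    MissingDataError,
    NewickParseError,
    PaintingIncompleteError,
)

__all__ = [
    "Phylogeny",
    "RegimePainting",
    "AncestralEstimate",
    "read_newick",
    "patristic_distances",
    "independent_contrasts",
    "ancestral_continuous_ml",
    "ancestral_discrete_ml",
    "paint_regimes",
]


class Phylogeny:
    """Rooted binary tree with branch lengths (time units, e.g. My).

    Nodes are integer-indexed: tips ``0..n_tips-1`` (in ``tip_labels``
    order), internal nodes ``n_tips..2*n_tips-2``; the root is always the
    last index.  ``length[i]`` is the branch above node ``i`` (0 for the
    root); ``node_times[i]`` is the time from the root to node ``i``.
    """

    def __init__(self, parent: np.ndarray, length: np.ndarray, tip_labels: Sequence[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        if self.n_nodes != 2 * self.n_tips - 1:
            raise ValueError("tree must be binary: expected 2*n_tips-1 nodes")
        if len(set(self.tip_labels)) != self.n_tips:
            raise ValueError("tip labels must be unique")
        if np.any(self.length < 0):
            raise ValueError("branch lengths must be non-negative")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        for i in range(self.n_tips, self.n_nodes):
            if len(self.children[i]) != 2:
                raise ValueError("tree must be strictly binary")
        self._finish()

    def _finish(self) -> None:
        # preorder / postorder traversal index arrays
        pre: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            pre.append(v)
            stack.extend(reversed(self.children[v]))
        self.preorder = np.array(pre, dtype=int)
        self.postorder = self.preorder[::-1].copy()
        t = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                t[v] = t[self.parent[v]] + self.length[v]
        self.node_times = t
        self.depth = float(t[: self.n_tips].max())

    # -- construction ---------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index: dict = {}
        labels = []
        for i, nd in enumerate(tips):
            index[nd] = i
            labels.append(nd.taxon.label if nd.taxon else f"tip{i}")
        for j, nd in enumerate(internals):
            index[nd] = len(tips) + (len(internals) - 1 - j)  # root last
        n = len(tips) + len(internals)
        parent = np.full(n, -1, dtype=int)
        length = np.zeros(n)
        for nd in nodes:
            i = index[nd]
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
                length[i] = float(nd.edge.length or 0.0)
        return cls(parent, length, labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"could not parse Newick string: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if v < self.n_tips:
                core = self.tip_labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core + ";"
            return f"{core}:{self.length[v]:.10g}"

        return rec(self.root)

    # -- bookkeeping ----------------------------------------------------

    def tip_depths(self) -> np.ndarray:
        return self.node_times[: self.n_tips].copy()

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    def clade_tips(self, v: int) -> np.ndarray:
        """Tip indices descended from node ``v`` (``v`` itself if a tip)."""
        out: list[int] = []
        stack = [v]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(u)
            else:
                stack.extend(self.children[u])
        return np.array(sorted(out), dtype=int)

    def path_to_root(self, v: int) -> list[int]:
        """Nodes from ``v`` up to (and including) the root."""
        path = [v]
        while path[-1] != self.root:
            path.append(int(self.parent[path[-1]]))
        return path

    def shared_times(self) -> np.ndarray:
        """Matrix of MRCA times (time of the most recent common ancestor).

        Diagonal entries are the tip depths.  Under Brownian motion this is
        the tip covariance matrix up to the rate constant.  Cached.
        """
        cached = getattr(self, "_shared_times", None)
        if cached is not None:
            return cached
        n = self.n_tips
        S = np.zeros((n, n))
        for v in self.postorder:
            if v < n:
                continue
            groups = [self.clade_tips(c) for c in self.children[v]]
            for a in groups[0]:
                S[a, groups[1]] = self.node_times[v]
                S[groups[1], a] = self.node_times[v]
        S[np.diag_indices(n)] = self.tip_depths()
        self._shared_times = S
        return S

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth:.3g})"


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (with branch lengths) into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def patristic_distances(tree: Phylogeny) -> pd.DataFrame:
    """Pairwise path lengths between tips: t_ij = T_i + T_j - 2 * t(MRCA)."""
    T = tree.tip_depths()
    S = tree.shared_times()
    D = T[:, None] + T[None, :] - 2.0 * S
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=tree.tip_labels, columns=tree.tip_labels)


# ---------------------------------------------------------------------------
# regime painting
# ---------------------------------------------------------------------------


@dataclass
class RegimePainting:
    """One selective regime per branch, plus node and tip states.

    ``node_regime[i]`` is the regime of node ``i``; the branch above a
    non-root node carries that node's regime.  ``regime_labels`` fixes the
    regime (and optimum) ordering used by the Hansen-model design matrix.
    """

    tree: Phylogeny
    node_regime: np.ndarray  # label index per node
    regime_labels: list[str]
    jump_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.node_regime = np.asarray(self.node_regime, dtype=int)
        if len(self.node_regime) != self.tree.n_nodes:
            raise PaintingIncompleteError(
                f"painting covers {len(self.node_regime)} nodes, "
                f"tree has {self.tree.n_nodes}"
            )

    @property
    def tip_states(self) -> pd.Series:
        labels = [self.regime_labels[s] for s in self.node_regime[: self.tree.n_tips]]
        return pd.Series(labels, index=self.tree.tip_labels, name="regime")

    @property
    def root_regime(self) -> str:
        return self.regime_labels[self.node_regime[self.tree.root]]

    def branch_regime(self, node: int) -> str:
        return self.regime_labels[self.node_regime[node]]

    def used_labels(self) -> list[str]:
        used = set(self.node_regime.tolist())
        return [l for i, l in enumerate(self.regime_labels) if i in used]

    def merge(self, mapping: Mapping[str, str]) -> "RegimePainting":
        """Relabel regimes through ``mapping`` (old label -> merged label)."""
        new_labels: list[str] = []
        for l in self.regime_labels:
            m = mapping.get(l, l)
            if m not in new_labels:
                new_labels.append(m)
        lut = np.array(
            [new_labels.index(mapping.get(l, l)) for l in self.regime_labels], dtype=int
        )
        return RegimePainting(self.tree, lut[self.node_regime], new_labels)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in range(self.tree.n_nodes):
            rows.append(
                {
                    "node": v,
                    "label": self.tree.tip_labels[v] if v < self.tree.n_tips else "",
                    "regime": self.regime_labels[self.node_regime[v]],
                }
            )
        return pd.DataFrame(rows)

    def tip_segments(self, tip: int) -> list[tuple[float, float, int]]:
        """Root-to-tip regime segments ``(t_start, t_end, regime_index)``."""
        path = self.tree.path_to_root(tip)[::-1]  # root ... tip
        segs = []
        for v in path[1:]:
            t_child = self.tree.node_times[v]
            t_par = self.tree.node_times[self.tree.parent[v]]
            segs.append((t_par, t_child, int(self.node_regime[v])))
        return segs


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------


def independent_contrasts(
    tree: Phylogeny, traits: pd.DataFrame | pd.Series
) -> tuple[pd.DataFrame, np.ndarray]:
    """Felsenstein's phylogenetic independent contrasts and the rate matrix.

    Returns ``(contrasts, rate)`` where ``contrasts`` holds the n-1
    standardized contrasts per trait and ``rate`` is the evolutionary rate
    covariance (cross-products of standardized contrasts over n-1).
    """
    X = _tip_matrix(tree, traits)
    n, p = X.shape
    vals = np.zeros((tree.n_nodes, p))
    vals[:n] = X
    extra = np.zeros(tree.n_nodes)  # branch-length adjustment from pruning
    contrasts = []
    for v in tree.postorder:
        if v < n:
            continue
        c1, c2 = tree.children[v]
        v1 = tree.length[c1] + extra[c1]
        v2 = tree.length[c2] + extra[c2]
        if v1 + v2 <= 0:
            raise DegenerateBranchError(
                f"both child branches of node {v} have zero length"
            )
        contrasts.append((vals[c1] - vals[c2]) / np.sqrt(v1 + v2))
        vals[v] = (v2 * vals[c1] + v1 * vals[c2]) / (v1 + v2)
        extra[v] = v1 * v2 / (v1 + v2)
    C = np.array(contrasts)
    rate = C.T @ C / (n - 1)
    cols = X_columns(traits)
    return pd.DataFrame(C, columns=cols), rate


def _tip_matrix(tree: Phylogeny, traits) -> np.ndarray:
    """Align a species-indexed table/series to tip order; 2-D float array."""
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    if isinstance(traits, pd.DataFrame):
        missing = [l for l in tree.tip_labels if l not in traits.index]
        if missing:
            raise MissingDataError(f"no trait values for tips: {missing[:5]}")
        X = traits.loc[tree.tip_labels].to_numpy(dtype=float)
    else:
        X = np.asarray(traits, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != tree.n_tips:
            raise MissingDataError("trait array length does not match tip count")
    if np.isnan(X).any():
        raise MissingDataError("trait table contains missing values")
    return X


def X_columns(traits) -> list:
    if isinstance(traits, pd.Series):
        return [traits.name or 0]
    if isinstance(traits, pd.DataFrame):
        return list(traits.columns)
    X = np.asarray(traits)
    return list(range(1 if X.ndim == 1 else X.shape[1]))


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


@dataclass
class AncestralEstimate:
    """ML ancestral reconstruction: continuous node values or discrete
    per-node state probabilities (rows sum to 1)."""

    tree: Phylogeny
    node_values: np.ndarray | None = None  # (n_internal, p), root last
    node_state_probabilities: np.ndarray | None = None  # (n_nodes, k)
    state_labels: list[str] | None = None
    rate: float | None = None

    @property
    def root_value(self):
        if self.node_values is not None:
            return self.node_values[-1]
        return self.node_state_probabilities[self.tree.root]


def ancestral_continuous_ml(tree: Phylogeny, trait) -> AncestralEstimate:
    """ML node values for a continuous trait under Brownian motion.

    Joint ML node values minimize sum over branches of
    (x_child - x_parent)^2 / branch_length; the solution is a linear system
    in the internal-node values (tips fixed at their observations).  The
    root estimate coincides with the BM-GLS grand mean.
    """
    X = _tip_matrix(tree, trait)
    n, p = X.shape
    m = tree.n_nodes - n  # internal node count
    w = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if v != tree.root:
            if tree.length[v] <= 0:
                raise DegenerateBranchError(
                    f"zero-length branch above node {v}: ML estimate undefined"
                )
            w[v] = 1.0 / tree.length[v]
    # Laplacian system over internal nodes
    L = np.zeros((m, m))
    b = np.zeros((m, p))
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        u = tree.parent[v]
        iu = u - n
        if v < n:
            L[iu, iu] += w[v]
            b[iu] += w[v] * X[v]
        else:
            iv = v - n
            L[iu, iu] += w[v]
            L[iv, iv] += w[v]
            L[iu, iv] -= w[v]
            L[iv, iu] -= w[v]
    vals = np.linalg.solve(L, b)
    return AncestralEstimate(tree=tree, node_values=vals)


def _er_transition(k: int, rate: float, t: np.ndarray) -> np.ndarray:
    """Equal-rates Mk transition probabilities.

    Rate ``rate`` for each of the k-1 destination states; P(t) has
    p_same = 1/k + (k-1)/k * exp(-k*rate*t), p_diff = 1/k * (1 - exp(-k*rate*t)).
    """
    e = np.exp(-k * rate * np.asarray(t, dtype=float))
    p_diff = (1.0 - e) / k
    p_same = e + p_diff
    return p_same, p_diff


def _mk_down_pass(tree: Phylogeny, tip_idx: np.ndarray, k: int, rate: float):
    """Partial likelihoods of the data below each node, with scaling.

    Returns (down, log_scale) where down[v, s] is proportional to
    P(data below v | state s at v) and log_scale the accumulated log of the
    normalizing constants (so the true log-likelihood can be recovered).
    """
    n = tree.n_tips
    down = np.zeros((tree.n_nodes, k))
    down[np.arange(n), tip_idx] = 1.0
    log_scale = 0.0
    msgs = np.zeros((tree.n_nodes, k))  # message from child v to its parent
    for v in tree.postorder:
        if v >= n:
            down[v] = 1.0
            for c in tree.children[v]:
                down[v] *= msgs[c]
            s = down[v].sum()
            if s <= 0:
                raise FloatingPointError("underflow in pruning")
            down[v] /= s
            log_scale += np.log(s)
        if v != tree.root:
            p_same, p_diff = _er_transition(k, rate, tree.length[v])
            tot = down[v].sum()
            msgs[v] = p_diff * tot + (p_same - p_diff) * down[v]
    return down, msgs, log_scale


def _mk_loglik(tree: Phylogeny, tip_idx: np.ndarray, k: int, rate: float) -> float:
    down, _, log_scale = _mk_down_pass(tree, tip_idx, k, rate)
    root = down[tree.root]  # normalized at the root, so sum is 1
    return float(np.log(root.sum() / k) + log_scale)


def ancestral_discrete_ml(
    tree: Phylogeny, tip_states, labels: Sequence[str] | None = None
) -> AncestralEstimate:
    """Marginal ML ancestral states under an equal-rates Mk model.

    The single transition rate is fitted by maximum likelihood with the
    pruning algorithm (flat root prior); marginal node probabilities come
    from the down-pass/up-pass recursion and sum to 1 at every node.
    """
    states = pd.Series(tip_states)
    states = states.reindex(tree.tip_labels)
    if states.isna().any():
        raise MissingDataError("tip states missing for some species")
    if labels is None:
        labels = sorted(states.unique())
    labels = list(labels)
    k = len(labels)
    tip_idx = np.array([labels.index(s) for s in states], dtype=int)

    if k == 1 or len(set(tip_idx)) == 1:
        probs = np.zeros((tree.n_nodes, k))
        if k == 1:
            probs[:, 0] = 1.0
            return AncestralEstimate(
                tree=tree, node_state_probabilities=probs, state_labels=labels, rate=0.0
            )
        probs[:, tip_idx[0]] = 1.0
        probs[np.arange(tree.n_tips), :] = 0.0
        probs[np.arange(tree.n_tips), tip_idx] = 1.0
        return AncestralEstimate(
            tree=tree, node_state_probabilities=probs, state_labels=labels, rate=0.0
        )

    scale = 1.0 / max(tree.depth, 1e-12)
    res = minimize_scalar(
        lambda lr: -_mk_loglik(tree, tip_idx, k, np.exp(lr)),
        bounds=(np.log(1e-6 * scale), np.log(1e4 * scale)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rate = float(np.exp(res.x))

    down, msgs, _ = _mk_down_pass(tree, tip_idx, k, rate)
    up = np.zeros((tree.n_nodes, k))
    up[tree.root] = 1.0 / k
    for v in tree.preorder:
        if v < tree.n_tips:
            continue
        for c in tree.children[v]:
            sib_msg = np.ones(k)
            for b in tree.children[v]:
                if b != c:
                    sib_msg *= msgs[b]
            parent_part = up[v] * sib_msg
            p_same, p_diff = _er_transition(k, rate, tree.length[c])
            tot = parent_part.sum()
            up[c] = p_diff * tot + (p_same - p_diff) * parent_part
            s = up[c].sum()
            if s > 0:
                up[c] /= s
    marg = down * up
    marg /= marg.sum(axis=1, keepdims=True)
    return AncestralEstimate(
        tree=tree, node_state_probabilities=marg, state_labels=labels, rate=rate
    )


def paint_regimes(
    tree: Phylogeny, estimate: AncestralEstimate, tip_states=None
) -> RegimePainting:
    """Paint branches from a discrete ancestral estimate.

    Each internal node takes its maximum-probability state; probability
    ties resolve toward the parent's state (root ties toward the first
    label in canonical order).  A branch carries its child node's state, so
    terminal branches carry the tips' own observed states.
    """
    if estimate.node_state_probabilities is None:
        raise ValueError("paint_regimes needs a discrete ancestral estimate")
    labels = list(estimate.state_labels)
    probs = estimate.node_state_probabilities
    node_regime = np.zeros(tree.n_nodes, dtype=int)
    tol = 1e-12
    for v in tree.preorder:
        row = probs[v]
        best = row.max()
        cands = np.flatnonzero(row >= best - tol)
        if len(cands) > 1 and v != tree.root:
            par = node_regime[tree.parent[v]]
            choice = par if par in cands else int(cands[0])
        else:
            choice = int(cands[0])
        node_regime[v] = choice
    if tip_states is not None:
        states = pd.Series(tip_states).reindex(tree.tip_labels)
        node_regime[: tree.n_tips] = [labels.index(s) for s in states]
    return RegimePainting(tree, node_regime, labels)
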