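"""Dated-phylogeny container and the covariance structure used by every statistic.

A :class:`DatedTree` is a rooted, binary, ultrametric tree with branch
lengths in millions of years (my).  Ages are measured backwards from the
present, so all tips sit at age 0 and the root at age ``root_age`` mya.
The phylogenetic variance-covariance matrix :math:`C` — entry
:math:`C_{ij}` being the shared path length from the root down to the most
recent common ancestor of tips *i* and *j* — is what Brownian-motion trait
models, Blomberg's K and Pagel's lambda all operate on.

Nodes are indexed ``0 .. 2n-2``: tips ``0 .. n-1`` (in the order they appear
in the source Newick) and internal nodes ``n .. 2n-2`` in postorder, the
root last.  That indexing is stable and is what shift reports and node-age
vectors are keyed by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "DatedTree",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "lambda_transform",
    "DEFAULT_ULTRAMETRIC_RTOL",
]

#: Relative tolerance on root-to-tip depths used by the ultrametricity check.
#: Dated trees emitted by MCMC samplers carry rounding noise at this scale.
DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid tree that violates a dated-tree invariant."""


@dataclass(frozen=True)
class DatedTree:
    """Rooted binary ultrametric phylogeny with branch lengths in my.

    Parameters
    ----------
    labels
        Tip labels, unique and non-empty; tip *i* is node *i*.
    children
        Integer array of shape ``(n-1, 2)``; row *k* holds the two child
        node indices of internal node ``n + k``.  Rows are in postorder, so
        every child index is smaller than ``n + k`` and the last row is the
        root.
    blen
        Branch length above each node, shape ``(2n-1,)``; the root entry is 0.
    """

    labels: tuple[str, ...]
    children: np.ndarray
    blen: np.ndarray
    _depths: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "children", np.asarray(self.children, dtype=np.intp))
        object.__setattr__(self, "blen", np.asarray(self.blen, dtype=float))
        n = len(labels)
        if n < 2:
            raise TreeValidationError("a dated tree needs at least 2 tips")
        if len(set(labels)) != n or any(not lab for lab in labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(
                f"tip labels must be unique and non-empty (duplicates: {dupes})"
            )
        if self.children.shape != (n - 1, 2):
            raise TreeValidationError(
                f"binary rooted tree with {n} tips needs {n - 1} internal nodes"
            )
        if self.blen.shape != (2 * n - 1,):
            raise TreeValidationError("blen must have one entry per node")
        if np.any(self.blen < 0) or not np.all(np.isfinite(self.blen)):
            raise TreeValidationError("branch lengths must be finite and >= 0")
        if not np.any(self.blen > 0):
            raise TreeValidationError("at least one branch length must be > 0")
        for k in range(n - 1):
            if np.any(self.children[k] >= n + k):
                raise TreeValidationError("children rows must be in postorder")
        # depth of each node below the root: one top-down pass (rows are
        # postorder, so iterating rows in reverse visits parents first)
        depths = np.zeros(2 * n - 1)
        for k in range(n - 2, -1, -1):
            node = n + k
            depths[self.children[k]] = depths[node] + self.blen[self.children[k]]
        object.__setattr__(self, "_depths", depths)
        if np.any(self.blen[np.arange(n)] == 0):
            warnings.warn(
                "tree has zero-length terminal branches; contrast variances "
                "at the parent nodes are degenerate",
                stacklevel=3,
            )

    # ------------------------------------------------------------------ shape

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def root_age(self) -> float:
        """Depth of the root below the present (my)."""
        return float(self._depths[: self.n_tips].max())

    def depths(self) -> np.ndarray:
        """Depth of every node below the root (my), indexed by node id."""
        return self._depths.copy()

    def parent_array(self) -> np.ndarray:
        """Parent node index per node (-1 for the root)."""
        n = self.n_tips
        parent = np.full(self.n_nodes, -1, dtype=np.intp)
        for k in range(n - 1):
            parent[self.children[k]] = n + k
        return parent

    def is_ultrametric(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> bool:
        tip_depths = self._depths[: self.n_tips]
        scale = tip_depths.max()
        return bool(scale > 0 and np.all(np.abs(tip_depths - scale) <= rtol * scale))

    def _require_ultrametric(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> None:
        if not self.is_ultrametric(rtol):
            tip_depths = self._depths[: self.n_tips]
            raise TreeValidationError(
                "tree is not ultrametric within relative tolerance "
                f"{rtol:g}: root-to-tip depths span "
                f"[{tip_depths.min():.6g}, {tip_depths.max():.6g}] my"
            )

    def descendant_tips(self, node: int) -> np.ndarray:
        """Tip indices descending from ``node`` (the node itself if a tip)."""
        n = self.n_tips
        if node < n:
            return np.array([node], dtype=np.intp)
        stack = [node]
        tips: list[int] = []
        while stack:
            v = stack.pop()
            if v < n:
                tips.append(v)
            else:
                stack.extend(self.children[v - n])
        return np.array(sorted(tips), dtype=np.intp)

    def mrca(self, tip_labels: Iterable[str]) -> int:
        """Node index of the most recent common ancestor of the given tips."""
        want = set(tip_labels)
        unknown = want - set(self.labels)
        if unknown:
            raise KeyError(f"unknown tip labels: {sorted(unknown)}")
        idx = {self.labels.index(lab) for lab in want}
        parent = self.parent_array()
        for k in range(self.n_tips - 1):
            node = self.n_tips + k
            if idx <= set(self.descendant_tips(node)):
                return node
        return self.root

    def node_label(self, node: int) -> str:
        """Stable human-readable name: the tip, or the two extreme descendant tips."""
        if node < self.n_tips:
            return self.labels[node]
        tips = self.descendant_tips(node)
        names = sorted(self.labels[t] for t in tips)
        return f"{names[0]}|{names[-1]}"

    # -------------------------------------------------------------- operations

    def node_ages(self, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> np.ndarray:
        """Ages (mya) of the ``n-1`` internal nodes, indexed in postorder.

        The root age is the maximum; all ages lie in ``[0, root_age]``.
        Requires an ultrametric tree — ages are only meaningful when every
        tip sits at the present.
        """
        self._require_ultrametric(rtol)
        root_age = self.root_age
        ages = root_age - self._depths[self.n_tips :]
        return np.clip(ages, 0.0, root_age)

    def vcv(self) -> np.ndarray:
        """Phylogenetic variance-covariance matrix over tips.

        ``C[i, j]`` is the root-to-MRCA path length of tips *i*, *j*;
        ``C[i, i]`` is the root-to-tip depth.  Symmetric and positive
        semi-definite by construction; for an ultrametric tree every
        diagonal entry equals ``root_age``.
        """
        n = self.n_tips
        C = np.zeros((n, n))
        C[np.arange(n), np.arange(n)] = self._depths[:n]
        for k in range(n - 1):
            node = n + k
            left, right = self.children[k]
            lt = self.descendant_tips(left)
            rt = self.descendant_tips(right)
            C[np.ix_(lt, rt)] = self._depths[node]
            C[np.ix_(rt, lt)] = self._depths[node]
        return C

    def prune_to(self, keep: Iterable[str]) -> "DatedTree":
        """Induced subtree on ``keep``; unifurcations are collapsed by
        summing branch lengths, so ultrametricity and all pairwise shared
        depths are preserved."""
        keep = set(keep)
        unknown = sorted(keep - set(self.labels))
        if unknown:
            raise KeyError(f"species not in tree: {unknown}")
        if len(keep) < 2:
            raise TreeValidationError("prune_to needs at least 2 species")
        n = self.n_tips
        keep_idx = [i for i, lab in enumerate(self.labels) if lab in keep]
        if len(keep_idx) == n:
            return self
        new_labels: list[str] = []
        # mapping old node -> (new node id, accumulated branch length above it)
        sub: dict[int, tuple[int, float]] = {}
        for i in keep_idx:
            sub[i] = (len(new_labels), self.blen[i])
            new_labels.append(self.labels[i])
        n_keep = len(new_labels)
        internal: list[tuple[int, int]] = []
        internal_blen: list[tuple[float, float]] = []
        for k in range(n - 1):
            node = n + k
            present = [c for c in self.children[k] if c in sub]
            if not present:
                continue
            if len(present) == 1:
                cid, acc = sub[present[0]]
                sub[node] = (cid, acc + self.blen[node])
            else:
                new_id = n_keep + len(internal)
                internal.append((sub[present[0]][0], sub[present[1]][0]))
                internal_blen.append((sub[present[0]][1], sub[present[1]][1]))
                sub[node] = (new_id, self.blen[node])
        # assemble branch lengths: tips then internals; internal child lengths
        # were accumulated, store them on the child entries
        blen = np.zeros(2 * n_keep - 1)
        children = np.asarray(internal, dtype=np.intp)
        for pair, lens in zip(internal, internal_blen):
            for c, ln in zip(pair, lens):
                blen[c] = ln
        # root accumulated length is dropped (root has no branch above)
        return DatedTree(tuple(new_labels), children, blen)

    # --------------------------------------------------------------- newick io

    def to_newick(self) -> str:
        """Serialize to Newick with branch lengths at full precision."""
        n = self.n_tips

        def fmt_label(lab: str) -> str:
            if any(ch in lab for ch in " ()[]:;,'\t\n"):
                return "'" + lab.replace("'", "''") + "'"
            return lab

        def render(node: int) -> str:
            if node < n:
                return f"{fmt_label(self.labels[node])}:{float(self.blen[node])!r}"
            left, right = self.children[node - n]
            inner = f"({render(left)},{render(right)})"
            if node == self.root:
                return inner
            return f"{inner}:{float(self.blen[node])!r}"

        return render(self.root) + ";"


def _min_tip_label(node: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def read_newick(
    source: str,
    *,
    resolve_polytomies: bool = False,
    require_ultrametric: bool = True,
    rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> DatedTree:
    """Parse a rooted dated tree from a Newick string or file path.

    Polytomies are rejected unless ``resolve_polytomies`` is set, in which
    case each multifurcation is resolved deterministically (children ordered
    by smallest descendant tip label) into zero-length bifurcations —
    independent contrasts require a binary tree.
    """
    text = source
    if "(" not in source:  # looks like a path, not newick
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickParseError("empty tip label")
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise NewickParseError("missing branch length on an internal or tip edge")
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        if len(kids) == 1:
            raise NewickParseError("unifurcation in input tree")
        if len(kids) > 2:
            if not resolve_polytomies:
                raise TreeValidationError(
                    f"polytomy with {len(kids)} children; pass "
                    "resolve_polytomies=True to resolve into zero-length "
                    "bifurcations"
                )
            kids = sorted(kids, key=_min_tip_label)
            for k in kids:
                node.remove_child(k)
            # left-fold into zero-length cherries
            acc = kids[0]
            for nxt in kids[1:-1]:
                joint = dendropy.Node(edge_length=0.0)
                joint.add_child(acc)
                joint.add_child(nxt)
                acc = joint
            node.add_child(acc)
            node.add_child(kids[-1])

    labels: list[str] = []
    tip_index: dict[int, int] = {}
    # index tips in their order of appearance in the newick (preorder)
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            tip_index[id(node)] = len(labels)
            labels.append(node.taxon.label)
    n = len(labels)
    if len(set(labels)) != n:
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate tip labels: {dupes}")
    if n < 2:
        raise NewickParseError("tree has fewer than 2 tips")

    children_rows: list[tuple[int, int]] = []
    blen = np.zeros(2 * n - 1)
    node_id: dict[int, int] = dict(tip_index)
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            blen[node_id[id(node)]] = float(node.edge.length)
            continue
        kids = node.child_nodes()
        this = n + len(children_rows)
        children_rows.append((node_id[id(kids[0])], node_id[id(kids[1])]))
        node_id[id(node)] = this
        if node.parent_node is not None:
            blen[this] = float(node.edge.length)

    tree = DatedTree(tuple(labels), np.asarray(children_rows, dtype=np.intp), blen)
    if require_ultrametric:
        tree._require_ultrametric(rtol)
    return tree


def write_newick(tree: DatedTree) -> str:
    return tree.to_newick()


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: scale off-diagonal covariances by ``lam``.

    ``lam = 1`` returns C unchanged (Brownian motion); ``lam = 0`` returns
    the diagonal (star-tree, no phylogenetic covariance).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out
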