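"""Felsenstein's phylogenetic independent contrasts and trait-shift detection.

At each internal node of a binary tree the difference between its two
daughter values, standardized by the expected Brownian variance (sum of
the daughters' variance-adjusted branch lengths), gives one contrast;
under Brownian motion the n-1 standardized contrasts are i.i.d.
N(0, sigma2).  Nodes whose observed contrast magnitude is extreme against
a tip-permutation null are flagged as significant trait shifts — clades
whose trait distribution is larger or smaller than the rest of the tree
predicts.

Because ancestral values in the pruning recursion are weighted averages of
tip values, every standardized contrast is a fixed linear combination of
the tip vector; the coefficient matrix is built once and the permutation
null reduces to a matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .treeio import DatedTree
from .phylosignal import align_trait

__all__ = ["ContrastSet", "ShiftReport", "pic", "detect_shifts", "contrast_matrix"]


@dataclass(frozen=True)
class ContrastSet:
    """Per-internal-node contrasts, postorder; ``node_ids`` index the tree."""

    node_ids: np.ndarray
    raw: np.ndarray  # x_i - x_j across each node's daughters
    variance: np.ndarray  # v_i + v_j (my), branch lengths variance-adjusted
    standardized: np.ndarray  # raw / sqrt(variance)
    node_value: np.ndarray  # weighted ancestral estimate at the node
    adjusted_blen: np.ndarray  # node's parent branch after the v_i v_j/(v_i+v_j) bump
    node_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.node_ids,
                "node_name": list(self.node_names),
                "raw_contrast": self.raw,
                "contrast_variance": self.variance,
                "standardized_contrast": self.standardized,
                "ancestral_value": self.node_value,
                "adjusted_branch_length": self.adjusted_blen,
            }
        )


@dataclass(frozen=True)
class ShiftReport:
    """Shift-detection outcome: one row per internal node."""

    table: pd.DataFrame  # node, node_name, age column added downstream
    n_replicates: int
    alpha: float
    correction: Optional[str]
    mode: str
    seed: Optional[int]

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def _pic_arrays(tree: DatedTree):
    """Shared pruning pass: adjusted branch lengths and the linear maps.

    Returns (variance, W, L, adjusted) where W maps tips -> node values and
    L maps tips -> standardized contrasts, both with one row per internal
    node in postorder.
    """
    n = tree.n_tips
    eps = np.finfo(float).eps * max(tree.root_age, 1.0)
    v = tree.blen.copy()
    W = np.zeros((2 * n - 1, n))
    W[np.arange(n), np.arange(n)] = 1.0
    raw_rows = np.zeros((n - 1, n))
    variance = np.zeros(n - 1)
    adjusted = np.zeros(n - 1)
    for k in range(n - 1):
        node = n + k
        i, j = tree.children[k]
        vi, vj = v[i], v[j]
        if vi == 0 and vj == 0:
            raise ValueError(
                f"both daughter branch variances are zero at node {node} "
                f"({tree.node_label(node)}); contrasts undefined"
            )
        if vi == 0 or vj == 0:
            warnings.warn(
                f"zero-length daughter branch at node {node}; adding machine "
                "epsilon x root_age to keep the contrast finite",
                stacklevel=3,
            )
            vi = vi or eps
            vj = vj or eps
        raw_rows[k] = W[i] - W[j]
        variance[k] = vi + vj
        W[node] = (W[i] / vi + W[j] / vj) / (1.0 / vi + 1.0 / vj)
        v[node] += vi * vj / (vi + vj)
        adjusted[k] = v[node]
    L = raw_rows / np.sqrt(variance)[:, None]
    return variance, W, L, adjusted, raw_rows


def contrast_matrix(tree: DatedTree) -> np.ndarray:
    """(n-1) x n matrix mapping a tip vector to its standardized contrasts."""
    return _pic_arrays(tree)[2]


def pic(tree: DatedTree, x: pd.Series | np.ndarray) -> ContrastSet:
    """Phylogenetic independent contrasts of a complete trait vector."""
    if isinstance(x, pd.Series):
        tree, x = align_trait(tree, x, min_species=2)
    x = np.asarray(x, dtype=float)
    if len(x) != tree.n_tips:
        raise ValueError("trait vector length does not match tip count")
    n = tree.n_tips
    variance, W, L, adjusted, raw_rows = _pic_arrays(tree)
    node_ids = np.arange(n, 2 * n - 1)
    return ContrastSet(
        node_ids=node_ids,
        raw=raw_rows @ x,
        variance=variance,
        standardized=L @ x,
        node_value=W[n:] @ x,
        adjusted_blen=adjusted,
        node_names=tuple(tree.node_label(v) for v in node_ids),
    )


def detect_shifts(
    tree: DatedTree,
    x: pd.Series | np.ndarray,
    n_replicates: int = 9999,
    alpha: float = 0.05,
    seed=None,
    correction: Optional[Literal["bh"]] = None,
    mode: Literal["per-node", "pooled"] = "per-node",
) -> ShiftReport:
    """Flag internal nodes whose standardized contrast is extreme.

    The null distribution comes from permuting trait values across tips
    and recomputing all standardized contrasts.  ``mode="per-node"``
    compares each node to its own permutation distribution (two-sided
    empirical P with add-one smoothing); ``mode="pooled"`` compares each
    node to the pooled distribution of all nodes' permuted contrasts,
    which borrows strength across nodes at the cost of ignoring per-node
    variance structure.  ``correction="bh"`` applies Benjamini-Hochberg
    across nodes before flagging at level ``alpha``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_replicates < 99:
        warnings.warn(
            f"n_replicates={n_replicates} gives coarse P-value resolution",
            stacklevel=2,
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if isinstance(x, pd.Series):
        tree, x = align_trait(tree, x)
    x = np.asarray(x, dtype=float)
    n = tree.n_tips
    variance, W, L, adjusted, raw_rows = _pic_arrays(tree)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(x, (n_replicates, 1)), axis=1).T  # n x B
    # evaluate the observed vector through the same matrix product as the
    # permutations: BLAS gemm vs gemv differ at machine precision, which
    # would otherwise break exact ties (e.g. constant traits)
    all_cols = np.abs(L @ np.column_stack([x, perms]))
    obs = all_cols[:, 0]
    null = all_cols[:, 1:]  # (n-1) x B
    if mode == "per-node":
        exceed = np.sum(null >= obs[:, None], axis=1)
        denom = n_replicates
    elif mode == "pooled":
        pooled = np.sort(null.ravel())
        exceed = len(pooled) - np.searchsorted(pooled, obs, side="left")
        denom = null.size
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = (1 + exceed) / (1 + denom)

    if correction == "bh":
        p_adj = _benjamini_hochberg(p)
        flagged = p_adj <= alpha
    elif correction is None:
        p_adj = p
        flagged = p <= alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")

    node_ids = np.arange(n, 2 * n - 1)
    table = pd.DataFrame(
        {
            "node": node_ids,
            "node_name": [tree.node_label(v) for v in node_ids],
            "abs_standardized_contrast": obs,
            "p_value": p,
            "p_adjusted": p_adj,
            "flagged": flagged,
        }
    )
    return ShiftReport(
        table=table,
        n_replicates=n_replicates,
        alpha=alpha,
        correction=correction,
        mode=mode,
        seed=seed if isinstance(seed, int) else None,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
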