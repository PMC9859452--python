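"""Intra-individual ecological dissimilarities between paired samples.

Bray-Curtis is abundance-only; the UniFrac family weights shared and
unshared phylogenetic branch length.  Unweighted UniFrac uses only
presence/absence, weighted UniFrac only abundances, and generalized
UniFrac interpolates between them through an exponent alpha on the total
branch abundance (alpha = 0.5 is the usual compromise; at alpha = 1 it
coincides with normalized weighted UniFrac).

Unweighted and weighted UniFrac delegate to scikit-bio; generalized
UniFrac is computed here by an explicit post-order branch traversal, which
also serves as an independent route for cross-checking the weighted form.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.beta import unweighted_unifrac as _skbio_unweighted

from .core import LongitudinalMicrobiomeTable, relative_abundances
from .pairing import SamplePair

__all__ = [
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "generalized_unifrac",
    "pairwise_dissimilarities",
    "METRICS",
]

METRICS = (
    "bray_curtis",
    "unweighted_unifrac",
    "generalized_unifrac",
    "weighted_unifrac",
)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min(x,y)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("inputs must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors are all zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def unweighted_unifrac(x, y, tree: TreeNode, taxa: Sequence[str]) -> float:
    """Fraction of total branch length unique to one sample's taxon set."""
    presence_x = (np.asarray(x) > 0).astype(int)
    presence_y = (np.asarray(y) > 0).astype(int)
    return float(
        _skbio_unweighted(presence_x, presence_y, taxa=list(taxa), tree=tree)
    )


def weighted_unifrac(
    px,
    py,
    tree: TreeNode,
    taxa: Sequence[str],
    normalized: bool = True,
    _index: Optional["_BranchIndex"] = None,
) -> float:
    """Abundance-weighted UniFrac; normalized form is bounded in [0, 1].

    raw: sum_b l_b |A_b - B_b|; normalized divides by sum_b l_b (A_b + B_b)
    (equivalently the root-to-tip-depth-weighted abundance sum), with A_b,
    B_b the relative abundance of the subtree below branch b.  Computed by
    branch traversal so fractional abundance vectors are handled exactly.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    for v in (px, py):
        if (v < 0).any() or v.sum() <= 0:
            raise ValueError("inputs must be non-negative with positive total")
    px = px / px.sum()
    py = py / py.sum()
    index = _index if _index is not None else _BranchIndex(tree, taxa)
    A = index.masses(px)
    B = index.masses(py)
    raw = float((index.lengths * np.abs(A - B)).sum())
    if not normalized:
        return raw
    denom = float((index.lengths * (A + B)).sum())
    if denom == 0:
        raise ValueError("tree carries no branch length under either sample")
    return raw / denom


class _BranchIndex:
    """Per-branch leaf membership for fast repeated traversals.

    For each non-root branch b with length l_b, ``masses(p)`` returns the
    total abundance of the leaves below b.  Built once per (tree, taxa).
    """

    def __init__(self, tree: TreeNode, taxa: Sequence[str]):
        taxa = list(taxa)
        tip_names = {t.name for t in tree.tips()}
        missing = [t for t in taxa if t not in tip_names]
        if missing:
            raise ValueError(f"taxa not found in tree: {missing[:5]}")
        col = {t: j for j, t in enumerate(taxa)}
        lengths: List[float] = []
        members: List[np.ndarray] = []
        # postorder accumulation of leaf index sets
        leafsets = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                leafsets[id(node)] = (
                    np.array([col[node.name]]) if node.name in col else np.array([], dtype=int)
                )
            else:
                leafsets[id(node)] = (
                    np.concatenate([leafsets[id(c)] for c in node.children])
                    if node.children
                    else np.array([], dtype=int)
                )
            if node is not tree:
                lengths.append(float(node.length or 0.0))
                members.append(leafsets[id(node)])
        self.lengths = np.asarray(lengths)
        self.indicator = np.zeros((len(members), len(taxa)))
        for b, idx in enumerate(members):
            self.indicator[b, idx] = 1.0

    def masses(self, p: np.ndarray) -> np.ndarray:
        return self.indicator @ np.asarray(p, dtype=float)


def generalized_unifrac(
    px,
    py,
    tree: TreeNode,
    taxa: Sequence[str],
    alpha: float = 0.5,
    _index: Optional[_BranchIndex] = None,
) -> float:
    """Generalized UniFrac with abundance exponent alpha in [0, 1].

    d = sum_b l_b (A_b + B_b)^alpha |A_b - B_b| / (A_b + B_b)
        / sum_b l_b (A_b + B_b)^alpha,

    over branches with A_b + B_b > 0, where A_b, B_b are the relative
    abundances of the subtree below branch b in each sample.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    for v in (px, py):
        if (v < 0).any() or v.sum() <= 0:
            raise ValueError("inputs must be non-negative with positive total")
    px = px / px.sum()
    py = py / py.sum()
    index = _index if _index is not None else _BranchIndex(tree, taxa)
    A = index.masses(px)
    B = index.masses(py)
    total = A + B
    active = total > 0
    w = index.lengths[active] * total[active] ** alpha
    num = (w * np.abs(A[active] - B[active]) / total[active]).sum()
    den = w.sum()
    if den == 0:
        raise ValueError("no branch carries abundance from either sample")
    return float(num / den)


def pairwise_dissimilarities(
    table: LongitudinalMicrobiomeTable,
    pairs: Sequence[SamplePair],
    metric: str = "bray_curtis",
    tree: Optional[TreeNode] = None,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """One dissimilarity per sample pair.

    UniFrac metrics require ``tree``; when no tree is available only
    Bray-Curtis can be computed.  Returns a DataFrame with subject,
    pair_id, observed_lag_days, metric, alpha and value columns.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    needs_tree = metric != "bray_curtis"
    if needs_tree and tree is None:
        raise ValueError(
            f"metric {metric!r} requires a phylogenetic tree; without one "
            "only bray_curtis is available"
        )
    pairs = list(pairs)
    taxa = table.taxon_ids
    counts = table.counts
    rel = relative_abundances(table) if metric != "unweighted_unifrac" else None
    index = (
        _BranchIndex(tree, taxa)
        if metric in ("generalized_unifrac", "weighted_unifrac")
        else None
    )

    values = []
    for p in pairs:
        if metric == "bray_curtis":
            v = bray_curtis(counts[p.sample_earlier], counts[p.sample_later])
        elif metric == "unweighted_unifrac":
            v = unweighted_unifrac(
                counts[p.sample_earlier], counts[p.sample_later], tree, taxa
            )
        elif metric == "weighted_unifrac":
            v = weighted_unifrac(
                rel[p.sample_earlier].to_numpy(),
                rel[p.sample_later].to_numpy(),
                tree,
                taxa,
                _index=index,
            )
        else:
            v = generalized_unifrac(
                rel[p.sample_earlier].to_numpy(),
                rel[p.sample_later].to_numpy(),
                tree,
                taxa,
                alpha=alpha,
                _index=index,
            )
        values.append(v)
    return pd.DataFrame(
        {
            "subject": [p.subject for p in pairs],
            "pair_id": [p.pair_id for p in pairs],
            "observed_lag_days": [p.observed_lag_days for p in pairs],
            "metric": metric,
            "alpha": alpha if metric == "generalized_unifrac" else np.nan,
            "value": values,
        }
    )
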