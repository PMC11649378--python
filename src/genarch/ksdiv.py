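"""Gene-structure divergence via two-sample Kolmogorov–Smirnov distances.

Whole-genome feature distributions (per-gene intron ratios, pooled intron
lengths, per-gene intron counts) are compared between species pairs with
the two-sample KS statistic — the supremum gap between empirical CDFs, 0
for identical and 1 for non-overlapping distributions.  The resulting
distance matrix is mapped onto the fixed dated topology by ordinary least
squares over tip-pair path equations, giving a tree whose branch lengths
are in KS units; dividing by the dated branch lengths yields divergence
rates (KS per Myr, or per Byr ×1000) globally, per clade, and per branch.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .tree import DatedTree, TreeNode, assign_branches

logger = logging.getLogger(__name__)

__all__ = [
    "ks_distance",
    "pairwise_matrix",
    "fit_branch_lengths",
    "divergence_rates",
    "RateTree",
]


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample KS statistic: sup |ECDF_a − ECDF_b| over pooled points."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def pairwise_matrix(
    distributions: Mapping[str, Sequence[float]], feature: str = "feature"
) -> pd.DataFrame:
    """Symmetric species × species KS distance matrix.

    Species with empty distributions are dropped with a warning.
    """
    kept = {}
    for name, values in distributions.items():
        arr = np.asarray(values, float)
        if arr.size == 0:
            logger.warning("species %s has an empty %s distribution; dropped",
                           name, feature)
            continue
        kept[name] = arr
    names = sorted(kept)
    if len(names) < 2:
        raise ValueError("need at least 2 species with non-empty distributions")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    mat.attrs["feature"] = feature
    for a, b in itertools.combinations(names, 2):
        d = ks_distance(kept[a], kept[b])
        mat.loc[a, b] = mat.loc[b, a] = d
    return mat


@dataclass
class RateTree:
    """The dated topology re-lengthed in KS units, with per-branch rates."""

    ks_tree: DatedTree
    dated_tree: DatedTree
    residual_rss: float

    def branch_table(self) -> pd.DataFrame:
        dated = {self.dated_tree.clade_key(b): b.length
                 for b in self.dated_tree.branches()}
        rows = []
        for branch in self.ks_tree.branches():
            key = self.ks_tree.clade_key(branch)
            ld = dated[key]
            rows.append(
                {
                    "branch": key,
                    "length_ks": branch.length,
                    "length_myr": ld,
                    "rate_per_myr": branch.length / ld if ld > 0 else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _pair_paths(tree: DatedTree):
    """Tip-pair path incidence over branches.

    When the root is bifurcating its two child branches are unidentifiable
    from tip-pair distances (every path crossing the root uses both), so
    they are merged into one pseudo-edge: the column of the second root
    child is removed and any path containing the pair loads the first root
    child's column with coefficient 1 (the parameter then represents the
    *sum* of the two root branch lengths).
    """
    branches = tree.branches()
    col = {node: j for j, node in enumerate(branches)}
    merged = None  # (kept_col, removed_col); kept < removed in preorder
    if len(tree.root.children) == 2:
        left, right = tree.root.children
        merged = (col[left], col[right])
    tips = tree.tips()
    root_paths = {}
    for tip in tips:
        path = set()
        node = tip
        while node.parent is not None:
            path.add(col[node])
            node = node.parent
        root_paths[tip] = path
    pairs = list(itertools.combinations(tips, 2))

    if merged is None:
        eff = {j: j for j in range(len(branches))}
        n_eff = len(branches)
    else:
        kept, removed = merged
        eff = {}
        for j in range(len(branches)):
            if j == removed:
                eff[j] = kept
            else:
                eff[j] = j - 1 if j > removed else j
        n_eff = len(branches) - 1

    A = np.zeros((len(pairs), n_eff))
    for r, (u, v) in enumerate(pairs):
        sym_diff = root_paths[u] ^ root_paths[v]
        for j in sym_diff:
            A[r, eff[j]] = 1.0  # root-edge pair collapses to coefficient 1
    return A, branches, pairs, merged, eff


def fit_branch_lengths(
    ks_matrix: pd.DataFrame,
    dated_tree: DatedTree,
    use_nnls: bool = False,
) -> RateTree:
    """Least-squares branch lengths on the fixed dated topology.

    Minimizes ``Σ_{i<j} (d_ij − Σ_{b∈path(i,j)} ℓ_b)²`` over branch lengths
    (ordinary, unweighted least squares); negative solutions are clamped to
    zero after solving (or the fit is non-negative from the start with
    ``use_nnls``).  A bifurcating root's two branches are unidentifiable
    from distances alone: they are fitted as one merged edge whose length
    is then split in proportion to the dated branch lengths.
    """
    tips = set(ks_matrix.index)
    tree_tips = set(dated_tree.tip_names())
    if not tips <= tree_tips:
        raise ValueError(f"matrix species missing from tree: {sorted(tips - tree_tips)}")
    work = dated_tree.copy()
    if tips < tree_tips:
        work.drop_tips(tree_tips - tips)

    A, branches, pairs, merged, eff = _pair_paths(work)
    d = np.array([ks_matrix.loc[u.name, v.name] for u, v in pairs])
    if use_nnls:
        sol, _ = nnls(A, d)
    else:
        sol, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = d - A @ sol
    rss = float(resid @ resid)
    sol = np.clip(sol, 0.0, None)

    # expand the merged root pseudo-edge back to two branches, splitting its
    # fitted length in proportion to the dated branch lengths
    lengths = np.empty(len(branches))
    for j in range(len(branches)):
        lengths[j] = sol[eff[j]]
    if merged is not None:
        kept, removed = merged
        la, lb = branches[kept].length, branches[removed].length
        share = la / (la + lb) if (la + lb) > 0 else 0.5
        fused = sol[eff[kept]]
        lengths[kept] = fused * share
        lengths[removed] = fused * (1.0 - share)

    ks_tree = work.copy()
    key_to_len = {work.clade_key(b): l for b, l in zip(branches, lengths)}
    for branch in ks_tree.branches():
        branch.length = float(key_to_len[ks_tree.clade_key(branch)])
    return RateTree(ks_tree=ks_tree, dated_tree=work, residual_rss=rss)


def divergence_rates(
    rate_tree: RateTree,
    clade_map: Mapping[str, str] | None = None,
    per_byr: bool = False,
) -> dict:
    """Global, per-clade, and per-branch gene-structure divergence rates.

    Rates are total KS tree length over total dated tree length (and the
    same ratio over each clade's assigned branches); per-branch rates are
    the branch-wise ratios, missing where the dated branch length is 0.
    ``per_byr`` scales from per-Myr to per-Byr (×1000).
    """
    ks_tree, dated = rate_tree.ks_tree, rate_tree.dated_tree
    ks_keys = {ks_tree.clade_key(b): b.length for b in ks_tree.branches()}
    dated_keys = {dated.clade_key(b): b.length for b in dated.branches()}
    if set(ks_keys) != set(dated_keys):
        raise ValueError("KS and dated trees have different topologies")
    unit = 1000.0 if per_byr else 1.0

    global_rate = unit * sum(ks_keys.values()) / sum(dated_keys.values())
    per_branch = {
        key: (unit * ks_keys[key] / dated_keys[key]) if dated_keys[key] > 0 else np.nan
        for key in ks_keys
    }
    out = {"global": global_rate, "per_branch": per_branch, "per_clade": {}}
    if clade_map is not None:
        labels = assign_branches(dated, clade_map)
        sums: dict[str, list[float]] = {}
        for branch, label in labels.items():
            key = dated.clade_key(branch)
            sums.setdefault(label, [0.0, 0.0])
            sums[label][0] += ks_keys[key]
            sums[label][1] += dated_keys[key]
        out["per_clade"] = {
            label: unit * ks_sum / myr_sum if myr_sum > 0 else np.nan
            for label, (ks_sum, myr_sum) in sums.items()
            if label != "stem"
        }
    return out
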