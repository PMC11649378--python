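"""Rate-heterogeneous trait evolution via phylogenetic ridge regression.

The model regresses tip trait values on the *path matrix* of the tree:
``X[i, b]`` is the length of branch ``b`` if it lies on the root-to-tip-*i*
path, else 0.  Each branch then carries its own rate ``β_b`` (trait units
per Myr), the state at any node is the root state plus the rate-weighted
path sum, and the ridge penalty ``λ Σ β_b²`` makes the heavily
over-parameterized system identifiable.  The root state is estimated first
as the generalized-least-squares phylogenetic mean under Brownian-motion
covariance and held fixed; ``λ`` is chosen by leave-one-out cross-validated
tip prediction error on a log-spaced grid.  A single-rate Brownian-motion
fit (ML σ², GLS ancestral states) serves as the homogeneous baseline.

Both models follow the Model → ``fit()`` → Results pattern: construct a
model from a tree and tip values, call ``fit``, and read estimates,
ancestral reconstructions and summaries off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .tree import DatedTree, TreeNode

__all__ = [
    "build_path_matrix",
    "phylo_covariance_matrix",
    "RidgeRateModel",
    "RidgeRateResults",
    "BrownianMotionModel",
    "BrownianMotionResults",
    "rescale_tree",
]

DEFAULT_LAMBDA_GRID = np.logspace(-6, 3, 40)


def _tip_vector(tree: DatedTree, tip_values) -> tuple[list[str], np.ndarray]:
    names = tree.tip_names()
    if isinstance(tip_values, pd.Series):
        tip_values = tip_values.to_dict()
    missing = [n for n in names if n not in tip_values]
    if missing:
        raise ValueError(f"tip values missing for: {missing}")
    y = np.asarray([float(tip_values[n]) for n in names])
    if not np.all(np.isfinite(y)):
        bad = [n for n, v in zip(names, y) if not np.isfinite(v)]
        raise ValueError(f"non-finite trait values for: {bad}")
    return names, y


def build_path_matrix(tree: DatedTree) -> tuple[np.ndarray, list[TreeNode]]:
    """Tips × branches design matrix of root-to-tip branch lengths.

    Returns ``(X, branches)`` where ``branches`` fixes the column order
    (preorder, each branch identified by its child node).  Row sums equal
    root-to-tip path lengths; zero-length branches yield zero columns.
    """
    branches = tree.branches()
    col = {node: j for j, node in enumerate(branches)}
    tips = tree.tips()
    X = np.zeros((len(tips), len(branches)))
    for i, tip in enumerate(tips):
        node = tip
        while node.parent is not None:
            X[i, col[node]] = node.length
            node = node.parent
    return X, branches


def phylo_covariance_matrix(tree: DatedTree) -> np.ndarray:
    """Brownian-motion covariance among tips: shared root-to-MRCA path length."""
    X, _ = build_path_matrix(tree)
    # C[i,j] = sum of branch lengths common to both root-to-tip paths
    return X @ (X > 0).T.astype(float)


_phylo_cov = phylo_covariance_matrix


def _gls_mean(C: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    jitter = 1e-10 * np.trace(C) / n
    factor = cho_factor(C + jitter * np.eye(n))
    ones = np.ones(n)
    w = cho_solve(factor, ones)
    return float(w @ y / (w @ ones))


@dataclass
class RidgeRateResults:
    """Fitted per-branch rates, root state and derived quantities."""

    model: "RidgeRateModel"
    root_state: float
    beta: np.ndarray  # per-branch rates, column order of the path matrix
    lambda_: float
    cv_error: float
    cv_path: pd.Series  # LOOCV error per grid value (empty for fixed λ)

    # ------------------------------------------------------------ views
    @property
    def lambda_normalized(self) -> float:
        """λ mapped to (0, 1) via λ/(1+λ); used by replicate-validity rules."""
        return self.lambda_ / (1.0 + self.lambda_)

    @property
    def rates(self) -> pd.Series:
        tree = self.model.tree
        keys = [tree.clade_key(b) for b in self.model.branch_nodes]
        return pd.Series(self.beta, index=keys, name="rate")

    def ancestral_states(self) -> dict[str, float]:
        """State at every node: root state plus the rate-weighted path sum."""
        return {
            self.model.tree.clade_key(node): value
            for node, value in self.node_states().items()
        }

    def node_states(self) -> dict[TreeNode, float]:
        tree = self.model.tree
        beta = {b: self.beta[j] for j, b in enumerate(self.model.branch_nodes)}
        states: dict[TreeNode, float] = {tree.root: self.root_state}
        for node in tree.nodes():
            if node.parent is not None:
                states[node] = states[node.parent] + beta[node] * node.length
        return states

    @property
    def fitted_tips(self) -> pd.Series:
        states = self.node_states()
        tips = self.model.tree.tips()
        return pd.Series([states[t] for t in tips], index=[t.name for t in tips])

    @property
    def resid(self) -> pd.Series:
        return pd.Series(self.model.y, index=self.model.tip_names) - self.fitted_tips

    def rescaled_tree(self) -> DatedTree:
        return rescale_tree(self.model.tree, self)

    def rates_frame(self) -> pd.DataFrame:
        tree = self.model.tree
        return pd.DataFrame(
            {
                "branch": [tree.clade_key(b) for b in self.model.branch_nodes],
                "length_myr": [b.length for b in self.model.branch_nodes],
                "rate": self.beta,
            }
        )

    def summary(self) -> str:
        lines = [
            "Phylogenetic ridge regression (rate-heterogeneous trait evolution)",
            f"  trait:            {self.model.trait_name}",
            f"  n tips:           {len(self.model.y)}",
            f"  n branches:       {len(self.beta)}",
            f"  root state:       {self.root_state:.6g}",
            f"  lambda:           {self.lambda_:.6g}"
            f"  (normalized {self.lambda_normalized:.4f})",
            f"  LOOCV error:      {self.cv_error:.6g}",
            f"  mean |rate|:      {np.mean(np.abs(self.beta)):.6g} per Myr",
            f"  max |rate|:       {np.max(np.abs(self.beta)):.6g} per Myr",
        ]
        return "\n".join(lines)


class RidgeRateModel:
    """Phylogenetic ridge regression of a tip trait on the tree's branches.

    Parameters
    ----------
    tree:
        Rooted tree with branch lengths in Myr (polytomies allowed).
    tip_values:
        Mapping or Series of trait value per tip label.  Apply any variance
        -stabilizing transform (e.g. log10 for lengths and ratios) before
        fitting; the model itself is transform-agnostic.
    """

    def __init__(self, tree: DatedTree, tip_values, trait_name: str = "trait"):
        if tree.n_tips < 3:
            raise ValueError("at least 3 tips are required")
        self.tree = tree
        self.trait_name = trait_name
        self.tip_names, self.y = _tip_vector(tree, tip_values)
        self.X, self.branch_nodes = build_path_matrix(tree)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, trait: str, tree: DatedTree, species_col=None
    ) -> "RidgeRateModel":
        series = (
            data.set_index(species_col)[trait] if species_col else data[trait]
        )
        return cls(tree, series, trait_name=trait)

    def fit(
        self,
        lam: float | str = "auto",
        lambda_grid: Sequence[float] | None = None,
    ) -> RidgeRateResults:
        root = _gls_mean(_phylo_cov(self.tree), self.y)
        r = self.y - root
        U, s, Vt = np.linalg.svd(self.X, full_matrices=False)
        Ur = U.T @ r
        r_perp = r - U @ Ur  # component outside the column space (p < n case)
        rowsum = np.einsum("ij,ij->i", U, U)

        def loocv(lmb: float) -> float:
            # exact ridge LOO residual e_i/(1−h_i), with e and 1−h computed
            # in cancellation-free form (both are O(λ) near interpolation)
            anti = lmb / (s**2 + lmb)
            e = U @ (anti * Ur) + r_perp
            one_minus_h = (1.0 - rowsum) + np.einsum("ij,j,ij->i", U, anti, U)
            return float(np.mean((e / one_minus_h) ** 2))

        if lam == "auto":
            grid = np.asarray(
                DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, float
            )
            errors = np.array([loocv(l) for l in grid])
            best = int(np.argmin(errors))
            lam_val = float(grid[best])
            cv_path = pd.Series(errors, index=grid, name="loocv_error")
            cv_err = float(errors[best])
        else:
            lam_val = max(float(lam), np.finfo(float).eps)
            cv_path = pd.Series(dtype=float, name="loocv_error")
            cv_err = loocv(lam_val)

        beta = Vt.T @ (s / (s**2 + lam_val) * Ur)
        return RidgeRateResults(
            model=self,
            root_state=root,
            beta=beta,
            lambda_=lam_val,
            cv_error=cv_err,
            cv_path=cv_path,
        )


def rescale_tree(tree: DatedTree, fit: RidgeRateResults) -> DatedTree:
    """Scale branch lengths by |rate| while conserving total tree length.

    ``ℓ'_b = |β_b| ℓ_b · Σℓ / Σ|β|ℓ``; a branch evolving fast in either
    direction becomes long, a zero-rate branch collapses to length 0, and
    the grand total is preserved exactly so downstream BM-based methods see
    a tree of the same overall size.
    """
    if fit.model.tree is not tree:
        # allow a structurally identical copy
        if sorted(fit.model.tree.tip_names()) != sorted(tree.tip_names()):
            raise ValueError("fit was produced on a different tree")
    weights = np.abs(fit.beta) * np.array(
        [b.length for b in fit.model.branch_nodes]
    )
    total = sum(b.length for b in fit.model.branch_nodes)
    if weights.sum() == 0:
        raise ValueError("all rates are zero; rescaling is degenerate")
    scale = total / weights.sum()
    out = tree.copy()
    key_to_weight = {
        fit.model.tree.clade_key(b): w
        for b, w in zip(fit.model.branch_nodes, weights)
    }
    for branch in out.branches():
        branch.length = key_to_weight[out.clade_key(branch)] * scale
    return out


@dataclass
class BrownianMotionResults:
    """Single-rate Brownian-motion fit: ML σ², root state, GLS ancestry."""

    model: "BrownianMotionModel"
    sigma2: float
    root_state: float
    loglik: float

    @property
    def aic(self) -> float:
        return 2 * 2 - 2 * self.loglik  # root + sigma2

    def ancestral_states(self) -> dict[str, float]:
        tree = self.model.tree
        return {
            tree.clade_key(node): val for node, val in self.node_states().items()
        }

    def node_states(self) -> dict[TreeNode, float]:
        """GLS/ML reconstruction: conditional mean of each internal node."""
        tree = self.model.tree
        tips = tree.tips()
        depth = tree.depths()
        C = _phylo_cov(tree)
        n = len(tips)
        jitter = 1e-10 * np.trace(C) / n
        factor = cho_factor(C + jitter * np.eye(n))
        resid = self.model.y - self.root_state
        alpha = cho_solve(factor, resid)

        tipsets = {node: tree._tipset(node) for node in tree.nodes()}
        states: dict[TreeNode, float] = {}
        for node in tree.nodes():
            if node.is_leaf():
                states[node] = float(
                    self.model.y[self.model.tip_names.index(node.name)]
                )
                continue
            # covariance of node with each tip: depth of their common ancestor
            cov = np.empty(n)
            for i, tip in enumerate(tips):
                if tip.name in tipsets[node]:
                    cov[i] = depth[node]
                else:
                    anc = node
                    while tip.name not in tipsets[anc]:
                        anc = anc.parent
                    cov[i] = depth[anc]
            states[node] = self.root_state + float(cov @ alpha)
        return states

    def summary(self) -> str:
        return "\n".join(
            [
                "Brownian-motion trait model (single rate)",
                f"  trait:      {self.model.trait_name}",
                f"  n tips:     {len(self.model.y)}",
                f"  sigma^2:    {self.sigma2:.6g} per Myr",
                f"  root state: {self.root_state:.6g}",
                f"  logLik:     {self.loglik:.6g}",
                f"  AIC:        {self.aic:.6g}",
            ]
        )


class BrownianMotionModel:
    """ML Brownian motion on a dated tree (the homogeneous-rate baseline)."""

    def __init__(self, tree: DatedTree, tip_values, trait_name: str = "trait"):
        if tree.n_tips < 3:
            raise ValueError("at least 3 tips are required")
        self.tree = tree
        self.trait_name = trait_name
        self.tip_names, self.y = _tip_vector(tree, tip_values)
        depths = tree.depths()
        if any(depths[t] <= 0 for t in tree.tips()):
            raise ValueError("zero root-to-tip path length; invalid branch lengths")

    def fit(self) -> BrownianMotionResults:
        C = _phylo_cov(self.tree)
        n = len(self.y)
        jitter = 1e-10 * np.trace(C) / n
        factor = cho_factor(C + jitter * np.eye(n))
        ones = np.ones(n)
        w = cho_solve(factor, ones)
        root = float(w @ self.y / (w @ ones))
        resid = self.y - root
        quad = float(resid @ cho_solve(factor, resid))
        sigma2 = quad / n
        logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return BrownianMotionResults(
            model=self, sigma2=sigma2, root_state=root, loglik=loglik
        )
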