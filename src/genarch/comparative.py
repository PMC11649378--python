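"""Phylogenetic comparative inference: PGLS, AIC comparison, phylo-ANOVA.

PGLS is generalized least squares whose error covariance is the
Brownian-motion phylogenetic covariance of the working tree — either the
dated tree (a homogeneous-rate assumption) or a rate-rescaled tree, which
lets a rate-heterogeneous evolutionary model propagate into the regression.
Model support comes with ML log-likelihoods so that AIC comparisons across
working trees are well defined.  The phylogenetic ANOVA obtains its null
F-distribution by simulating Brownian traits on the working tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

from .ridge import phylo_covariance_matrix
from .tree import DatedTree

__all__ = [
    "phylo_covariance",
    "PGLS",
    "PGLSResults",
    "compare_models",
    "PhylogeneticANOVA",
    "AnovaResult",
    "fdr_adjust",
]


def phylo_covariance(tree: DatedTree) -> pd.DataFrame:
    """Tip × tip BM covariance (shared root-to-MRCA path length), labeled."""
    names = tree.tip_names()
    return pd.DataFrame(phylo_covariance_matrix(tree), index=names, columns=names)


def _prepare_cov(C: np.ndarray) -> tuple[np.ndarray, float]:
    n = C.shape[0]
    jitter = 1e-10 * np.trace(C) / n
    factor = cho_factor(C + jitter * np.eye(n), lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return factor, logdet


class PGLS:
    """Phylogenetic generalized least squares regression.

    Parameters
    ----------
    y:
        Response values aligned to ``exog`` rows.
    exog:
        Design matrix *including* an intercept column (DataFrame or array).
    tree / cov:
        Working tree (BM covariance is derived from it) or an explicit
        covariance matrix; exactly one must be supplied.  Rows must be
        aligned to the tree's tip order when a tree is given.
    """

    def __init__(self, y, exog, tree: DatedTree | None = None,
                 cov: np.ndarray | None = None, names: list[str] | None = None):
        if (tree is None) == (cov is None):
            raise ValueError("supply exactly one of tree or cov")
        if isinstance(exog, pd.DataFrame):
            names = names or list(exog.columns)
            exog = exog.to_numpy(float)
        self.exog = np.asarray(exog, float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.names = names or [f"x{j}" for j in range(self.exog.shape[1])]
        self.y = np.asarray(y, float).ravel()
        if tree is not None:
            cov = phylo_covariance_matrix(tree)
        self.C = np.asarray(cov, float)
        if self.C.shape != (len(self.y), len(self.y)):
            raise ValueError("covariance shape does not match response length")
        if self.exog.shape[0] != len(self.y):
            raise ValueError("design and response lengths differ")
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            from scipy.linalg import qr  # name offenders via pivoted QR

            _, _, piv = qr(self.exog, pivoting=True)
            bad = sorted(self.names[j] for j in piv[rank:])
            raise ValueError(f"collinear predictor columns: {bad}")

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame,
                     tree: DatedTree | None = None,
                     cov: np.ndarray | None = None) -> "PGLS":
        """Build from a patsy formula, e.g. ``"y ~ x1 + x2 + x1:x2"``.

        When a tree is given, ``data`` must be indexed by tip label; rows
        are reordered to the tree's tip order.
        """
        if tree is not None:
            data = data.loc[tree.tip_names()]
        ymat, xmat = patsy.dmatrices(formula, data, return_type="dataframe")
        return cls(ymat.iloc[:, 0].to_numpy(), xmat, tree=tree, cov=cov)

    def fit(self) -> "PGLSResults":
        factor, logdet = _prepare_cov(self.C)
        n, p = self.exog.shape
        Cinv_X = cho_solve(factor, self.exog)
        Cinv_y = cho_solve(factor, self.y)
        XtCX = self.exog.T @ Cinv_X
        beta = np.linalg.solve(XtCX, self.exog.T @ Cinv_y)
        resid = self.y - self.exog @ beta
        rss = float(resid @ cho_solve(factor, resid))
        sigma2 = rss / n  # ML
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

        bcov = sigma2 * np.linalg.inv(XtCX)
        bse = np.sqrt(np.diag(bcov))
        tvals = beta / bse
        pvals = 2 * stats.t.sf(np.abs(tvals), df=max(n - p, 1))

        # null (GLS intercept-only) RSS for R^2
        ones = np.ones(n)
        w = cho_solve(factor, ones)
        mu = float((w @ self.y) / (w @ ones))
        resid0 = self.y - mu
        rss0 = float(resid0 @ cho_solve(factor, resid0))
        r2 = 1.0 - rss / rss0 if rss0 > 0 else np.nan
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan

        return PGLSResults(
            model=self,
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(bse, index=self.names),
            tvalues=pd.Series(tvals, index=self.names),
            pvalues=pd.Series(pvals, index=self.names),
            sigma2=sigma2,
            llf=loglik,
            rsquared=r2,
            rsquared_adj=adj,
            nobs=n,
            df_model=p,
        )


@dataclass
class PGLSResults:
    model: PGLS
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    llf: float
    rsquared: float
    rsquared_adj: float
    nobs: int
    df_model: int

    @property
    def k_params(self) -> int:
        return self.df_model + 1  # coefficients + sigma^2

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    def summary(self) -> str:
        rows = [
            "Phylogenetic GLS regression (BM covariance on working tree)",
            f"  n = {self.nobs}, k = {self.k_params}, "
            f"logLik = {self.llf:.4g}, AIC = {self.aic:.4g}",
            f"  R2 = {self.rsquared:.4g}, adjusted R2 = {self.rsquared_adj:.4g}",
            f"  {'term':<20}{'coef':>12}{'se':>12}{'t':>10}{'P>|t|':>12}",
        ]
        for name in self.params.index:
            rows.append(
                f"  {name:<20}{self.params[name]:>12.5g}{self.bse[name]:>12.5g}"
                f"{self.tvalues[name]:>10.3f}{self.pvalues[name]:>12.3g}"
            )
        return "\n".join(rows)


@dataclass
class ModelComparison:
    delta_aic: float
    preferred: str


def compare_models(fit_a: PGLSResults, fit_b: PGLSResults,
                   label_a: str = "a", label_b: str = "b") -> ModelComparison:
    """AIC comparison of two fits of the same response; lower AIC wins."""
    if fit_a.nobs != fit_b.nobs:
        raise ValueError("fits have different numbers of observations")
    delta = fit_a.aic - fit_b.aic
    return ModelComparison(
        delta_aic=delta, preferred=label_b if delta > 0 else label_a
    )


@dataclass
class AnovaResult:
    F_obs: float
    p_sim: float
    n_sims: int
    groups: list[str]
    seed: int | None
    group_means: pd.Series = field(default=None)

    def summary(self) -> str:
        return (
            "Phylogenetic ANOVA (BM simulation null on working tree)\n"
            f"  groups: {', '.join(self.groups)}\n"
            f"  F = {self.F_obs:.4g}, P = {self.p_sim:.4g} "
            f"({self.n_sims} simulations)"
        )


class PhylogeneticANOVA:
    """One-way ANOVA with a Brownian-motion simulation null.

    The observed F statistic is compared with F statistics from traits
    simulated under BM on the working tree, with σ² and root estimated from
    the data; the p-value uses the add-one correction
    ``p = (1 + #{F_sim ≥ F_obs}) / (1 + n_sims)``.
    """

    def __init__(self, y, groups, tree: DatedTree):
        names = tree.tip_names()
        if isinstance(y, pd.Series):
            y = y.loc[names]
        if isinstance(groups, (pd.Series, dict)):
            groups = pd.Series(groups).loc[names]
        self.y = np.asarray(y, float)
        self.groups = np.asarray(groups)
        self.tree = tree
        labels, counts = np.unique(self.groups, return_counts=True)
        if len(labels) < 2 or np.any(counts < 2):
            raise ValueError("need at least 2 groups with at least 2 tips each")
        self.labels = [str(l) for l in labels]

    @staticmethod
    def _f_stat(Y: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
        """Vectorized one-way F over columns of Y (each column one dataset)."""
        Y = np.atleast_2d(Y.T).T  # ensure (n, m)
        n, m = Y.shape
        grand = Y.mean(axis=0)
        ss_between = np.zeros(m)
        ss_within = np.zeros(m)
        for g in range(n_groups):
            mask = codes == g
            ng = mask.sum()
            gm = Y[mask].mean(axis=0)
            ss_between += ng * (gm - grand) ** 2
            ss_within += ((Y[mask] - gm) ** 2).sum(axis=0)
        df1 = n_groups - 1
        df2 = n - n_groups
        return (ss_between / df1) / (ss_within / df2)

    def fit(self, n_sims: int = 1000,
            rng: np.random.Generator | int | None = None) -> AnovaResult:
        if n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        seed = rng if isinstance(rng, int) else None
        rng = np.random.default_rng(rng)
        codes = np.searchsorted(np.array(self.labels), self.groups.astype(str))
        n_groups = len(self.labels)
        F_obs = float(self._f_stat(self.y[:, None], codes, n_groups)[0])

        C = phylo_covariance_matrix(self.tree)
        n = len(self.y)
        factor, _ = _prepare_cov(C)
        ones = np.ones(n)
        w = cho_solve(factor, ones)
        root = float(w @ self.y / (w @ ones))
        resid = self.y - root
        sigma2 = float(resid @ cho_solve(factor, resid)) / n

        L = np.linalg.cholesky(C + 1e-10 * np.trace(C) / n * np.eye(n))
        Z = rng.standard_normal((n, n_sims))
        sims = root + np.sqrt(sigma2) * (L @ Z)
        F_sim = self._f_stat(sims, codes, n_groups)
        p = (1 + int(np.sum(F_sim >= F_obs))) / (1 + n_sims)
        means = pd.Series(
            [self.y[self.groups.astype(str) == l].mean() for l in self.labels],
            index=self.labels,
        )
        return AnovaResult(
            F_obs=F_obs, p_sim=p, n_sims=n_sims,
            groups=self.labels, seed=seed, group_means=means,
        )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
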