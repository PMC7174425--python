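"""Phylogenetic comparative machinery.

Tree-derived quantities used downstream of the feature suite:

* the cophenetic (patristic) distance matrix and the Brownian-motion
  covariance matrix (shared root-to-MRCA path lengths) of a species tree;
* principal-component decomposition of species x species matrices with
  broken-stick component selection;
* Pagel's lambda — maximum-likelihood phylogenetic signal of a trait under
  the Brownian model whose off-diagonal covariances are scaled by lambda;
* phylogenetic generalized least squares (PGLS) with lambda estimated
  jointly by ML, and whitened-space partial R^2 per covariate.

Both estimators follow the statsmodels convention: a model object built
from data whose ``fit()`` returns a results object with a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .errors import TreeError

__all__ = [
    "load_tree",
    "tree_from_string",
    "cophenetic_matrix",
    "phylo_covariance",
    "pc_decompose",
    "broken_stick_select",
    "lambda_transform",
    "PagelsLambda",
    "PagelsLambdaResults",
    "PGLS",
    "PGLSResults",
    "PCDecomposition",
]

_LOG2PI = math.log(2.0 * math.pi)


def load_tree(path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip labels")
    return labels


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic distances: sum of branch lengths on the tip-to-tip path."""
    labels = _tip_labels(tree)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise TreeError("tree has an edge without a branch length")
    pdm = tree.phylogenetic_distance_matrix()
    idx = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(idx[a], idx[labels[j]])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def phylo_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian covariance C[i, j] = shared root-to-MRCA path length.

    Diagonal entries are root-to-tip distances. Constructed in one postorder
    sweep: each edge of length L adds L to C[i, j] for every tip pair (i, j)
    in its subtree.
    """
    labels = _tip_labels(tree)
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = np.array([pos[node.taxon.label]])
        else:
            tips_below[node] = np.concatenate([tips_below[ch] for ch in node.child_nodes()])
        if node is not tree.seed_node:
            L = node.edge.length
            if L is None:
                raise TreeError("tree has an edge without a branch length")
            idx = tips_below[node]
            C[np.ix_(idx, idx)] += L
    return pd.DataFrame(C, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# PCA with broken-stick selection


@dataclass
class PCDecomposition:
    """Principal-component scores of a species-level matrix."""

    scores: pd.DataFrame
    explained_fraction: np.ndarray
    n_retained: int
    selection: str

    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_retained]


def pc_decompose(
    x: pd.DataFrame,
    scale_columns: bool = True,
    selection: str = "broken_stick",
    n_components: int | None = None,
) -> PCDecomposition:
    """Centered (and by default column-standardized) PCA of a numeric matrix.

    Column standardization mirrors the default of correlation-based PCA
    software; constant columns are dropped with a warning since they carry
    no variance. ``selection`` is ``"broken_stick"`` or ``"fixed"`` (then
    ``n_components`` is required).
    """
    X = x.astype(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    std = X.std(axis=0, ddof=1)
    constant = std[std == 0].index
    if len(constant):
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d constant column(s) before PCA", len(constant)
        )
        X = X.drop(columns=constant)
        std = std.drop(constant)
    V = X - X.mean(axis=0)
    if scale_columns:
        V = V / std
    U, s, _ = np.linalg.svd(V.to_numpy(), full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    scores = U * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=X.index, columns=cols)
    if selection == "broken_stick":
        n_ret = broken_stick_select(frac)
    elif selection == "fixed":
        if n_components is None:
            raise ValueError("fixed selection needs n_components")
        n_ret = min(n_components, scores.shape[1])
    else:
        raise ValueError(f"unknown selection {selection!r}")
    return PCDecomposition(scores_df, frac, n_ret, selection)


def broken_stick_select(explained) -> int:
    """Number of leading components whose variance fraction beats the
    broken-stick null ``b_k = (1/p) * sum_{i=k..p} 1/i`` (strict >),
    stopping at the first failure."""
    f = np.asarray(explained, dtype=float)
    p = len(f)
    if p == 0:
        return 0
    tail = np.cumsum(1.0 / np.arange(p, 0, -1))[::-1]  # sum_{i=k..p} 1/i
    b = tail / p
    n = 0
    for fk, bk in zip(f, b):
        if fk > bk:
            n += 1
        else:
            break
    return n


# ---------------------------------------------------------------------------
# Pagel's lambda


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal phylogenetic covariances by lambda."""
    C = np.asarray(C, dtype=float)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _lambda_max(C: np.ndarray, cap: float = 10.0) -> float:
    """Largest lambda keeping the transformed covariance positive definite
    (at least 1)."""

    def pd_ok(lam: float) -> bool:
        try:
            np.linalg.cholesky(lambda_transform(C, lam))
            return True
        except np.linalg.LinAlgError:
            return False

    if not pd_ok(1.0):
        return 1.0
    lo, hi = 1.0, cap
    if pd_ok(hi):
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pd_ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _profile_loglik(C: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float, float]:
    """Profile log-likelihood of lambda under the Brownian MVN model.

    mu and sigma^2 are profiled analytically:
    ``mu = (1'V^-1 y)/(1'V^-1 1)``, ``sigma2 = r'V^-1 r / n``.
    Returns (loglik, mu, sigma2).
    """
    n = len(y)
    V = lambda_transform(C, lam)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    ones = np.ones(n)
    Li_y = scipy.linalg.solve_triangular(L, y, lower=True)
    Li_1 = scipy.linalg.solve_triangular(L, ones, lower=True)
    mu = float(Li_1 @ Li_y / (Li_1 @ Li_1))
    r = Li_y - mu * Li_1
    q = float(r @ r)
    if q <= 0:
        return -np.inf, mu, 0.0
    sigma2 = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + logdet + n)
    return ll, mu, sigma2


@dataclass
class PagelsLambdaResults:
    """ML estimate of Pagel's lambda with profile-likelihood CI."""

    lambda_: float
    sigma2: float
    mu: float
    loglik: float
    loglik_lambda0: float
    ci95: tuple[float, float]
    p_vs_zero: float
    lambda_max: float
    degenerate: bool = False
    n: int = 0

    @property
    def lr_stat(self) -> float:
        return 2.0 * (self.loglik - self.loglik_lambda0)

    def summary(self) -> str:
        lo, hi = self.ci95
        lines = [
            "Pagel's lambda (ML)",
            f"  n tips        {self.n}",
            f"  lambda        {self.lambda_:.4f}  (95% CI {lo:.4f}-{hi:.4f})",
            f"  sigma^2       {self.sigma2:.6g}",
            f"  mu            {self.mu:.6g}",
            f"  logLik        {self.loglik:.4f}",
            f"  LR vs lambda=0  {self.lr_stat:.4f}  (p = {self.p_vs_zero:.3g})",
        ]
        if self.degenerate:
            lines.append("  note: likelihood flat in lambda (degenerate CI)")
        return "\n".join(lines)


class PagelsLambda:
    """ML phylogenetic-signal model for one continuous trait.

    The trait is modelled as multivariate normal with mean ``mu`` and
    covariance ``sigma^2 * V(lambda)`` where ``V(lambda)`` is the Brownian
    tree covariance with off-diagonals scaled by lambda. ``fit()`` maximizes
    the likelihood over ``lambda in [0, lambda_max]`` (lambda_max being the
    largest value keeping V positive definite, at least 1), with ``mu`` and
    ``sigma^2`` profiled analytically.
    """

    def __init__(self, tree_or_cov, trait: pd.Series):
        C = tree_or_cov if isinstance(tree_or_cov, pd.DataFrame) else phylo_covariance(tree_or_cov)
        trait = pd.Series(trait).astype(float)
        missing = [t for t in C.index if t not in trait.index]
        if missing:
            raise ValueError(f"trait missing for tip(s): {missing[:5]}")
        self.labels = list(C.index)
        self.C = C.to_numpy(dtype=float)
        self.y = trait.reindex(self.labels).to_numpy(dtype=float)
        if np.isnan(self.y).any():
            raise ValueError("trait contains NaN")

    def loglik(self, lam: float) -> float:
        return _profile_loglik(self.C, self.y, lam)[0]

    def fit(self, n_restarts: int = 10, tol: float = 1e-8) -> PagelsLambdaResults:
        lam_max = _lambda_max(self.C)
        grid = np.linspace(0.0, lam_max, n_restarts + 1)
        lls = np.array([self.loglik(l) for l in grid])
        degenerate = bool(np.ptp(lls[np.isfinite(lls)]) < 1e-10) if np.isfinite(lls).any() else True
        best_lam, best_ll = float(grid[np.argmax(lls)]), float(np.max(lls))
        if not degenerate:
            i = int(np.argmax(lls))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            res = scipy.optimize.minimize_scalar(
                lambda l: -self.loglik(l), bounds=(lo, hi), method="bounded",
                options={"xatol": tol},
            )
            if -res.fun >= best_ll:
                best_lam, best_ll = float(res.x), float(-res.fun)
        _, mu, sigma2 = _profile_loglik(self.C, self.y, best_lam)
        ll0 = self.loglik(0.0)
        lr = max(0.0, 2.0 * (best_ll - ll0))
        p0 = float(scipy.stats.chi2.sf(lr, df=1))
        ci = self._profile_ci(best_lam, best_ll, lam_max) if not degenerate else (0.0, lam_max)
        return PagelsLambdaResults(
            lambda_=best_lam, sigma2=sigma2, mu=mu, loglik=best_ll,
            loglik_lambda0=ll0, ci95=ci, p_vs_zero=p0, lambda_max=lam_max,
            degenerate=degenerate, n=len(self.y),
        )

    def _profile_ci(self, lam_hat: float, ll_hat: float, lam_max: float) -> tuple[float, float]:
        cut = ll_hat - 0.5 * scipy.stats.chi2.ppf(0.95, df=1)

        def g(l: float) -> float:
            return self.loglik(l) - cut

        lo = 0.0
        if g(0.0) < 0 and lam_hat > 0:
            lo = float(scipy.optimize.brentq(g, 0.0, lam_hat, xtol=1e-8))
        hi = lam_max
        if g(lam_max) < 0 and lam_hat < lam_max:
            hi = float(scipy.optimize.brentq(g, lam_hat, lam_max, xtol=1e-8))
        return lo, hi


def pagels_lambda(tree_or_cov, trait: pd.Series, **fit_kwargs) -> PagelsLambdaResults:
    """Convenience wrapper: ``PagelsLambda(tree, trait).fit()``."""
    return PagelsLambda(tree_or_cov, trait).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PGLSResults:
    """PGLS coefficient estimates with per-covariate partial R^2."""

    params: pd.Series
    bse: pd.Series
    lambda_: float
    sigma2: float
    loglik: float
    partial_r2: pd.Series
    residual_df: int
    n: int

    def summary(self) -> str:
        lines = [
            "Phylogenetic generalized least squares",
            f"  n = {self.n}, residual df = {self.residual_df}, "
            f"lambda = {self.lambda_:.4f}, sigma^2 = {self.sigma2:.6g}",
            f"  logLik = {self.loglik:.4f}",
            f"  {'term':<20}{'coef':>12}{'se':>12}{'partial R2':>12}",
        ]
        for name in self.params.index:
            pr2 = self.partial_r2.get(name, float("nan"))
            pr2_s = f"{pr2:>12.4f}" if np.isfinite(pr2) else f"{'':>12}"
            lines.append(f"  {name:<20}{self.params[name]:>12.4g}{self.bse[name]:>12.4g}{pr2_s}")
        return "\n".join(lines)


class PGLS:
    """Phylogenetic generalized least squares regression.

    ``y = X b + e`` with ``e ~ N(0, sigma^2 V(lambda))``; lambda is
    estimated by ML jointly with the coefficients (profiled GLS) unless
    fixed. Partial R^2 of covariate j is
    ``(SSE_reduced(j) - SSE_full) / SSE_reduced(j)`` computed in the
    V(lambda)-whitened space.
    """

    def __init__(self, tree_or_cov, y: pd.Series, X: pd.DataFrame, add_intercept: bool = True):
        C = tree_or_cov if isinstance(tree_or_cov, pd.DataFrame) else phylo_covariance(tree_or_cov)
        self.labels = list(C.index)
        self.C = C.to_numpy(dtype=float)
        self.y = pd.Series(y).astype(float).reindex(self.labels).to_numpy()
        X = pd.DataFrame(X).astype(float).reindex(self.labels)
        if add_intercept and "Intercept" not in X.columns:
            X.insert(0, "Intercept", 1.0)
        if np.isnan(self.y).any() or X.isna().to_numpy().any():
            raise ValueError("y and X must be complete for every tip")
        self.X = X
        self._check_rank()

    def _check_rank(self):
        A = self.X.to_numpy()
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            # name columns not pivotal in a QR factorization
            _, _, piv = scipy.linalg.qr(A, pivoting=True)
            dependent = sorted(self.X.columns[i] for i in piv[rank:])
            raise ValueError(f"design matrix is rank deficient; dependent column(s): {dependent}")

    def _gls(self, lam: float):
        V = lambda_transform(self.C, lam)
        L = np.linalg.cholesky(V)
        yw = scipy.linalg.solve_triangular(L, self.y, lower=True)
        Xw = scipy.linalg.solve_triangular(L, self.X.to_numpy(), lower=True)
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        sse = float(resid @ resid)
        n = len(yw)
        sigma2 = sse / n
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * (n * _LOG2PI + n * math.log(max(sigma2, 1e-300)) + logdet + n)
        return beta, sse, sigma2, ll, (L, Xw, yw)

    def loglik(self, lam: float) -> float:
        try:
            return self._gls(lam)[3]
        except np.linalg.LinAlgError:
            return -np.inf

    def fit(self, lambda_: float | str = "ml", n_restarts: int = 10) -> PGLSResults:
        lam_max = _lambda_max(self.C)
        if lambda_ == "ml":
            grid = np.linspace(0.0, lam_max, n_restarts + 1)
            lls = np.array([self.loglik(l) for l in grid])
            i = int(np.argmax(lls))
            lam_hat, ll_hat = float(grid[i]), float(lls[i])
            if np.ptp(lls[np.isfinite(lls)]) > 1e-10:
                res = scipy.optimize.minimize_scalar(
                    lambda l: -self.loglik(l),
                    bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
                    method="bounded", options={"xatol": 1e-8},
                )
                if -res.fun >= ll_hat:
                    lam_hat, ll_hat = float(res.x), float(-res.fun)
        else:
            lam_hat = float(lambda_)
            ll_hat = self.loglik(lam_hat)
        beta, sse_full, sigma2, ll, (L, Xw, yw) = self._gls(lam_hat)
        n, p = Xw.shape
        df = n - p
        s2_unbiased = sse_full / df if df > 0 else np.nan
        XtX_inv = np.linalg.pinv(Xw.T @ Xw)
        bse = np.sqrt(np.maximum(np.diag(XtX_inv) * s2_unbiased, 0.0))
        partial = {}
        for j, name in enumerate(self.X.columns):
            if name == "Intercept":
                continue
            keep = [k for k in range(p) if k != j]
            beta_r, _, _, _ = np.linalg.lstsq(Xw[:, keep], yw, rcond=None)
            resid_r = yw - Xw[:, keep] @ beta_r
            sse_r = float(resid_r @ resid_r)
            partial[name] = 0.0 if sse_r == 0 else (sse_r - sse_full) / sse_r
        return PGLSResults(
            params=pd.Series(beta, index=self.X.columns),
            bse=pd.Series(bse, index=self.X.columns),
            lambda_=lam_hat,
            sigma2=sigma2,
            loglik=ll_hat,
            partial_r2=pd.Series(partial),
            residual_df=df,
            n=n,
        )
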