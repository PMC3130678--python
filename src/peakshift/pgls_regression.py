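"""Diet PCA and phylogenetic GLS regression under an OU covariance.

The regression relates shape principal components (responses) to diet
principal components and skull length (predictors) across species, with
phylogenetic non-independence modelled by the Martins-Hansen covariance
V_ij = gamma * exp(-alpha * t_ij), where t_ij is the patristic distance and
alpha the restraining force of stabilizing selection.  alpha is profiled
out by maximum likelihood (gamma concentrates analytically as the GLS
residual variance); coefficients, per-predictor partial correlations,
t-based p-values, per-response generalized R^2, variance inflation factors
and a Wilks-lambda multivariate test are reported on the whitened data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from sklearn.decomposition import PCA

from .errors import CollinearityError
from .phylo import Phylogeny, patristic_distances

__all__ = [
    "DietPCA",
    "OUCovariance",
    "PGLSFit",
    "PGLS",
    "diet_pca",
    "ou_covariance",
    "pgls_fit",
    "vif",
]


# ---------------------------------------------------------------------------
# diet PCA
# ---------------------------------------------------------------------------


@dataclass
class DietPCA:
    scores: pd.DataFrame
    loadings: pd.DataFrame  # variables x components
    eigenvalues: np.ndarray


def diet_pca(diet: pd.DataFrame) -> DietPCA:
    """Correlation-matrix PCA of the diet rank variables.

    Variables are standardized to unit variance, so the eigenvalues sum to
    the number of (retained) variables; zero-variance columns are dropped
    with a warning.  Scores are centred.
    """
    if diet.shape[0] < 2 or diet.shape[1] < 2:
        raise ValueError("diet PCA needs at least 2 species and 2 variables")
    X = diet.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(diet.columns[~keep])
        warnings.warn(f"dropping zero-variance diet variables: {dropped}")
        X = X[:, keep]
    cols = list(diet.columns[keep])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA().fit(Z)
    scores = pca.transform(Z)
    names = [f"dietPC{i + 1}" for i in range(scores.shape[1])]
    return DietPCA(
        scores=pd.DataFrame(scores, index=diet.index, columns=names),
        loadings=pd.DataFrame(pca.components_.T, index=cols, columns=names),
        eigenvalues=pca.explained_variance_,
    )


# ---------------------------------------------------------------------------
# OU covariance
# ---------------------------------------------------------------------------


@dataclass
class OUCovariance:
    """Martins-Hansen interspecific covariance V_ij = gamma*exp(-alpha*t_ij)."""

    alpha: float
    gamma: float
    V: pd.DataFrame


def ou_covariance(tree: Phylogeny, alpha: float, gamma: float = 1.0) -> OUCovariance:
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = patristic_distances(tree)
    V = gamma * np.exp(-alpha * t)
    return OUCovariance(alpha=float(alpha), gamma=float(gamma), V=V)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


@dataclass
class PGLSFit:
    """Per-response coefficient table plus fit-level summaries."""

    coefficients: pd.DataFrame  # predictors x responses
    partial_correlations: pd.DataFrame
    p_values: pd.DataFrame
    r2: pd.Series
    alpha_hat: float
    gamma_hat: pd.Series  # per response
    log_likelihood: float
    vif: pd.Series
    wilks_lambda: float | None = None
    wilks_p: float | None = None

    def table(self) -> pd.DataFrame:
        """Long report: one row per (response, predictor)."""
        rows = []
        for resp in self.coefficients.columns:
            for pred in self.coefficients.index:
                rows.append(
                    {
                        "response": resp,
                        "R2": self.r2[resp],
                        "predictor": pred,
                        "b": self.coefficients.loc[pred, resp],
                        "r": self.partial_correlations.loc[pred, resp],
                        "P": self.p_values.loc[pred, resp],
                    }
                )
        return pd.DataFrame(rows)


class PGLS:
    """Multivariate phylogenetic GLS regression with OU error covariance.

    Parameters
    ----------
    tree:
        The phylogeny supplying patristic distances.
    alpha:
        If given, the OU restraining force is fixed; otherwise it is
        estimated by profile maximum likelihood over ``alpha_bounds``
        (log-scale bounded search), with the equilibrium variance gamma
        concentrated out analytically per response.
    """

    def __init__(self, tree: Phylogeny, alpha: float | None = None,
                 alpha_bounds: tuple[float, float] = (1e-6, 1e3)):
        self.tree = tree
        self.alpha = alpha
        self.alpha_bounds = alpha_bounds

    def get_params(self, deep=True):
        return {"tree": self.tree, "alpha": self.alpha, "alpha_bounds": self.alpha_bounds}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- internals -------------------------------------------------------

    def _whiten(self, alpha, X1, Y, t):
        V0 = np.exp(-alpha * t)
        n = len(V0)
        try:
            L = np.linalg.cholesky(V0)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(V0 + 1e-10 * np.eye(n))
        Xw = solve_triangular(L, X1, lower=True)
        Yw = solve_triangular(L, Y, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return Xw, Yw, logdet

    def _profile_loglik(self, alpha, X1, Y, t):
        Xw, Yw, logdet = self._whiten(alpha, X1, Y, t)
        n, q = Y.shape
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        rss = ((Yw - Xw @ beta) ** 2).sum(axis=0)
        if np.any(rss <= 0):
            return -np.inf
        gamma = rss / n
        # sum over responses of -n/2 log(2 pi gamma_r) - logdet/2 - n/2
        ll = -0.5 * (n * np.log(2 * np.pi * gamma) + logdet + n).sum()
        return float(ll)

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame):
        X = X.to_frame() if isinstance(X, pd.Series) else X
        Y = Y.to_frame() if isinstance(Y, pd.Series) else Y
        order = self.tree.tip_labels
        X = X.loc[order]
        Y = Y.loc[order]
        n, m = X.shape
        q = Y.shape[1]
        if m + 1 >= n:
            raise ValueError("need n > m + 1 species for the regression")
        t = patristic_distances(self.tree).to_numpy()
        X1 = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        Ym = Y.to_numpy(dtype=float)

        self._check_collinearity(X)

        if self.alpha is not None:
            alpha_hat = float(self.alpha)
        else:
            lo, hi = self.alpha_bounds
            res = minimize_scalar(
                lambda la: -self._profile_loglik(np.exp(la), X1, Ym, t),
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            cands = [np.exp(res.x), lo, hi]
            lls = [self._profile_loglik(a, X1, Ym, t) for a in cands]
            alpha_hat = float(cands[int(np.argmax(lls))])

        Xw, Yw, logdet = self._whiten(alpha_hat, X1, Ym, t)
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        resid = Yw - Xw @ beta
        rss = (resid**2).sum(axis=0)
        df = n - m - 1
        sigma2 = rss / df
        XtXinv = np.linalg.pinv(Xw.T @ Xw)
        se = np.sqrt(np.outer(np.diag(XtXinv), sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        partial = tstat / np.sqrt(tstat**2 + df)

        # intercept-only whitened fit for TSS
        ones_w = Xw[:, :1]
        b0, *_ = np.linalg.lstsq(ones_w, Yw, rcond=None)
        tss = ((Yw - ones_w @ b0) ** 2).sum(axis=0)
        r2 = 1.0 - rss / np.where(tss > 0, tss, np.nan)

        gamma = rss / n
        ll = float(np.sum(-0.5 * (n * np.log(2 * np.pi * gamma) + logdet + n)))

        # Wilks' lambda for the predictors jointly (Rao's F approximation)
        wl = wp = None
        if q >= 1 and m >= 1:
            E = resid.T @ resid
            E0 = (Yw - ones_w @ b0).T @ (Yw - ones_w @ b0)
            H = E0 - E
            det_E = np.linalg.det(E)
            det_EH = np.linalg.det(E + H)
            if det_EH > 0 and det_E > 0:
                wl = det_E / det_EH
                wp = _rao_f_pvalue(wl, q, m, n - m - 1)

        pred_names = ["intercept"] + list(X.columns)
        self.alpha_ = alpha_hat
        self.gamma_ = pd.Series(gamma, index=Y.columns, name="gamma")
        self.coef_ = pd.DataFrame(beta, index=pred_names, columns=Y.columns)
        self.partial_corr_ = pd.DataFrame(partial[1:], index=list(X.columns), columns=Y.columns)
        self.pvalues_ = pd.DataFrame(pvals[1:], index=list(X.columns), columns=Y.columns)
        self.r2_ = pd.Series(r2, index=Y.columns, name="R2")
        self.loglik_ = ll
        self.wilks_lambda_ = wl
        self.wilks_p_ = wp
        self.vif_ = (
            vif(X, np.exp(-alpha_hat * t)) if m >= 2 else pd.Series(np.ones(m), index=X.columns)
        )
        return self

    def _check_collinearity(self, X: pd.DataFrame) -> None:
        Xc = X.to_numpy(dtype=float)
        Xc = Xc - Xc.mean(axis=0)
        sd = Xc.std(axis=0)
        if np.any(sd == 0):
            bad = list(X.columns[sd == 0])
            raise CollinearityError(f"constant predictor columns: {bad}", bad)
        R = np.corrcoef(Xc, rowvar=False)
        if R.ndim == 2:
            iu = np.triu_indices_from(R, k=1)
            hits = np.flatnonzero(np.abs(R[iu]) > 0.9999)
            if len(hits):
                bad = sorted(
                    {X.columns[iu[0][h]] for h in hits} | {X.columns[iu[1][h]] for h in hits}
                )
                raise CollinearityError(f"collinear predictor columns: {bad}", bad)


def _rao_f_pvalue(wilks: float, q: int, m: int, df_error: int) -> float:
    """Rao's F approximation for Wilks' lambda with q responses, m predictors."""
    if q * m <= 0:
        return np.nan
    t_den = q**2 + m**2 - 5
    s = np.sqrt((q**2 * m**2 - 4) / t_den) if t_den > 0 else 1.0
    df1 = q * m
    df2 = s * (df_error - (q - m + 1) / 2.0) - (q * m - 2) / 2.0
    if df2 <= 0:
        return np.nan
    lam_s = wilks ** (1.0 / s)
    f = (1 - lam_s) / lam_s * df2 / df1
    return float(stats.f.sf(f, df1, df2))


def pgls_fit(responses: pd.DataFrame, predictors: pd.DataFrame, tree: Phylogeny,
             alpha: float | None = None) -> PGLSFit:
    """Fit the multivariate PGLS regression; returns a Table-1-shaped report."""
    model = PGLS(tree, alpha=alpha).fit(predictors, responses)
    return PGLSFit(
        coefficients=model.coef_.iloc[1:],
        partial_correlations=model.partial_corr_,
        p_values=model.pvalues_,
        r2=model.r2_,
        alpha_hat=model.alpha_,
        gamma_hat=model.gamma_,
        log_likelihood=model.loglik_,
        vif=model.vif_,
        wilks_lambda=model.wilks_lambda_,
        wilks_p=model.wilks_p_,
    )


def vif(predictors: pd.DataFrame, V) -> pd.Series:
    """GLS variance inflation factors: VIF_j = 1/(1 - R^2_j) from the GLS
    regression of predictor j on the remaining predictors (with intercept)."""
    X = predictors.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("VIF needs at least 2 predictors")
    V = V.to_numpy() if isinstance(V, pd.DataFrame) else np.asarray(V, float)
    if isinstance(V, np.ndarray) and V.shape != (n, n):
        raise ValueError("V must be n x n")
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    Xw = solve_triangular(L, np.column_stack([np.ones(n), X]), lower=True)
    out = np.empty(m)
    for j in range(m):
        yj = Xw[:, j + 1]
        others = np.delete(Xw, j + 1, axis=1)
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        res = yj - others @ beta
        b0, *_ = np.linalg.lstsq(Xw[:, :1], yj, rcond=None)
        tss = ((yj - Xw[:, :1] @ b0) ** 2).sum()
        r2 = 1.0 - (res**2).sum() / tss if tss > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=predictors.columns, name="VIF")
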