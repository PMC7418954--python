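"""Phylogenetic generalized least squares with Pagel's lambda.

The error covariance of a regression across species is proportional to the
Brownian-motion structure of the phylogeny, optionally shrunk toward a star
phylogeny by Pagel's lambda (off-diagonal multiplier).  Lambda is profiled
by maximum likelihood over [0, 1]; all model comparison uses ML fits
(a REML switch exists for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import Phylogeny, apply_lambda, vcv_bm

__all__ = [
    "GLSFit",
    "loglik_mvn",
    "gls_fit",
    "pgls_lambda",
    "residual_trait",
    "covariate_model",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def loglik_mvn(y: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    """Exact multivariate normal log-density of ``y`` given mean and V."""
    y = np.asarray(y, dtype=float)
    r = y - np.asarray(mean, dtype=float)
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    q = r @ linalg.cho_solve((c, low), r)
    return float(-0.5 * (len(y) * _LOG2PI + logdet + q))


@dataclass
class GLSFit:
    """Result of a (phylogenetic) GLS fit.

    ``sigma2`` is the ML rate estimate e' V^-1 e / n (trait variance per
    unit of the covariance structure's scale); standard errors and
    t-statistics use the unbiased residual variance with n - p degrees of
    freedom, the convention of standard pGLS software.  ``residuals`` are
    on the raw trait scale, in tip order.
    """

    coefficients: pd.Series
    se: pd.Series
    tstats: pd.Series
    pvalues: pd.Series
    sigma2: float
    lam: float | None
    loglik: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    p: int
    reml: bool = False
    lambda_profile: list[tuple[float, float]] = field(default_factory=list, repr=False)

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def whitened_rss(self) -> float:
        return float(self.sigma2 * self.n)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.round(8).to_dict(),
            "se": self.se.round(8).to_dict(),
            "t": self.tstats.round(6).to_dict(),
            "P": self.pvalues.round(8).to_dict(),
            "sigma2": self.sigma2,
            "lambda": self.lam,
            "loglik": self.loglik,
            "n": self.n,
            "p": self.p,
        }


def _as_design(X, names):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def gls_fit(
    y,
    X,
    V,
    names: list[str] | None = None,
    reml: bool = False,
    lam: float | None = None,
) -> GLSFit:
    """Generalized least squares of ``y`` on design ``X`` with covariance V.

    beta = (X' V^-1 X)^-1 X' V^-1 y, computed by Cholesky whitening.  With
    V = I this reduces to OLS.  The log-likelihood is the ML (or REML)
    profile with sigma^2 concentrated out.
    """
    y = np.asarray(y, dtype=float)
    X, names = _as_design(X, names)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    try:
        c, low = linalg.cho_factor(np.asarray(V, dtype=float), lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    L = np.tril(c)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(Xw, rowvar=False)
        bad = [
            f"{names[i]}~{names[j]}"
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999999
        ]
        raise ValueError(f"singular design (collinear columns): {bad or names}")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    fitted = X @ beta
    resid = y - fitted
    ew = yw - Xw @ beta
    rss = float(ew @ ew)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    sigma2_ml = rss / n
    if reml:
        sigma2_like = rss / (n - p)
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        loglik = -0.5 * (
            (n - p) * (_LOG2PI + np.log(sigma2_like) + 1.0) + logdet + logdet_xtx
        )
    else:
        loglik = -0.5 * (n * (_LOG2PI + np.log(sigma2_ml) + 1.0) + logdet)
    s2 = rss / (n - p)  # unbiased, for standard errors
    cov_beta = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    return GLSFit(
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tstats=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=sigma2_ml,
        lam=lam,
        loglik=float(loglik),
        residuals=resid,
        fitted=fitted,
        n=n,
        p=p,
        reml=reml,
    )


def pgls_lambda(
    y,
    X,
    tree: Phylogeny,
    names: list[str] | None = None,
    reml: bool = False,
    tol: float = 1e-6,
) -> GLSFit:
    """pGLS with Pagel's lambda profiled by ML over [0, 1].

    The profile likelihood is maximized by bounded scalar search; the
    endpoint fits at lambda = 0 and 1 are always evaluated so boundary
    optima are found exactly.
    """
    y = np.asarray(y, dtype=float)
    X, names = _as_design(X, names)
    if len(y) != tree.n_tips:
        raise ValueError(f"y has {len(y)} values but tree has {tree.n_tips} tips")
    V0 = vcv_bm(tree)

    def fit_at(lam: float) -> GLSFit:
        return gls_fit(y, X, apply_lambda(V0, lam), names=names, reml=reml, lam=lam)

    def neg_ll(lam: float) -> float:
        return -fit_at(lam).loglik

    res = optimize.minimize_scalar(
        neg_ll, bounds=(0.0, 1.0), method="bounded", options={"xatol": tol}
    )
    candidates = [(0.0, -neg_ll(0.0)), (1.0, -neg_ll(1.0))]
    if res.success:
        candidates.append((float(res.x), -float(res.fun)))
    best_lam, _ = max(candidates, key=lambda t: t[1])
    fit = fit_at(best_lam)
    fit.lambda_profile = [(l, ll) for l, ll in candidates]
    return fit


def design_with_intercept(x, extra: dict[str, np.ndarray] | None = None):
    """[1, x, extra...] design matrix with column names."""
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(x), x]
    names = ["intercept", "x"]
    for k, v in (extra or {}).items():
        cols.append(np.asarray(v, dtype=float))
        names.append(k)
    return np.column_stack(cols), names


def residual_trait(y, x, tree: Phylogeny, reml: bool = False) -> np.ndarray:
    """Raw-scale residuals of the lambda-ML pGLS of y on x, tip-ordered.

    This is the working definition of "relative larynx size": larynx size
    after removing the shared allometry with body size across all species,
    with phylogenetic error structure.
    """
    X, names = design_with_intercept(x)
    fit = pgls_lambda(y, X, tree, names=names, reml=reml)
    return fit.residuals


def covariate_model(
    y,
    x,
    z,
    tree: Phylogeny,
    z_name: str = "z",
    interaction: bool = True,
) -> GLSFit:
    """pGLS of y on x plus a covariate and its interaction with x.

    Rows with a missing covariate are dropped (listwise deletion) and the
    tree is pruned to the retained species; the retained n is reported on
    the fit.  The covariate may be categorical (two levels, coded 0/1) or
    numeric.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = _encode_covariate(z, z_name)
    keep = ~np.isnan(z)
    if keep.sum() < len(z):
        labels = [tree.tip_labels[i] for i in np.where(keep)[0]]
        tree = tree.prune_to(labels)
        order = [labels.index(l) for l in tree.tip_labels]
        idx = np.where(keep)[0][order]
        y, x, z = y[idx], x[idx], z[idx]
    if np.nanstd(z) == 0:
        raise ValueError(f"covariate {z_name!r} is constant after subsetting")
    extra = {z_name: z}
    if interaction:
        extra[f"x:{z_name}"] = x * z
    X, names = design_with_intercept(x, extra)
    return pgls_lambda(y, X, tree, names=names)


def _encode_covariate(z, z_name: str) -> np.ndarray:
    z = pd.Series(z)
    if z.dtype == object or isinstance(z.dtype, pd.CategoricalDtype):
        levels = sorted(set(v for v in z.dropna().unique()))
        if len(levels) != 2:
            raise ValueError(
                f"categorical covariate {z_name!r} must have exactly 2 levels, "
                f"got {levels}"
            )
        return z.map({levels[0]: 0.0, levels[1]: 1.0}).to_numpy(dtype=float)
    return z.to_numpy(dtype=float)
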