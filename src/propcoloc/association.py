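"""Single-SNP association scans and joint multi-SNP regression fits.

These supply the coefficient vectors and covariance matrices ``(b1, V1)`` and
``(b2, V2)`` consumed by the proportionality test.  Quantitative traits are
fit by ordinary least squares; binary traits by logistic regression via
iteratively reweighted least squares (IRLS, tolerance 1e-8, max 50
iterations).  Cohort independence, Cov(b1, b2) = 0, is an assumption of the
downstream test: two case-control studies may only be compared if they do not
share controls, hence :func:`split_controls`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from propcoloc.genotype_data import GenotypeMatrix, TraitVector

logger = logging.getLogger(__name__)

_IRLS_TOL = 1e-8
_IRLS_MAXIT = 50


class FitError(RuntimeError):
    """A regression fit could not be completed."""


@dataclass
class RegressionFit:
    """Joint regression of one trait on q SNPs or components.

    ``b`` and ``V`` exclude the intercept; ``bic = -2*loglik + (q+1)*log(n)``
    counts the intercept as a parameter.
    """

    snp_or_component_ids: list
    b: np.ndarray
    V: np.ndarray
    trait_kind: str
    n: int
    loglik: float
    bic: float
    converged: bool = True

    @property
    def q(self) -> int:
        return len(self.b)


@dataclass
class ScanResult:
    """Per-SNP univariate association results for one cohort."""

    snp_ids: list
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    top_index: int

    @property
    def top_snp(self) -> str:
        return self.snp_ids[self.top_index]


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept prepended; returns beta, cov (unbiased sigma^2), loglik."""
    n, k = X.shape
    Xi = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta
    rss = float(resid @ resid)
    dof = n - (k + 1)
    if dof <= 0:
        raise FitError("not enough samples for the requested design")
    sigma2 = rss / dof
    XtX = Xi.T @ Xi
    cov = sigma2 * np.linalg.inv(XtX)
    sig2_mle = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sig2_mle) + 1.0)
    return beta, cov, loglik


def _irls_logistic(X: np.ndarray, y: np.ndarray):
    """Logistic MLE with intercept prepended; returns beta, cov, loglik, converged."""
    n, k = X.shape
    Xi = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    ybar = np.clip(y.mean(), 1e-10, 1 - 1e-10)
    beta[0] = np.log(ybar / (1 - ybar))
    converged = False
    for _ in range(_IRLS_MAXIT):
        eta = np.clip(Xi @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        XtW = Xi.T * w
        try:
            new = np.linalg.solve(XtW @ Xi, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix in logistic fit") from exc
        step = np.max(np.abs(new - beta))
        beta = new
        if step < _IRLS_TOL:
            converged = True
            break
    eta = np.clip(Xi @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((Xi.T * w) @ Xi)
    loglik = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    return beta, cov, loglik, converged


def _score_test_p(x: np.ndarray, y: np.ndarray) -> float:
    """Univariate logistic score test, used when Wald is unreliable."""
    ybar = y.mean()
    u = float(x @ (y - ybar))
    v = ybar * (1 - ybar) * float(((x - x.mean()) ** 2).sum())
    if v <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / v, 1))


def _design(g, ids):
    """Columns named by ids from a GenotypeMatrix or a (matrix, ids) pair."""
    if isinstance(g, GenotypeMatrix):
        idx = [g.snp_index(i) for i in ids]
        return g.dosages[:, idx]
    X, names = g
    lookup = {n: j for j, n in enumerate(names)}
    return np.asarray(X)[:, [lookup[i] for i in ids]]


def single_snp_scan(g: GenotypeMatrix, y: TraitVector) -> ScanResult:
    """Univariate association of each SNP with the trait (Wald p-values).

    Logistic regression for a binary trait, linear for quantitative, each
    with an intercept.  Monomorphic SNPs get p = 1 with a warning; logistic
    fits showing separation fall back to a score-test p-value.  The most
    associated SNP is the smallest p, ties broken by SNP order.
    """
    if g.missing_mask.any():
        raise ValueError("impute genotypes before scanning")
    if len(y) != g.n_samples:
        raise ValueError("trait length does not match genotype rows")
    n, p = g.dosages.shape
    yv = y.values
    beta = np.zeros(p)
    se = np.full(p, np.inf)
    pval = np.ones(p)
    if y.kind == "quantitative":
        # vectorised simple regression: slope = Sxy/Sxx, SE from residual MS
        X = g.dosages
        xm = X - X.mean(axis=0)
        ym = yv - yv.mean()
        sxx = (xm ** 2).sum(axis=0)
        mono = sxx <= 0
        sxx_safe = np.where(mono, 1.0, sxx)
        slope = (xm * ym[:, None]).sum(axis=0) / sxx_safe
        rss = (ym ** 2).sum() - slope ** 2 * sxx_safe
        sig2 = np.maximum(rss, 0.0) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(sig2 / sxx_safe)
            t = np.where(s > 0, slope / s, np.inf)
        pv = 2 * stats.t.sf(np.abs(t), n - 2)
        beta = np.where(mono, 0.0, slope)
        se = np.where(mono, np.inf, s)
        pval = np.where(mono, 1.0, np.clip(pv, np.finfo(float).tiny, 1.0))
        if mono.any():
            logger.warning("scan: %d monomorphic SNP(s) set to p=1", mono.sum())
    else:
        for j in range(p):
            x = g.dosages[:, j]
            if np.ptp(x) == 0:
                logger.warning("scan: monomorphic SNP %s set to p=1", g.snps[j])
                continue
            try:
                bj, cov, _, conv = _irls_logistic(x[:, None], yv)
            except FitError:
                conv = False
                bj, cov = None, None
            if conv and cov[1, 1] > 0 and abs(bj[1]) < 15:
                beta[j] = bj[1]
                se[j] = np.sqrt(cov[1, 1])
                z = bj[1] / se[j]
                pval[j] = max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny)
            else:
                logger.warning("scan: separation/non-convergence at %s, "
                               "score-test fallback", g.snps[j])
                if bj is not None:
                    beta[j] = bj[1]
                pval[j] = max(_score_test_p(x, yv), np.finfo(float).tiny)
    top = int(np.argmin(pval))  # argmin takes the first minimum: SNP-order ties
    return ScanResult(snp_ids=list(g.snps), beta=beta, se=se, p=pval, top_index=top)


def fit_joint(g, y: TraitVector, ids) -> RegressionFit:
    """Maximum-likelihood multiple regression of the trait on the named columns.

    ``g`` is a :class:`GenotypeMatrix`, or a ``(scores, names)`` pair for
    component scores.  Aliased (rank-deficient) columns are dropped with a
    warning; the returned ``b``/``V`` exclude the intercept.
    """
    ids = list(ids)
    X = _design(g, ids)
    # drop duplicated/aliased columns, keeping first occurrences
    keep: list[int] = []
    for j in range(X.shape[1]):
        cols = keep + [j]
        M = np.column_stack([np.ones(X.shape[0]), X[:, cols]])
        if np.linalg.matrix_rank(M) == len(cols) + 1:
            keep.append(j)
        else:
            logger.warning("fit_joint: dropping aliased column %r", ids[j])
    if not keep:
        raise FitError("design has no informative columns after dropping aliases")
    ids = [ids[j] for j in keep]
    X = X[:, keep]
    n, q = X.shape
    if y.kind == "quantitative":
        beta, cov, loglik = _ols(X, y.values)
        converged = True
    else:
        beta, cov, loglik, converged = _irls_logistic(X, y.values)
        if not converged:
            logger.warning("fit_joint: logistic IRLS did not converge")
    bic = -2.0 * loglik + (q + 1) * np.log(n)
    return RegressionFit(
        snp_or_component_ids=ids,
        b=beta[1:],
        V=cov[1:, 1:],
        trait_kind=y.kind,
        n=n,
        loglik=loglik,
        bic=float(bic),
        converged=converged,
    )


def split_controls(control_ids, seed: int):
    """Randomly partition a shared control set into two halves.

    Two case-control cohorts entering the proportionality test must not share
    controls (the test assumes Cov(b1, b2) = 0); this utility makes the split
    reproducible.
    """
    rng = np.random.default_rng(seed)
    ids = list(control_ids)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    g1 = sorted(ids[i] for i in perm[:half])
    g2 = sorted(ids[i] for i in perm[half:])
    return g1, g2
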