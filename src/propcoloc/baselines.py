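"""Biased comparison methods: conditional testing, the rank score of Nica
et al., and naive SNP-selection strategies for proportional testing.

These are shipped for benchmarking only.  Selecting SNPs by strength of
observed association biases coefficient estimates away from the null
(winner's curse), which inflates the type 1 error of any downstream
colocalisation test.  The unbiased alternatives live in
:mod:`propcoloc.pc_coloc` and :mod:`propcoloc.bma_coloc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import lasso_path

from propcoloc.genotype_data import GenotypeMatrix, TraitVector
from propcoloc.association import fit_joint, single_snp_scan

logger = logging.getLogger(__name__)

_LASSO_SEED = 20130

STRATEGIES = ("top_pair", "lasso_union", "lasso_two_stage")


@dataclass
class NicaScore:
    """Rank of the conditioning SNP's p-value among all per-SNP conditionings.

    A score near 1 says conditioning on k' removes association with k about
    as well as the best SNP in the region — consistent with colocalisation;
    under distinct unlinked causal variants the score is uniform on (0, 1].
    """

    score: float
    p_values: dict
    k: str
    k_prime: str


def conditional_test(g: GenotypeMatrix, y: TraitVector, k: str,
                     k_prime: str) -> float:
    """Wald p-value for SNP k in a regression of y on (k', k).

    Tests H0: y independent of X_k given X_{k'}.  A collinear pair
    (r^2 = 1) leaves the conditional effect undefined; p = 1 is returned
    with a warning.
    """
    if k == k_prime:
        raise ValueError("test SNP and conditioning SNP must differ")
    xk = g.dosages[:, g.snp_index(k)]
    xkp = g.dosages[:, g.snp_index(k_prime)]
    if np.ptp(xk) == 0 or np.ptp(xkp) == 0:
        logger.warning("conditional_test: monomorphic SNP, p=1")
        return 1.0
    r = np.corrcoef(xk, xkp)[0, 1]
    if abs(r) > 1 - 1e-12:
        logger.warning("conditional_test: %s and %s are collinear (r^2=1); "
                       "p undefined, returning 1", k, k_prime)
        return 1.0
    fit = fit_joint(g, y, [k_prime, k])
    if fit.snp_or_component_ids != [k_prime, k]:
        logger.warning("conditional_test: aliased design, returning 1")
        return 1.0
    z = fit.b[1] / np.sqrt(fit.V[1, 1])
    return float(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny))


def nica_score(g: GenotypeMatrix, y: TraitVector, k: str,
               k_prime: str) -> NicaScore:
    """Residual-rank colocalisation score.

    For every SNP j != k, residualise y on X_j and test Spearman correlation
    of the residuals with X_k, giving p-values P_j (j = k' included, j = k
    excluded).  The score is the ascending rank of P_{k'} divided by the
    number of P_j values; it tends to 1 when the traits share a causal
    variant.  Spearman p-values use the large-sample t approximation for
    n >= 50 and an exact permutation distribution below that.
    """
    if k == k_prime:
        raise ValueError("test SNP and conditioning SNP must differ")
    xk = g.dosages[:, g.snp_index(k)]
    n = g.n_samples
    pvals = {}
    for j, snp in enumerate(g.snps):
        if snp == k:
            continue
        xj = g.dosages[:, j]
        X = np.column_stack([np.ones(n), xj])
        beta, *_ = np.linalg.lstsq(X, y.values, rcond=None)
        resid = y.values - X @ beta
        if n < 50:
            rho = stats.spearmanr(resid, xk).statistic
            if not np.isfinite(rho):
                p = 1.0
            else:
                rng = np.random.default_rng(_LASSO_SEED)
                null = np.array([
                    stats.spearmanr(rng.permutation(resid), xk).statistic
                    for _ in range(2000)
                ])
                p = (1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / 2001
        else:
            p = stats.spearmanr(resid, xk).pvalue
        pvals[snp] = float(p) if np.isfinite(p) else 1.0
    ordered = sorted(pvals.values())
    rank = int(np.searchsorted(ordered, pvals[k_prime], side="right"))
    score = rank / len(pvals)
    return NicaScore(score=score, p_values=pvals, k=k, k_prime=k_prime)


def _lasso_select(X: np.ndarray, y: np.ndarray, seed: int = _LASSO_SEED):
    """Column indices selected by a 10-fold cross-validated lasso (1-SE rule).

    The trait (binary or quantitative) is fit on the squared-error lasso
    path; the largest penalty whose CV error is within one standard error of
    the minimum picks the active set.
    """
    from sklearn.model_selection import KFold

    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alphas, _, _ = lasso_path(Xc, yc, alphas=50)
    kf = KFold(n_splits=10, shuffle=True, random_state=seed)
    errs = np.zeros((10, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(Xc)):
        _, coefs, _ = lasso_path(Xc[tr], yc[tr], alphas=alphas)
        pred = Xc[te] @ coefs  # (n_te, n_alphas)
        errs[f] = ((pred - yc[te][:, None]) ** 2).mean(axis=0)
    mean_err = errs.mean(axis=0)
    se_err = errs.std(axis=0, ddof=1) / np.sqrt(10)
    best = int(np.argmin(mean_err))
    # 1-SE rule: sparsest model within one SE of the minimum CV error
    ok = np.where(mean_err <= mean_err[best] + se_err[best])[0]
    pick = int(ok[0])  # alphas are descending: first qualifying = largest penalty
    _, coefs, _ = lasso_path(Xc, yc, alphas=alphas)
    return list(np.where(np.abs(coefs[:, pick]) > 1e-10)[0])


def naive_select(g1: GenotypeMatrix, y1: TraitVector,
                 g2: GenotypeMatrix, y2: TraitVector,
                 strategy: str = "top_pair", seed: int = _LASSO_SEED):
    """Trait-driven SNP selection (the biased strategies P1-P3).

    * ``top_pair``: the most-associated SNP from each cohort's scan.
    * ``lasso_union``: union of per-cohort lasso active sets.
    * ``lasso_two_stage``: lasso on cohort 1, then lasso on cohort 2 with
      the cohort-1 SNPs entering unpenalised (via residualisation).

    Selections of fewer than two SNPs fall back to ``top_pair`` (augmented
    with the next-ranked SNP if the two scans agree), with a warning.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    common = [s for s in g1.snps if s in set(g2.snps)]
    gc1 = g1.subset_snps(common)
    gc2 = g2.subset_snps(common)

    def _top_pair():
        s1 = single_snp_scan(gc1, y1)
        s2 = single_snp_scan(gc2, y2)
        sel = {s1.top_snp, s2.top_snp}
        if len(sel) < 2:
            logger.warning("naive_select: both scans pick %s; adding "
                           "next-ranked SNP", s1.top_snp)
            order = np.argsort(s1.p, kind="stable")
            for i in order:
                if s1.snp_ids[i] not in sel:
                    sel.add(s1.snp_ids[i])
                    break
        return sel

    if strategy == "top_pair":
        sel = _top_pair()
    elif strategy == "lasso_union":
        i1 = _lasso_select(gc1.dosages, y1.values, seed)
        i2 = _lasso_select(gc2.dosages, y2.values, seed + 1)
        sel = {common[i] for i in i1} | {common[i] for i in i2}
    else:  # lasso_two_stage
        i1 = _lasso_select(gc1.dosages, y1.values, seed)
        stage1 = [common[i] for i in i1]
        rest = [s for s in common if s not in stage1]
        sel = set(stage1)
        if stage1 and rest:
            # unpenalised stage-1 SNPs: residualise y2 and the remaining SNPs
            idx1 = [common.index(s) for s in stage1]
            B = np.column_stack([np.ones(gc2.n_samples),
                                 gc2.dosages[:, idx1]])
            H, *_ = np.linalg.lstsq(B, y2.values, rcond=None)
            ry = y2.values - B @ H
            idxr = [common.index(s) for s in rest]
            Xr = gc2.dosages[:, idxr]
            G, *_ = np.linalg.lstsq(B, Xr, rcond=None)
            rX = Xr - B @ G
            i2 = _lasso_select(rX, ry, seed + 1)
            sel |= {rest[i] for i in i2}
        elif not stage1:
            i2 = _lasso_select(gc2.dosages, y2.values, seed + 1)
            sel = {common[i] for i in i2}
    if len(sel) < 2:
        logger.warning("naive_select(%s): fewer than 2 SNPs selected, "
                       "falling back to top_pair", strategy)
        sel = _top_pair()
    return sorted(sel)
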