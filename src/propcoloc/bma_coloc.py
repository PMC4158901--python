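"""Bayesian model averaging over small SNP models for colocalisation testing.

Instead of selecting one SNP set (and paying winner's curse), the model is
treated as a nuisance parameter: every unordered subset of 2 (or 3) SNPs is
fitted to both traits, weighted by an approximate posterior probability built
from the Bayesian Information Criterion of the two fits, and the posterior
predictive p-value is the weight-averaged p-value

    ppp = sum_m P*(m) P(m)

with a uniform prior over the model universe.  The eta posterior reported is
the corresponding mixture of per-model theta posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from propcoloc.genotype_data import GenotypeMatrix, TraitVector
from propcoloc.association import FitError, fit_joint
from propcoloc.proportional_core import (
    DEFAULT_N_GRID,
    PropTestResult,
    ThetaPosterior,
    eta_credible_interval,
    make_theta_grid,
    ppp_value,
    profile_test,
    theta_posterior,
)

logger = logging.getLogger(__name__)

DEFAULT_PRUNE_MASS = 0.9999


@dataclass
class ModelSpace:
    """Enumerated SNP subsets with per-trait BICs and posterior weights."""

    models: list                 # tuples of SNP ids, sorted within and across
    size: int
    bic1: np.ndarray = None
    bic2: np.ndarray = None
    posterior: np.ndarray = None
    pruned: np.ndarray = None

    def __len__(self) -> int:
        return len(self.models)

    def retained(self):
        if self.pruned is None:
            return list(range(len(self.models)))
        return [i for i in range(len(self.models)) if not self.pruned[i]]


def enumerate_models(snp_ids, size: int) -> ModelSpace:
    """All unordered SNP subsets of the given size, lexicographic order.

    With p SNPs there are C(p, 2) two-SNP and C(p, 3) three-SNP models —
    e.g. 4,950 and 161,700 respectively for p = 100 — so the model universe
    grows quickly with region density.
    """
    snp_ids = list(snp_ids)
    if size not in (2, 3):
        raise ValueError("model size must be 2 or 3")
    if size > len(snp_ids):
        raise ValueError(f"model size {size} exceeds SNP count {len(snp_ids)}")
    models = [tuple(sorted(m)) for m in combinations(sorted(snp_ids), size)]
    assert len(models) == comb(len(snp_ids), size)
    return ModelSpace(models=models, size=size)


def model_posteriors(space: ModelSpace,
                     g1: GenotypeMatrix, y1: TraitVector,
                     g2: GenotypeMatrix, y2: TraitVector,
                     prune_mass: float = DEFAULT_PRUNE_MASS) -> ModelSpace:
    """BIC-approximated posterior weight of every model, then pruning.

    For model m the joint (both-trait) marginal likelihood is approximated by
    exp(-(BIC1(m) + BIC2(m)) / 2) — a product over the two independent
    cohorts — and normalised under a uniform model prior.  Models are ranked
    by weight and the minimal prefix reaching cumulative mass ``prune_mass``
    is retained; the rest are pruned and the weights renormalised.
    """
    if not 0 < prune_mass <= 1:
        raise ValueError("prune_mass must lie in (0, 1]")
    nm = len(space.models)
    bic1 = np.full(nm, np.nan)
    bic2 = np.full(nm, np.nan)
    failed = np.zeros(nm, dtype=bool)
    fits = []
    for i, m in enumerate(space.models):
        try:
            f1 = fit_joint(g1, y1, m)
            f2 = fit_joint(g2, y2, m)
            if f1.snp_or_component_ids != list(m) or \
               f2.snp_or_component_ids != list(m):
                raise FitError("aliased SNPs within model")
            bic1[i], bic2[i] = f1.bic, f2.bic
            fits.append((f1, f2))
        except (FitError, np.linalg.LinAlgError) as exc:
            logger.warning("model %s pruned: %s", m, exc)
            failed[i] = True
            fits.append(None)
    if failed.all():
        raise FitError("every model failed to fit")
    total = bic1 + bic2
    ok = ~failed
    logw = np.where(ok, -(total - np.nanmin(total[ok])) / 2.0, -np.inf)
    w = np.exp(logw)
    w /= w.sum()
    # retain the minimal top-weight prefix reaching prune_mass
    if prune_mass >= 1.0:
        keep = ok.copy()
    else:
        order = np.argsort(-w, kind="stable")
        cum = np.cumsum(w[order])
        ncut = int(np.searchsorted(cum, prune_mass - 1e-12) + 1)
        keep = np.zeros(nm, dtype=bool)
        keep[order[:ncut]] = True
        keep &= ok
    w2 = np.where(keep, w, 0.0)
    w2 /= w2.sum()
    space.bic1, space.bic2 = bic1, bic2
    space.posterior = w2
    space.pruned = ~keep
    space._fits = fits
    return space


def bma_test(g1: GenotypeMatrix, y1: TraitVector,
             g2: GenotypeMatrix, y2: TraitVector,
             size: int = 2,
             prune_mass: float = DEFAULT_PRUNE_MASS,
             prior_scale: float = 1.0,
             n_grid: int = DEFAULT_N_GRID,
             ci_level: float = 0.95) -> PropTestResult:
    """Model-averaged posterior predictive colocalisation test.

    Every retained model contributes its own ppp (P*(m)) and theta
    posterior; the returned ppp is the posterior-weighted average and the
    returned posterior is the weight-mixture, from which eta-hat (mixture
    mode) and the credible interval are computed.  The profile statistic
    reported is that of the highest-weight model.
    """
    common = [s for s in g1.snps if s in set(g2.snps)]
    space = enumerate_models(common, size)
    space = model_posteriors(space, g1, y1, g2, y2, prune_mass=prune_mass)
    mix = None
    ppp = 0.0
    per_model = np.full(len(space), np.nan)
    for i in space.retained():
        f1, f2 = space._fits[i]
        post = theta_posterior(f1, f2, prior_scale=prior_scale, n_grid=n_grid)
        pstar = ppp_value(post, f1, f2)
        per_model[i] = pstar
        wgt = space.posterior[i]
        ppp += wgt * pstar
        mix = post.density * wgt if mix is None else mix + post.density * wgt
    grid = make_theta_grid(n_grid)
    ref_post = ThetaPosterior(
        grid=grid,
        density=mix / np.trapezoid(mix, grid),
        prior_scale=prior_scale,
    )
    top = int(np.argmax(space.posterior))
    f1t, f2t = space._fits[top]
    eta_top, stat_top, p_top = profile_test(f1t, f2t, n_grid=n_grid)
    lo, hi, has0, has1 = eta_credible_interval(ref_post, ci_level)
    result = PropTestResult(
        eta_hat=float(np.tan(ref_post.mode)),
        stat=stat_top,
        df=size - 1,
        p_profile=p_top,
        ppp=float(np.clip(ppp, 0.0, 1.0)),
        posterior=ref_post,
        eta_ci=(lo, hi),
        ci_level=ci_level,
        contains_zero=has0,
        contains_one=has1,
        extra={
            "model_space": space,
            "per_model_ppp": per_model,
            "top_model": space.models[top],
        },
    )
    return result


def model_table(space: ModelSpace, per_model_ppp=None):
    """Per-model summary rows (SNPs, bic1, bic2, weight, ppp) for output."""
    import pandas as pd

    rows = []
    for i, m in enumerate(space.models):
        rows.append({
            "snps": ",".join(m),
            "bic1": space.bic1[i],
            "bic2": space.bic2[i],
            "weight": space.posterior[i],
            "pruned": bool(space.pruned[i]),
            "ppp": (per_model_ppp[i] if per_model_ppp is not None else np.nan),
        })
    return pd.DataFrame(rows).sort_values("weight", ascending=False,
                                          kind="stable").reset_index(drop=True)
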