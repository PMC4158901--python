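"""Principal-component summarisation of a region and the PC proportionality test.

Variable selection based on trait association biases downstream coefficient
estimates (winner's curse).  Principal components of the *combined* genotype
matrix avoid this: the basis depends only on genotypes, components are
mutually uncorrelated, and both cohorts are projected into the same space
using centering/scaling constants computed on the combined data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from propcoloc.genotype_data import GenotypeMatrix, TraitVector, merge_cohorts
from propcoloc.association import fit_joint
from propcoloc.proportional_core import (
    DEFAULT_N_GRID,
    PropTestResult,
    proportional_test,
)

logger = logging.getLogger(__name__)

DEFAULT_PC_THRESHOLD = 0.90


@dataclass
class PCBasis:
    """Orthonormal SNP-space basis of the centred, scaled combined matrix."""

    loadings: np.ndarray          # n_snps x n_components, orthonormal columns
    variance_fractions: np.ndarray  # descending, sums to 1 over all components
    snp_means: np.ndarray
    snp_scales: np.ndarray
    snp_ids: list

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, g: GenotypeMatrix, components=None) -> np.ndarray:
        """Component scores of a cohort, using the combined-data constants."""
        idx = [g.snp_index(s) for s in self.snp_ids]
        Z = (g.dosages[:, idx] - self.snp_means) / self.snp_scales
        L = self.loadings if components is None else self.loadings[:, components]
        return Z @ L


def build_pc_basis(combined: GenotypeMatrix) -> PCBasis:
    """SVD basis of the centred, unit-variance combined dosage matrix.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so the basis is deterministic.
    """
    if combined.missing_mask.any():
        raise ValueError("impute before building a PC basis")
    X = combined.dosages
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    zero = scales == 0
    if zero.any():
        bad = [combined.snps[j] for j in np.where(zero)[0]]
        raise ValueError(f"zero-variance SNP(s) in combined data: {bad}")
    Z = (X - means) / scales
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt.T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    loadings = loadings * flip
    var = svals ** 2
    fractions = var / var.sum()
    return PCBasis(
        loadings=loadings,
        variance_fractions=fractions,
        snp_means=means,
        snp_scales=scales,
        snp_ids=list(combined.snps),
    )


def select_components(basis: PCBasis, threshold: float = DEFAULT_PC_THRESHOLD):
    """Indices of the smallest leading component set capturing ``threshold``
    of the combined genetic variance."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(basis.variance_fractions)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, basis.n_components)
    return list(range(k))


def pc_test(g1: GenotypeMatrix, y1: TraitVector,
            g2: GenotypeMatrix, y2: TraitVector,
            threshold: float = DEFAULT_PC_THRESHOLD,
            prior_scale: float = 1.0,
            n_grid: int = DEFAULT_N_GRID,
            ci_level: float = 0.95) -> PropTestResult:
    """Proportionality test on the leading principal components.

    Merges the cohorts, builds the combined basis, selects the smallest
    leading component set reaching ``threshold`` of the variance, projects
    each cohort with the combined centering/scaling, fits each trait on its
    cohort's component scores, and runs the proportional test.
    """
    merged, _ = merge_cohorts(g1, g2)
    basis = build_pc_basis(merged)
    comps = select_components(basis, threshold)
    if len(comps) >= min(g1.n_samples, g2.n_samples) / 10:
        logger.warning("pc_test: %d components for cohorts of %d/%d samples "
                       "— overfitting risk", len(comps), g1.n_samples,
                       g2.n_samples)
    names = [f"PC{i + 1}" for i in comps]
    s1 = basis.project(g1, comps)
    s2 = basis.project(g2, comps)
    f1 = fit_joint((s1, names), y1, names)
    f2 = fit_joint((s2, names), y2, names)
    common = [i for i in f1.snp_or_component_ids if i in f2.snp_or_component_ids]
    if common != f1.snp_or_component_ids or common != f2.snp_or_component_ids:
        f1 = fit_joint((s1, names), y1, common)
        f2 = fit_joint((s2, names), y2, common)
    result = proportional_test(f1, f2, prior_scale=prior_scale,
                               n_grid=n_grid, ci_level=ci_level)
    result.n_components = len(common)
    return result
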