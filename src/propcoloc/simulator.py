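"""Synthetic haplotype panels and trait simulation for calibration studies.

The panel generator emulates a phased reference panel over a GWAS-scale
region: a Gaussian copula with within-block autocorrelation ``rho`` is
thresholded at per-SNP quantiles so allele frequencies are uniform between a
minor-allele-frequency floor (default 5%) and 0.5, giving block-structured
LD with realistic r^2 decay.  Case-control cohorts are drawn under a
multiplicative disease model (per-allele relative risk), quantitative traits
with a fixed variance explained per causal variant.  Tag-SNP thinning stands
in for a genotyping array, and panel admixture supports sensitivity analyses
of the equal-LD assumption.

All randomness flows from explicit seeds; a rerun with the same seed
reproduces every dataset and results table bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from propcoloc.genotype_data import GenotypeMatrix, TraitVector
from propcoloc.association import single_snp_scan, fit_joint
from propcoloc.proportional_core import proportional_test
from propcoloc.pc_coloc import pc_test
from propcoloc.bma_coloc import bma_test
from propcoloc.baselines import conditional_test, naive_select

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 25
DEFAULT_RHO = 0.9
DEFAULT_MAF_FLOOR = 0.05
DEFAULT_TAG_FRACTION = 0.3
SCREEN_P = 1e-4


@dataclass
class HaplotypePanel:
    """Phased synthetic haplotypes with block LD."""

    haplotypes: np.ndarray          # n_hap x n_snp, entries {0, 1}
    maf: np.ndarray                 # realised per-SNP frequency of allele 1
    blocks: list                    # (start, stop) column ranges
    population: np.ndarray          # label per haplotype
    snp_ids: list = None
    positions: np.ndarray = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j + 1}" for j in range(self.n_snps)]
        if self.positions is None:
            self.positions = np.arange(1, self.n_snps + 1) * 1000

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def r2_matrix(self) -> np.ndarray:
        if not hasattr(self, "_r2"):
            c = np.corrcoef(self.haplotypes.T.astype(float))
            self._r2 = np.nan_to_num(c) ** 2
        return self._r2


@dataclass
class SimScenario:
    """One cell of a simulation study.

    ``n_shared`` causal variants act on both traits; ``n_private`` additional
    distinct variants act on each trait separately.  ``effect`` is a
    per-allele relative risk for binary traits or the variance explained per
    causal variant for quantitative ones.  ``tag_fraction`` < 1 thins the
    genotyped SNPs (the causal variants may be lost like any other);
    ``admix_pi`` draws that fraction of the second cohort's haplotypes from
    an alternate panel.  ``r2_range`` restricts the LD between the two
    traits' private causal variants.
    """

    name: str
    trait_kind: str = "binary"          # binary | quantitative
    n_shared: int = 1
    n_private: int = 0
    effect: float = 1.2
    n_case: int = 2000
    n_control: int = 2000
    n_samples: int = 1000
    tag_fraction: float = 1.0
    admix_pi: float = 0.0
    r2_range: tuple = None

    def __post_init__(self):
        if self.trait_kind not in ("binary", "quantitative"):
            raise ValueError("trait_kind must be binary or quantitative")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if not 0 <= self.admix_pi <= 1:
            raise ValueError("admix_pi must lie in [0, 1]")
        if self.n_shared + self.n_private < 1:
            raise ValueError("at least one causal variant required")


def make_panel(n_hap: int = 2000, n_snp: int = 100,
               block_size: int = DEFAULT_BLOCK_SIZE,
               rho: float = DEFAULT_RHO,
               maf_floor: float = DEFAULT_MAF_FLOOR,
               seed: int = 0,
               population: str = "POP1",
               shift: float = 0.0) -> HaplotypePanel:
    """Draw a synthetic phased panel with block-autocorrelated LD.

    Latent per-haplotype Gaussians follow an AR(1) process with parameter
    ``rho`` within blocks of ``block_size`` SNPs (independent across
    blocks); alleles are the indicator of the latent value falling below the
    per-SNP quantile of a target frequency drawn Uniform(maf_floor, 0.5).
    SNPs whose realised frequency drifts below the floor (or above
    1 - floor) are redrawn with fresh target frequencies.  ``shift``
    perturbs the target frequencies, giving a mildly diverged population for
    admixture studies.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if not 0 < maf_floor < 0.5:
        raise ValueError("maf_floor must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    blocks = [(b, min(b + block_size, n_snp)) for b in range(0, n_snp, block_size)]

    def draw_block(width, n_rows):
        z = np.empty((n_rows, width))
        z[:, 0] = rng.standard_normal(n_rows)
        for t in range(1, width):
            z[:, t] = rho * z[:, t - 1] + np.sqrt(1 - rho ** 2) * \
                rng.standard_normal(n_rows)
        return z

    hap = np.empty((n_hap, n_snp), dtype=np.int8)
    freqs = np.empty(n_snp)
    for (b0, b1) in blocks:
        width = b1 - b0
        z = draw_block(width, n_hap)
        f = rng.uniform(maf_floor, 0.5, size=width)
        f = np.clip(f + shift * rng.standard_normal(width) * 0.1,
                    maf_floor, 1 - maf_floor)
        hap[:, b0:b1] = (z < stats.norm.ppf(f)).astype(np.int8)
        freqs[b0:b1] = f
    # redraw SNPs whose realised minor-allele frequency fell below the floor
    for _ in range(50):
        realised = hap.mean(axis=0)
        bad = np.where(np.minimum(realised, 1 - realised) < maf_floor)[0]
        if bad.size == 0:
            break
        for j in bad:
            f = rng.uniform(maf_floor + 0.02, 0.5)
            z = rng.standard_normal(n_hap)
            hap[:, j] = (z < stats.norm.ppf(f)).astype(np.int8)
            freqs[j] = f
    realised = hap.mean(axis=0)
    if np.any(np.minimum(realised, 1 - realised) < maf_floor * 0.5):
        raise RuntimeError("could not realise the requested MAF floor")
    return HaplotypePanel(
        haplotypes=hap,
        maf=realised,
        blocks=blocks,
        population=np.array([population] * n_hap),
    )


def admix_panels(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
                 pi: float, seed: int = 0) -> HaplotypePanel:
    """Mix two panels: each output haplotype comes from ``panel_b`` with
    probability ``pi``, otherwise from ``panel_a`` (sampled with
    replacement; output size matches ``panel_a``)."""
    if panel_a.n_snps != panel_b.n_snps:
        raise ValueError("panels must cover the same SNPs")
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = panel_a.n_hap
    from_b = rng.random(n) < pi
    rows_a = rng.integers(0, panel_a.n_hap, size=n)
    rows_b = rng.integers(0, panel_b.n_hap, size=n)
    hap = np.where(from_b[:, None], panel_b.haplotypes[rows_b],
                   panel_a.haplotypes[rows_a]).astype(np.int8)
    pop = np.where(from_b, panel_b.population[rows_b],
                   panel_a.population[rows_a])
    return HaplotypePanel(
        haplotypes=hap,
        maf=hap.mean(axis=0),
        blocks=list(panel_a.blocks),
        population=pop,
        snp_ids=list(panel_a.snp_ids),
        positions=panel_a.positions.copy(),
    )


def _genotypes_from_pairs(panel: HaplotypePanel, h1, h2) -> np.ndarray:
    return (panel.haplotypes[h1] + panel.haplotypes[h2]).astype(float)


def _as_matrix(panel: HaplotypePanel, dosages: np.ndarray,
               prefix: str) -> GenotypeMatrix:
    n = dosages.shape[0]
    return GenotypeMatrix(
        samples=[f"{prefix}{i + 1}" for i in range(n)],
        snps=list(panel.snp_ids),
        positions=panel.positions.copy(),
        alleles=[("A", "B")] * panel.n_snps,
        dosages=dosages,
    )


def simulate_case_control(panel: HaplotypePanel, causal_snp: str, rr: float,
                          n_case: int, n_control: int, seed: int = 0,
                          sample_prefix: str = "s"):
    """Retrospective sampling under a multiplicative risk model.

    Controls are random haplotype pairs from the panel.  Case pairs are
    rejection-sampled with acceptance probability rr^(causal allele count) /
    rr^2, the multiplicative model for a rare disease.
    """
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    rng = np.random.default_rng(seed)
    j = panel.snp_ids.index(causal_snp)
    ctrl = _genotypes_from_pairs(
        panel,
        rng.integers(0, panel.n_hap, n_control),
        rng.integers(0, panel.n_hap, n_control),
    )
    cases = []
    need = n_case
    attempts = 0
    while need > 0:
        batch = max(4 * need, 1000)
        h1 = rng.integers(0, panel.n_hap, batch)
        h2 = rng.integers(0, panel.n_hap, batch)
        count = panel.haplotypes[h1, j] + panel.haplotypes[h2, j]
        accept_p = rr ** count.astype(float) / max(rr, 1.0 / rr) ** 2
        if rr < 1:
            accept_p = rr ** count.astype(float)  # already <= 1
        keep = rng.random(batch) < accept_p
        attempts += batch
        got = _genotypes_from_pairs(panel, h1[keep], h2[keep])
        cases.append(got[:need])
        need -= min(need, got.shape[0])
        if attempts > 1e7 and need > 0:
            raise RuntimeError("case acceptance rate below 1e-4; reduce rr")
    case = np.vstack(cases)
    dosages = np.vstack([case, ctrl])
    y = np.concatenate([np.ones(n_case), np.zeros(n_control)])
    g = _as_matrix(panel, dosages, sample_prefix)
    return g, TraitVector(kind="binary", values=y)


def simulate_quantitative(panel: HaplotypePanel, causal_snps, var_fractions,
                          n: int, seed: int = 0, sample_prefix: str = "s"):
    """Gaussian trait with a fixed variance explained per causal variant.

    y = sum_c beta_c X_c + eps with beta_c = sqrt(v_c / (2 f_c (1 - f_c)))
    (Hardy-Weinberg genotype variance) and eps ~ N(0, 1 - sum v_c), so the
    total variance is about one when the causal variants are unlinked.
    """
    causal_snps = list(causal_snps)
    var_fractions = np.asarray(var_fractions, dtype=float)
    if np.any(var_fractions <= 0) or var_fractions.sum() >= 1:
        raise ValueError("variance fractions must be positive and sum below 1")
    if len(causal_snps) != len(var_fractions):
        raise ValueError("one variance fraction per causal variant required")
    rng = np.random.default_rng(seed)
    dosages = _genotypes_from_pairs(
        panel, rng.integers(0, panel.n_hap, n), rng.integers(0, panel.n_hap, n))
    idx = [panel.snp_ids.index(s) for s in causal_snps]
    f = panel.maf[idx]
    beta = np.sqrt(var_fractions / (2 * f * (1 - f)))
    y = dosages[:, idx] @ beta + \
        rng.standard_normal(n) * np.sqrt(1 - var_fractions.sum())
    g = _as_matrix(panel, dosages, sample_prefix)
    return g, TraitVector(kind="quantitative", values=y)


def tag_subset(g: GenotypeMatrix, fraction: float, seed: int = 0,
               keep: list = None) -> GenotypeMatrix:
    """Random SNP thinning to ceil(fraction * p) columns (position order kept).

    Emulates genotyping-array density; causal SNPs are removable like any
    other unless explicitly listed in ``keep``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1:
        return g
    rng = np.random.default_rng(seed)
    p = g.n_snps
    k = int(np.ceil(fraction * p))
    chosen = set(rng.choice(p, size=k, replace=False).tolist())
    if keep:
        chosen |= {g.snp_index(s) for s in keep}
    if not chosen:
        raise ValueError("tag subset is empty")
    ids = [g.snps[j] for j in sorted(chosen)]
    return g.subset_snps(ids)


def screen_min_p(g: GenotypeMatrix, y: TraitVector,
                 threshold: float = SCREEN_P) -> bool:
    """Keep a dataset only if some single-SNP association reaches
    ``threshold`` — the test is meant for regions with established signal."""
    scan = single_snp_scan(g, y)
    return bool(scan.p.min() <= threshold)


def sample_causal_pair(panel: HaplotypePanel, r2_range, rng,
                       max_tries: int = 2000):
    """A pair of distinct SNPs whose haplotype r^2 lies in ``r2_range``."""
    lo, hi = r2_range
    R2 = panel.r2_matrix()
    best, best_dist = None, np.inf
    for _ in range(max_tries):
        i, j = rng.choice(panel.n_snps, size=2, replace=False)
        r = R2[i, j]
        if lo <= r <= hi:
            return panel.snp_ids[i], panel.snp_ids[j], float(r)
        d = min(abs(r - lo), abs(r - hi))
        if d < best_dist:
            best, best_dist = (panel.snp_ids[i], panel.snp_ids[j], float(r)), d
    logger.warning("sample_causal_pair: no pair in r2 range %s after %d "
                   "tries; using closest (r2=%.3f)", r2_range, max_tries,
                   best[2])
    return best


def _draw_cohort(panel, scenario: SimScenario, causal, effects, seed, prefix):
    if scenario.trait_kind == "binary":
        # multiplicative risks combine across causal variants
        if len(causal) == 1:
            return simulate_case_control(panel, causal[0], effects[0],
                                         scenario.n_case, scenario.n_control,
                                         seed=seed, sample_prefix=prefix)
        return _simulate_case_control_multi(panel, causal, effects,
                                            scenario.n_case,
                                            scenario.n_control, seed, prefix)
    return simulate_quantitative(panel, causal, effects, scenario.n_samples,
                                 seed=seed, sample_prefix=prefix)


def _simulate_case_control_multi(panel, causal, rrs, n_case, n_control, seed,
                                 prefix):
    rng = np.random.default_rng(seed)
    idx = [panel.snp_ids.index(s) for s in causal]
    rrs = np.asarray(rrs, float)
    ctrl = _genotypes_from_pairs(
        panel, rng.integers(0, panel.n_hap, n_control),
        rng.integers(0, panel.n_hap, n_control))
    cases, need = [], n_case
    cap = float(np.prod(np.maximum(rrs, 1.0 / rrs) ** 2))
    while need > 0:
        batch = max(4 * need, 1000)
        h1 = rng.integers(0, panel.n_hap, batch)
        h2 = rng.integers(0, panel.n_hap, batch)
        counts = (panel.haplotypes[h1][:, idx] +
                  panel.haplotypes[h2][:, idx]).astype(float)
        accept = np.prod(rrs ** counts, axis=1) / cap
        keepm = rng.random(batch) < accept
        got = _genotypes_from_pairs(panel, h1[keepm], h2[keepm])
        cases.append(got[:need])
        need -= min(need, got.shape[0])
    dosages = np.vstack([np.vstack(cases), ctrl])
    y = np.concatenate([np.ones(n_case), np.zeros(n_control)])
    return _as_matrix(panel, dosages, prefix), TraitVector("binary", y)


def _apply_method(method, g1, y1, g2, y2, meta, alpha,
                  pc_threshold=0.85):
    """One method on one replicate; returns (p-like value, reject?).

    A NaN p-value means the method is not applicable to this replicate
    (e.g. the conditioning causal variant was lost to tag thinning) and the
    replicate is not counted for it.
    """
    shared_causal = meta.get("shared", [])
    if method == "C1":
        k = single_snp_scan(g1, y1).top_snp
        kp = single_snp_scan(g2, y2).top_snp
        p = 1.0 if k == kp else conditional_test(g1, y1, k=k, k_prime=kp)
        return p, p < alpha
    if method == "C2":
        if not shared_causal or shared_causal[0] not in g1.snps:
            return np.nan, False
        k = single_snp_scan(g1, y1).top_snp
        kp = shared_causal[0]
        p = 1.0 if k == kp else conditional_test(g1, y1, k=k, k_prime=kp)
        return p, p < alpha
    if method in ("P1", "P2", "P3"):
        strat = {"P1": "top_pair", "P2": "lasso_union",
                 "P3": "lasso_two_stage"}[method]
        sel = naive_select(g1, y1, g2, y2, strategy=strat)
        f1 = fit_joint(g1, y1, sel)
        f2 = fit_joint(g2, y2, sel)
        res = proportional_test(f1, f2)
        return res.ppp, res.ppp < alpha
    if method.startswith("PC"):
        thr = pc_threshold
        res = pc_test(g1, y1, g2, y2, threshold=thr)
        return res.ppp, res.ppp < alpha
    if method in ("BMA2", "BMA3"):
        res = bma_test(g1, y1, g2, y2, size=int(method[-1]))
        return res.ppp, res.ppp < alpha
    if method == "MAX":
        # oracle: test the causal variants themselves (simulation-only)
        union = sorted(set(meta.get("causal1", [])) |
                       set(meta.get("causal2", [])))
        union = [s for s in union if s in g1.snps]
        if len(union) < 2:
            return np.nan, False
        f1 = fit_joint(g1, y1, union)
        f2 = fit_joint(g2, y2, union)
        res = proportional_test(f1, f2)
        return res.ppp, res.ppp < alpha
    raise ValueError(f"unknown method {method!r}")


def _replicate(panel, panel2, scenario: SimScenario, rng):
    """Draw one screened replicate pair; returns (g1, y1, g2, y2, meta)."""
    for attempt in range(200):
        seed1 = int(rng.integers(2 ** 31))
        seed2 = int(rng.integers(2 ** 31))
        rng_local = np.random.default_rng(int(rng.integers(2 ** 31)))
        shared = list(rng_local.choice(panel.snp_ids, size=scenario.n_shared,
                                       replace=False)) \
            if scenario.n_shared else []
        if scenario.n_private:
            rest = [s for s in panel.snp_ids if s not in shared]
            if scenario.r2_range is not None and scenario.n_private == 1:
                a, b, r2 = sample_causal_pair(panel, scenario.r2_range,
                                              rng_local)
                priv1, priv2 = [a], [b]
            else:
                pick = rng_local.choice(rest, size=2 * scenario.n_private,
                                        replace=False)
                priv1 = list(pick[:scenario.n_private])
                priv2 = list(pick[scenario.n_private:])
                r2 = np.nan
        else:
            priv1, priv2, r2 = [], [], np.nan
        causal1 = shared + priv1
        causal2 = shared + priv2
        # per-variant effect (relative risk or variance fraction)
        eff1 = [scenario.effect] * len(causal1)
        eff2 = [scenario.effect] * len(causal2)
        cohort2_panel = panel2 if panel2 is not None else panel
        g1, y1 = _draw_cohort(panel, scenario, causal1, eff1, seed1, "a")
        g2, y2 = _draw_cohort(cohort2_panel, scenario, causal2, eff2, seed2,
                              "b")
        if scenario.tag_fraction < 1:
            tag_seed = int(rng.integers(2 ** 31))
            g1 = tag_subset(g1, scenario.tag_fraction, seed=tag_seed)
            g2 = g2.subset_snps(g1.snps)
        if screen_min_p(g1, y1) and screen_min_p(g2, y2):
            meta = {"shared": shared, "causal1": causal1, "causal2": causal2,
                    "causal_r2": r2, "redraws": attempt}
            return g1, y1, g2, y2, meta
    raise RuntimeError("could not draw a replicate passing the association "
                       "screen; weaken the scenario or lower the threshold")


def rate_ratio_ci(k1: int, n1: int, k2: int, n2: int, level: float = 0.95):
    """Delta-method confidence interval for a ratio of two rejection rates.

    Used in the admixture sensitivity analysis, where the quantity of
    interest is the type-1-error rate under mixing relative to no mixing.
    Returns (ratio, lower, upper); adds half a count when a cell is empty.
    """
    if min(n1, n2) <= 0:
        raise ValueError("both studies need at least one replicate")
    a1 = (k1 + 0.5) / (n1 + 0.5) if k1 == 0 else k1 / n1
    a2 = (k2 + 0.5) / (n2 + 0.5) if k2 == 0 else k2 / n2
    ratio = a1 / a2
    # var(log ratio) = (1-p1)/(n1 p1) + (1-p2)/(n2 p2)
    var_log = (1 - a1) / (n1 * a1) + (1 - a2) / (n2 * a2)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var_log)
    return ratio, ratio * np.exp(-half), ratio * np.exp(half)


def run_study(scenarios, methods, n_reps: int, alpha: float = 0.05,
              seed: int = 0, panel_kwargs: dict = None,
              pc_threshold: float = 0.85) -> pd.DataFrame:
    """Rejection rates per scenario x method.

    One panel is drawn per scenario (two, when ``admix_pi`` > 0, the second
    mildly diverged); each replicate draws screened cohort pairs and applies
    every requested method to the identical data.  Replicates failing the
    single-SNP association screen are redrawn and counted.

    Returns a table with columns scenario_id, method, n_reps, rejections,
    rate, se (binomial), mean_causal_r2, redraws.
    """
    panel_kwargs = dict(panel_kwargs or {})
    master = np.random.default_rng(seed)
    rows = []
    if n_reps == 0:
        return pd.DataFrame(columns=[
            "scenario_id", "method", "n_reps", "rejections", "rate", "se",
            "mean_causal_r2", "redraws"])
    for scenario in scenarios:
        pseed = int(master.integers(2 ** 31))
        panel = make_panel(seed=pseed, **panel_kwargs)
        panel2 = None
        if scenario.admix_pi > 0:
            alt = make_panel(seed=pseed + 1, shift=1.0,
                             population="POP2", **panel_kwargs)
            panel2 = admix_panels(panel, alt, scenario.admix_pi,
                                  seed=pseed + 2)
        rej = {m: 0 for m in methods}
        used = {m: 0 for m in methods}
        r2s, redraws = [], 0
        rep_rng = np.random.default_rng(int(master.integers(2 ** 31)))
        for _ in range(n_reps):
            g1, y1, g2, y2, meta = _replicate(panel, panel2, scenario,
                                              rep_rng)
            r2s.append(meta["causal_r2"])
            redraws += meta["redraws"]
            for m in methods:
                try:
                    p, reject = _apply_method(m, g1, y1, g2, y2, meta,
                                              alpha,
                                              pc_threshold=pc_threshold)
                except Exception as exc:  # recorded, not fatal
                    logger.warning("scenario %s method %s failed: %s",
                                   scenario.name, m, exc)
                    continue
                if np.isnan(p):
                    continue
                used[m] += 1
                rej[m] += int(reject)
        for m in methods:
            n_used = used[m]
            rate = rej[m] / n_used if n_used else np.nan
            se = (np.sqrt(rate * (1 - rate) / n_used)
                  if n_used else np.nan)
            rows.append({
                "scenario_id": scenario.name,
                "method": m,
                "n_reps": n_used,
                "rejections": rej[m],
                "rate": rate,
                "se": se,
                "mean_causal_r2": (float(np.nanmean(r2s))
                                   if r2s and not np.all(np.isnan(r2s))
                                   else np.nan),
                "redraws": redraws,
            })
    return pd.DataFrame(rows)
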