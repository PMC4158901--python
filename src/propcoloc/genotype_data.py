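"""Regional genotype containers: reading, validation, imputation and merging.

Genotypes are stored as alt-allele dosages in ``[0, 2]`` — integer counts
{0, 1, 2} straight off a VCF or dosage table, real-valued after regression
imputation of missing cells.  Coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype input."""


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix for one cohort over one genomic region.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows), unique.
    snps : list of str
        Ordered SNP identifiers (columns), unique, sorted by position.
    positions : ndarray of int
        1-based base-pair coordinates, one per SNP.
    alleles : list of (str, str)
        (ref, alt) pair per SNP; dosages count alt alleles.
    dosages : ndarray, shape (n_samples, n_snps)
        Values in [0, 2]; fractional only after imputation.
    missing_mask : ndarray of bool
        True where the genotype was absent in the input.
    """

    samples: list
    snps: list
    positions: np.ndarray
    alleles: list
    dosages: np.ndarray
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.dosages.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.dosages.shape
        if len(self.samples) != n:
            raise GenotypeError("sample count does not match dosage rows")
        if not (len(self.snps) == len(self.positions) == len(self.alleles) == p):
            raise GenotypeError("SNP metadata lengths do not match dosage columns")
        if len(set(self.samples)) != n:
            raise GenotypeError("duplicate sample identifiers")
        if len(set(self.snps)) != p:
            raise GenotypeError("duplicate SNP identifiers")
        observed = self.dosages[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise GenotypeError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        return self.snps.index(snp_id)

    def subset_snps(self, ids) -> "GenotypeMatrix":
        """Column subset in the given order."""
        idx = [self.snp_index(s) for s in ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            positions=self.positions[idx],
            alleles=[self.alleles[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )

    def subset_samples(self, row_idx) -> "GenotypeMatrix":
        row_idx = np.asarray(row_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in row_idx],
            snps=list(self.snps),
            positions=self.positions.copy(),
            alleles=list(self.alleles),
            dosages=self.dosages[row_idx].copy(),
            missing_mask=self.missing_mask[row_idx].copy(),
        )


@dataclass
class TraitVector:
    """One trait, sample-aligned with a :class:`GenotypeMatrix`.

    ``kind`` is ``"binary"`` (0 = control, 1 = case; logistic regression) or
    ``"quantitative"`` (linear regression).
    """

    kind: str
    values: np.ndarray
    samples: list = None

    def __post_init__(self):
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trait values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")
        if self.kind == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("binary trait must be coded 0/1")

    def __len__(self) -> int:
        return len(self.values)


def _read_dosage_table(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise GenotypeError(f"duplicate SNP identifier in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    snps = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    missing = ~np.isfinite(values)
    values = np.where(missing, 0.0, values)
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        snps=snps,
        positions=np.arange(1, len(snps) + 1),
        alleles=[("A", "B")] * len(snps),
        dosages=values,
        missing_mask=missing,
    )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, positions, alleles, cols, miss = [], [], [], [], []
    for i, var in enumerate(vcf):
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=0.0)
        m = gt == 2
        snps.append(vid)
        positions.append(var.POS)
        alleles.append((var.REF, var.ALT[0] if var.ALT else "."))
        cols.append(dose)
        miss.append(m)
    if len(set(snps)) != len(snps):
        raise GenotypeError(f"duplicate SNP identifier in {path}")
    if not snps:
        raise GenotypeError(f"no variant records in {path}")
    order = np.argsort(np.asarray(positions), kind="stable")
    return GenotypeMatrix(
        samples=samples,
        snps=[snps[i] for i in order],
        positions=np.asarray(positions)[order],
        alleles=[alleles[i] for i in order],
        dosages=np.column_stack([cols[i] for i in order]),
        missing_mask=np.column_stack([miss[i] for i in order]),
    )


def read_genotypes(path, format: str = "dosage_table") -> GenotypeMatrix:
    """Read a regional genotype matrix.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"vcf", "dosage_table"}
        ``vcf``: VCF 4.x, GT field converted to alt-allele dosage, ``./.``
        marked missing.  ``dosage_table``: tab-delimited, header row of SNP
        ids, first column sample id, cells in {0,1,2} or empty/NA for missing.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_trait(path, kind: str) -> TraitVector:
    """Read a two-column (sample id, value) trait file, tab-delimited."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "value"])
    return TraitVector(kind=kind, values=df["value"].to_numpy(float),
                       samples=[str(s) for s in df["sample"]])


def impute_missing(g: GenotypeMatrix, max_predictors: int = 5) -> GenotypeMatrix:
    """Fill missing dosages by multiple regression on correlated neighbours.

    Each SNP with missing cells is regressed (least squares, with intercept)
    on the up-to-``max_predictors`` fully observed SNPs most correlated with
    it in absolute Pearson terms, ties broken by SNP order; fitted values are
    clipped to [0, 2].  Falls back to the SNP's observed mean when no complete
    predictor exists.  Observed cells are never altered.
    """
    if not g.missing_mask.any():
        return g
    if np.any(g.missing_mask.all(axis=0)):
        bad = [g.snps[j] for j in np.where(g.missing_mask.all(axis=0))[0]]
        raise GenotypeError(f"SNP(s) missing in all samples: {bad}")
    frac = g.missing_mask.mean(axis=0)
    if np.any(frac >= 0.5):
        bad = [g.snps[j] for j in np.where(frac >= 0.5)[0]]
        raise GenotypeError(f"SNP(s) with >=50% missing genotypes: {bad}")
    if np.any(g.missing_mask.all(axis=1)):
        raise GenotypeError("sample with no observed genotypes")

    dos = g.dosages.copy()
    complete = ~g.missing_mask.any(axis=0)
    for j in np.where(g.missing_mask.any(axis=0))[0]:
        obs = ~g.missing_mask[:, j]
        target = dos[obs, j]
        cand = np.where(complete)[0]
        cand = cand[cand != j]
        if cand.size and np.std(target) > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                cors = np.array([
                    abs(np.corrcoef(target, dos[obs, c])[0, 1]) for c in cand
                ])
            cors = np.nan_to_num(cors)
            # stable sort keeps SNP order on ties
            top = cand[np.argsort(-cors, kind="stable")[:max_predictors]]
        else:
            top = np.array([], dtype=int)
        miss = g.missing_mask[:, j]
        if top.size == 0:
            dos[miss, j] = target.mean()
            continue
        X = np.column_stack([np.ones(obs.sum()), dos[obs][:, top]])
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        Xm = np.column_stack([np.ones(miss.sum()), dos[miss][:, top]])
        dos[miss, j] = np.clip(Xm @ beta, 0.0, 2.0)
    return replace(g, dosages=dos, missing_mask=np.zeros_like(g.missing_mask))


def merge_cohorts(g1: GenotypeMatrix, g2: GenotypeMatrix):
    """Row-stack two cohorts over their common SNPs.

    SNPs are intersected by identifier (order of ``g1`` kept); an exact
    ref/alt swap in cohort 2 is recoded as ``2 - dosage``; any other allele
    mismatch is an error.  Strand-ambiguous A/T and C/G SNPs are flagged in
    the log but retained.

    Returns
    -------
    merged : GenotypeMatrix
    cohort_labels : ndarray of int
        0 for rows from ``g1``, 1 for rows from ``g2``.
    """
    if g1.missing_mask.any() or g2.missing_mask.any():
        raise GenotypeError("impute both cohorts before merging")
    common = [s for s in g1.snps if s in set(g2.snps)]
    dropped = (set(g1.snps) | set(g2.snps)) - set(common)
    if dropped:
        logger.warning("merge_cohorts: dropping %d SNPs absent from one cohort: %s",
                       len(dropped), sorted(dropped))
    if not common:
        raise GenotypeError("no SNPs shared between cohorts")
    a = g1.subset_snps(common)
    b = g2.subset_snps(common)
    dos2 = b.dosages.copy()
    for j, snp in enumerate(common):
        r1, alt1 = a.alleles[j]
        r2, alt2 = b.alleles[j]
        if (r1.upper(), alt1.upper()) in _AMBIGUOUS_PAIRS:
            logger.warning("merge_cohorts: strand-ambiguous SNP %s (%s/%s) retained",
                           snp, r1, alt1)
        if (r1, alt1) == (r2, alt2):
            continue
        if (r1, alt1) == (alt2, r2):
            dos2[:, j] = 2.0 - dos2[:, j]
            logger.info("merge_cohorts: recoded ref/alt swap at %s", snp)
        else:
            raise GenotypeError(
                f"allele mismatch at {snp}: {r1}/{alt1} vs {r2}/{alt2}")
    samples = list(a.samples)
    s2 = list(b.samples)
    if set(samples) & set(s2):
        # merged container still needs unique row ids
        s2 = [f"{s}::2" for s in s2]
    merged = GenotypeMatrix(
        samples=samples + s2,
        snps=list(a.snps),
        positions=a.positions.copy(),
        alleles=list(a.alleles),
        dosages=np.vstack([a.dosages, dos2]),
    )
    labels = np.concatenate([np.zeros(a.n_samples, int), np.ones(b.n_samples, int)])
    return merged, labels
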