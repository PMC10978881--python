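"""Genotype QC filters and methylation pre-correction.

QC removes SNPs on missingness (>5%), Hardy-Weinberg exact-test departure
(p < 1e-6), minor allele frequency (<1%) and imputation info score (<0.8).
Methylation is residualized on fixed covariates plus batch indicators, then
rank-based inverse-normal transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotypes import GenotypeSet


@dataclass
class QCThresholds:
    max_missing_rate: float = 0.05
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    info_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "hwe_p_min", "maf_min", "info_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (conditional on allele
    counts) no more probable than the observed one — the standard exact SNP
    HWE test. Monomorphic sites return 1.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise ValueError("no genotype observations")
    n_rare = 2 * min(n_aa_hom, n_bb_hom) + n_het
    if n_rare == 0:
        return 1.0
    # log-probability of each feasible het count given allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1.0)
        - gammaln(rare_hom + 1.0)
        - gammaln(common_hom + 1.0)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def qc_genotypes(
    genos: GenotypeSet, thresholds: QCThresholds | None = None
) -> tuple[GenotypeSet, pd.DataFrame]:
    """Filter SNPs; returns the filtered set and an exclusion log.

    Filter order (first failing reason recorded): missingness, info score,
    MAF, HWE. SNP order is preserved. Idempotent.
    """
    th = thresholds or QCThresholds()
    dos = genos.dosages
    n_ind = dos.shape[0]
    miss_rate = np.isnan(dos).sum(axis=0) / n_ind
    info = genos.variants["info"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dos, axis=0) / 2.0
    af = np.where(np.isnan(af), 0.0, af)
    maf = np.minimum(af, 1.0 - af)

    reasons: list[tuple[str, str]] = []
    keep = np.ones(genos.n_snps, dtype=bool)
    hard = np.rint(dos)
    for j in range(genos.n_snps):
        snp = genos.variants["snp"].iloc[j]
        if miss_rate[j] > th.max_missing_rate:
            keep[j] = False
            reasons.append((snp, "missing"))
        elif info[j] < th.info_min:
            keep[j] = False
            reasons.append((snp, "info"))
        elif maf[j] < th.maf_min:
            keep[j] = False
            reasons.append((snp, "maf"))
        else:
            col = hard[:, j]
            col = col[~np.isnan(col)]
            n_bb = int((col == 2).sum())
            n_het = int((col == 1).sum())
            n_aa = int((col == 0).sum())
            if hwe_exact_test(n_aa, n_het, n_bb) < th.hwe_p_min:
                keep[j] = False
                reasons.append((snp, "hwe"))
    if not keep.any():
        warnings.warn("all SNPs removed by QC", stacklevel=2)
    log = pd.DataFrame(reasons, columns=["snp", "reason"])
    return genos.subset(np.flatnonzero(keep)), log


def adjust_methylation(
    values: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-probe least-squares residuals after regressing out covariates.

    Numeric covariate columns enter as-is; non-numeric columns are expanded
    to batch indicator columns. An intercept is always included. Collinear
    columns are handled by a minimum-norm least-squares fit (rank-deficient
    designs warn).
    """
    if values.shape[1] != len(covariates):
        raise ValueError("covariate rows must match methylation columns (individuals)")
    if covariates.isna().any().any():
        raise ValueError("missing covariate values")
    numeric = covariates.select_dtypes(include=[np.number])
    categorical = covariates.select_dtypes(exclude=[np.number])
    parts = [np.ones((len(covariates), 1))]
    if numeric.shape[1]:
        parts.append(numeric.to_numpy(dtype=float))
    if categorical.shape[1]:
        dummies = pd.get_dummies(categorical, drop_first=True)
        if dummies.shape[1]:
            parts.append(dummies.to_numpy(dtype=float))
    design = np.hstack(parts)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient covariate design ({rank} < {design.shape[1]}); "
            "collinear columns absorbed by least squares",
            stacklevel=2,
        )
    y = values.to_numpy(dtype=float).T  # individuals x probes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return pd.DataFrame(resid.T, index=values.index, columns=values.columns)


def rank_int(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset (c = 3/8).

    Maps value of rank r (ties averaged) to ``Phi^{-1}((r - c) / (n - 2c + 1))``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("rank_int expects a 1-D vector")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.nanstd(x) == 0:
        raise ValueError("constant vector cannot be transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def rank_int_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`rank_int` to each probe (row) of a matrix."""
    out = np.vstack([rank_int(row) for row in values.to_numpy(dtype=float)])
    return pd.DataFrame(out, index=values.index, columns=values.columns)
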