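"""Cis-window association scans, lead-SNP extraction, and IVW meta-analysis."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeSet

#: Default stringent significance threshold (Bonferroni for probes x window SNPs).
P_SIG = 1e-10
#: Default replication threshold (Bonferroni for independent QTL count).
P_REP = 1e-6

STATS_COLUMNS = [
    "probe", "snp", "chrom", "pos", "effect_allele", "other_allele",
    "af", "beta", "se", "p", "n",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def cis_window(
    probe_pos: int, variant_table: pd.DataFrame, window: int = 1_000_000
) -> np.ndarray:
    """Indices of SNPs within the closed interval [pos - window, pos + window]."""
    if window < 0:
        raise ValueError("window must be non-negative")
    pos = variant_table["pos"].to_numpy()
    return np.flatnonzero((pos >= probe_pos - window) & (pos <= probe_pos + window))


def assoc_scan(
    y: np.ndarray,
    genos: GenotypeSet,
    snp_indices: np.ndarray,
    probe: str = "",
) -> pd.DataFrame:
    """OLS of the phenotype on each window SNP (with intercept).

    Missing dosages are mean-imputed per SNP. Zero-variance SNPs are dropped
    with a warning. Two-sided p-values come from the t distribution with
    n - 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != genos.n_individuals:
        raise ValueError("phenotype length does not match genotype individuals")
    snp_indices = np.asarray(snp_indices, dtype=int)
    if snp_indices.size == 0:
        return pd.DataFrame(columns=STATS_COLUMNS)
    g = genos.dosages[:, snp_indices].astype(float)
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        nan_r, nan_c = np.where(np.isnan(g))
        g = g.copy()
        g[nan_r, nan_c] = col_mean[nan_c]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    keep = sxx > 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} zero-variance SNPs dropped from scan", stacklevel=2
        )
    sxy = gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        syy = float(yc @ yc)
        rss = syy - beta * sxy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore"):
            tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    var = genos.variants.iloc[snp_indices]
    out = pd.DataFrame(
        {
            "probe": probe,
            "snp": var["snp"].to_numpy(),
            "chrom": var["chrom"].to_numpy(),
            "pos": var["pos"].to_numpy(),
            "effect_allele": var["alt"].to_numpy(),
            "other_allele": var["ref"].to_numpy(),
            "af": g.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )
    return out[keep].reset_index(drop=True)


def scan_cohort(
    phenotypes: pd.DataFrame,
    genos: GenotypeSet,
    probes: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Scan every probe's cis window; probes with empty windows are skipped."""
    frames = []
    probe_pos = dict(zip(probes["probe"], probes["pos"]))
    for probe in phenotypes.index:
        idx = cis_window(int(probe_pos[probe]), genos.variants, window)
        if idx.size == 0:
            continue
        frames.append(
            assoc_scan(phenotypes.loc[probe].to_numpy(), genos, idx, probe=probe)
        )
    if not frames:
        return pd.DataFrame(columns=STATS_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def lead_snp(records: pd.DataFrame, probe_pos: int | None = None) -> pd.Series:
    """The most significant record for one probe.

    Tie-break: smaller p, then larger ``|beta/se|``, then smaller distance to
    the probe (when ``probe_pos`` given), then smaller position.
    """
    if len(records) == 0:
        raise ValueError("no records for probe")
    df = records.copy()
    df["_absz"] = -np.abs(df["beta"] / df["se"])
    df["_dist"] = (
        np.abs(df["pos"] - probe_pos) if probe_pos is not None else 0
    )
    df = df.sort_values(["p", "_absz", "_dist", "pos"], kind="mergesort")
    return records.loc[df.index[0]]


def lead_snps(
    stats_df: pd.DataFrame, probes: pd.DataFrame, ancestry: str = ""
) -> pd.DataFrame:
    """Per-probe lead record table from a stacked summary-statistic frame."""
    probe_pos = dict(zip(probes["probe"], probes["pos"]))
    rows = []
    for probe, grp in stats_df.groupby("probe", sort=False):
        rec = lead_snp(grp, probe_pos.get(probe))
        rows.append(
            {
                "probe": probe,
                "snp": rec["snp"],
                "pos": rec["pos"],
                "effect_allele": rec["effect_allele"],
                "other_allele": rec["other_allele"],
                "af": rec["af"],
                "beta": rec["beta"],
                "se": rec["se"],
                "p": rec["p"],
                "n": rec["n"],
                "ancestry": ancestry,
            }
        )
    return pd.DataFrame(rows)


def ivw_meta_arrays(
    betas: np.ndarray, ses: np.ndarray
) -> tuple[float, float, float]:
    """Fixed-effects inverse-variance meta-analysis of one probe-SNP pair.

    ``w_i = 1/se_i^2``; pooled beta is the weighted mean, pooled se is
    ``(sum w)^-1/2``, p from the normal z statistic.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("no cohorts to meta-analyse")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
    return beta, se, p


def ivw_meta(cohort_stats: list[pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyse per-cohort summary statistics over shared (probe, snp) keys.

    Assumes alleles were harmonized beforehand (see :func:`harmonize_alleles`).
    A pair present in only a subset of cohorts is pooled over that subset.
    """
    if not cohort_stats:
        raise ValueError("no cohorts to meta-analyse")
    stacked = pd.concat(cohort_stats, ignore_index=True)
    if (stacked["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / stacked["se"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["beta"])
    agg = stacked.groupby(["probe", "snp"], sort=False).agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        effect_allele=("effect_allele", "first"),
        other_allele=("other_allele", "first"),
        af=("af", "mean"),
        n=("n", "sum"),
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
    )
    agg["beta"] = agg["_wb"] / agg["_w"]
    agg["se"] = 1.0 / np.sqrt(agg["_w"])
    z = agg["beta"] / agg["se"]
    agg["p"] = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    agg = agg.drop(columns=["_w", "_wb"]).reset_index()
    return agg[STATS_COLUMNS]


def harmonize_alleles(
    records: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Align effect alleles of ``records`` to a reference allele table.

    ``reference`` needs columns ``snp, effect_allele, other_allele`` (and
    ``af`` for resolving strand-ambiguous SNPs). Swapped alleles flip the
    effect sign and frequency. Strand-ambiguous pairs (A/T, C/G) are kept
    only when both frequencies are unambiguous (MAF < 0.4); other mismatches
    are dropped with a warning.
    """
    ref = reference.set_index("snp")
    keep_rows = []
    n_dropped = 0
    for _, row in records.iterrows():
        snp = row["snp"]
        if snp not in ref.index:
            n_dropped += 1
            continue
        r = ref.loc[snp]
        ea, oa = row["effect_allele"], row["other_allele"]
        ambiguous = (ea, oa) in AMBIGUOUS_PAIRS
        if (ea, oa) == (r["effect_allele"], r["other_allele"]):
            if ambiguous and not _af_consistent(row.get("af"), r.get("af")):
                n_dropped += 1
                continue
            keep_rows.append(row)
        elif (ea, oa) == (r["other_allele"], r["effect_allele"]):
            if ambiguous and not _af_consistent(
                1.0 - row.get("af", np.nan), r.get("af")
            ):
                n_dropped += 1
                continue
            flipped = row.copy()
            flipped["effect_allele"], flipped["other_allele"] = oa, ea
            flipped["beta"] = -row["beta"]
            if "af" in flipped:
                flipped["af"] = 1.0 - row["af"]
            keep_rows.append(flipped)
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"harmonize_alleles dropped {n_dropped} records "
            "(mismatched or unresolvable strand-ambiguous alleles)",
            stacklevel=2,
        )
    if not keep_rows:
        return records.iloc[0:0].copy()
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def _af_consistent(af_a: float | None, af_b: float | None, maf_cap: float = 0.4) -> bool:
    """Strand-ambiguous SNPs are resolvable only when clearly away from 0.5."""
    if af_a is None or af_b is None or np.isnan(af_a) or np.isnan(af_b):
        return False
    if min(af_a, 1 - af_a) >= maf_cap or min(af_b, 1 - af_b) >= maf_cap:
        return False
    return (af_a < 0.5) == (af_b < 0.5)
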