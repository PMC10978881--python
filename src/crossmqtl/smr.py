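"""Summary-based Mendelian randomization with the HEIDI heterogeneity filter.

The SMR statistic tests whether a SNP's effect on an outcome trait is
mediated by the exposure (methylation): with z_zx = b_zx/se_zx and
z_zy = b_zy/se_zy,

    T_SMR = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2)  ~  chi-square(1)

and the mediated effect is b_xy = b_zy / b_zx with a delta-method SE. HEIDI
compares b_xy estimates across LD-linked SNPs: under a single shared causal
variant they agree up to sampling noise; under linkage of distinct causal
variants they diverge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import cis_window
from .genotypes import GenotypeSet
from .ld import ld_matrix
from .synthdata import EAS, EUR

#: SMR significance presets; Methods-style default (Bonferroni over probes).
P_SMR_DEFAULT = 1e-7
P_SMR_RESULTS = 1e-6
P_HEIDI_MIN = 0.01
GWAS_SIG = 5e-8
WEAK_INSTRUMENT_CHI2 = 10.0

#: HEIDI eligible-SNP conventions (SMR-software style defaults).
HEIDI_R2_BOUNDS = (0.05, 0.9)
HEIDI_MAX_SNPS = 20
HEIDI_P_EXPOSURE = 1.6e-3
HEIDI_MIN_SNPS = 3


@dataclass
class SMRResult:
    probe: str
    trait: str
    ancestry: str
    snp: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    reason: str = ""


def smr_test(
    b_zx: float, se_zx: float, b_zy: float, se_zy: float
) -> tuple[float, float, float]:
    """Mediated effect, its SE, and the SMR p-value for one instrument."""
    if se_zx <= 0 or se_zy <= 0:
        raise ValueError("standard errors must be positive")
    z_zx = b_zx / se_zx
    z_zy = b_zy / se_zy
    if z_zx**2 < WEAK_INSTRUMENT_CHI2:
        warnings.warn(
            f"weak instrument: z_zx^2 = {z_zx**2:.2f} < {WEAK_INSTRUMENT_CHI2}",
            stacklevel=2,
        )
    if z_zx == 0:
        raise ValueError("instrument effect is exactly zero")
    t_smr = (z_zx**2 * z_zy**2) / (z_zx**2 + z_zy**2) if z_zy != 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    b_xy = b_zy / b_zx
    var_xy = (se_zy**2) / b_zx**2 + (b_zy**2 * se_zx**2) / b_zx**4
    return float(b_xy), float(np.sqrt(var_xy)), p_smr


def _bxy_covariance(
    b_zx: np.ndarray, se_zx: np.ndarray, b_zy: np.ndarray, se_zy: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Delta-method covariance of the per-SNP b_xy estimates.

    Exposure and outcome samples are independent; within each dataset the
    effect estimates of linked SNPs correlate approximately as the reference
    LD correlation ``r``.
    """
    inv_zx = 1.0 / b_zx
    cov_y = r * np.outer(se_zy, se_zy) * np.outer(inv_zx, inv_zx)
    grad_x = b_zy / b_zx**2
    cov_x = r * np.outer(se_zx, se_zx) * np.outer(grad_x, grad_x)
    return cov_y + cov_x


def heidi_test(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ref: GenotypeSet,
    top_snp: str,
    r2_bounds: tuple[float, float] = HEIDI_R2_BOUNDS,
    max_snps: int = HEIDI_MAX_SNPS,
    p_exposure_max: float = HEIDI_P_EXPOSURE,
) -> tuple[float | None, int, str]:
    """HEIDI p-value for one locus; returns (p, n_snps_used, reason).

    Eligible SNPs: present in exposure, outcome, and the reference panel;
    reference r^2 with the top SNP inside ``r2_bounds``; exposure
    p < ``p_exposure_max``. The ``max_snps`` strongest exposure signals are
    kept. The sum of squared standardized deviations of b_xy(i) from
    b_xy(top) is referred to a Satterthwaite-matched scaled chi-square.
    """
    expo = exposure.set_index("snp")
    outc = outcome.set_index("snp")
    if top_snp not in expo.index or top_snp not in outc.index or top_snp not in ref:
        return None, 0, "top_snp_unavailable"
    shared = [
        s for s in expo.index
        if s != top_snp and s in outc.index and s in ref
    ]
    lo, hi = r2_bounds
    top_idx = ref.snp_index(top_snp)
    eligible = []
    for s in shared:
        if float(expo.loc[s, "p"]) >= p_exposure_max:
            continue
        idx = ref.snp_index(s)
        r_pair = ld_matrix(ref, np.array([top_idx, idx]))[0, 1]
        if lo < r_pair**2 < hi:
            eligible.append((s, float((expo.loc[s, "beta"] / expo.loc[s, "se"]) ** 2)))
    if len(eligible) < HEIDI_MIN_SNPS:
        return None, len(eligible), "too_few_eligible_snps"
    eligible.sort(key=lambda t: (-t[1], t[0]))
    snps = [top_snp] + [s for s, _ in eligible[:max_snps]]

    b_zx = expo.loc[snps, "beta"].to_numpy(dtype=float)
    se_zx = expo.loc[snps, "se"].to_numpy(dtype=float)
    b_zy = outc.loc[snps, "beta"].to_numpy(dtype=float)
    se_zy = outc.loc[snps, "se"].to_numpy(dtype=float)
    r = ld_matrix(ref, np.array([ref.snp_index(s) for s in snps]))

    cov_bxy = _bxy_covariance(b_zx, se_zx, b_zy, se_zy, r)
    b_xy = b_zy / b_zx
    d = b_xy[1:] - b_xy[0]
    m = len(d)
    cov_d = (
        cov_bxy[1:, 1:]
        - cov_bxy[1:, [0]]
        - cov_bxy[[0], 1:]
        + cov_bxy[0, 0]
    )
    sd_d = np.sqrt(np.diag(cov_d))
    z_d = d / sd_d
    corr_d = cov_d / np.outer(sd_d, sd_d)
    t_heidi = float((z_d**2).sum())
    # two-moment match of the correlated chi-square sum
    mean_t = float(m)
    var_t = 2.0 * float((corr_d**2).sum())
    scale = var_t / (2.0 * mean_t)
    df = 2.0 * mean_t**2 / var_t
    p = float(stats.chi2.sf(t_heidi / scale, df=df))
    return p, m, ""


def ancestry_specific_smr(
    labels: pd.DataFrame,
    leads: dict[str, pd.DataFrame],
    meta_stats: dict[str, pd.DataFrame],
    gwas: dict[tuple[str, str], pd.DataFrame],
    panels: dict[str, GenotypeSet],
    probes: pd.DataFrame,
    p_smr_thresh: float = P_SMR_DEFAULT,
    p_heidi_min: float = P_HEIDI_MIN,
    gwas_sig: float = GWAS_SIG,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """SMR + HEIDI over every (ancestry-specific probe, trait) pair.

    ``leads`` and ``meta_stats`` map ancestry -> per-probe lead table /
    stacked cis statistics; ``gwas`` maps (trait, ancestry) -> GWAS summary
    table with columns ``snp, pos, effect_allele, beta, se, p, n``. A probe
    is dropped for a trait when the alternate ancestry's GWAS shows any
    signal at ``p < gwas_sig`` inside the probe's cis window.
    """
    probe_pos = dict(zip(probes["probe"], probes["pos"]))
    specific = labels[labels["label"].isin(["EUR_SPECIFIC", "EAS_SPECIFIC"])]
    traits = sorted({t for t, _ in gwas})
    rows = []
    for _, prow in specific.iterrows():
        probe = prow["probe"]
        ancestry = EUR if prow["label"] == "EUR_SPECIFIC" else EAS
        alt = EAS if ancestry == EUR else EUR
        lead = leads[ancestry].set_index("probe").loc[probe]
        pos = int(probe_pos[probe])
        expo_cis = meta_stats[ancestry]
        expo_cis = expo_cis[expo_cis["probe"] == probe]
        for trait in traits:
            res = _smr_one(
                probe, trait, ancestry, alt, lead, pos, expo_cis,
                gwas, panels, window, gwas_sig,
            )
            if res is not None:
                rows.append(res)
    out = pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=[
            "probe", "trait", "ancestry", "snp", "b_xy", "se_xy",
            "p_smr", "p_heidi", "n_heidi_snps", "reason",
        ],
    )
    if len(out):
        out["significant"] = (
            (out["p_smr"] < p_smr_thresh)
            & out["p_heidi"].notna()
            & (out["p_heidi"] > p_heidi_min)
        )
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def _smr_one(
    probe, trait, ancestry, alt, lead, pos, expo_cis, gwas, panels, window, gwas_sig
) -> SMRResult | None:
    key = (trait, ancestry)
    if key not in gwas:
        return None
    gw = gwas[key]
    # ancestry-specificity guard: any alternate-ancestry GWAS hit in the window
    alt_key = (trait, alt)
    if alt_key in gwas:
        gw_alt = gwas[alt_key]
        in_window = (gw_alt["pos"] >= pos - window) & (gw_alt["pos"] <= pos + window)
        if (gw_alt.loc[in_window, "p"] < gwas_sig).any():
            return SMRResult(
                probe, trait, ancestry, str(lead["snp"]), np.nan, np.nan,
                np.nan, None, 0, reason="alt_ancestry_gwas_signal",
            )
    gw_idx = gw.set_index("snp")
    snp = str(lead["snp"])
    if snp not in gw_idx.index:
        return SMRResult(
            probe, trait, ancestry, snp, np.nan, np.nan, np.nan, None, 0,
            reason="instrument_absent_from_gwas",
        )
    grow = gw_idx.loc[snp]
    b_zy, se_zy = float(grow["beta"]), float(grow["se"])
    if "effect_allele" in gw.columns and "effect_allele" in lead.index:
        if grow["effect_allele"] != lead["effect_allele"]:
            b_zy = -b_zy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b_xy, se_xy, p_smr = smr_test(
            float(lead["beta"]), float(lead["se"]), b_zy, se_zy
        )
    p_heidi, n_heidi, reason = heidi_test(expo_cis, gw, panels[ancestry], snp)
    return SMRResult(
        probe, trait, ancestry, snp, b_xy, se_xy, p_smr, p_heidi, n_heidi, reason
    )
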