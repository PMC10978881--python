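"""Correlation of QTL effect sizes between datasets, corrected for estimation error.

Naive Pearson correlation of estimated effects is attenuated by sampling
noise. The method-of-moments estimator here subtracts the mean squared
standard error from each observed effect variance before standardizing the
covariance:

    r_b = cov(b1, b2) / sqrt((var(b1) - mean(se1^2)) * (var(b2) - mean(se2^2)))

For sample-independent datasets the covariance needs no error correction.
Standard errors come from a delete-one jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_PAIRS = 10


@dataclass
class RbEstimate:
    rb: float
    se: float
    n_pairs: int
    pearson: float  # uncorrected correlation, for attenuation comparison


def _rb_from_moments(cov12, v1, v2, mse1, mse2) -> float:
    c1, c2 = v1 - mse1, v2 - mse2
    if c1 <= 0 or c2 <= 0:
        raise ValueError(
            "effects indistinguishable from noise (corrected variance <= 0)"
        )
    return cov12 / np.sqrt(c1 * c2)


def estimate_rb(
    b1: np.ndarray, se1: np.ndarray, b2: np.ndarray, se2: np.ndarray
) -> RbEstimate:
    """Error-corrected effect correlation with delete-one jackknife SE.

    The point estimate is clipped to [-1, 1] with a warning when sampling
    noise pushes it outside the admissible range.
    """
    b1, se1, b2, se2 = (np.asarray(a, dtype=float) for a in (b1, se1, b2, se2))
    n = len(b1)
    if not (len(se1) == len(b2) == len(se2) == n):
        raise ValueError("pair arrays must have equal length")
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} pairs, got {n}")
    if (se1 <= 0).any() or (se2 <= 0).any():
        raise ValueError("standard errors must be positive")

    cov12 = float(np.cov(b1, b2, ddof=1)[0, 1])
    v1 = float(np.var(b1, ddof=1))
    v2 = float(np.var(b2, ddof=1))
    rb = _rb_from_moments(cov12, v1, v2, float(np.mean(se1**2)), float(np.mean(se2**2)))

    # vectorized delete-one jackknife via sum downdates
    s1, s2 = b1.sum(), b2.sum()
    ss1, ss2 = (b1**2).sum(), (b2**2).sum()
    s12 = (b1 * b2).sum()
    t1, t2 = (se1**2).sum(), (se2**2).sum()
    m = n - 1
    mu1 = (s1 - b1) / m
    mu2 = (s2 - b2) / m
    v1_i = (ss1 - b1**2 - m * mu1**2) / (m - 1)
    v2_i = (ss2 - b2**2 - m * mu2**2) / (m - 1)
    cov_i = (s12 - b1 * b2 - m * mu1 * mu2) / (m - 1)
    mse1_i = (t1 - se1**2) / m
    mse2_i = (t2 - se2**2) / m
    denom_i = (v1_i - mse1_i) * (v2_i - mse2_i)
    with np.errstate(invalid="ignore", divide="ignore"):
        rb_i = np.where(denom_i > 0, cov_i / np.sqrt(np.maximum(denom_i, 1e-300)), np.nan)
    valid = np.isfinite(rb_i)
    if valid.sum() < 2:
        se_jack = float("nan")
    else:
        r = rb_i[valid]
        k = len(r)
        se_jack = float(np.sqrt((k - 1) / k * ((r - r.mean()) ** 2).sum()))

    if abs(rb) > 1:
        warnings.warn(
            f"r_b estimate {rb:.3f} outside [-1, 1]; clipped", stacklevel=2
        )
        rb = float(np.clip(rb, -1.0, 1.0))
    pearson = float(np.corrcoef(b1, b2)[0, 1])
    return RbEstimate(rb=float(rb), se=se_jack, n_pairs=n, pearson=pearson)


def rb_matrix(
    cohort_stats: dict[str, pd.DataFrame],
    cohort_leads: dict[str, pd.DataFrame],
    p_lead_max: float = 1.0,
) -> pd.DataFrame:
    """Pairwise r_b table across datasets.

    For each ordered (discovery, replication) pair, lead SNPs are ascertained
    in the discovery dataset only (avoiding joint-minimum ascertainment bias)
    and their effects looked up in the replication dataset's summary
    statistics. Cells with fewer than ``MIN_PAIRS`` overlapping lead SNPs are
    reported missing. The matrix is not symmetric.
    """
    rows = []
    for disc, leads in cohort_leads.items():
        sel = leads[leads["p"] <= p_lead_max]
        for repl, stats_df in cohort_stats.items():
            if repl == disc:
                continue
            lookup = stats_df.set_index(["probe", "snp"])[["beta", "se"]]
            keys = list(zip(sel["probe"], sel["snp"]))
            present = [k in lookup.index for k in keys]
            matched = sel[present]
            n_absent = len(sel) - len(matched)
            if len(matched) < MIN_PAIRS:
                warnings.warn(
                    f"<{MIN_PAIRS} overlapping lead SNPs for ({disc}, {repl})",
                    stacklevel=2,
                )
                rows.append((disc, repl, np.nan, np.nan, len(matched), n_absent, np.nan))
                continue
            rep = lookup.loc[list(zip(matched["probe"], matched["snp"]))]
            est = estimate_rb(
                matched["beta"].to_numpy(), matched["se"].to_numpy(),
                rep["beta"].to_numpy(), rep["se"].to_numpy(),
            )
            rows.append((disc, repl, est.rb, est.se, est.n_pairs, n_absent, est.pearson))
    return pd.DataFrame(
        rows,
        columns=["discovery", "replication", "rb", "se", "n_pairs", "n_absent", "pearson"],
    )
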