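"""Reference-panel LD: pairwise r-squared, LD blocks, and block overlap."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet

R2_STRONG = 0.8


class MonomorphicSNPError(ValueError):
    """LD is undefined for a SNP with zero dosage variance in the panel."""


@dataclass
class LDBlock:
    """SNPs in strong LD with an anchor SNP in one reference panel."""

    anchor: str
    members: dict[str, float]  # snp -> r2 with anchor (anchor itself at 1.0)
    panel: str = ""

    def __post_init__(self) -> None:
        self.members.setdefault(self.anchor, 1.0)

    @property
    def snps(self) -> set[str]:
        return set(self.members)


def _dosage_clean(genos: GenotypeSet, snp: str) -> np.ndarray:
    d = genos.dosage(snp).astype(float)
    if np.isnan(d).any():
        d = np.where(np.isnan(d), np.nanmean(d), d)
    return d


def ld_r2(ref: GenotypeSet, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosages in the reference panel."""
    a = _dosage_clean(ref, snp_a)
    b = _dosage_clean(ref, snp_b)
    if np.var(a) == 0:
        raise MonomorphicSNPError(f"{snp_a} is monomorphic in the panel")
    if np.var(b) == 0:
        raise MonomorphicSNPError(f"{snp_b} is monomorphic in the panel")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def ld_r2_safe(ref: GenotypeSet, snp_a: str, snp_b: str) -> float | None:
    """Like :func:`ld_r2` but returns None for absent/monomorphic SNPs."""
    if snp_a not in ref or snp_b not in ref:
        return None
    try:
        return ld_r2(ref, snp_a, snp_b)
    except MonomorphicSNPError:
        return None


def ld_matrix(ref: GenotypeSet, snp_indices: np.ndarray) -> np.ndarray:
    """Dosage correlation matrix (r, not r^2) over the given variant indices.

    Monomorphic columns get zero off-diagonal correlation (their rows are
    unusable for conditioning and are filtered by callers).
    """
    g = ref.dosages[:, np.asarray(snp_indices, dtype=int)].astype(float)
    if np.isnan(g).any():
        mu = np.nanmean(g, axis=0)
        nan_r, nan_c = np.where(np.isnan(g))
        g = g.copy()
        g[nan_r, nan_c] = mu[nan_c]
    sd = g.std(axis=0)
    ok = sd > 0
    gz = np.zeros_like(g)
    gz[:, ok] = (g[:, ok] - g[:, ok].mean(axis=0)) / sd[ok]
    r = gz.T @ gz / g.shape[0]
    np.fill_diagonal(r, 1.0)
    return r


def ld_block(
    ref: GenotypeSet,
    anchor: str,
    candidate_indices: np.ndarray | None = None,
    r2_min: float = R2_STRONG,
    panel: str = "",
) -> LDBlock:
    """All candidate SNPs with r^2 > ``r2_min`` to the anchor (anchor included)."""
    a = _dosage_clean(ref, anchor)
    if np.var(a) == 0:
        raise MonomorphicSNPError(f"anchor {anchor} is monomorphic in the panel")
    if candidate_indices is None:
        candidate_indices = np.arange(ref.n_snps)
    members: dict[str, float] = {anchor: 1.0}
    g = ref.dosages[:, np.asarray(candidate_indices, dtype=int)].astype(float)
    if np.isnan(g).any():
        mu = np.nanmean(g, axis=0)
        nan_r, nan_c = np.where(np.isnan(g))
        g = g.copy()
        g[nan_r, nan_c] = mu[nan_c]
    sd = g.std(axis=0)
    ok = sd > 0
    az = (a - a.mean()) / a.std()
    with np.errstate(invalid="ignore"):
        r = np.zeros(g.shape[1])
        r[ok] = (g[:, ok] - g[:, ok].mean(axis=0)).T @ az / (len(a) * sd[ok])
    r2 = np.minimum(r * r, 1.0)
    names = ref.variants["snp"].to_numpy()[candidate_indices]
    for name, val, good in zip(names, r2, ok):
        if good and val > r2_min and name != anchor:
            members[name] = float(val)
    return LDBlock(anchor=anchor, members=members, panel=panel)


def blocks_overlap(a: LDBlock, b: LDBlock) -> bool:
    """True iff the two blocks share at least one member SNP."""
    return not a.snps.isdisjoint(b.snps)


def blocks_to_frame(blocks: list[LDBlock]) -> pd.DataFrame:
    rows = [
        (blk.anchor, snp, r2, blk.panel)
        for blk in blocks
        for snp, r2 in sorted(blk.members.items())
    ]
    return pd.DataFrame(rows, columns=["anchor", "member", "r2", "panel"])
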