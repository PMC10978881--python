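"""Stringent / ancestry-specific mQTL sets, hierarchical sharing
classification of cross-ancestry lead-SNP relationships, and
allele-frequency heterogeneity summaries."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from . import ld as ldmod
from .genotypes import GenotypeSet
from .synthdata import EAS, EUR


class SharingCategory(Enum):
    """Hierarchy of evidence for a shared genetic association.

    Rules are exclusive top-down: a probe satisfying an earlier rule is not
    carried into later categories.
    """

    SAME_LEAD_SAME_DIRECTION = "same_lead_same_direction"
    STRONG_LD = "strong_ld"
    BLOCK_OVERLAP = "block_overlap"
    COJO_SAME_SNP = "cojo_same_snp"
    COJO_BLOCK_OVERLAP = "cojo_block_overlap"
    UNEXPLAINED = "unexplained"


SHARED_CATEGORIES = [c for c in SharingCategory if c is not SharingCategory.UNEXPLAINED]

STRINGENT = "STRINGENT"
EUR_SPECIFIC = "EUR_SPECIFIC"
EAS_SPECIFIC = "EAS_SPECIFIC"
OTHER = "OTHER"


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage rounded to the report precision (1 decimal by default)."""
    if total <= 0:
        return 0.0
    return round(100.0 * count / total, decimals)


def define_sets(
    lead_eur: pd.DataFrame,
    lead_eas: pd.DataFrame,
    cohort_leads: list[tuple[str, pd.DataFrame]] | None = None,
    p_sig: float = 1e-10,
    p_rep: float = 1e-6,
) -> pd.DataFrame:
    """Label each probe STRINGENT / EUR_SPECIFIC / EAS_SPECIFIC / OTHER.

    STRINGENT: each ancestry's own lead SNP reaches ``p < p_sig``.
    Ancestry-specific: ``p < p_sig`` in one ancestry while the other
    ancestry's best cis p-value stays above ``p_rep``. Specific probes are
    excluded (flagged, relabelled OTHER) when the two ancestries share the
    same lead SNP or when the probe is significant at ``p_sig`` in an
    individual cohort of the alternate ancestry — both patterns point at
    power rather than genuine ancestry specificity.

    ``cohort_leads`` is a list of (ancestry, per-probe lead table) at the
    individual-cohort level, used only for the second exclusion.
    """
    le = lead_eur.set_index("probe")
    la = lead_eas.set_index("probe")
    cohort_leads = cohort_leads or []
    cohort_sig: dict[str, set[str]] = {EUR: set(), EAS: set()}
    for ancestry, leads in cohort_leads:
        sig = leads.loc[leads["p"] < p_sig, "probe"]
        cohort_sig[ancestry].update(sig)

    rows = []
    for probe in sorted(set(le.index) | set(la.index)):
        in_eur, in_eas = probe in le.index, probe in la.index
        p_e = float(le.loc[probe, "p"]) if in_eur else np.nan
        p_a = float(la.loc[probe, "p"]) if in_eas else np.nan
        same_lead = (
            in_eur and in_eas and le.loc[probe, "snp"] == la.loc[probe, "snp"]
        )
        label, reason = OTHER, ""
        alt_cohort_sig = False
        if not (in_eur and in_eas):
            reason = "absent_in_one_ancestry"
        elif p_e < p_sig and p_a < p_sig:
            label = STRINGENT
        elif p_e < p_sig and p_a > p_rep:
            label = EUR_SPECIFIC
        elif p_a < p_sig and p_e > p_rep:
            label = EAS_SPECIFIC
        else:
            reason = "between_thresholds"
        if label in (EUR_SPECIFIC, EAS_SPECIFIC):
            alt = EAS if label == EUR_SPECIFIC else EUR
            alt_cohort_sig = probe in cohort_sig[alt]
            if same_lead:
                label, reason = OTHER, "excluded_same_lead"
            elif alt_cohort_sig:
                label, reason = OTHER, "excluded_alt_cohort_significant"
        rows.append(
            {
                "probe": probe,
                "label": label,
                "p_eur": p_e,
                "p_eas": p_a,
                "same_lead": same_lead,
                "alt_cohort_sig": alt_cohort_sig,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClassifyContext:
    """Reference panels and windows used by the sharing classifier."""

    panels: dict[str, GenotypeSet]
    r2_strong: float = 0.8
    window: int = 1_000_000

    def window_indices(self, ancestry: str, pos: int) -> np.ndarray:
        var = self.panels[ancestry].variants
        p = var["pos"].to_numpy()
        return np.flatnonzero((p >= pos - self.window) & (p <= pos + self.window))

    def block(self, ancestry: str, snp: str, probe_pos: int) -> ldmod.LDBlock | None:
        panel = self.panels[ancestry]
        if snp not in panel:
            return None
        try:
            return ldmod.ld_block(
                panel, snp, self.window_indices(ancestry, probe_pos),
                r2_min=self.r2_strong, panel=ancestry,
            )
        except ldmod.MonomorphicSNPError:
            return None


def classify_shared_mqtl(
    probe: str,
    lead_eur: pd.Series,
    lead_eas: pd.Series,
    ctx: ClassifyContext,
    probe_pos: int,
    cojo_snps: list[str] | None = None,
) -> tuple[SharingCategory, str]:
    """Apply the sharing hierarchy to one stringent-set probe.

    Rule order: (1) identical lead SNP with matching harmonized effect sign;
    (2) lead-lead r^2 > threshold in either panel; (3) the leads' LD blocks
    (each built in its own ancestry's panel) intersect; (4) the EAS lead is
    among the conditionally independent EUR signals; (5) the EAS lead's
    block intersects any conditional signal's block; otherwise UNEXPLAINED.
    """
    note = ""
    snp_e, snp_a = lead_eur["snp"], lead_eas["snp"]
    if snp_e == snp_a and np.sign(lead_eur["beta"]) == np.sign(lead_eas["beta"]):
        return SharingCategory.SAME_LEAD_SAME_DIRECTION, note

    r2s = []
    for ancestry in (EUR, EAS):
        r2 = ldmod.ld_r2_safe(ctx.panels[ancestry], snp_e, snp_a)
        if r2 is None:
            note = f"ld_unavailable_{ancestry.lower()};" + note
        else:
            r2s.append(r2)
    if any(r2 > ctx.r2_strong for r2 in r2s):
        return SharingCategory.STRONG_LD, note

    block_e = ctx.block(EUR, snp_e, probe_pos)
    block_a = ctx.block(EAS, snp_a, probe_pos)
    if block_e is not None and block_a is not None and ldmod.blocks_overlap(block_e, block_a):
        return SharingCategory.BLOCK_OVERLAP, note

    cojo_snps = cojo_snps or []
    if snp_a in cojo_snps:
        return SharingCategory.COJO_SAME_SNP, note
    if block_a is not None:
        for snp in cojo_snps:
            blk = ctx.block(EUR, snp, probe_pos)
            if blk is not None and ldmod.blocks_overlap(blk, block_a):
                return SharingCategory.COJO_BLOCK_OVERLAP, note
    return SharingCategory.UNEXPLAINED, note


def classify_all(
    labels: pd.DataFrame,
    lead_eur: pd.DataFrame,
    lead_eas: pd.DataFrame,
    probes: pd.DataFrame,
    ctx: ClassifyContext,
    cojo_results: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Run the hierarchy over every stringent-set probe."""
    le = lead_eur.set_index("probe")
    la = lead_eas.set_index("probe")
    pos = dict(zip(probes["probe"], probes["pos"]))
    cojo_results = cojo_results or {}
    rows = []
    for probe in labels.loc[labels["label"] == STRINGENT, "probe"]:
        cat, note = classify_shared_mqtl(
            probe, le.loc[probe], la.loc[probe], ctx, int(pos[probe]),
            cojo_results.get(probe),
        )
        rows.append({"probe": probe, "category": cat.value, "note": note})
    return pd.DataFrame(rows, columns=["probe", "category", "note"])


def tally_categories(
    counts: dict[SharingCategory, int] | pd.Series, total: int | None = None
) -> pd.DataFrame:
    """Counts and percentages per sharing category plus the shared total.

    Percentages are relative to the stringent-set size (``total``, defaulting
    to the sum of counts) and rounded to 1 decimal. "Putative shared" is
    every category except UNEXPLAINED.
    """
    if isinstance(counts, pd.Series):
        counts = {SharingCategory(k): int(v) for k, v in counts.items()}
    full = {c: int(counts.get(c, 0)) for c in SharingCategory}
    if total is None:
        total = sum(full.values())
    rows = [
        {"category": c.value, "count": full[c], "percent": percent(full[c], total)}
        for c in SharingCategory
    ]
    shared = sum(full[c] for c in SHARED_CATEGORIES)
    rows.append(
        {"category": "total_shared", "count": shared, "percent": percent(shared, total)}
    )
    return pd.DataFrame(rows)


def set_report(
    n_probes_analyzed: int,
    n_any_mqtl: int,
    n_stringent: int,
    n_specific: int,
    n_eur_specific: int,
    n_eas_specific: int,
) -> pd.DataFrame:
    """Headline set sizes with report-style percentages.

    Denominator conventions: probes with any significant
    mQTL are a share of all analyzed probes; stringent and ancestry-specific
    sets are shares of probes with any mQTL; the EUR/EAS split is a share of
    the ancestry-specific set.
    """
    rows = [
        ("probes_analyzed", n_probes_analyzed, None, np.nan),
        ("any_mqtl", n_any_mqtl, "probes_analyzed", percent(n_any_mqtl, n_probes_analyzed)),
        ("stringent_both_ancestries", n_stringent, "any_mqtl", percent(n_stringent, n_any_mqtl)),
        ("ancestry_specific", n_specific, "any_mqtl", percent(n_specific, n_any_mqtl)),
        ("eur_specific", n_eur_specific, "ancestry_specific", percent(n_eur_specific, n_specific)),
        ("eas_specific", n_eas_specific, "ancestry_specific", percent(n_eas_specific, n_specific)),
    ]
    return pd.DataFrame(rows, columns=["set", "count", "denominator", "percent"])


def af_heterogeneity(
    labels: pd.DataFrame,
    lead_eur: pd.DataFrame,
    lead_eas: pd.DataFrame,
    panels: dict[str, GenotypeSet],
    rare_af: float = 0.01,
    r2_weak: float = 0.2,
    r2_strong: float = 0.8,
) -> pd.DataFrame:
    """Per ancestry-specific probe: alternate-ancestry MAF and lead-lead LD.

    The LD bucket uses the larger of the two panel r^2 values (either-panel
    rule): ``incalculable`` when neither panel yields an estimate, otherwise
    ``weak`` (< r2_weak), ``intermediate`` or ``strong`` (> r2_strong).
    """
    le = lead_eur.set_index("probe")
    la = lead_eas.set_index("probe")
    rows = []
    for _, row in labels[labels["label"].isin([EUR_SPECIFIC, EAS_SPECIFIC])].iterrows():
        probe = row["probe"]
        own_ancestry = EUR if row["label"] == EUR_SPECIFIC else EAS
        alt_ancestry = EAS if own_ancestry == EUR else EUR
        own_lead = (le if own_ancestry == EUR else la).loc[probe]
        alt_panel = panels[alt_ancestry]
        if own_lead["snp"] in alt_panel:
            af = float(alt_panel.variants.set_index("snp").loc[own_lead["snp"], "af"])
            maf = min(af, 1.0 - af)
            rare = maf < rare_af
        else:
            maf, rare = np.nan, False
        # LD between the two ancestries' leads, either-panel rule
        alt_lead = (la if own_ancestry == EUR else le).loc[probe]
        r2s = [
            r2
            for ancestry in (EUR, EAS)
            if (r2 := ldmod.ld_r2_safe(panels[ancestry], own_lead["snp"], alt_lead["snp"]))
            is not None
        ]
        if not r2s:
            bucket = "incalculable"
        else:
            best = max(r2s)
            bucket = (
                "weak" if best < r2_weak else "strong" if best > r2_strong else "intermediate"
            )
        rows.append(
            {
                "probe": probe,
                "label": row["label"],
                "alt_maf": maf,
                "rare_in_alt": bool(rare),
                "ld_bucket": bucket,
            }
        )
    return pd.DataFrame(
        rows, columns=["probe", "label", "alt_maf", "rare_in_alt", "ld_bucket"]
    )
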