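"""Single-causal-variant Bayesian fine mapping and credible sets.

With the number of causal signals fixed at one, sum-of-single-effects fine
mapping collapses to Wakefield approximate Bayes factors under a uniform
causal prior across the cis window. Cross-ancestry fine mapping multiplies
the per-population Bayes factors (independent samples, shared causal
position, population-specific effect sizes), which concentrates posterior
mass on SNPs supported by both LD structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import synthdata
from .assoc import scan_cohort
from .preprocess import rank_int
from .synthdata import EAS, EUR, PopulationModel

MODE_CROSS = "CROSS"


@dataclass
class PriorSpec:
    """Grid of prior effect-variance values on the standardized scale.

    Bayes factors are averaged over the grid, avoiding a per-locus prior
    optimization step.
    """

    w_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.4)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.w_grid):
            raise ValueError("all prior variances must be positive")


@dataclass
class CredibleSet:
    probe: str
    mode: str  # EUR, EAS, or CROSS
    members: dict[str, float]  # snp -> PIP, insertion order = descending PIP
    size: int
    coverage: float = 0.95

    @property
    def snps(self) -> list[str]:
        return list(self.members)


def log_abf(beta: float | np.ndarray, se: float | np.ndarray, w: float) -> np.ndarray:
    """Log approximate Bayes factor for association versus a null effect.

    ``log ABF = 0.5 log(se^2/(se^2+W)) + z^2 W / (2 (se^2+W))`` with
    ``z = beta/se``. Positive values favour association; W -> 0 gives 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if w <= 0:
        raise ValueError("prior variance must be positive")
    v = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + z2 * w / (2.0 * (v + w))


def _log_bf_grid(beta: np.ndarray, se: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Per-SNP log Bayes factor averaged over the prior-variance grid."""
    lbf = np.stack([log_abf(beta, se, w) for w in prior.w_grid])
    return logsumexp(lbf, axis=0) - np.log(len(prior.w_grid))


def pips_single(stats_df: pd.DataFrame, prior: PriorSpec | None = None) -> pd.DataFrame:
    """Posterior inclusion probabilities under a single causal variant.

    Uniform causal prior over the window SNPs; PIP_j = BF_j / sum_k BF_k.
    Returns a frame with columns ``snp, pos, pip`` summing to 1.
    """
    if len(stats_df) == 0:
        raise ValueError("empty cis window")
    prior = prior or PriorSpec()
    lbf = _log_bf_grid(stats_df["beta"].to_numpy(), stats_df["se"].to_numpy(), prior)
    pip = np.exp(lbf - logsumexp(lbf))
    return pd.DataFrame(
        {"snp": stats_df["snp"].to_numpy(), "pos": stats_df["pos"].to_numpy(), "pip": pip}
    )


def pips_cross(
    stats_eur: pd.DataFrame,
    stats_eas: pd.DataFrame,
    prior: PriorSpec | None = None,
) -> pd.DataFrame:
    """Cross-ancestry PIPs from the product of per-population Bayes factors.

    SNP universes are joined on the union of the two windows; a SNP missing
    in one population contributes BF = 1 there. SNPs absent from both are
    excluded by construction.
    """
    prior = prior or PriorSpec()
    frames = {}
    for label, df in ((EUR, stats_eur), (EAS, stats_eas)):
        if len(df):
            lbf = _log_bf_grid(df["beta"].to_numpy(), df["se"].to_numpy(), prior)
            frames[label] = pd.DataFrame(
                {"snp": df["snp"].to_numpy(), "pos": df["pos"].to_numpy(), "lbf": lbf}
            ).set_index("snp")
    if not frames:
        raise ValueError("no statistics in either population")
    union = pd.concat(frames.values()).groupby(level=0).agg(pos=("pos", "first"))
    total = np.zeros(len(union))
    for f in frames.values():
        total += f["lbf"].reindex(union.index).fillna(0.0).to_numpy()
    pip = np.exp(total - logsumexp(total))
    out = union.reset_index().rename(columns={"index": "snp"})
    out["pip"] = pip
    return out.sort_values("pos", kind="mergesort").reset_index(drop=True)


def credible_set(
    pips: pd.DataFrame, probe: str = "", mode: str = EUR, coverage: float = 0.95
) -> CredibleSet:
    """Smallest set of SNPs whose PIPs reach the coverage target.

    SNPs enter in descending PIP order, with exact PIP ties broken by
    genomic position; the prefix stops as soon as cumulative PIP >= coverage.
    """
    total = float(pips["pip"].sum())
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"PIPs must be normalized (sum {total:.6f})")
    df = pips.sort_values(["pip", "pos"], ascending=[False, True], kind="mergesort")
    csum = df["pip"].cumsum().to_numpy()
    k = int(np.searchsorted(csum, coverage - 1e-12) + 1)
    k = min(k, len(df))
    chosen = df.iloc[:k]
    return CredibleSet(
        probe=probe,
        mode=mode,
        members=dict(zip(chosen["snp"], chosen["pip"])),
        size=k,
        coverage=coverage,
    )


def dedupe_leads(leads: pd.DataFrame) -> pd.DataFrame:
    """Keep only the smallest-p probe among probes sharing a lead SNP."""
    df = leads.sort_values(["p", "probe"], kind="mergesort")
    return df.drop_duplicates(subset="snp", keep="first").sort_index()


def read_bed_mask(path) -> pd.DataFrame:
    """Region mask as BED (0-based half-open): chrom, start, end."""
    return pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )


def mask_probes(probes: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Drop probes falling inside any masked region."""
    keep = np.ones(len(probes), dtype=bool)
    for _, reg in mask.iterrows():
        inside = (
            (probes["chrom"].astype(str) == reg["chrom"])
            & (probes["pos"] > reg["start"])  # BED start is 0-based
            & (probes["pos"] <= reg["end"])
        )
        keep &= ~inside.to_numpy()
    return probes[keep].reset_index(drop=True)


def filter_outlier_sets(
    sets_by_mode: dict[str, dict[str, CredibleSet]],
    iqr_mult: float = 3.0,
) -> tuple[dict[str, dict[str, CredibleSet]], pd.DataFrame]:
    """Drop probes whose set size is a gross outlier in at least one mode.

    A probe is excluded when, in any mode, its credible-set size exceeds
    ``mean + iqr_mult * IQR`` of that mode's sizes (strict inequality, so a
    degenerate IQR of 0 keeps everything at the mean).
    """
    excluded: set[str] = set()
    log_rows = []
    for mode, sets in sets_by_mode.items():
        if len(sets) < 4:
            continue
        sizes = np.array([cs.size for cs in sets.values()], dtype=float)
        q75, q25 = np.percentile(sizes, [75, 25])
        cutoff = sizes.mean() + iqr_mult * (q75 - q25)
        for probe, cs in sets.items():
            if cs.size > cutoff:
                excluded.add(probe)
                log_rows.append({"probe": probe, "mode": mode, "size": cs.size, "cutoff": cutoff})
    filtered = {
        mode: {p: cs for p, cs in sets.items() if p not in excluded}
        for mode, sets in sets_by_mode.items()
    }
    return filtered, pd.DataFrame(log_rows, columns=["probe", "mode", "size", "cutoff"])


# ---------------------------------------------------------------------------
# Sample-size versus resolution experiment


@dataclass
class ExperimentInputs:
    """Frozen inputs for the resolution experiment: generator + causal truth."""

    model: PopulationModel
    afs_eur: np.ndarray
    afs_eas: np.ndarray
    probes: pd.DataFrame
    causal_index: np.ndarray
    b_eur: np.ndarray
    b_eas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.b_eas is None:
            self.b_eas = self.b_eur


def _simulated_scan(
    inputs: ExperimentInputs,
    population: str,
    n: int,
    seed: int,
    window: int,
) -> pd.DataFrame:
    afs = inputs.afs_eas if population == EAS else inputs.afs_eur
    b = inputs.b_eas if population == EAS else inputs.b_eur
    genos = synthdata.simulate_genotypes(inputs.model, afs, n, seed, population=population)
    truth = synthdata.SimTruth(
        probes=list(inputs.probes["probe"]),
        causal_index=inputs.causal_index,
        b_eur=b,
        b_eas=b,
        rho_b=1.0,
    )
    meth = synthdata.simulate_methylation(genos, truth, None, seed=seed + 1, population=population)
    normed = pd.DataFrame(
        np.vstack([rank_int(row) for row in meth.to_numpy()]),
        index=meth.index, columns=meth.columns,
    )
    return scan_cohort(normed, genos, inputs.probes, window=window)


def _sizes_from_scans(
    scan_eur: pd.DataFrame,
    scan_eas: pd.DataFrame | None,
    probes: pd.DataFrame,
    prior: PriorSpec,
    coverage: float,
    mode: str,
) -> list[int]:
    sizes = []
    eas_by_probe = (
        dict(tuple(scan_eas.groupby("probe", sort=False))) if scan_eas is not None else {}
    )
    for probe, grp in scan_eur.groupby("probe", sort=False):
        if scan_eas is None:
            pips = pips_single(grp, prior)
        else:
            pips = pips_cross(grp, eas_by_probe.get(probe, grp.iloc[0:0]), prior)
        sizes.append(credible_set(pips, probe=str(probe), mode=mode, coverage=coverage).size)
    return sizes


def sample_size_experiment(
    inputs: ExperimentInputs,
    n_grid: list[int],
    seed: int,
    eas_add: int = 0,
    window: int = 1_000_000,
    prior: PriorSpec | None = None,
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Credible-set size as a function of discovery sample size.

    For each ``n`` in the ascending grid a fresh EUR cohort of size ``n`` is
    simulated with each probe's designated causal SNP and effect, scanned,
    and fine mapped; with ``eas_add > 0`` an EAS cohort of that size is
    additionally simulated and cross-ancestry sets are recorded at each grid
    point. Deterministic given ``seed``.
    """
    if any(n < 50 for n in n_grid):
        raise ValueError("grid sample sizes below 50 are refused")
    if sorted(n_grid) != list(n_grid):
        raise ValueError("n_grid must be ascending")
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        scan_eur = _simulated_scan(inputs, EUR, n, int(rng.integers(2**31)), window)
        sizes = _sizes_from_scans(scan_eur, None, inputs.probes, prior, coverage, EUR)
        rows.append((EUR, n, 0, n, float(np.mean(sizes)), float(np.median(sizes)), len(sizes)))
        if eas_add > 0:
            scan_eas = _simulated_scan(inputs, EAS, eas_add, int(rng.integers(2**31)), window)
            sizes = _sizes_from_scans(scan_eur, scan_eas, inputs.probes, prior, coverage, MODE_CROSS)
            rows.append(
                (MODE_CROSS, n, eas_add, n + eas_add,
                 float(np.mean(sizes)), float(np.median(sizes)), len(sizes))
            )
    return pd.DataFrame(
        rows,
        columns=["mode", "n_eur", "n_eas", "n_total", "mean_size", "median_size", "n_probes"],
    )
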