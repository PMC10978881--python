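"""Two-population synthetic data with known ground truth.

Generates genotype panels for two diverged populations (Balding-Nichols
allele-frequency model, population-specific LD blocks from a thresholded
AR(1) latent Gaussian), methylation phenotypes with cross-population
correlated causal effects, and covariate/batch structure. Every downstream
stage of the pipeline can be exercised against the recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeSet, write_dosage_tsv, write_vcf

EUR = "EUR"
EAS = "EAS"


@dataclass
class PopulationModel:
    """Parameters of the two-population genotype generator.

    ``block_lengths`` partitions the ``n_snps`` SNPs into LD blocks; within a
    block the latent Gaussian used to generate haplotypes has AR(1)
    correlation ``rho ** |i - j|`` with population-specific ``rho``. EAS block
    boundaries are shifted by ``eas_block_shift`` SNPs so the two populations
    tag a shared causal variant with different neighbours.
    """

    n_snps: int
    block_lengths: list[int]
    rho_eur: float = 0.9
    rho_eas: float = 0.9
    fst: float = 0.1
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    chrom: str = "1"
    snp_spacing: int = 5000
    eas_block_shift: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if sum(self.block_lengths) != self.n_snps:
            raise ValueError("sum(block_lengths) must equal n_snps")
        for rho in (self.rho_eur, self.rho_eas):
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"rho must be in [0, 1), got {rho}")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        lo, hi = self.ancestral_af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_af_range must lie within (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def positions(self) -> np.ndarray:
        return (np.arange(self.n_snps) + 1) * self.snp_spacing

    def snp_ids(self) -> list[str]:
        return [f"snp{i + 1}" for i in range(self.n_snps)]

    def block_bounds(self, population: str) -> list[tuple[int, int]]:
        """Half-open [start, stop) block bounds for the given population."""
        shift = self.eas_block_shift if population == EAS else 0
        edges = np.cumsum([0] + list(self.block_lengths))
        if shift:
            cuts = sorted({0, self.n_snps, *(int((e + shift) % self.n_snps) for e in edges[1:-1])})
            cuts = [c for c in cuts if 0 <= c <= self.n_snps]
            if cuts[0] != 0:
                cuts.insert(0, 0)
            if cuts[-1] != self.n_snps:
                cuts.append(self.n_snps)
            edges = np.array(cuts)
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def rho(self, population: str) -> float:
        return self.rho_eas if population == EAS else self.rho_eur


def sample_population_afs(model: PopulationModel) -> pd.DataFrame:
    """Draw ancestral and per-population allele frequencies.

    Ancestral frequency ``f`` is uniform on ``ancestral_af_range``; each
    population frequency is Beta(f(1-F)/F, (1-f)(1-F)/F) with F = ``fst``
    (the Balding-Nichols model), so E[f_pop] = f and
    Var[f_pop] = F f(1-f).

    Returns a DataFrame with columns ``f_anc, f_eur, f_eas``.
    """
    rng = np.random.default_rng(model.seed)
    lo, hi = model.ancestral_af_range
    f = rng.uniform(lo, hi, size=model.n_snps)
    scale = (1.0 - model.fst) / model.fst
    f_eur = rng.beta(f * scale, (1.0 - f) * scale)
    f_eas = rng.beta(f * scale, (1.0 - f) * scale)
    return pd.DataFrame({"f_anc": f, "f_eur": f_eur, "f_eas": f_eas})


def _simulate_haplotypes(
    afs: np.ndarray,
    bounds: list[tuple[int, int]],
    rho: float,
    n_haplotypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype alleles by thresholding a blockwise-AR(1) latent Gaussian.

    A SNP with frequency ``p`` carries the alternate allele when its latent
    value falls below ``Phi^{-1}(p)``; adjacent within-block latents have
    correlation ``rho ** distance``, giving tunable LD.
    """
    n_snps = len(afs)
    z = np.empty((n_haplotypes, n_snps))
    innov = rng.standard_normal((n_haplotypes, n_snps))
    sqrt1m = np.sqrt(1.0 - rho * rho)
    for start, stop in bounds:
        z[:, start] = innov[:, start]
        for j in range(start + 1, stop):
            z[:, j] = rho * z[:, j - 1] + sqrt1m * innov[:, j]
    thresholds = stats.norm.ppf(np.clip(afs, 0.0, 1.0))
    return (z < thresholds[None, :]).astype(np.int8)


def simulate_genotypes(
    model: PopulationModel,
    afs: np.ndarray,
    n_individuals: int,
    seed: int,
    population: str = EUR,
    sample_prefix: str | None = None,
) -> GenotypeSet:
    """Diploid dosages for one cohort/panel of the given population.

    Genotype = sum of two independent haplotypes; dosages in {0, 1, 2} with
    NaN injected at ``model.missing_rate``.
    """
    afs = np.asarray(afs, dtype=float)
    if len(afs) != model.n_snps:
        raise ValueError("afs length must equal model.n_snps")
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    rng = np.random.default_rng(seed)
    bounds = model.block_bounds(population)
    rho = model.rho(population)
    haps = _simulate_haplotypes(afs, bounds, rho, 2 * n_individuals, rng)
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    if model.missing_rate > 0:
        mask = rng.random(dosages.shape) < model.missing_rate
        dosages[mask] = np.nan
    prefix = sample_prefix or f"{population.lower()}"
    samples = [f"{prefix}_{i + 1}" for i in range(n_individuals)]
    with np.errstate(invalid="ignore"):
        realized = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "snp": model.snp_ids(),
            "chrom": model.chrom,
            "pos": model.positions(),
            "ref": "A",
            "alt": "G",
            "af": realized,
            "info": 1.0,
        }
    )
    return GenotypeSet(dosages=dosages, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# Phenotype truth


@dataclass
class SimTruth:
    """Ground truth for simulated methylation probes."""

    probes: list[str]
    causal_index: np.ndarray  # SNP column index per probe
    b_eur: np.ndarray  # causal effect, phenotype-SD units
    b_eas: np.ndarray
    rho_b: float
    noise_var: float = 1.0
    covar_effects: dict[str, float] = field(default_factory=dict)
    batch_effect: float = 0.0

    def effects(self, population: str) -> np.ndarray:
        return self.b_eas if population == EAS else self.b_eur

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probes": self.probes,
            "causal_index": self.causal_index.tolist(),
            "b_eur": self.b_eur.tolist(),
            "b_eas": self.b_eas.tolist(),
            "rho_b": self.rho_b,
            "noise_var": self.noise_var,
            "covar_effects": self.covar_effects,
            "batch_effect": self.batch_effect,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            probes=d["probes"],
            causal_index=np.array(d["causal_index"], dtype=int),
            b_eur=np.array(d["b_eur"]),
            b_eas=np.array(d["b_eas"]),
            rho_b=d["rho_b"],
            noise_var=d["noise_var"],
            covar_effects=d["covar_effects"],
            batch_effect=d["batch_effect"],
        )


def draw_effect_pairs(
    n_probes: int,
    rho_b: float,
    effect_sd: float,
    rng: np.random.Generator,
    private_frac_eur: float = 0.0,
    private_frac_eas: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal effect pairs with correlation ``rho_b``.

    A ``private_frac_eur`` fraction of probes has its EAS effect zeroed
    (EUR-private causal variant) and vice versa; private probes are disjoint.
    """
    if not -1.0 <= rho_b <= 1.0:
        raise ValueError("rho_b must be in [-1, 1]")
    cov = effect_sd**2 * np.array([[1.0, rho_b], [rho_b, 1.0]])
    pairs = rng.multivariate_normal([0.0, 0.0], cov, size=n_probes)
    b_eur, b_eas = pairs[:, 0].copy(), pairs[:, 1].copy()
    n_priv_eur = int(round(private_frac_eur * n_probes))
    n_priv_eas = int(round(private_frac_eas * n_probes))
    order = rng.permutation(n_probes)
    b_eas[order[:n_priv_eur]] = 0.0
    b_eur[order[n_priv_eur : n_priv_eur + n_priv_eas]] = 0.0
    return b_eur, b_eas


def make_probes(
    model: PopulationModel,
    n_probes: int,
    rng: np.random.Generator,
    max_offset: int = 50_000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Probe table plus the causal SNP index per probe.

    Each probe is anchored near a randomly chosen causal SNP (within
    ``max_offset`` bp) so the causal SNP always lies inside the probe's cis
    window.
    """
    if n_probes > model.n_snps:
        raise ValueError("more probes than SNPs")
    causal = rng.choice(model.n_snps, size=n_probes, replace=False)
    positions = model.positions()[causal]
    offsets = rng.integers(-max_offset, max_offset + 1, size=n_probes)
    probe_pos = np.maximum(1, positions + offsets)
    probes = pd.DataFrame(
        {
            "probe": [f"cg{i + 1:06d}" for i in range(n_probes)],
            "chrom": model.chrom,
            "pos": probe_pos,
        }
    )
    return probes, causal


def simulate_covariates(
    n_individuals: int, rng: np.random.Generator, n_batches: int = 2
) -> pd.DataFrame:
    """Sex, age, age^2, two cell proportions, and a batch label."""
    sex = rng.integers(0, 2, size=n_individuals)
    age = rng.uniform(20, 80, size=n_individuals)
    cd4 = rng.beta(8, 12, size=n_individuals)
    mono = rng.beta(2, 18, size=n_individuals)
    batch = rng.integers(0, n_batches, size=n_individuals)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "age2": age**2,
            "cd4t": cd4,
            "mono": mono,
            "batch": [f"b{b + 1}" for b in batch],
        }
    )


def simulate_methylation(
    genos: GenotypeSet,
    truth: SimTruth,
    covariates: pd.DataFrame | None,
    seed: int,
    population: str = EUR,
    beta_scale: bool = False,
) -> pd.DataFrame:
    """Probe x individual methylation values.

    ``y = dosage * b_pop + covariates @ gamma + batch offsets + noise``. With
    ``beta_scale`` the latent values are squashed to (0, 100) by a logistic
    map (array Beta-value convention).
    """
    rng = np.random.default_rng(seed)
    n_ind = genos.n_individuals
    if covariates is not None and len(covariates) != n_ind:
        raise ValueError("covariates do not match genotype individuals")
    b = truth.effects(population)
    if len(b) != len(truth.probes):
        raise ValueError("effect vector length mismatch")
    if (truth.causal_index < 0).any() or (truth.causal_index >= genos.n_snps).any():
        raise ValueError("causal index out of range")
    dos = genos.dosages[:, truth.causal_index]  # (n_ind, n_probes)
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos = dos.copy()
        dos[nan_r, nan_c] = col_mean[nan_c]
    base = dos * b[None, :]  # (n_ind, n_probes)
    covar_part = np.zeros(n_ind)
    if covariates is not None:
        for name, gamma in truth.covar_effects.items():
            covar_part = covar_part + gamma * covariates[name].to_numpy(dtype=float)
        if truth.batch_effect and "batch" in covariates:
            codes = pd.Categorical(covariates["batch"]).codes
            covar_part = covar_part + truth.batch_effect * codes
    noise = rng.standard_normal((n_ind, len(truth.probes))) * np.sqrt(truth.noise_var)
    y = base + covar_part[:, None] + noise
    if beta_scale:
        y = 100.0 / (1.0 + np.exp(-y / 2.0))
    return pd.DataFrame(y.T, index=truth.probes, columns=genos.samples)


# ---------------------------------------------------------------------------
# Whole-study convenience layer


@dataclass
class CohortSpec:
    name: str
    ancestry: str  # EUR or EAS
    n: int


@dataclass
class Cohort:
    name: str
    ancestry: str
    genos: GenotypeSet
    covariates: pd.DataFrame
    methylation: pd.DataFrame  # raw probe x individual values


@dataclass
class Study:
    model: PopulationModel
    afs: pd.DataFrame
    panels: dict[str, GenotypeSet]
    cohorts: list[Cohort]
    probes: pd.DataFrame
    truth: SimTruth

    def cohorts_of(self, ancestry: str) -> list[Cohort]:
        return [c for c in self.cohorts if c.ancestry == ancestry]


def simulate_study(
    model: PopulationModel,
    cohort_specs: list[CohortSpec],
    n_probes: int,
    rho_b: float = 0.9,
    effect_sd: float = 0.5,
    noise_var: float = 1.0,
    private_frac_eur: float = 0.0,
    private_frac_eas: float = 0.0,
    panel_n: int = 500,
    covar_effects: dict[str, float] | None = None,
    batch_effect: float = 0.0,
    beta_scale: bool = False,
) -> Study:
    """Simulate reference panels, cohorts, probes, phenotypes, and truth."""
    rng = np.random.default_rng(model.seed)
    afs = sample_population_afs(model)
    probes, causal = make_probes(model, n_probes, rng)
    b_eur, b_eas = draw_effect_pairs(
        n_probes, rho_b, effect_sd, rng,
        private_frac_eur=private_frac_eur, private_frac_eas=private_frac_eas,
    )
    truth = SimTruth(
        probes=list(probes["probe"]),
        causal_index=causal,
        b_eur=b_eur,
        b_eas=b_eas,
        rho_b=rho_b,
        noise_var=noise_var,
        covar_effects=covar_effects or {},
        batch_effect=batch_effect,
    )
    pop_af = {EUR: afs["f_eur"].to_numpy(), EAS: afs["f_eas"].to_numpy()}
    panels = {
        EUR: simulate_genotypes(
            model, pop_af[EUR], panel_n, seed=int(rng.integers(2**31)),
            population=EUR, sample_prefix="ref_eur",
        ),
        EAS: simulate_genotypes(
            model, pop_af[EAS], panel_n, seed=int(rng.integers(2**31)),
            population=EAS, sample_prefix="ref_eas",
        ),
    }
    cohorts = []
    for spec in cohort_specs:
        genos = simulate_genotypes(
            model, pop_af[spec.ancestry], spec.n, seed=int(rng.integers(2**31)),
            population=spec.ancestry, sample_prefix=spec.name,
        )
        covars = simulate_covariates(spec.n, rng)
        meth = simulate_methylation(
            genos, truth, covars, seed=int(rng.integers(2**31)),
            population=spec.ancestry, beta_scale=beta_scale,
        )
        cohorts.append(Cohort(spec.name, spec.ancestry, genos, covars, meth))
    return Study(model=model, afs=afs, panels=panels, cohorts=cohorts, probes=probes, truth=truth)


def write_study(study: Study, outdir: str | Path) -> None:
    """Materialize a study as plain-text files (VCF/TSV/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    study.afs.to_csv(outdir / "allele_freqs.tsv", sep="\t", index=False)
    study.truth.to_json(outdir / "truth.json")
    for label, panel in study.panels.items():
        write_vcf(panel, outdir / f"panel_{label.lower()}.vcf")
    for cohort in study.cohorts:
        write_vcf(cohort.genos, outdir / f"{cohort.name}.vcf")
        write_dosage_tsv(cohort.genos, outdir / f"{cohort.name}.dosage.tsv")
        cohort.covariates.to_csv(outdir / f"{cohort.name}.covariates.tsv", sep="\t", index=False)
        cohort.methylation.to_csv(outdir / f"{cohort.name}.methylation.tsv", sep="\t")
    manifest = pd.DataFrame(
        [(c.name, c.ancestry, c.genos.n_individuals) for c in study.cohorts],
        columns=["cohort", "ancestry", "n"],
    )
    manifest.to_csv(outdir / "cohorts.tsv", sep="\t", index=False)
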