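"""Pipeline orchestration: simulate -> QC -> scan -> meta -> r_b -> sets ->
COJO -> classification -> fine mapping -> resolution experiment -> SMR.

All stages run in memory on a simulated study and write plain-text reports;
every output file carries the seed and a config hash in header comments so
reruns are verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, classify, cojo, finemap, rb, smr, synthdata
from .preprocess import QCThresholds, adjust_methylation, qc_genotypes, rank_int_rows
from .synthdata import EAS, EUR, CohortSpec, PopulationModel

STAGES = [
    "simulate", "qc", "adjust", "scan", "meta", "rb", "sets",
    "cojo", "classify", "afhet", "finemap", "simsize", "smr",
]

_REQUIRES = {
    "qc": ["simulate"],
    "adjust": ["simulate"],
    "scan": ["qc", "adjust"],
    "meta": ["scan"],
    "rb": ["scan"],
    "sets": ["meta"],
    "cojo": ["meta"],
    "classify": ["sets", "cojo"],
    "afhet": ["sets"],
    "finemap": ["sets"],
    "simsize": ["simulate"],
    "smr": ["sets"],
}


class PipelineDependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Single document of every knob the pipeline uses; analysis thresholds
    are defaults here and never hard-coded downstream."""

    seed: int = 1
    # simulation
    n_snps: int = 400
    n_blocks: int = 40
    rho_eur: float = 0.9
    rho_eas: float = 0.9
    fst: float = 0.1
    eas_block_shift: int = 5
    snp_spacing: int = 5000
    n_probes: int = 300
    panel_n: int = 400
    rho_b: float = 0.9
    effect_sd: float = 0.5
    noise_var: float = 1.0
    private_frac_eur: float = 0.1
    private_frac_eas: float = 0.1
    cohorts: list[dict] = field(
        default_factory=lambda: [
            {"name": "eur_a", "ancestry": EUR, "n": 800},
            {"name": "eur_b", "ancestry": EUR, "n": 800},
            {"name": "eas_a", "ancestry": EAS, "n": 800},
        ]
    )
    # thresholds
    p_sig: float = 1e-10
    p_rep: float = 1e-6
    r2_strong: float = 0.8
    r2_weak: float = 0.2
    rare_af: float = 0.01
    coverage: float = 0.95
    cis_window: int = 1_000_000
    cojo_p: float = 1e-10
    p_smr: float = smr.P_SMR_DEFAULT
    p_heidi: float = smr.P_HEIDI_MIN
    gwas_sig: float = smr.GWAS_SIG
    # stage behaviour
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    simsize_grid: list[int] = field(default_factory=lambda: [300, 600])
    simsize_probes: int = 60
    simsize_eas_add: int = 300
    smr_n_gwas: int = 1500
    smr_n_traits: int = 2

    def __post_init__(self) -> None:
        for name in ("p_sig", "p_rep", "rare_af", "coverage", "r2_strong", "r2_weak"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in STAGES}

    def model(self) -> PopulationModel:
        base, extra = divmod(self.n_snps, self.n_blocks)
        lengths = [base + (1 if i < extra else 0) for i in range(self.n_blocks)]
        return PopulationModel(
            n_snps=self.n_snps,
            block_lengths=lengths,
            rho_eur=self.rho_eur,
            rho_eas=self.rho_eas,
            fst=self.fst,
            eas_block_shift=self.eas_block_shift,
            snp_spacing=self.snp_spacing,
            seed=self.seed,
        )

    def cohort_specs(self) -> list[CohortSpec]:
        return [CohortSpec(c["name"], c["ancestry"], int(c["n"])) for c in self.cohorts]

    def sha(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed} config_sha={config.sha()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class PipelineState:
    """Accumulated in-memory products keyed by stage."""

    study: synthdata.Study | None = None
    qc_genos: dict[str, object] = field(default_factory=dict)
    phenotypes: dict[str, pd.DataFrame] = field(default_factory=dict)
    cohort_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    cohort_leads: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta_leads: dict[str, pd.DataFrame] = field(default_factory=dict)
    labels: pd.DataFrame | None = None
    cojo_results: dict[str, cojo.ConditionalResult] = field(default_factory=dict)
    done: set[str] = field(default_factory=set)


def _check_deps(stage: str, state: PipelineState) -> None:
    for dep in _REQUIRES.get(stage, []):
        if dep not in state.done:
            raise PipelineDependencyError(
                f"stage '{stage}' requires output of stage '{dep}', which did "
                "not run (disabled in config or failed); enable it and rerun"
            )


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, upto: str | None = None
) -> PipelineState:
    """Execute the enabled stages in order, writing reports under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    state = PipelineState()
    stages = STAGES if upto is None else STAGES[: STAGES.index(upto) + 1]
    for stage in stages:
        if not config.stages.get(stage, True):
            continue
        _check_deps(stage, state)
        _STAGE_FNS[stage](config, state, outdir)
        state.done.add(stage)
    return state


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    study = synthdata.simulate_study(
        config.model(),
        config.cohort_specs(),
        n_probes=config.n_probes,
        rho_b=config.rho_b,
        effect_sd=config.effect_sd,
        noise_var=config.noise_var,
        private_frac_eur=config.private_frac_eur,
        private_frac_eas=config.private_frac_eas,
        panel_n=config.panel_n,
    )
    state.study = study
    synthdata.write_study(study, outdir / "data")


def _stage_qc(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    th = QCThresholds()
    logs = []
    for cohort in state.study.cohorts:
        filtered, log = qc_genotypes(cohort.genos, th)
        state.qc_genos[cohort.name] = filtered
        log = log.assign(cohort=cohort.name)
        logs.append(log)
    _write(
        pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(),
        outdir / "qc_exclusions.tsv", config,
    )


def _stage_adjust(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    for cohort in state.study.cohorts:
        resid = adjust_methylation(cohort.methylation, cohort.covariates)
        state.phenotypes[cohort.name] = rank_int_rows(resid)


def _stage_scan(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    counts = []
    for cohort in state.study.cohorts:
        genos = state.qc_genos[cohort.name]
        stats = assoc.scan_cohort(
            state.phenotypes[cohort.name], genos, state.study.probes,
            window=config.cis_window,
        )
        leads = assoc.lead_snps(stats, state.study.probes, ancestry=cohort.ancestry)
        state.cohort_stats[cohort.name] = stats
        state.cohort_leads[cohort.name] = leads
        _write(leads, outdir / f"leads_{cohort.name}.tsv", config)
        counts.append(
            (cohort.name, cohort.ancestry, len(leads),
             int((leads["p"] < config.p_sig).sum()))
        )
    _write(
        pd.DataFrame(counts, columns=["cohort", "ancestry", "n_probes_scanned", "n_significant"]),
        outdir / "scan_counts.tsv", config,
    )


def _stage_meta(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    for ancestry in (EUR, EAS):
        names = [c.name for c in state.study.cohorts_of(ancestry)]
        if not names:
            continue
        meta = assoc.ivw_meta([state.cohort_stats[n] for n in names])
        leads = assoc.lead_snps(meta, state.study.probes, ancestry=ancestry)
        state.meta_stats[ancestry] = meta
        state.meta_leads[ancestry] = leads
        _write(leads, outdir / f"meta_leads_{ancestry.lower()}.tsv", config)


def _stage_rb(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = rb.rb_matrix(state.cohort_stats, state.cohort_leads)
    _write(table, outdir / "rb_matrix.tsv", config)


def _stage_sets(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    cohort_leads = [
        (c.ancestry, state.cohort_leads[c.name]) for c in state.study.cohorts
    ]
    labels = classify.define_sets(
        state.meta_leads[EUR], state.meta_leads[EAS], cohort_leads,
        p_sig=config.p_sig, p_rep=config.p_rep,
    )
    state.labels = labels
    _write(labels, outdir / "set_labels.tsv", config)
    n_any = int(
        ((labels["p_eur"] < config.p_sig) | (labels["p_eas"] < config.p_sig)).sum()
    )
    n_specific = int(labels["label"].isin([classify.EUR_SPECIFIC, classify.EAS_SPECIFIC]).sum())
    report = classify.set_report(
        n_probes_analyzed=len(state.study.probes),
        n_any_mqtl=n_any,
        n_stringent=int((labels["label"] == classify.STRINGENT).sum()),
        n_specific=n_specific,
        n_eur_specific=int((labels["label"] == classify.EUR_SPECIFIC).sum()),
        n_eas_specific=int((labels["label"] == classify.EAS_SPECIFIC).sum()),
    )
    _write(report, outdir / "set_report.tsv", config)


def _stage_cojo(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    # conditional analysis runs for EUR only by default (reference-panel size guard)
    stringent = set(state.labels.loc[state.labels["label"] == classify.STRINGENT, "probe"])
    stats = state.meta_stats[EUR]
    stats = stats[stats["probe"].isin(stringent)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state.cojo_results = cojo.cojo_all(
            stats, state.study.panels[EUR], p_thresh=config.cojo_p
        )
    frames = [r.to_frame() for r in state.cojo_results.values()]
    _write(
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["probe", "snp", "order", "joint_beta", "joint_se", "cond_p"]
        ),
        outdir / "cojo.tsv", config,
    )


def _stage_classify(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    ctx = classify.ClassifyContext(
        panels=state.study.panels, r2_strong=config.r2_strong, window=config.cis_window
    )
    cojo_snps = {p: r.snps for p, r in state.cojo_results.items()}
    cats = classify.classify_all(
        state.labels, state.meta_leads[EUR], state.meta_leads[EAS],
        state.study.probes, ctx, cojo_snps,
    )
    _write(cats, outdir / "sharing_categories.tsv", config)
    counts = cats["category"].value_counts()
    tally = classify.tally_categories(counts, total=len(cats))
    _write(tally, outdir / "sharing_tally.tsv", config)
    tally_json = {
        row["category"]: {"count": int(row["count"]), "percent": float(row["percent"])}
        for _, row in tally.iterrows()
    }
    (outdir / "sharing_tally.json").write_text(json.dumps(tally_json, indent=1))


def _stage_afhet(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    het = classify.af_heterogeneity(
        state.labels, state.meta_leads[EUR], state.meta_leads[EAS],
        state.study.panels, rare_af=config.rare_af,
        r2_weak=config.r2_weak, r2_strong=config.r2_strong,
    )
    _write(het, outdir / "af_heterogeneity.tsv", config)


def _stage_finemap(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    labels = state.labels
    stringent = labels[labels["label"] == classify.STRINGENT]
    leads_eur = state.meta_leads[EUR].set_index("probe")
    leads_eas = state.meta_leads[EAS].set_index("probe")
    same_lead = [
        p for p in stringent["probe"]
        if leads_eur.loc[p, "snp"] == leads_eas.loc[p, "snp"]
    ]
    sub = leads_eur.loc[same_lead].reset_index()
    sub = finemap.dedupe_leads(sub)
    prior = finemap.PriorSpec()
    by_probe = {
        EUR: dict(tuple(state.meta_stats[EUR].groupby("probe", sort=False))),
        EAS: dict(tuple(state.meta_stats[EAS].groupby("probe", sort=False))),
    }
    sets: dict[str, dict[str, finemap.CredibleSet]] = {EUR: {}, EAS: {}, finemap.MODE_CROSS: {}}
    for probe in sub["probe"]:
        se = by_probe[EUR].get(probe)
        sa = by_probe[EAS].get(probe)
        if se is None or sa is None:
            continue
        sets[EUR][probe] = finemap.credible_set(
            finemap.pips_single(se, prior), probe, EUR, config.coverage
        )
        sets[EAS][probe] = finemap.credible_set(
            finemap.pips_single(sa, prior), probe, EAS, config.coverage
        )
        sets[finemap.MODE_CROSS][probe] = finemap.credible_set(
            finemap.pips_cross(se, sa, prior), probe, finemap.MODE_CROSS, config.coverage
        )
    sets, excl = finemap.filter_outlier_sets(sets)
    rows = [
        {"probe": cs.probe, "mode": mode, "snp": s, "pip": pip}
        for mode, d in sets.items()
        for cs in d.values()
        for s, pip in cs.members.items()
    ]
    _write(pd.DataFrame(rows, columns=["probe", "mode", "snp", "pip"]),
           outdir / "credible_sets.tsv", config)
    _write(excl, outdir / "finemap_outliers.tsv", config)
    summary = pd.DataFrame(
        [
            {
                "mode": mode,
                "n_probes": len(d),
                "mean_size": float(np.mean([cs.size for cs in d.values()])) if d else np.nan,
                "median_size": float(np.median([cs.size for cs in d.values()])) if d else np.nan,
            }
            for mode, d in sets.items()
        ]
    )
    _write(summary, outdir / "credible_set_sizes.tsv", config)


def _stage_simsize(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    study = state.study
    k = min(config.simsize_probes, len(study.probes))
    inputs = finemap.ExperimentInputs(
        model=study.model,
        afs_eur=study.afs["f_eur"].to_numpy(),
        afs_eas=study.afs["f_eas"].to_numpy(),
        probes=study.probes.iloc[:k].reset_index(drop=True),
        causal_index=study.truth.causal_index[:k],
        b_eur=study.truth.b_eur[:k],
        b_eas=study.truth.b_eas[:k],
    )
    table = finemap.sample_size_experiment(
        inputs, config.simsize_grid, seed=config.seed + 7,
        eas_add=config.simsize_eas_add, window=config.cis_window,
        coverage=config.coverage,
    )
    _write(table, outdir / "simsize.tsv", config)


def _stage_smr(config: PipelineConfig, state: PipelineState, outdir: Path) -> None:
    gwas = simulate_demo_gwas(config, state.study)
    results = smr.ancestry_specific_smr(
        state.labels, state.meta_leads, state.meta_stats, gwas,
        state.study.panels, state.study.probes,
        p_smr_thresh=config.p_smr, p_heidi_min=config.p_heidi,
        gwas_sig=config.gwas_sig, window=config.cis_window,
    )
    _write(results, outdir / "smr.tsv", config)


def simulate_demo_gwas(
    config: PipelineConfig, study: synthdata.Study
) -> dict[tuple[str, str], pd.DataFrame]:
    """Synthetic trait GWAS per ancestry: traits mediated by methylation at
    the first few ancestry-specific-capable probes, from fresh cohorts."""
    rng = np.random.default_rng(config.seed + 101)
    gwas: dict[tuple[str, str], pd.DataFrame] = {}
    pop_af = {EUR: study.afs["f_eur"].to_numpy(), EAS: study.afs["f_eas"].to_numpy()}
    n_traits = config.smr_n_traits
    mediated = rng.choice(len(study.truth.probes), size=n_traits, replace=False)
    for t, probe_i in enumerate(mediated):
        trait = f"trait{t + 1}"
        for ancestry in (EUR, EAS):
            genos = synthdata.simulate_genotypes(
                study.model, pop_af[ancestry], config.smr_n_gwas,
                seed=int(rng.integers(2**31)), population=ancestry,
            )
            meth = synthdata.simulate_methylation(
                genos, study.truth, None, seed=int(rng.integers(2**31)),
                population=ancestry,
            )
            y = 0.5 * meth.iloc[probe_i].to_numpy() + rng.standard_normal(config.smr_n_gwas)
            stats = assoc.assoc_scan(y, genos, np.arange(genos.n_snps), probe=trait)
            stats = stats.drop(columns=["probe"])
            gwas[(trait, ancestry)] = stats
    return gwas


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "adjust": _stage_adjust,
    "scan": _stage_scan,
    "meta": _stage_meta,
    "rb": _stage_rb,
    "sets": _stage_sets,
    "cojo": _stage_cojo,
    "classify": _stage_classify,
    "afhet": _stage_afhet,
    "finemap": _stage_finemap,
    "simsize": _stage_simsize,
    "smr": _stage_smr,
}
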