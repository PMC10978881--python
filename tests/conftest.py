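import numpy as np
import pandas as pd
import pytest

from crossmqtl import assoc, synthdata as sd
from crossmqtl.preprocess import rank_int_rows
from crossmqtl.synthdata import EAS, EUR, CohortSpec, PopulationModel


@pytest.fixture(scope="session")
def small_model() -> PopulationModel:
    return PopulationModel(
        n_snps=300,
        block_lengths=[10] * 30,
        rho_eur=0.9,
        rho_eas=0.9,
        fst=0.1,
        eas_block_shift=5,
        snp_spacing=5000,
        seed=11,
    )


@pytest.fixture(scope="session")
def study(small_model) -> sd.Study:
    """Moderate two-ancestry study reused by the integration-level tests."""
    specs = [
        CohortSpec("eur_a", EUR, 600),
        CohortSpec("eur_b", EUR, 600),
        CohortSpec("eas_a", EAS, 600),
    ]
    return sd.simulate_study(
        small_model,
        specs,
        n_probes=120,
        rho_b=0.95,
        effect_sd=0.6,
        noise_var=1.0,
        private_frac_eur=0.15,
        private_frac_eas=0.1,
        panel_n=400,
    )


@pytest.fixture(scope="session")
def scanned(study):
    """Per-cohort INT phenotype scans plus within-ancestry meta results."""
    cohort_stats = {}
    cohort_leads = {}
    for cohort in study.cohorts:
        phen = rank_int_rows(cohort.methylation)
        stats = assoc.scan_cohort(phen, cohort.genos, study.probes)
        cohort_stats[cohort.name] = stats
        cohort_leads[cohort.name] = assoc.lead_snps(stats, study.probes, cohort.ancestry)
    meta_stats = {}
    meta_leads = {}
    for ancestry in (EUR, EAS):
        names = [c.name for c in study.cohorts_of(ancestry)]
        meta = assoc.ivw_meta([cohort_stats[n] for n in names])
        meta_stats[ancestry] = meta
        meta_leads[ancestry] = assoc.lead_snps(meta, study.probes, ancestry)
    return {
        "cohort_stats": cohort_stats,
        "cohort_leads": cohort_leads,
        "meta_stats": meta_stats,
        "meta_leads": meta_leads,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_stats_frame(rows) -> pd.DataFrame:
    """Helper for hand-built summary-statistic fixtures."""
    return pd.DataFrame(rows, columns=assoc.STATS_COLUMNS)
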