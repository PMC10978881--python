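import numpy as np
import pandas as pd
import pytest

from crossmqtl import classify, ld
from crossmqtl import synthdata as sd
from crossmqtl.classify import (
    EAS_SPECIFIC,
    EUR_SPECIFIC,
    OTHER,
    STRINGENT,
    SharingCategory,
    af_heterogeneity,
    classify_shared_mqtl,
    define_sets,
    percent,
    set_report,
    tally_categories,
)
from crossmqtl.synthdata import EAS, EUR


def _lead(probe, snp, p, beta=1.0, ancestry=EUR, pos=100):
    return {
        "probe": probe, "snp": snp, "pos": pos, "effect_allele": "G",
        "other_allele": "A", "af": 0.3, "beta": beta, "se": 0.1, "p": p,
        "n": 1000, "ancestry": ancestry,
    }


def _leads(rows):
    return pd.DataFrame(rows)


class TestDefineSets:
    def test_stringent(self):
        labels = define_sets(
            _leads([_lead("cg1", "a", 1e-15)]),
            _leads([_lead("cg1", "b", 1e-12, ancestry=EAS)]),
        )
        assert labels.loc[0, "label"] == STRINGENT

    def test_eur_specific(self):
        labels = define_sets(
            _leads([_lead("cg1", "a", 1e-15)]),
            _leads([_lead("cg1", "b", 1e-5, ancestry=EAS)]),
        )
        assert labels.loc[0, "label"] == EUR_SPECIFIC

    def test_gap_case_other(self):
        labels = define_sets(
            _leads([_lead("cg1", "a", 1e-15)]),
            _leads([_lead("cg1", "b", 1e-8, ancestry=EAS)]),
        )
        assert labels.loc[0, "label"] == OTHER
        assert labels.loc[0, "reason"] == "between_thresholds"

    def test_eas_specific(self):
        labels = define_sets(
            _leads([_lead("cg1", "a", 1e-5)]),
            _leads([_lead("cg1", "b", 1e-12, ancestry=EAS)]),
        )
        assert labels.loc[0, "label"] == EAS_SPECIFIC

    def test_same_lead_exclusion(self):
        labels = define_sets(
            _leads([_lead("cg1", "a", 1e-15)]),
            _leads([_lead("cg1", "a", 1e-5, ancestry=EAS)]),
        )
        assert labels.loc[0, "label"] == OTHER
        assert labels.loc[0, "reason"] == "excluded_same_lead"
        assert labels.loc[0, "same_lead"]

    def test_alt_cohort_significance_exclusion(self):
        cohort_leads = [(EAS, _leads([_lead("cg1", "c", 1e-12, ancestry=EAS)]))]
        labels = define_sets(
            _leads([_lead("cg1", "a", 1e-15)]),
            _leads([_lead("cg1", "b", 1e-5, ancestry=EAS)]),
            cohort_leads=cohort_leads,
        )
        assert labels.loc[0, "label"] == OTHER
        assert labels.loc[0, "reason"] == "excluded_alt_cohort_significant"

    def test_absent_probe(self):
        labels = define_sets(
            _leads([_lead("cg1", "a", 1e-15)]),
            _leads([_lead("cg2", "b", 1e-15, ancestry=EAS)]),
        )
        assert (labels["label"] == OTHER).all()
        assert (labels["reason"] == "absent_in_one_ancestry").all()


def _panel_pair(rho=0.99, n=2000, n_snps=30, shift=5):
    model = sd.PopulationModel(
        n_snps=n_snps, block_lengths=[10] * (n_snps // 10), rho_eur=rho,
        rho_eas=rho, fst=0.05, seed=9, eas_block_shift=shift,
    )
    afs = np.full(n_snps, 0.5)
    return {
        EUR: sd.simulate_genotypes(model, afs, n, seed=1, population=EUR),
        EAS: sd.simulate_genotypes(model, afs, n, seed=2, population=EAS),
    }


class TestClassifyShared:
    def setup_method(self):
        self.panels = _panel_pair()
        self.ctx = classify.ClassifyContext(panels=self.panels)

    def test_same_lead_same_direction(self):
        cat, _ = classify_shared_mqtl(
            "cg1",
            pd.Series(_lead("cg1", "snp5", 1e-20, beta=0.5)),
            pd.Series(_lead("cg1", "snp5", 1e-18, beta=0.4, ancestry=EAS)),
            self.ctx, probe_pos=25_000,
        )
        assert cat == SharingCategory.SAME_LEAD_SAME_DIRECTION

    def test_same_lead_opposite_sign_falls_through(self):
        cat, _ = classify_shared_mqtl(
            "cg1",
            pd.Series(_lead("cg1", "snp5", 1e-20, beta=0.5)),
            pd.Series(_lead("cg1", "snp5", 1e-18, beta=-0.4, ancestry=EAS)),
            self.ctx, probe_pos=25_000,
        )
        # same SNP has r2 = 1 with itself: rescued by the strong-LD rule
        assert cat == SharingCategory.STRONG_LD

    def test_strong_ld_neighbours(self):
        cat, _ = classify_shared_mqtl(
            "cg1",
            pd.Series(_lead("cg1", "snp5", 1e-20)),
            pd.Series(_lead("cg1", "snp6", 1e-18, ancestry=EAS)),
            self.ctx, probe_pos=25_000,
        )
        assert cat in (SharingCategory.STRONG_LD, SharingCategory.BLOCK_OVERLAP)

    def test_cojo_same_snp(self):
        # distant SNPs in different blocks: no LD evidence, rescued by COJO
        cat, _ = classify_shared_mqtl(
            "cg1",
            pd.Series(_lead("cg1", "snp2", 1e-20)),
            pd.Series(_lead("cg1", "snp25", 1e-18, ancestry=EAS)),
            self.ctx, probe_pos=75_000,
            cojo_snps=["snp2", "snp25"],
        )
        assert cat == SharingCategory.COJO_SAME_SNP

    def test_unexplained(self):
        cat, _ = classify_shared_mqtl(
            "cg1",
            pd.Series(_lead("cg1", "snp2", 1e-20)),
            pd.Series(_lead("cg1", "snp25", 1e-18, ancestry=EAS)),
            self.ctx, probe_pos=75_000,
        )
        assert cat == SharingCategory.UNEXPLAINED

    def test_monomorphic_lead_noted(self):
        panels = _panel_pair()
        panels[EAS].dosages[:, 7] = 0.0  # snp8 monomorphic in EAS
        ctx = classify.ClassifyContext(panels=panels)
        cat, note = classify_shared_mqtl(
            "cg1",
            pd.Series(_lead("cg1", "snp8", 1e-20)),
            pd.Series(_lead("cg1", "snp25", 1e-18, ancestry=EAS)),
            ctx, probe_pos=40_000,
        )
        assert "ld_unavailable_eas" in note


class TestTally:
    def test_table_arithmetic(self):
        counts = {
            SharingCategory.SAME_LEAD_SAME_DIRECTION: 9153,
            SharingCategory.STRONG_LD: 40648,
            SharingCategory.BLOCK_OVERLAP: 3069,
            SharingCategory.COJO_SAME_SNP: 1031,
            SharingCategory.COJO_BLOCK_OVERLAP: 3999,
        }
        tally = tally_categories(counts, total=80394).set_index("category")
        assert tally.loc["same_lead_same_direction", "percent"] == 11.4
        assert tally.loc["strong_ld", "percent"] == 50.6
        assert tally.loc["block_overlap", "percent"] == 3.8
        assert tally.loc["cojo_same_snp", "percent"] == 1.3
        assert tally.loc["cojo_block_overlap", "percent"] == 5.0
        assert tally.loc["total_shared", "count"] == 57900
        assert tally.loc["total_shared", "percent"] == 72.0

    def test_all_unexplained(self):
        tally = tally_categories({SharingCategory.UNEXPLAINED: 10}).set_index("category")
        assert tally.loc["total_shared", "count"] == 0
        assert tally.loc["total_shared", "percent"] == 0.0

    def test_single_category(self):
        tally = tally_categories({SharingCategory.STRONG_LD: 7}).set_index("category")
        assert tally.loc["strong_ld", "percent"] == 100.0

    def test_counts_sum_and_percent_sum(self):
        counts = {c: 10 for c in SharingCategory}
        tally = tally_categories(counts)
        per_cat = tally[tally["category"] != "total_shared"]
        assert per_cat["count"].sum() == 60
        assert abs(per_cat["percent"].sum() - 100.0) < 0.3  # rounding slack


class TestSetReport:
    def test_headline_percentages(self):
        report = set_report(404503, 129155, 80394, 28925, 21084, 7841).set_index("set")
        assert report.loc["any_mqtl", "percent"] == 31.9
        assert report.loc["stringent_both_ancestries", "percent"] == 62.2
        assert report.loc["ancestry_specific", "percent"] == 22.4
        assert report.loc["eur_specific", "percent"] == 72.9
        assert report.loc["eas_specific", "percent"] == 27.1

    def test_percent_zero_total(self):
        assert percent(5, 0) == 0.0


class TestAfHeterogeneity:
    def _labels(self, label=EUR_SPECIFIC):
        return pd.DataFrame(
            [{"probe": "cg1", "label": label, "p_eur": 1e-15, "p_eas": 1e-3,
              "same_lead": False, "alt_cohort_sig": False, "reason": ""}]
        )

    def test_rare_flag(self):
        panels = _panel_pair()
        # force snp3 nearly absent in EAS panel
        panels[EAS].dosages[:, 2] = 0.0
        panels[EAS].dosages[:5, 2] = 1.0
        panels[EAS].variants.loc[2, "af"] = 5 / (2 * panels[EAS].n_individuals)
        het = af_heterogeneity(
            self._labels(),
            _leads([_lead("cg1", "snp3", 1e-15)]),
            _leads([_lead("cg1", "snp25", 1e-3, ancestry=EAS)]),
            panels,
        )
        assert het.loc[0, "rare_in_alt"]

    def test_private_variant_incalculable(self):
        panels = _panel_pair()
        panels[EAS].dosages[:, 2] = 0.0  # monomorphic in EAS
        panels[EUR].dosages[:, 2] = np.random.default_rng(0).binomial(
            2, 0.3, panels[EUR].n_individuals
        )
        panels[EAS].variants.loc[2, "af"] = 0.0
        het = af_heterogeneity(
            self._labels(),
            _leads([_lead("cg1", "snp3", 1e-15)]),
            _leads([_lead("cg1", "snp3", 1e-3, ancestry=EAS)]),
            panels,
        )
        assert het.loc[0, "rare_in_alt"]
        # lead pair is (snp3, snp3): EAS panel cannot score it, EUR can
        assert het.loc[0, "ld_bucket"] != "incalculable"

    def test_common_not_rare(self):
        panels = _panel_pair()
        het = af_heterogeneity(
            self._labels(),
            _leads([_lead("cg1", "snp3", 1e-15)]),
            _leads([_lead("cg1", "snp25", 1e-3, ancestry=EAS)]),
            panels,
        )
        assert not het.loc[0, "rare_in_alt"]
        assert het.loc[0, "ld_bucket"] in {"weak", "intermediate", "strong"}


class TestEndToEnd:
    def test_stringent_classification_mostly_ld_explained(self, study, scanned):
        labels = define_sets(
            scanned["meta_leads"][EUR], scanned["meta_leads"][EAS],
            [(c.ancestry, scanned["cohort_leads"][c.name]) for c in study.cohorts],
        )
        ctx = classify.ClassifyContext(panels=study.panels)
        cats = classify.classify_all(
            labels, scanned["meta_leads"][EUR], scanned["meta_leads"][EAS],
            study.probes, ctx,
        )
        assert len(cats) > 20
        top3 = {
            SharingCategory.SAME_LEAD_SAME_DIRECTION.value,
            SharingCategory.STRONG_LD.value,
            SharingCategory.BLOCK_OVERLAP.value,
        }
        frac = cats["category"].isin(top3).mean()
        assert frac >= 0.9

    def test_specific_sets_enriched_for_private_truth(self, study, scanned):
        labels = define_sets(
            scanned["meta_leads"][EUR], scanned["meta_leads"][EAS],
            [(c.ancestry, scanned["cohort_leads"][c.name]) for c in study.cohorts],
        ).set_index("probe")
        truth = study.truth
        private = {
            p for p, be, ba in zip(truth.probes, truth.b_eur, truth.b_eas)
            if (be == 0) != (ba == 0)
        }
        spec_probes = set(labels[labels["label"].isin([EUR_SPECIFIC, EAS_SPECIFIC])].index)
        str_probes = set(labels[labels["label"] == STRINGENT].index)
        if spec_probes and str_probes:
            frac_spec = len(spec_probes & private) / len(spec_probes)
            frac_str = len(str_probes & private) / max(len(str_probes), 1)
            assert frac_spec > frac_str

    def test_deterministic(self, study, scanned):
        args = (
            scanned["meta_leads"][EUR], scanned["meta_leads"][EAS],
            [(c.ancestry, scanned["cohort_leads"][c.name]) for c in study.cohorts],
        )
        pd.testing.assert_frame_equal(define_sets(*args), define_sets(*args))
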