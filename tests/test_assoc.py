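import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossmqtl import assoc
from crossmqtl.genotypes import GenotypeSet


def _genos(dosages, pos=None, alleles=None):
    dosages = np.asarray(dosages, dtype=float)
    n_snps = dosages.shape[1]
    ref, alt = ("A", "G") if alleles is None else alleles
    variants = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(n_snps)],
            "chrom": "1",
            "pos": pos if pos is not None else np.arange(1, n_snps + 1) * 1000,
            "ref": ref,
            "alt": alt,
            "af": np.nanmean(dosages, axis=0) / 2,
            "info": 1.0,
        }
    )
    return GenotypeSet(
        dosages=dosages, variants=variants,
        samples=[f"i{k}" for k in range(dosages.shape[0])],
    )


class TestCisWindow:
    def test_closed_interval_boundaries(self):
        table = pd.DataFrame({"pos": [999_999, 1_000_000, 3_000_000, 3_000_001]})
        idx = assoc.cis_window(2_000_000, table, window=1_000_000)
        assert list(idx) == [1, 2]

    def test_degenerate_window(self):
        table = pd.DataFrame({"pos": [5, 10, 15]})
        assert list(assoc.cis_window(10, table, window=0)) == [1]

    def test_empty(self):
        table = pd.DataFrame({"pos": [10_000_000]})
        assert len(assoc.cis_window(1000, table)) == 0

    def test_negative_window(self):
        with pytest.raises(ValueError):
            assoc.cis_window(10, pd.DataFrame({"pos": [1]}), window=-1)


class TestAssocScan:
    def test_noiseless(self, rng):
        g = _genos(rng.binomial(2, 0.4, size=(200, 3)))
        y = 2.0 * g.dosages[:, 1]
        out = assoc.assoc_scan(y, g, np.array([1]))
        assert out["beta"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert out["p"].iloc[0] < 1e-100

    def test_null_type_one_error(self, rng):
        n, m = 500, 4000
        g = _genos(rng.binomial(2, 0.3, size=(n, m)))
        y = rng.standard_normal(n)
        out = assoc.assoc_scan(y, g, np.arange(m))
        frac = (out["p"] < 0.05).mean()
        # binomial 4-sigma bound on 4000 tests
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / m)

    def test_matches_closed_form_ols(self, rng):
        n = 300
        g = _genos(rng.binomial(2, 0.4, size=(n, 5)))
        y = rng.standard_normal(n) + 0.3 * g.dosages[:, 0]
        out = assoc.assoc_scan(y, g, np.arange(5))
        for j in range(5):
            X = np.column_stack([np.ones(n), g.dosages[:, j]])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            sigma2 = res[0] / (n - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert out["beta"].iloc[j] == pytest.approx(coef[1], abs=1e-10)
            assert out["se"].iloc[j] == pytest.approx(se, abs=1e-10)
            t = coef[1] / se
            assert out["p"].iloc[j] == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-8)

    def test_mean_imputation_of_missing(self, rng):
        d = rng.binomial(2, 0.4, size=(100, 1)).astype(float)
        d[:5, 0] = np.nan
        g = _genos(d)
        y = rng.standard_normal(100)
        out = assoc.assoc_scan(y, g, np.array([0]))
        assert np.isfinite(out["beta"].iloc[0])

    def test_zero_variance_dropped(self, rng):
        d = np.zeros((50, 2))
        d[:, 1] = rng.binomial(2, 0.5, 50)
        g = _genos(d)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = assoc.assoc_scan(rng.standard_normal(50), g, np.arange(2))
        assert list(out["snp"]) == ["s1"]

    def test_p_consistent_with_z(self, rng):
        # p matches the t-tail of beta/se to 1e-6 relative
        g = _genos(rng.binomial(2, 0.3, size=(400, 10)))
        y = rng.standard_normal(400)
        out = assoc.assoc_scan(y, g, np.arange(10))
        t = out["beta"] / out["se"]
        expected = 2 * stats.t.sf(np.abs(t), 398)
        np.testing.assert_allclose(out["p"], expected, rtol=1e-6)


class TestLeadSnp:
    def _records(self, ps, pos=None, betas=None, ses=None):
        m = len(ps)
        return pd.DataFrame(
            {
                "probe": "cg1",
                "snp": [f"s{i}" for i in range(m)],
                "pos": pos if pos is not None else np.arange(m) * 100,
                "beta": betas if betas is not None else np.ones(m),
                "se": ses if ses is not None else np.ones(m),
                "p": ps,
            }
        )

    def test_min_p_chosen(self):
        rec = assoc.lead_snp(self._records([1e-12, 1e-3]))
        assert rec["snp"] == "s0"

    def test_tie_break_distance(self):
        df = self._records([1e-8, 1e-8], pos=[500, 800])
        rec = assoc.lead_snp(df, probe_pos=1000)
        assert rec["snp"] == "s1"  # distance 200 < 500

    def test_single_record(self):
        df = self._records([0.5])
        assert assoc.lead_snp(df)["snp"] == "s0"

    def test_tie_break_z_before_distance(self):
        df = self._records([1e-8, 1e-8], betas=[1.0, 2.0], ses=[1.0, 1.0])
        assert assoc.lead_snp(df, probe_pos=0)["snp"] == "s1"

    def test_empty_error(self):
        with pytest.raises(ValueError):
            assoc.lead_snp(self._records([]))


class TestIVWMeta:
    def test_identical_cohorts(self):
        b, s, k = 0.7, 0.2, 4
        beta, se, p = assoc.ivw_meta_arrays([b] * k, [s] * k)
        assert beta == pytest.approx(b)
        assert se == pytest.approx(s / np.sqrt(k))

    def test_hand_computed(self):
        beta, se, _ = assoc.ivw_meta_arrays([1.0, 0.0], [1.0, 1.0])
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(np.sqrt(0.5))

    def test_single_cohort_identity(self):
        beta, se, p = assoc.ivw_meta_arrays([0.3], [0.1])
        assert (beta, se) == (pytest.approx(0.3), pytest.approx(0.1))
        assert p == pytest.approx(2 * stats.norm.sf(3.0), rel=1e-12)

    def test_z2_closed_form(self, rng):
        betas = rng.normal(0.2, 0.1, 6)
        ses = rng.uniform(0.05, 0.3, 6)
        beta, se, _ = assoc.ivw_meta_arrays(betas, ses)
        w = 1 / ses**2
        z2_expected = (w * betas).sum() ** 2 / w.sum()
        assert (beta / se) ** 2 == pytest.approx(z2_expected)

    def test_partition_associativity(self, rng):
        betas = rng.normal(0.2, 0.1, 7)
        ses = rng.uniform(0.05, 0.3, 7)
        whole = assoc.ivw_meta_arrays(betas, ses)
        b12, s12, _ = assoc.ivw_meta_arrays(betas[:3], ses[:3])
        b3, s3, _ = assoc.ivw_meta_arrays(betas[3:], ses[3:])
        nested = assoc.ivw_meta_arrays([b12, b3], [s12, s3])
        assert nested[0] == pytest.approx(whole[0], rel=1e-12)
        assert nested[1] == pytest.approx(whole[1], rel=1e-12)

    def test_se_positive_required(self):
        with pytest.raises(ValueError):
            assoc.ivw_meta_arrays([1.0], [0.0])

    def test_frame_meta(self, rng):
        base = pd.DataFrame(
            {
                "probe": "cg1", "snp": ["a", "b"], "chrom": "1", "pos": [1, 2],
                "effect_allele": "G", "other_allele": "A", "af": 0.5,
                "beta": [1.0, 0.5], "se": [1.0, 0.2], "p": [0.3, 0.01], "n": 100,
            }
        )
        other = base.copy()
        other["beta"] = [0.0, 0.5]
        meta = assoc.ivw_meta([base, other]).set_index("snp")
        assert meta.loc["a", "beta"] == pytest.approx(0.5)
        assert meta.loc["a", "se"] == pytest.approx(np.sqrt(0.5))
        assert meta.loc["a", "n"] == 200


class TestHarmonize:
    def _rec(self, snp="s1", ea="G", oa="A", beta=1.0, af=0.2):
        return pd.DataFrame(
            [{"snp": snp, "effect_allele": ea, "other_allele": oa, "beta": beta, "af": af}]
        )

    def test_swap_flips_sign(self):
        ref = self._rec(ea="A", oa="G", af=0.8)
        out = assoc.harmonize_alleles(self._rec(), ref)
        assert out["beta"].iloc[0] == -1.0
        assert out["effect_allele"].iloc[0] == "A"
        assert out["af"].iloc[0] == pytest.approx(0.8)

    def test_identity(self):
        ref = self._rec()
        out = assoc.harmonize_alleles(self._rec(), ref)
        assert out["beta"].iloc[0] == 1.0

    def test_ambiguous_at_half_dropped(self):
        rec = self._rec(ea="A", oa="T", af=0.5)
        ref = self._rec(ea="A", oa="T", af=0.5)
        with pytest.warns(UserWarning, match="dropped"):
            out = assoc.harmonize_alleles(rec, ref)
        assert len(out) == 0

    def test_ambiguous_resolved_by_af(self):
        rec = self._rec(ea="C", oa="G", af=0.1)
        ref = self._rec(ea="C", oa="G", af=0.12)
        out = assoc.harmonize_alleles(rec, ref)
        assert len(out) == 1

    def test_mismatch_dropped(self):
        rec = self._rec(ea="C", oa="A")
        ref = self._rec(ea="G", oa="T")
        with pytest.warns(UserWarning, match="dropped"):
            out = assoc.harmonize_alleles(rec, ref)
        assert len(out) == 0


def test_scan_power_regime(study, scanned):
    # strong-effect, common-variant probes should overwhelmingly reach p < 1e-10
    truth = study.truth
    eur_af = study.afs["f_eur"].to_numpy()[truth.causal_index]
    maf = np.minimum(eur_af, 1 - eur_af)
    strong = [
        p for p, be, f in zip(truth.probes, truth.b_eur, maf)
        if abs(be) > 0.5 and f > 0.2
    ]
    leads = scanned["meta_leads"]["EUR"].set_index("probe")
    hit = np.mean([leads.loc[p, "p"] < 1e-10 for p in strong if p in leads.index])
    assert hit > 0.95


def test_power_half_sd_common_variant(rng):
    # b = 0.5 SD at MAF 0.3, n = 1500: essentially complete power at p < 1e-10
    from crossmqtl.preprocess import rank_int

    n, n_probes, b = 1500, 200, 0.5
    g = rng.binomial(2, 0.3, size=(n, n_probes)).astype(float)
    y = b * g + rng.standard_normal((n, n_probes))
    hits = 0
    for j in range(n_probes):
        yj = rank_int(y[:, j])
        gj = g[:, j] - g[:, j].mean()
        beta = gj @ yj / (gj @ gj)
        rss = ((yj - yj.mean()) ** 2).sum() - beta * (gj @ yj)
        se = np.sqrt(rss / (n - 2) / (gj @ gj))
        if 2 * stats.t.sf(abs(beta / se), n - 2) < 1e-10:
            hits += 1
    assert hits / n_probes > 0.99
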