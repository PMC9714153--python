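"""EWAS models: paired fits, partial F-tests, meta-analysis, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mqtlewas._regress import DegeneratePredictorError, ols_fit
from mqtlewas.ewas import (BirthweightEwas, EwasRecord, compare_models,
                           ewas_design, fit_pair, gestational_age_mask,
                           meta_ewas, partial_f, sensitivity_fit)


def record(rss, df, cpg="cg1", model="mqtl", **kw):
    base = dict(cpg_id=cpg, model=model, beta_bw=0.0, se=1.0, t=0.0, p=1.0,
                n=df + 5, mqtl_snp_id=None, rss=rss, df_resid=df)
    base.update(kw)
    return EwasRecord(**base)


class TestDesign:
    def test_beta_bw_invariant_to_covariate_order(self, basic_samples):
        rng = np.random.default_rng(0)
        y = rng.normal(0.5, 0.05, len(basic_samples))
        X, names = ewas_design(basic_samples)
        fit1 = ols_fit(X, y, colnames=names)
        # permute all columns after birthweight
        perm = [0, 1] + list(rng.permutation(np.arange(2, X.shape[1])))
        fit2 = ols_fit(X[:, perm], y)
        assert fit1.beta[1] == pytest.approx(fit2.beta[1], abs=1e-10)

    def test_all_seven_cell_fractions_trip_rank_guard(self, basic_samples):
        bad = basic_samples.copy()
        # adding granulocytes makes fractions sum to 1: collinear with intercept
        bad["cell_Gran"] = 1.0 - bad[[c for c in bad.columns
                                      if c.startswith("cell_")]].sum(axis=1)
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 0.05, len(bad))
        X, names = ewas_design(bad)
        Xg = np.column_stack([X, bad["cell_Gran"].to_numpy(float)])
        with pytest.raises(DegeneratePredictorError, match="aliased"):
            ols_fit(Xg, y, colnames=names + ["cell_Gran"])

    def test_gestational_age_exclusion_mask(self, basic_samples):
        s = basic_samples.copy()
        s.loc[:2, "gestational_age"] = 28.0
        mask = gestational_age_mask(s)
        assert (~mask).sum() == 3


class TestFitPair:
    def test_no_mqtl_records_identical_except_tag(self, basic_samples):
        rng = np.random.default_rng(2)
        y = rng.normal(0.5, 0.05, len(basic_samples))
        rec_m, rec_p = fit_pair(y, basic_samples, None)
        assert rec_m.model == "mqtl" and rec_p.model == "plain"
        for f in ("beta_bw", "se", "t", "p", "n", "rss", "df_resid"):
            assert getattr(rec_m, f) == getattr(rec_p, f)

    def test_planted_bw_effect_recovered(self, basic_samples):
        rng = np.random.default_rng(3)
        bw = basic_samples["birthweight"].to_numpy(float)
        y = np.clip(0.5 + 2e-5 * (bw - 3400) + rng.normal(0, 0.02,
                                                          len(bw)), 0, 1)
        rec_m, rec_p = fit_pair(y, basic_samples, None)
        assert abs(rec_p.beta_bw - 2e-5) < 2 * rec_p.se

    def test_strong_mqtl_shrinks_bw_se(self, basic_samples):
        rng = np.random.default_rng(4)
        n = len(basic_samples)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = np.clip(0.5 + 0.08 * g + rng.normal(0, 0.02, n), 0, 1)
        rec_m, rec_p = fit_pair(y, basic_samples, g, "snp1")
        assert rec_m.se < rec_p.se
        assert rec_m.mqtl_snp_id == "snp1"


class TestPartialF:
    def test_equal_rss_gives_f_zero_p_one(self):
        F, p = partial_f(record(10.0, 90), record(10.0, 91))
        assert F == 0.0
        assert p == 1.0

    def test_q1_equals_squared_t(self):
        """With one added column the partial F equals t^2 of that column."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(40, 120))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            extra = rng.normal(size=n)
            y = X @ rng.normal(size=4) + 0.3 * extra + rng.normal(size=n)
            fit_r = ols_fit(X, y)
            Xf = np.column_stack([X, extra])
            fit_f = ols_fit(Xf, y)
            F, p = partial_f((fit_f.rss, fit_f.df_resid),
                             (fit_r.rss, fit_r.df_resid))
            assert F == pytest.approx(fit_f.t[-1] ** 2, abs=1e-8 * max(1, F))
            assert p == pytest.approx(fit_f.p[-1], abs=1e-8)

    def test_nested_order_enforced(self):
        with pytest.raises(ValueError, match="fewer parameters"):
            partial_f(record(5.0, 90), record(6.0, 90))

    def test_null_covariate_p_uniform(self, basic_samples):
        """Adding an unrelated dosage yields uniform partial-F P values."""
        rng = np.random.default_rng(6)
        n = len(basic_samples)
        pvals = []
        for _ in range(500):
            y = rng.normal(0.5, 0.05, n)
            g = rng.binomial(2, 0.3, n).astype(float)
            rec_m, rec_p = fit_pair(y, basic_samples, g, "s")
            _, fp = partial_f(rec_m, rec_p)
            pvals.append(fp)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMetaEwas:
    def _table(self, betas, ses):
        return pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(len(betas))],
                             "beta_bw": betas, "se": ses})

    def test_single_dataset_passthrough_with_bonferroni(self):
        t = self._table([1e-5, -2e-5], [1e-5, 0.5e-5])
        out = meta_ewas([t])
        row = out.set_index("cpg_id").loc["cg0"]
        assert row["pooled_beta"] == pytest.approx(1e-5)
        assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.025)

    def test_opposite_signs_cancel(self):
        t1 = self._table([3e-5], [1e-5])
        t2 = self._table([-3e-5], [1e-5])
        meta = meta_ewas([t1, t2])
        z_single = 3e-5 / 1e-5
        assert abs(meta["z"].iloc[0]) < z_single
        assert meta["direction"].iloc[0] == "+-"

    def test_power_and_fwer_with_generous_planted_effects(self):
        from mqtlewas.ewas import BirthweightEwas
        from mqtlewas.synthetic_cohort import SimConfig, simulate_cohort
        cfg = SimConfig(n_samples={"NLW": 250, "LAT": 250}, n_variants=100,
                        n_cpgs=150, chrom_length=20_000_000,
                        frac_cpgs_with_mqtl=0.0, frac_cpgs_bw_assoc=0.3,
                        bw_effect_fixed=0.05, noise_sd=0.02, seed=19)
        cohort = simulate_cohort(cfg)
        tables = [BirthweightEwas(d["methylation"], d["samples"],
                                  model="plain").fit().table
                  for d in cohort["strata"].values()]
        meta = meta_ewas(tables).set_index("cpg_id")
        truth = cohort["truth"].cpgs.set_index("cpg_id")
        planted = [c for c in meta.index if truth.loc[c, "bw_beta"] != 0]
        nulls = [c for c in meta.index if truth.loc[c, "bw_beta"] == 0]
        # generous planted effects: most should clear Bonferroni
        assert meta.loc[planted, "significant"].mean() >= 0.8
        # false positives among nulls stay at the Bonferroni expectation
        assert meta.loc[nulls, "significant"].sum() <= 3


class TestCompareModels:
    def test_identical_tables_all_zero_change(self, ewas_fit):
        t = ewas_fit["mqtl"][0]
        comp, summary = compare_models(t, t)
        assert (comp["rel_change"].dropna() == 0).all()
        assert summary["frac_more_significant_with_mqtl"] == 0.0

    def test_rel_change_arithmetic(self):
        m = pd.DataFrame([{"cpg_id": "cg1", "beta_bw": 0.13, "p": 0.01}])
        p = pd.DataFrame([{"cpg_id": "cg1", "beta_bw": 0.10, "p": 0.05}])
        comp, _ = compare_models(m, p)
        assert comp["rel_change"].iloc[0] == pytest.approx(0.30)
        assert bool(comp["changed_gt_20pct"].iloc[0])
        assert bool(comp["more_significant_with_mqtl"].iloc[0])

    def test_zero_plain_beta_marked_undefined(self):
        m = pd.DataFrame([{"cpg_id": "cg1", "beta_bw": 0.1, "p": 0.5}])
        p = pd.DataFrame([{"cpg_id": "cg1", "beta_bw": 0.0, "p": 0.5}])
        comp, _ = compare_models(m, p)
        assert not bool(comp["rel_change_defined"].iloc[0])
        assert np.isnan(comp["rel_change"].iloc[0])

    def test_strong_mqtls_make_majority_more_significant(self):
        """When mQTLs explain much methylation variance and birthweight
        truly acts on the CpGs, correcting for the mQTL sharpens the
        birthweight test for most mQTL-matched CpGs."""
        from mqtlewas.ewas import fit_paired_dataset
        from mqtlewas.meta_db import build_database
        from mqtlewas.mqtl_scan import scan_dataset
        from mqtlewas.synthetic_cohort import SimConfig, simulate_cohort
        cfg = SimConfig(n_samples={"NLW": 300, "LAT": 40}, n_variants=300,
                        n_cpgs=100, chrom_length=12_000_000,
                        frac_cpgs_with_mqtl=0.8, mqtl_effect_fixed=0.06,
                        maf_range={"NLW": (0.3, 0.3), "LAT": (0.3, 0.3)},
                        frac_cpgs_bw_assoc=1.0, bw_effect_fixed=0.03,
                        noise_sd=0.02, seed=29)
        cohort = simulate_cohort(cfg)
        d = cohort["strata"]["NLW"]
        sc = scan_dataset(d["methylation"], d["genotypes"], d["samples"],
                          n_perm=500, seed=29).table
        db = build_database([sc])
        res_m, res_p = fit_paired_dataset(d["methylation"], d["samples"],
                                          d["genotypes"], db)
        matched = res_m.table[res_m.table["mqtl_snp_id"].notna()]
        comp, summary = compare_models(matched, res_p.table)
        assert summary["n_compared"] >= 50
        assert summary["frac_more_significant_with_mqtl"] > 0.5
        assert summary["frac_partial_F_significant"] > 0.5


class TestSensitivity:
    def test_missing_rows_dropped_with_count(self, basic_samples):
        s = basic_samples.copy()
        s.loc[:2, "maternal_weight_gain"] = np.nan
        rng = np.random.default_rng(7)
        y = rng.normal(0.5, 0.05, len(s))
        rec = sensitivity_fit(y, s, None)
        assert rec.n == len(s) - 3
        assert rec.model == "sensitivity"

    def test_constant_weight_gain_reduces_to_mqtl_model(self, basic_samples):
        s = basic_samples.copy()
        s["maternal_weight_gain"] = 0.0
        rng = np.random.default_rng(8)
        y = rng.normal(0.5, 0.05, len(s))
        rec = sensitivity_fit(y, s, None)
        rec_m, _ = fit_pair(y, s, None)
        assert rec.beta_bw == pytest.approx(rec_m.beta_bw, abs=1e-12)
        assert rec.df_resid == rec_m.df_resid

    def test_entirely_missing_column_raises(self, basic_samples):
        s = basic_samples.drop(columns=["maternal_weight_gain"])
        with pytest.raises(ValueError, match="missing entirely"):
            sensitivity_fit(np.zeros(len(s)), s, None)

    def test_too_much_missingness_raises(self, basic_samples):
        s = basic_samples.copy()
        s.loc[: int(0.1 * len(s)), "maternal_weight_gain"] = np.nan
        with pytest.raises(ValueError, match="95%"):
            sensitivity_fit(np.zeros(len(s)), s, None)

    def test_independent_weight_gain_barely_shifts_beta(self, basic_samples):
        """Weight gain independent of methylation: beta_bw moves < 0.5 SE."""
        rng = np.random.default_rng(9)
        n = len(basic_samples)
        shifts = []
        for _ in range(100):
            y = np.clip(rng.normal(0.5, 0.05, n), 0, 1)
            rec_m, _ = fit_pair(y, basic_samples, None)
            rec_s = sensitivity_fit(y, basic_samples, None)
            shifts.append(abs(rec_s.beta_bw - rec_m.beta_bw) <= 0.5 * rec_m.se)
        assert np.mean(shifts) >= 0.95


class TestBirthweightEwasModel:
    def test_excludes_preterm_subjects(self, ewas_cohort):
        _, cohort = ewas_cohort
        d = cohort["strata"]["NLW"]
        n_preterm = (d["samples"]["gestational_age"] < 30).sum()
        model = BirthweightEwas(d["methylation"], d["samples"], model="plain")
        assert model.n_excluded == n_preterm
        assert (model.samples["gestational_age"] >= 30).all()

    def test_summary_mentions_model_and_counts(self, ewas_fit, ewas_cohort):
        _, cohort = ewas_cohort
        d = cohort["strata"]["NLW"]
        res = BirthweightEwas(d["methylation"], d["samples"],
                              model="plain").fit()
        s = res.summary()
        assert "plain model" in s
        assert str(len(res.table)) in s
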