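"""Paired birthweight EWAS: models with and without the matched mQTL covariate.

Per CpG, methylation beta value is regressed on birthweight (grams, the
coefficient of interest) plus sex, gestational age (weeks), methylation
batch, the case-control selection factor, six deconvoluted cell-type
proportions (granulocytes excluded to avoid collinearity, as the fractions
sum to one), and ten genetic principal components.  The mQTL model adds the
CpG's assigned mQTL dosage when the database carries one; the plain model
omits it; the sensitivity model further adds maternal weight gain.
Subjects with gestational age below 30 weeks are excluded before any
design matrix is formed.

Whether the mQTL covariate earns its place is judged per CpG with a nested
partial F-test, F = ((RSS_reduced - RSS_full)/q) / (RSS_full/df_full); with
a single added column this equals the squared t of the mQTL coefficient.
Per-dataset results are pooled per platform by inverse-variance
meta-analysis and Bonferroni-corrected at alpha / (CpGs tested).  The
model-comparison report flags CpGs whose birthweight coefficient moved by
more than 20% after mQTL correction and counts which CpGs became more
significant with the genetic covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regress import ols_fit
from .io_formats import (CELL_COVARIATE_COLUMNS, GenotypeMatrix,
                         MethylationMatrix)
from .meta_db import MqtlDatabase, inverse_variance_meta

logger = logging.getLogger(__name__)

EWAS_PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]
MIN_GESTATIONAL_AGE = 30.0

EWAS_COLUMNS = ["cpg_id", "model", "beta_bw", "se", "t", "p", "n",
                "mqtl_snp_id", "rss", "df_resid"]


@dataclass
class EwasRecord:
    """One CpG's fit under one model (mqtl / plain / sensitivity)."""

    cpg_id: str
    model: str
    beta_bw: float
    se: float
    t: float
    p: float
    n: int
    mqtl_snp_id: str | None
    rss: float
    df_resid: int


# ---------------------------------------------------------------------------
# sample filtering and design construction
# ---------------------------------------------------------------------------

def gestational_age_mask(samples: pd.DataFrame,
                         min_weeks: float = MIN_GESTATIONAL_AGE) -> np.ndarray:
    """Inclusion mask; the exclusion count is logged for audit."""
    mask = samples["gestational_age"].to_numpy(float) >= min_weeks
    n_excl = int((~mask).sum())
    if n_excl:
        logger.info("excluding %d subject(s) with gestational age < %g weeks",
                    n_excl, min_weeks)
    return mask


def ewas_design(samples: pd.DataFrame, mqtl_dosage: np.ndarray | None = None,
                maternal_weight_gain: bool = False,
                ) -> tuple[np.ndarray, list[str]]:
    """Full EWAS design matrix (intercept first, birthweight second).

    A constant requested column (e.g. degenerate maternal weight gain) is
    dropped with a warning rather than tripping the rank guard.
    """
    n = len(samples)
    cols = [np.ones(n), samples["birthweight"].to_numpy(float)]
    names = ["intercept", "birthweight"]
    cols.append((samples["sex"] == "M").to_numpy(float))
    names.append("sex_M")
    cols.append(samples["gestational_age"].to_numpy(float))
    names.append("gestational_age")
    for c in pd.get_dummies(samples["batch"], drop_first=True).columns:
        cols.append((samples["batch"] == c).to_numpy(float))
        names.append(f"batch_{c}")
    cols.append(samples["case_status"].to_numpy(float))
    names.append("case_status")
    for c in CELL_COVARIATE_COLUMNS:
        cols.append(samples[c].to_numpy(float))
        names.append(c)
    for c in EWAS_PC_COLUMNS:
        cols.append(samples[c].to_numpy(float))
        names.append(c)
    if maternal_weight_gain:
        mwg = samples["maternal_weight_gain"].to_numpy(float)
        if np.ptp(mwg) == 0:
            logger.warning("maternal_weight_gain is constant; column dropped")
        else:
            cols.append(mwg)
            names.append("maternal_weight_gain")
    if mqtl_dosage is not None:
        cols.append(np.asarray(mqtl_dosage, dtype=float))
        names.append("mqtl")
    return np.column_stack(cols), names


def _record_from_fit(fit, cpg_id: str, model: str,
                     mqtl_snp_id: str | None) -> EwasRecord:
    return EwasRecord(cpg_id=cpg_id, model=model, beta_bw=float(fit.beta[1]),
                      se=float(fit.se[1]), t=float(fit.t[1]),
                      p=float(fit.p[1]), n=fit.df_resid + fit.rank,
                      mqtl_snp_id=mqtl_snp_id, rss=fit.rss,
                      df_resid=fit.df_resid)


# ---------------------------------------------------------------------------
# per-CpG operations
# ---------------------------------------------------------------------------

def fit_pair(y: np.ndarray, samples: pd.DataFrame,
             mqtl_dosage: np.ndarray | None = None,
             mqtl_snp_id: str | None = None, cpg_id: str = "cpg",
             ) -> tuple[EwasRecord, EwasRecord]:
    """The mQTL-model and plain-model fits for one CpG.

    With no mQTL dosage the two records are identical apart from the model
    tag.  Gestational-age exclusion is assumed applied upstream.
    """
    y = np.asarray(y, dtype=float)
    X_plain, names_plain = ewas_design(samples)
    fit_plain = ols_fit(X_plain, y, colnames=names_plain)
    rec_plain = _record_from_fit(fit_plain, cpg_id, "plain", None)
    if mqtl_dosage is None:
        rec_mqtl = EwasRecord(**{**rec_plain.__dict__, "model": "mqtl"})
        return rec_mqtl, rec_plain
    X_full, names_full = ewas_design(samples, mqtl_dosage=mqtl_dosage)
    fit_full = ols_fit(X_full, y, colnames=names_full)
    rec_mqtl = _record_from_fit(fit_full, cpg_id, "mqtl", mqtl_snp_id)
    return rec_mqtl, rec_plain


def sensitivity_fit(y: np.ndarray, samples: pd.DataFrame,
                    mqtl_dosage: np.ndarray | None = None,
                    mqtl_snp_id: str | None = None, cpg_id: str = "cpg",
                    ) -> EwasRecord:
    """mQTL-model design plus maternal weight gain.

    Rows missing maternal weight gain are dropped (logged); the column must
    be present for at least 95% of samples.
    """
    if "maternal_weight_gain" not in samples.columns:
        raise ValueError("maternal_weight_gain column is missing entirely")
    mwg = samples["maternal_weight_gain"].to_numpy(float)
    present = ~np.isnan(mwg)
    if present.mean() < 0.95:
        raise ValueError(
            f"maternal_weight_gain present for only {100 * present.mean():.1f}% "
            "of samples (need >= 95%)")
    n_drop = int((~present).sum())
    if n_drop:
        logger.info("sensitivity model: dropping %d sample(s) with missing "
                    "maternal weight gain", n_drop)
    sub = samples[present].reset_index(drop=True)
    y = np.asarray(y, dtype=float)[present]
    dose = None if mqtl_dosage is None else np.asarray(mqtl_dosage)[present]
    X, names = ewas_design(sub, mqtl_dosage=dose, maternal_weight_gain=True)
    fit = ols_fit(X, y, colnames=names)
    return _record_from_fit(fit, cpg_id, "sensitivity", mqtl_snp_id)


def partial_f(full: EwasRecord | tuple, reduced: EwasRecord | tuple,
              ) -> tuple[float, float]:
    """Nested-model F test of the columns the full model adds.

    Accepts EwasRecords or raw (rss, df_resid) tuples.  With q = 1 added
    column, F equals the squared t statistic of that coefficient.
    """
    rss_f, df_f = ((full.rss, full.df_resid) if isinstance(full, EwasRecord)
                   else full)
    rss_r, df_r = ((reduced.rss, reduced.df_resid)
                   if isinstance(reduced, EwasRecord) else reduced)
    if df_f <= 0:
        raise ValueError("full model has no residual degrees of freedom")
    q = df_r - df_f
    if q < 1:
        raise ValueError("reduced model must have fewer parameters")
    if rss_r < rss_f - 1e-12 * max(1.0, rss_f):
        raise ValueError("reduced-model RSS below full-model RSS")
    F = max((rss_r - rss_f) / q, 0.0) / (rss_f / df_f)
    p = float(stats.f.sf(F, q, df_f))
    return float(F), p


# ---------------------------------------------------------------------------
# dataset-level Model / Results
# ---------------------------------------------------------------------------

class BirthweightEwas:
    """Birthweight EWAS model over one dataset.

    Parameters
    ----------
    meth, samples :
        Methylation matrix and covariate table over one sample set.
    geno, database :
        Genotypes and the mQTL database supplying the per-CpG assigned
        mQTL covariate; both optional for the plain model.
    model : {"mqtl", "plain", "sensitivity"}
    """

    def __init__(self, meth: MethylationMatrix, samples: pd.DataFrame,
                 geno: GenotypeMatrix | None = None,
                 database: MqtlDatabase | None = None, model: str = "mqtl",
                 min_gestational_age: float = MIN_GESTATIONAL_AGE):
        if model not in ("mqtl", "plain", "sensitivity"):
            raise ValueError(f"unknown model {model!r}")
        if model in ("mqtl", "sensitivity") and database is not None \
                and geno is None:
            raise ValueError("genotypes required to use the mQTL database")
        order = list(meth.sample_ids)
        samples = samples.set_index("sample_id").loc[order].reset_index()
        mask = gestational_age_mask(samples, min_gestational_age)
        self.n_excluded = int((~mask).sum())
        keep_ids = [s for s, m in zip(order, mask) if m]
        self.meth = meth.subset_samples(keep_ids)
        self.samples = samples[mask].reset_index(drop=True)
        self.geno = geno.subset_samples(keep_ids) if geno is not None else None
        self.database = database
        self.model = model
        self._assigned = ({} if database is None else
                          dict(zip(database.assigned()["cpg_id"],
                                   database.assigned()["snp_id"])))

    def _dosage_for(self, cpg_id: str):
        if self.model == "plain" or not self._assigned or self.geno is None:
            return None, None
        snp = self._assigned.get(cpg_id)
        if snp is None:
            return None, None
        try:
            return self.geno.dosage_of(snp), snp
        except KeyError:
            return None, None

    def fit(self) -> "EwasResults":
        records = []
        for i, cpg_id in enumerate(self.meth.cpgs["id"]):
            y = self.meth.betas[:, i]
            dose, snp = self._dosage_for(cpg_id)
            if self.model == "sensitivity":
                records.append(sensitivity_fit(y, self.samples, dose, snp,
                                               cpg_id=str(cpg_id)))
            elif self.model == "mqtl":
                rec, _ = fit_pair(y, self.samples, dose, snp,
                                  cpg_id=str(cpg_id))
                records.append(rec)
            else:
                _, rec = fit_pair(y, self.samples, None, cpg_id=str(cpg_id))
                records.append(rec)
        return EwasResults(records, model=self.model,
                           n_excluded=self.n_excluded)


class EwasResults:
    """Per-CpG birthweight association table for one model."""

    def __init__(self, records: list[EwasRecord], model: str,
                 n_excluded: int = 0):
        self.records = records
        self.model = model
        self.n_excluded = n_excluded

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{c: getattr(r, c) for c in EWAS_COLUMNS}
                             for r in self.records], columns=EWAS_COLUMNS)

    def summary(self) -> str:
        t = self.table
        thr = 0.05 / len(t) if len(t) else np.nan
        n_sig = int((t["p"] < thr).sum()) if len(t) else 0
        with_mqtl = int(t["mqtl_snp_id"].notna().sum()) if len(t) else 0
        return "\n".join([
            f"birthweight EWAS ({self.model} model)",
            "=" * 34,
            f"CpGs tested:                  {len(t)}",
            f"Samples excluded (GA < 30 w): {self.n_excluded}",
            f"CpGs with mQTL covariate:     {with_mqtl}",
            f"Bonferroni threshold:         {thr:.3g}",
            f"Bonferroni-significant CpGs:  {n_sig}",
        ])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def fit_paired_dataset(meth: MethylationMatrix, samples: pd.DataFrame,
                       geno: GenotypeMatrix, database: MqtlDatabase,
                       ) -> tuple[EwasResults, EwasResults]:
    """Both models over one dataset (shared sample exclusions)."""
    mqtl = BirthweightEwas(meth, samples, geno, database, model="mqtl").fit()
    plain = BirthweightEwas(meth, samples, model="plain").fit()
    return mqtl, plain


# ---------------------------------------------------------------------------
# per-platform meta-analysis
# ---------------------------------------------------------------------------

def meta_ewas(tables: list[pd.DataFrame], platform: str = "BOTH",
              alpha: float = 0.05) -> pd.DataFrame:
    """Inverse-variance pooling of per-dataset EWAS tables, Bonferroni-corrected.

    Input tables carry cpg_id / beta_bw / se; CpGs are pooled over the
    datasets that tested them.  The Bonferroni threshold is alpha divided
    by the number of CpGs meta-analyzed on the platform.
    """
    if not tables:
        raise ValueError("need at least one EWAS table")
    k = len(tables)
    by_cpg: dict[str, list] = {}
    for d, t in enumerate(tables):
        for _, row in t.iterrows():
            by_cpg.setdefault(str(row["cpg_id"]), []).append(
                (d, float(row["beta_bw"]), float(row["se"])))
    rows = []
    for cpg, contribs in by_cpg.items():
        m = inverse_variance_meta([(b, s) for _, b, s in contribs])
        present = {d for d, _, _ in contribs}
        signs = {d: ("+" if b >= 0 else "-") for d, b, _ in contribs}
        rows.append({"cpg_id": cpg, "pooled_beta": m["pooled_beta"],
                     "pooled_se": m["pooled_se"], "z": m["z"], "p": m["p"],
                     "log10_p": m["log10_p"],
                     "direction": "".join(signs.get(d, "?") for d in range(k)),
                     "n_datasets": len(present)})
    out = pd.DataFrame(rows)
    threshold = alpha / len(out)
    out["bonferroni_threshold"] = threshold
    out["significant"] = out["p"] < threshold
    out.attrs["platform"] = platform
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

COMPARISON_COLUMNS = ["cpg_id", "beta_mqtl", "beta_plain", "p_mqtl", "p_plain",
                      "rel_change", "changed_gt_20pct",
                      "more_significant_with_mqtl", "partial_F", "partial_F_p"]


def compare_models(mqtl_table: pd.DataFrame, plain_table: pd.DataFrame,
                   change_threshold: float = 0.20, alpha: float = 0.05,
                   bh: bool = False) -> tuple[pd.DataFrame, dict]:
    """Per-CpG comparison of the mQTL and plain models, with a summary.

    ``rel_change`` = (beta_mqtl - beta_plain) / |beta_plain|; the >20%
    flag follows its absolute value and is undefined (NaN, flag False but
    marked) when beta_plain is exactly 0.  Ties in P count as
    not-more-significant.  Partial F statistics are filled in when both
    tables carry rss/df_resid columns (per-dataset fits).  ``bh=True``
    adds Benjamini-Hochberg adjusted P values for the mQTL model.
    """
    m = mqtl_table.set_index("cpg_id")
    p = plain_table.set_index("cpg_id")
    shared = m.index.intersection(p.index)
    bcol_m = "beta_bw" if "beta_bw" in m.columns else "pooled_beta"
    bcol_p = "beta_bw" if "beta_bw" in p.columns else "pooled_beta"
    rows = []
    have_rss = ("rss" in m.columns and "rss" in p.columns
                and "df_resid" in m.columns)
    for cpg in shared:
        bm, bp = float(m.loc[cpg, bcol_m]), float(p.loc[cpg, bcol_p])
        pm, pp = float(m.loc[cpg, "p"]), float(p.loc[cpg, "p"])
        if bp == 0.0:
            rel, changed, defined = np.nan, False, False
        else:
            rel = (bm - bp) / abs(bp)
            changed = abs(rel) > change_threshold
            defined = True
        F = Fp = np.nan
        if have_rss and m.loc[cpg, "df_resid"] < p.loc[cpg, "df_resid"]:
            F, Fp = partial_f((float(m.loc[cpg, "rss"]),
                               int(m.loc[cpg, "df_resid"])),
                              (float(p.loc[cpg, "rss"]),
                               int(p.loc[cpg, "df_resid"])))
        rows.append({"cpg_id": cpg, "beta_mqtl": bm, "beta_plain": bp,
                     "p_mqtl": pm, "p_plain": pp, "rel_change": rel,
                     "changed_gt_20pct": changed,
                     "rel_change_defined": defined,
                     "more_significant_with_mqtl": pm < pp,
                     "partial_F": F, "partial_F_p": Fp})
    comp = pd.DataFrame(rows, columns=COMPARISON_COLUMNS
                        + ["rel_change_defined"])
    if bh and len(comp):
        order = np.argsort(comp["p_mqtl"].to_numpy())
        n = len(comp)
        ranked = comp["p_mqtl"].to_numpy()[order] * n / np.arange(1, n + 1)
        bh_adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(n)
        adj[order] = np.minimum(bh_adj, 1.0)
        comp["p_mqtl_bh"] = adj

    n = len(comp)
    thr = alpha / n if n else np.nan
    gained = int(((comp["p_mqtl"] < thr) & (comp["p_plain"] >= thr)).sum())
    lost = int(((comp["p_mqtl"] >= thr) & (comp["p_plain"] < thr)).sum())
    summary = {
        "n_compared": n,
        "frac_more_significant_with_mqtl":
            float(comp["more_significant_with_mqtl"].mean()) if n else np.nan,
        "frac_changed_gt_20pct":
            float(comp["changed_gt_20pct"].mean()) if n else np.nan,
        "gained_bonferroni": gained,
        "lost_bonferroni": lost,
        "frac_partial_F_significant":
            float((comp["partial_F_p"] < alpha).mean())
            if comp["partial_F_p"].notna().any() else np.nan,
    }
    return comp, summary
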