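"""Per-CpG cis-mQTL discovery with permutation-calibrated adjusted P values.

For each CpG the scan considers every QC-passing SNP within a 2 Mb window
flanking the CpG (1 Mb each side), fits covariate-adjusted marginal
regressions of methylation on dosage, and keeps the top SNP (smallest
nominal P).  Because the window holds many correlated tests, the nominal P
of the top SNP is optimistic; its null distribution is characterized
empirically by permuting the covariate-residualized methylation vector
(n_perm times, genotypes and covariates held fixed), recording the minimum
P across the window for each permutation, and fitting a Beta(a, b) to those
minima by maximum likelihood.  The adjusted P value is the fitted beta CDF
evaluated at the observed top nominal P — the probability of seeing a
smaller minimum under the null.  For K independent null variants the
minimum of K uniform P values is Beta(1, K), so the fitted shape2 tracks
the effective number of independent tests in the window.

Covariates in this stage are sex, methylation batch and the first five
genetic principal components; the EWAS stage uses its own, richer set.

The regression fast path uses the Frisch-Waugh-Lovell decomposition:
residualize y and each dosage column on the covariates once, then simple
regressions on the residuals reproduce the full-design marginal fit
exactly (same estimate, SE and P with df = n - p_covariates - 1).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._regress import DegeneratePredictorError, ols_fit
from .io_formats import GenotypeMatrix, MethylationMatrix, impute_missing_dosages

logger = logging.getLogger(__name__)

SCAN_PC_COLUMNS = [f"pc{i}" for i in range(1, 6)]
DEFAULT_WINDOW_BP = 2_000_000
DEFAULT_N_PERM = 1000


@dataclass
class MqtlRecord:
    """One CpG's top cis-SNP with permutation diagnostics."""

    cpg_id: str
    snp_id: str
    beta: float
    se: float
    nominal_p: float
    adjusted_p: float
    empirical_p: float
    n_perm: int
    beta_shape1: float
    beta_shape2: float
    n_cis_variants: int
    n_samples: int
    converged: bool
    effect_allele: str = ""
    other_allele: str = ""
    maf: float = float("nan")
    chrom: str = ""
    pos_cpg: int = 0
    pos_snp: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.adjusted_p <= 1.0):
            raise ValueError("adjusted_p outside [0, 1]")
        if self.beta_shape1 <= 0 or self.beta_shape2 <= 0:
            raise ValueError("beta shapes must be positive")
        if self.n_cis_variants < 1:
            raise ValueError("n_cis_variants must be >= 1")


# ---------------------------------------------------------------------------
# cis windows
# ---------------------------------------------------------------------------

def cis_window(cpg_chrom: str, cpg_pos: int, variants: pd.DataFrame,
               window_bp: int = DEFAULT_WINDOW_BP) -> np.ndarray:
    """Indices of variants within the cis window of a CpG.

    ``window_bp`` is the total flanking span (2 Mb default), i.e. variants
    with |pos_snp - pos_cpg| <= window_bp / 2 on the same chromosome.
    Binary search over the position-sorted variant table.
    """
    half = window_bp // 2
    on_chrom = np.where((variants["chrom"] == cpg_chrom).to_numpy())[0]
    if on_chrom.size == 0:
        return np.empty(0, dtype=int)
    pos = variants["pos"].to_numpy()[on_chrom]
    lo = np.searchsorted(pos, cpg_pos - half, side="left")
    hi = np.searchsorted(pos, cpg_pos + half, side="right")
    return on_chrom[lo:hi]


# ---------------------------------------------------------------------------
# marginal regression
# ---------------------------------------------------------------------------

def marginal_fit(y: np.ndarray, dosage: np.ndarray,
                 covariates: np.ndarray | None = None,
                 ) -> tuple[float, float, float, float]:
    """OLS of y on [1, dosage, covariates]; inference for the dosage term.

    Returns (beta, se, t, p) with a two-sided t test at n - p residual df.
    A perfect fit (zero residual variance) reports p = 0 by convention.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if np.ptp(dosage) == 0:
        raise DegeneratePredictorError("dosage is constant")
    n = len(y)
    cols = [np.ones(n), dosage]
    names = ["intercept", "dosage"]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        cols.extend(covariates.T)
        names.extend(f"covariate{i}" for i in range(covariates.shape[1]))
    fit = ols_fit(np.column_stack(cols), y, colnames=names)
    return float(fit.beta[1]), float(fit.se[1]), float(fit.t[1]), float(fit.p[1])


def _residual_stats(y_r: np.ndarray, X_r: np.ndarray, df: int):
    """Slopes/SEs/Ps of residualized simple regressions, via correlations."""
    xnorm = np.linalg.norm(X_r, axis=0)
    ynorm = np.linalg.norm(y_r)
    ok = xnorm > 1e-12
    r = np.zeros(X_r.shape[1])
    if ynorm > 0:
        r[ok] = (X_r[:, ok].T @ y_r) / (xnorm[ok] * ynorm)
    r = np.clip(r, -1.0, 1.0)
    beta = np.zeros_like(r)
    beta[ok] = r[ok] * ynorm / xnorm[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 0.0))
    t = np.where(np.abs(r) >= 1.0, np.inf * np.sign(r), t)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    se = np.zeros_like(beta)
    se[ok] = (ynorm / xnorm[ok]) * np.sqrt(np.maximum(1.0 - r[ok] ** 2, 0.0)
                                           / df)
    return beta, se, t, p, ok


# ---------------------------------------------------------------------------
# beta-distribution fit to permutation minima
# ---------------------------------------------------------------------------

def fit_beta_mle(x: np.ndarray, tol: float = 1e-8, max_iter: int = 100,
                 ) -> tuple[float, float, bool]:
    """Maximum-likelihood Beta(a, b) fit with a method-of-moments start.

    Newton iterations on the two-parameter score using digamma/trigamma;
    falls back to the method-of-moments estimate (converged=False) if the
    iteration does not settle within ``max_iter``.
    """
    x = np.clip(np.asarray(x, dtype=float), 1e-12, 1.0 - 1e-12)
    n = len(x)
    mean, var = x.mean(), x.var()
    if var <= 0:
        return 1.0, 1.0, False
    common = mean * (1 - mean) / var - 1.0
    a = max(mean * common, 1e-3)
    b = max((1 - mean) * common, 1e-3)
    mlx = np.log(x).mean()
    ml1x = np.log1p(-x).mean()
    a_mom, b_mom = a, b
    for _ in range(max_iter):
        psi_ab = special.digamma(a + b)
        g = np.array([psi_ab - special.digamma(a) + mlx,
                      psi_ab - special.digamma(b) + ml1x])
        tri_ab = special.polygamma(1, a + b)
        H = np.array([[tri_ab - special.polygamma(1, a), tri_ab],
                      [tri_ab, tri_ab - special.polygamma(1, b)]])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        a_new, b_new = a - step[0], b - step[1]
        if a_new <= 0 or b_new <= 0:
            a_new = max(a - 0.5 * step[0], a / 2)
            b_new = max(b - 0.5 * step[1], b / 2)
        if abs(a_new - a) < tol * (1 + abs(a)) and \
           abs(b_new - b) < tol * (1 + abs(b)):
            return float(a_new), float(b_new), True
        a, b = a_new, b_new
    return float(a_mom), float(b_mom), False


def _perm_seed(global_seed: int, cpg_id: str) -> np.random.SeedSequence:
    """Per-CpG permutation stream keyed on (seed, CpG id), order-independent."""
    return np.random.SeedSequence([global_seed, zlib.crc32(cpg_id.encode())])


# ---------------------------------------------------------------------------
# per-CpG scan
# ---------------------------------------------------------------------------

def scan_cpg(y: np.ndarray, cis_dosages: np.ndarray,
             cis_variants: pd.DataFrame, covariates: np.ndarray,
             cpg_id: str = "cpg", cpg_pos: int = 0,
             n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> MqtlRecord | None:
    """Top-SNP selection and beta-approximated adjusted P for one CpG.

    ``covariates`` must include an intercept column.  Returns None when no
    cis variant is usable (all monomorphic).  Ties at equal nominal P break
    to the SNP closest to the CpG, then lexicographically by id.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    df = n - covariates.shape[1] - 1
    if df <= 0:
        raise DegeneratePredictorError("too few samples for the scan design")
    Q = np.linalg.qr(np.asarray(covariates, dtype=float))[0]
    y_r = y - Q @ (Q.T @ y)
    X_r = np.asarray(cis_dosages, dtype=float)
    X_r = X_r - Q @ (Q.T @ X_r)

    beta, se, t, p, ok = _residual_stats(y_r, X_r, df)
    if not ok.any():
        return None

    pos = cis_variants["pos"].to_numpy()
    ids = cis_variants["id"].to_numpy()
    cand = np.where(ok)[0]
    order = np.lexsort((ids[cand].astype(str),
                        np.abs(pos[cand] - cpg_pos), p[cand]))
    top = cand[order[0]]

    rng = np.random.default_rng(_perm_seed(seed, cpg_id))
    Xn = X_r[:, ok] / np.linalg.norm(X_r[:, ok], axis=0)
    ynorm = np.linalg.norm(y_r)
    if ynorm == 0:
        return None
    perms = rng.permuted(np.tile(y_r, (n_perm, 1)), axis=1).T  # n x n_perm
    # re-residualize the permuted phenotypes so observed and permuted
    # correlations live in the same covariate-orthogonal subspace (keeps
    # the permutation null exchangeable with the observed statistic)
    perms -= Q @ (Q.T @ perms)
    pnorm = np.linalg.norm(perms, axis=0)
    pnorm[pnorm == 0] = 1.0
    rmax = np.abs(Xn.T @ perms).max(axis=0) / pnorm
    rmax = np.clip(rmax, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        tperm = rmax * np.sqrt(df / np.maximum(1.0 - rmax ** 2, 1e-300))
    min_p = 2.0 * stats.t.sf(tperm, df)

    # degenerate perfect fits are excluded from the beta fit
    fit_vals = min_p[min_p > 0]
    if len(fit_vals) >= 10:
        a, b, converged = fit_beta_mle(fit_vals)
    else:
        a, b, converged = 1.0, 1.0, False
    nominal_top = float(p[top])
    adjusted = float(stats.beta.cdf(nominal_top, a, b))
    empirical = float((1 + (min_p <= nominal_top).sum()) / (n_perm + 1))

    return MqtlRecord(
        cpg_id=cpg_id, snp_id=str(ids[top]), beta=float(beta[top]),
        se=float(se[top]), nominal_p=nominal_top, adjusted_p=adjusted,
        empirical_p=empirical, n_perm=n_perm, beta_shape1=a, beta_shape2=b,
        n_cis_variants=int(ok.sum()), n_samples=n, converged=converged,
        effect_allele=str(cis_variants["effect_allele"].iloc[top])
        if "effect_allele" in cis_variants else "",
        other_allele=str(cis_variants["other_allele"].iloc[top])
        if "other_allele" in cis_variants else "",
        maf=float(cis_variants["maf"].iloc[top])
        if "maf" in cis_variants else float("nan"),
        chrom=str(cis_variants["chrom"].iloc[top])
        if "chrom" in cis_variants else "",
        pos_cpg=int(cpg_pos), pos_snp=int(pos[top]),
    )


# ---------------------------------------------------------------------------
# CpG pre-filters
# ---------------------------------------------------------------------------

_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def prefilter_cpgs(meth: MethylationMatrix, geno: GenotypeMatrix,
                   common_maf: float = 0.05) -> np.ndarray:
    """Mask of CpGs eligible for association analysis.

    Drops CpGs on sex chromosomes and CpGs overlapping a common variant
    (MAF > ``common_maf`` at the CpG position or position + 1, the two
    bases of the CpG dinucleotide).
    """
    keep = ~meth.cpgs["chrom"].isin(_SEX_CHROMS).to_numpy()
    common = geno.variants[geno.variants["maf"] > common_maf]
    hot = {(c, p) for c, p in zip(common["chrom"], common["pos"])}
    for i, (c, p) in enumerate(zip(meth.cpgs["chrom"], meth.cpgs["pos"])):
        if (c, p) in hot or (c, p + 1) in hot:
            keep[i] = False
    return keep


def scan_covariates(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Scan-stage design block: intercept, sex, batch dummies, 5 genetic PCs."""
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append((samples["sex"] == "M").to_numpy(float))
    names.append("sex_M")
    batches = pd.get_dummies(samples["batch"], drop_first=True)
    for c in batches.columns:
        cols.append(batches[c].to_numpy(float))
        names.append(f"batch_{c}")
    for c in SCAN_PC_COLUMNS:
        cols.append(samples[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# dataset-level scan: Model / Results
# ---------------------------------------------------------------------------

def _align_samples(meth: MethylationMatrix, geno: GenotypeMatrix,
                   samples: pd.DataFrame):
    s_m, s_g = set(meth.sample_ids), set(geno.sample_ids)
    s_t = set(samples["sample_id"])
    if s_m != s_g or s_m != s_t:
        offenders = sorted((s_m ^ s_g) | (s_m ^ s_t))
        raise ValueError(f"sample IDs not aligned across inputs: {offenders[:10]}")
    order = list(meth.sample_ids)
    geno = geno.subset_samples(order)
    samples = samples.set_index("sample_id").loc[order].reset_index()
    return meth, geno, samples


class CisMqtlScan:
    """cis-mQTL scan model over one dataset (one stratum of one set).

    Parameters
    ----------
    meth, geno, samples :
        Aligned methylation matrix, QC'd genotype matrix and covariate
        table sharing one sample set.
    window_bp : int
        Total cis window span flanking each CpG (default 2 Mb).
    n_perm : int
        Permutations per CpG for the adjusted-P null (default 1000).
    apply_prefilters : bool
        Drop sex-chromosome CpGs and CpGs overlapping common variants.
    """

    def __init__(self, meth: MethylationMatrix, geno: GenotypeMatrix,
                 samples: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP,
                 n_perm: int = DEFAULT_N_PERM, apply_prefilters: bool = True):
        meth, geno, samples = _align_samples(meth, geno, samples)
        self.meth = meth
        self.geno = impute_missing_dosages(geno)
        self.samples = samples
        self.window_bp = window_bp
        self.n_perm = n_perm
        self.cpg_mask = (prefilter_cpgs(meth, geno) if apply_prefilters
                         else np.ones(meth.n_cpgs, dtype=bool))
        self.covariates, self.covariate_names = scan_covariates(samples)

    def fit(self, seed: int = 0, alpha: float = 0.05) -> "MqtlScanResults":
        records, skipped = [], []
        variants = self.geno.variants
        for i in np.where(self.cpg_mask)[0]:
            cpg = self.meth.cpgs.iloc[i]
            idx = cis_window(cpg["chrom"], int(cpg["pos"]), variants,
                             self.window_bp)
            if idx.size == 0:
                skipped.append((cpg["id"], "no cis variants"))
                continue
            rec = scan_cpg(self.meth.betas[:, i], self.geno.dosages[:, idx],
                           variants.iloc[idx], self.covariates,
                           cpg_id=str(cpg["id"]), cpg_pos=int(cpg["pos"]),
                           n_perm=self.n_perm, seed=seed)
            if rec is None:
                skipped.append((cpg["id"], "all cis variants degenerate"))
                continue
            records.append(rec)
            if len(records) % 1000 == 0:
                logger.info("scanned %d CpGs", len(records))
        return MqtlScanResults(records, skipped, alpha=alpha,
                               n_perm=self.n_perm, seed=seed)


RECORD_COLUMNS = ["cpg_id", "snp_id", "beta", "se", "nominal_p", "adjusted_p",
                  "empirical_p", "beta_shape1", "beta_shape2",
                  "n_cis_variants", "n_samples", "converged",
                  "effect_allele", "other_allele", "maf", "chrom",
                  "pos_cpg", "pos_snp"]


class MqtlScanResults:
    """Scan output: one record per CpG plus skip log and significance calls."""

    def __init__(self, records: list[MqtlRecord], skipped: list, alpha: float,
                 n_perm: int, seed: int):
        self.records = records
        self.skipped = skipped
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed

    @property
    def table(self) -> pd.DataFrame:
        df = pd.DataFrame([{c: getattr(r, c) for c in RECORD_COLUMNS}
                           for r in self.records], columns=RECORD_COLUMNS)
        df["significant"] = df["adjusted_p"] < self.alpha
        return df

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        t = self.table
        n_sig = int(t["significant"].sum()) if len(t) else 0
        frac = n_sig / len(t) if len(t) else float("nan")
        lines = [
            "cis-mQTL scan results",
            "=====================",
            f"CpGs scanned:             {len(t)}",
            f"CpGs skipped:             {len(self.skipped)}",
            f"Permutations per CpG:     {self.n_perm}",
            f"Significant (adj P<{self.alpha:g}): {n_sig} ({100 * frac:.1f}%)"
            if len(t) else "Significant: 0",
            f"Median cis variants/CpG:  "
            f"{t['n_cis_variants'].median():.0f}" if len(t) else "",
        ]
        return "\n".join(filter(None, lines))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", na_values=["NA"],
                           dtype={"cpg_id": str, "snp_id": str, "chrom": str})


def scan_dataset(meth: MethylationMatrix, geno: GenotypeMatrix,
                 samples: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP,
                 n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                 alpha: float = 0.05,
                 apply_prefilters: bool = True) -> MqtlScanResults:
    """Functional wrapper: build a :class:`CisMqtlScan` and fit it."""
    model = CisMqtlScan(meth, geno, samples, window_bp=window_bp,
                        n_perm=n_perm, apply_prefilters=apply_prefilters)
    return model.fit(seed=seed, alpha=alpha)
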