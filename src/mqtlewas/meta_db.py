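"""Fixed-effects meta-analysis of per-dataset mQTL scans and the CpG-SNP database.

Per-dataset scans are combined with inverse-variance weighting (w = 1/SE^2,
the "standard error" scheme of summary-statistic meta-analysis):

    pooled_beta = sum(w_i * beta_i) / sum(w_i)
    pooled_se   = sum(w_i) ** -0.5
    z = pooled_beta / pooled_se,  p = 2 * Phi(-|z|)

Effect sizes are sign-aligned to a common effect allele first; records whose
alleles neither match nor flip, and strand-ambiguous (A/T, C/G) variants
with MAF in [0.4, 0.5], are dropped with logged counts.  P values are
computed from z on the log scale so they survive below the float underflow
limit (reported additionally as log10_p).

The database keeps every (CpG, SNP) pair discovered in any contributing
dataset (adjusted P < 0.05 there); pairs seen in two or more datasets carry
the meta-analyzed statistics, singletons carry their one dataset's.  Within
a CpG, pairs rank by ascending P (ties: distance to the CpG, then SNP id);
the rank-1 SNP is the CpG's assigned mQTL, the covariate the EWAS stage
uses.  Cross-dataset agreement of assigned mQTLs is measured as identical
SNP or LD proxy (dosage r^2 above 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

DB_COLUMNS = ["cpg_id", "snp_id", "chrom", "pos_cpg", "pos_snp",
              "pooled_beta", "pooled_se", "z", "p", "log10_p", "direction",
              "n_datasets", "rank"]


@dataclass
class MetaRecord:
    """One meta-analyzed (CpG, SNP) pair."""

    cpg_id: str
    snp_id: str
    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    log10_p: float
    direction: str
    n_datasets: int

    def __post_init__(self) -> None:
        if self.pooled_se <= 0:
            raise ValueError("pooled_se must be positive")
        if abs(abs(self.z) - abs(self.pooled_beta) / self.pooled_se) > 1e-12 * \
                max(1.0, abs(self.z)):
            raise ValueError("z inconsistent with pooled_beta / pooled_se")


@dataclass
class MqtlDatabase:
    """Per-CpG ranked list of meta-analyzed CpG-SNP pairs."""

    table: pd.DataFrame
    platform: str = "BOTH"

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def n_cpgs(self) -> int:
        return self.table["cpg_id"].nunique()

    def assigned(self) -> pd.DataFrame:
        """The rank-1 (most significant) SNP per CpG: the assigned mQTLs."""
        return self.table[self.table["rank"] == 1].reset_index(drop=True)

    def mqtl_for(self, cpg_id: str) -> str | None:
        rows = self.table[(self.table["cpg_id"] == cpg_id)
                          & (self.table["rank"] == 1)]
        return None if rows.empty else str(rows["snp_id"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path, platform: str = "BOTH") -> "MqtlDatabase":
        t = pd.read_csv(path, sep="\t", na_values=["NA"],
                        dtype={"cpg_id": str, "snp_id": str, "chrom": str,
                               "direction": str})
        return cls(table=t, platform=platform)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(tables: list[pd.DataFrame],
                      ) -> tuple[list[pd.DataFrame], dict]:
    """Sign-align effect sizes across datasets to one effect allele per pair.

    The first dataset carrying a (cpg, snp) pair fixes its reference
    alleles; later records either match (kept), flip (beta negated), or are
    dropped as irreconcilable.  Strand-ambiguous variants (A/T or C/G) with
    MAF in [0.4, 0.5] are dropped everywhere, since their orientation
    cannot be resolved from frequency.
    """
    counts = {"ambiguous_dropped": 0, "irreconcilable_dropped": 0}
    reference: dict[tuple, tuple] = {}
    out = []
    for t in tables:
        t = t.copy()
        keep = np.ones(len(t), dtype=bool)
        for i, row in t.iterrows():
            ea, oa = str(row["effect_allele"]), str(row["other_allele"])
            maf = float(row.get("maf", np.nan))
            if frozenset((ea, oa)) in _AMBIGUOUS and \
                    not np.isnan(maf) and 0.4 <= maf <= 0.5:
                keep[i] = False
                counts["ambiguous_dropped"] += 1
                continue
            key = (row["cpg_id"], row["snp_id"])
            if key not in reference:
                reference[key] = (ea, oa)
                continue
            ref_ea, ref_oa = reference[key]
            if (ea, oa) == (ref_ea, ref_oa):
                continue
            if (ea, oa) == (ref_oa, ref_ea):
                t.loc[i, "beta"] = -row["beta"]
                t.loc[i, "effect_allele"] = ref_ea
                t.loc[i, "other_allele"] = ref_oa
                if not np.isnan(maf):
                    t.loc[i, "maf"] = maf  # MAF is fold-invariant
            else:
                keep[i] = False
                counts["irreconcilable_dropped"] += 1
        out.append(t[keep].reset_index(drop=True))
    if counts["ambiguous_dropped"] or counts["irreconcilable_dropped"]:
        logger.info("allele harmonization dropped %d ambiguous, "
                    "%d irreconcilable records",
                    counts["ambiguous_dropped"],
                    counts["irreconcilable_dropped"])
    return out, counts


# ---------------------------------------------------------------------------
# inverse-variance pooling
# ---------------------------------------------------------------------------

def inverse_variance_meta(effects: list[tuple[float, float]]) -> dict:
    """Pool (beta, se) pairs with inverse-variance fixed-effects weights."""
    if not effects:
        raise ValueError("need at least one (beta, se) input")
    betas = np.array([e[0] for e in effects], dtype=float)
    ses = np.array([e[1] for e in effects], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses ** 2
    pooled_beta = float((w * betas).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = pooled_beta / pooled_se
    log_p = np.log(2.0) + stats.norm.logsf(abs(z))
    return {
        "pooled_beta": pooled_beta,
        "pooled_se": pooled_se,
        "z": float(z),
        "p": float(np.exp(log_p)),
        "log10_p": float(log_p / np.log(10.0)),
        "direction": "".join("+" if b >= 0 else "-" for b in betas),
    }


# ---------------------------------------------------------------------------
# database construction
# ---------------------------------------------------------------------------

def build_database(scan_tables: list[pd.DataFrame], platform: str = "BOTH",
                   alpha: float = 0.05, harmonize: bool = True,
                   ) -> MqtlDatabase:
    """Union the significant pairs of several scans into one ranked database.

    ``scan_tables`` are per-dataset scan outputs (adjusted_p column
    required); only rows with adjusted_p < ``alpha`` contribute.  Direction
    strings use '?' for datasets not contributing a pair.
    """
    filtered = [t[t["adjusted_p"] < alpha].reset_index(drop=True)
                for t in scan_tables]
    if harmonize and all("effect_allele" in t.columns for t in filtered):
        filtered, _ = harmonize_alleles(filtered)
    k = len(filtered)

    by_pair: dict[tuple, list] = {}
    meta_info: dict[tuple, dict] = {}
    for d, t in enumerate(filtered):
        for _, row in t.iterrows():
            key = (str(row["cpg_id"]), str(row["snp_id"]))
            by_pair.setdefault(key, []).append((d, float(row["beta"]),
                                                float(row["se"]),
                                                float(row["nominal_p"])))
            if key not in meta_info:
                meta_info[key] = {
                    "chrom": row.get("chrom", ""),
                    "pos_cpg": int(row.get("pos_cpg", 0)),
                    "pos_snp": int(row.get("pos_snp", 0)),
                }

    rows = []
    for (cpg, snp), contribs in by_pair.items():
        present = {d: (b, s, p) for d, b, s, p in contribs}
        direction = "".join(
            ("+" if present[d][0] >= 0 else "-") if d in present else "?"
            for d in range(k))
        if len(contribs) >= 2:
            m = inverse_variance_meta([(b, s) for _, b, s, _ in contribs])
            beta, se, z, p, l10 = (m["pooled_beta"], m["pooled_se"], m["z"],
                                   m["p"], m["log10_p"])
        else:
            _, beta, se, p = contribs[0]
            z = beta / se if se > 0 else np.inf
            l10 = np.log10(p) if p > 0 else -np.inf
        info = meta_info[(cpg, snp)]
        rows.append({"cpg_id": cpg, "snp_id": snp, "chrom": info["chrom"],
                     "pos_cpg": info["pos_cpg"], "pos_snp": info["pos_snp"],
                     "pooled_beta": beta, "pooled_se": se, "z": z, "p": p,
                     "log10_p": l10, "direction": direction,
                     "n_datasets": len(contribs)})
    table = pd.DataFrame(rows, columns=DB_COLUMNS[:-1])
    if len(table):
        table["distance"] = np.abs(table["pos_snp"] - table["pos_cpg"])
        table = table.sort_values(["cpg_id", "p", "distance", "snp_id"],
                                  kind="mergesort").reset_index(drop=True)
        table["rank"] = table.groupby("cpg_id").cumcount() + 1
        table = table.drop(columns="distance")
    else:
        table["rank"] = pd.Series(dtype=int)
    return MqtlDatabase(table=table[DB_COLUMNS], platform=platform)


# ---------------------------------------------------------------------------
# LD and cross-dataset concordance
# ---------------------------------------------------------------------------

def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def concordance(db_a: MqtlDatabase, db_b: MqtlDatabase,
                geno: GenotypeMatrix, r2_min: float = 0.5) -> dict:
    """Cross-dataset agreement of assigned mQTLs over shared CpGs.

    Counts CpGs whose two databases assign the identical SNP, a different
    SNP in LD (r^2 > ``r2_min``) computed from ``geno`` dosages, and either.
    SNPs absent from the genotype matrix make a CpG untestable; untestable
    CpGs are excluded from the denominators and logged.
    """
    a = db_a.assigned().set_index("cpg_id")["snp_id"]
    b = db_b.assigned().set_index("cpg_id")["snp_id"]
    shared = a.index.intersection(b.index)
    known = set(geno.variants["id"])
    detail = []
    same = in_ld = untestable = 0
    for cpg in shared:
        sa, sb = str(a.loc[cpg]), str(b.loc[cpg])
        if sa == sb:
            same += 1
            detail.append((cpg, sa, sb, "same_snp", 1.0))
            continue
        if sa not in known or sb not in known:
            untestable += 1
            detail.append((cpg, sa, sb, "untestable", np.nan))
            continue
        try:
            r2 = ld_r2(geno.dosage_of(sa), geno.dosage_of(sb))
        except ValueError:
            untestable += 1
            detail.append((cpg, sa, sb, "untestable", np.nan))
            continue
        if r2 > r2_min:
            in_ld += 1
            detail.append((cpg, sa, sb, "in_ld", r2))
        else:
            detail.append((cpg, sa, sb, "discordant", r2))
    if untestable:
        logger.info("concordance: %d shared CpGs untestable "
                    "(SNP missing from genotypes)", untestable)
    n_testable = len(shared) - untestable
    return {
        "n_shared": int(len(shared)),
        "n_testable": int(n_testable),
        "same_snp": int(same),
        "in_ld": int(in_ld),
        "either": int(same + in_ld),
        "untestable": int(untestable),
        "detail": pd.DataFrame(detail, columns=["cpg_id", "snp_a", "snp_b",
                                                "status", "r2"]),
    }
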