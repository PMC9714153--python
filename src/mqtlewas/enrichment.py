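"""Genomic-feature enrichment of mQTL-matched CpGs.

Two complementary views are implemented and labelled distinctly:

* a disjoint 2x2 Fisher exact test (mQTL-matched vs the remaining CpGs,
  inside vs outside a feature), the classical enrichment contrast; and
* superset proportion tests per CpG-island-relation category, comparing
  the category share among mQTL-matched CpGs against the share among ALL
  array CpGs (a superset of the matched set) — the display convention of
  island-relation bar charts — using a two-sample chi-squared test without
  continuity correction, with star coding (<0.05 *, <0.01 **, <0.001 ***).

Fold enrichment is the feature rate among mQTL CpGs over the feature rate
among all CpGs tested: (a/(a+b)) / ((a+c)/(a+b+c+d)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ISLAND_RELATIONS


@dataclass
class EnrichmentResult:
    """One feature's 2x2 table with fold enrichment, odds ratio and P."""

    feature_name: str
    a: int  # mQTL-matched CpGs inside the feature
    b: int  # mQTL-matched CpGs outside
    c: int  # non-matched CpGs inside
    d: int  # non-matched CpGs outside
    fold_enrichment: float
    odds_ratio: float
    p: float

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_enrichment(membership_mqtl: np.ndarray,
                      membership_feature: np.ndarray,
                      feature_name: str = "feature") -> EnrichmentResult:
    """Two-sided Fisher exact test of feature overlap for mQTL-matched CpGs.

    The two-sided P sums hypergeometric probabilities of all tables at most
    as likely as the observed one (the standard convention).  Both margins
    must be non-degenerate.
    """
    mq = np.asarray(membership_mqtl, dtype=bool)
    ft = np.asarray(membership_feature, dtype=bool)
    if mq.shape != ft.shape:
        raise ValueError("membership vectors differ in length")
    if not (mq.any() and (~mq).any() and ft.any() and (~ft).any()):
        raise ValueError("a margin of the 2x2 table is empty; "
                         "enrichment undefined")
    a = int((mq & ft).sum())
    b = int((mq & ~ft).sum())
    c = int((~mq & ft).sum())
    d = int((~mq & ~ft).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    n = a + b + c + d
    fold = (a / (a + b)) / ((a + c) / n)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return EnrichmentResult(feature_name=feature_name, a=a, b=b, c=c, d=d,
                            fold_enrichment=float(fold),
                            odds_ratio=float(odds), p=float(p))


def enrichment_table(membership_mqtl: np.ndarray,
                     features: dict[str, np.ndarray]) -> pd.DataFrame:
    """Fisher enrichment for several feature tracks, one row per feature."""
    rows = []
    for name, member in features.items():
        r = fisher_enrichment(membership_mqtl, member, feature_name=name)
        rows.append({"feature": r.feature_name, "a": r.a, "b": r.b,
                     "c": r.c, "d": r.d,
                     "fold_enrichment": r.fold_enrichment,
                     "odds_ratio": r.odds_ratio, "p": r.p})
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def proportion_chisq(count1: int, n1: int, count2: int, n2: int,
                     ) -> tuple[float, float]:
    """Two-sample proportion test (chi-squared, no continuity correction)."""
    table = np.array([[count1, n1 - count1], [count2, n2 - count2]])
    if table.min() < 0 or n1 == 0 or n2 == 0:
        raise ValueError("invalid proportion-test counts")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def island_relation_test(cpgs: pd.DataFrame, mqtl_flags: np.ndarray,
                         ) -> pd.DataFrame:
    """Category shares among mQTL-matched CpGs vs all CpGs, with tests.

    ``cpgs`` needs an island_relation column; ``mqtl_flags`` marks the
    matched subset.  Comparison is against the full CpG set (superset).
    A combined shore-vs-rest row (N_Shore or S_Shore pooled) is appended.
    """
    flags = np.asarray(mqtl_flags, dtype=bool)
    if len(flags) != len(cpgs):
        raise ValueError("flag vector length mismatch")
    rel = cpgs["island_relation"].to_numpy()
    n_all, n_mqtl = len(rel), int(flags.sum())
    rows = []
    categories = list(ISLAND_RELATIONS) + ["Shore_combined"]
    for cat in categories:
        in_cat = (np.isin(rel, ["N_Shore", "S_Shore"])
                  if cat == "Shore_combined" else rel == cat)
        k_all, k_mqtl = int(in_cat.sum()), int((in_cat & flags).sum())
        if k_all == 0 or n_mqtl == 0:
            rows.append({"category": cat, "n_mqtl": k_mqtl, "n_all": k_all,
                         "prop_mqtl": np.nan, "prop_all": np.nan,
                         "chi2": np.nan, "p": np.nan, "stars": "NA"})
            continue
        prop_m, prop_a = k_mqtl / n_mqtl, k_all / n_all
        if prop_m == prop_a:
            chi2, p = 0.0, 1.0
        else:
            chi2, p = proportion_chisq(k_mqtl, n_mqtl, k_all, n_all)
        rows.append({"category": cat, "n_mqtl": k_mqtl, "n_all": k_all,
                     "prop_mqtl": prop_m, "prop_all": prop_a,
                     "chi2": chi2, "p": p, "stars": _stars(p)})
    return pd.DataFrame(rows)
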