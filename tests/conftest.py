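"""Shared fixtures: small synthetic cohorts reused across test modules.

Session-scoped cohorts keep the heavier scans (500 CpGs x 1000
permutations) to a single computation each.
"""

import logging

import numpy as np
import pandas as pd
import pytest

from mqtlewas.mqtl_scan import scan_dataset
from mqtlewas.synthetic_cohort import SimConfig, simulate_cohort

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two small strata with planted effects; fast, for plumbing tests."""
    cfg = SimConfig(n_samples={"NLW": 60, "LAT": 80}, n_variants=300,
                    n_cpgs=40, chrom_length=10_000_000, seed=11)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects: 500 CpGs, ~50 cis SNPs each, n = 300."""
    cfg = SimConfig(n_samples={"NLW": 300, "LAT": 40}, n_variants=2000,
                    n_cpgs=500, chrom_length=80_000_000,
                    frac_cpgs_with_mqtl=0.0, frac_cpgs_bw_assoc=0.0, seed=1)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_scan(null_cohort):
    """Full permutation scan of the null cohort's large stratum."""
    _, cohort = null_cohort
    d = cohort["strata"]["NLW"]
    return scan_dataset(d["methylation"], d["genotypes"], d["samples"],
                        n_perm=1000, seed=1)


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong planted mQTLs: effect 0.06/allele, MAF 0.3, noise SD 0.02."""
    cfg = SimConfig(n_samples={"NLW": 300, "LAT": 300}, n_variants=2000,
                    n_cpgs=500, chrom_length=80_000_000,
                    frac_cpgs_with_mqtl=0.2, mqtl_effect_fixed=0.06,
                    maf_range={"NLW": (0.3, 0.3), "LAT": (0.3, 0.3)},
                    frac_cpgs_bw_assoc=0.0, noise_sd=0.02, seed=2)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_scan(planted_cohort):
    _, cohort = planted_cohort
    d = cohort["strata"]["NLW"]
    return scan_dataset(d["methylation"], d["genotypes"], d["samples"],
                        n_perm=1000, seed=2)


@pytest.fixture(scope="session")
def ewas_cohort():
    """Planted birthweight effects alongside strong mQTLs, two strata."""
    cfg = SimConfig(n_samples={"NLW": 300, "LAT": 300}, n_variants=1000,
                    n_cpgs=200, chrom_length=40_000_000,
                    frac_cpgs_with_mqtl=0.3, mqtl_effect_fixed=0.06,
                    maf_range={"NLW": (0.3, 0.3), "LAT": (0.3, 0.3)},
                    frac_cpgs_bw_assoc=0.3, bw_effect_sd=0.02,
                    noise_sd=0.02, seed=3)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ewas_fit(ewas_cohort):
    """Scans of both strata, the pooled database, and paired EWAS fits."""
    from mqtlewas.ewas import fit_paired_dataset, meta_ewas
    from mqtlewas.meta_db import build_database

    _, cohort = ewas_cohort
    scans = []
    for s in ("NLW", "LAT"):
        d = cohort["strata"][s]
        scans.append(scan_dataset(d["methylation"], d["genotypes"],
                                  d["samples"], n_perm=1000, seed=3).table)
    db = build_database(scans)
    mqtl_tables, plain_tables = [], []
    for s in ("NLW", "LAT"):
        d = cohort["strata"][s]
        m, p = fit_paired_dataset(d["methylation"], d["samples"],
                                  d["genotypes"], db)
        mqtl_tables.append(m.table)
        plain_tables.append(p.table)
    return {"scans": scans, "db": db, "mqtl": mqtl_tables,
            "plain": plain_tables,
            "meta_mqtl": meta_ewas(mqtl_tables),
            "meta_plain": meta_ewas(plain_tables)}


@pytest.fixture()
def basic_samples():
    """Minimal valid covariate table for design-matrix tests."""
    rng = np.random.default_rng(0)
    n = 80
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": rng.choice(["F", "M"], n),
        "batch": rng.choice(["b0", "b1"], n),
        "case_status": rng.integers(0, 2, n),
        "gestational_age": rng.normal(39, 1.5, n).clip(31, 44),
        "birthweight": rng.normal(3400, 400, n).clip(1500),
        "maternal_weight_gain": rng.normal(13, 5, n).clip(0),
        "ancestry_group": "NLW",
    })
    for i in range(1, 11):
        df[f"pc{i}"] = rng.normal(0, 1, n)
    props = rng.dirichlet([2.5, 7, 1.5, 3, 3, 30, 4], n)
    for j, c in enumerate(["CD8T", "CD4T", "NK", "Bcell", "Mono", "nRBC"]):
        df[f"cell_{c}"] = props[:, j]
    return df
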