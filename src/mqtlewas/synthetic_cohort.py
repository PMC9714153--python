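"""Synthetic multi-stratum cohorts with planted cis-mQTL and birthweight effects.

The generator emulates the structure of a neonatal blood-spot study of two
self-reported ancestry strata ("NLW" and "LAT") that share one genome:
variant and CpG positions, LD-block layout, and the planted causal
architecture (which CpGs have a cis-mQTL, which are birthweight-associated,
and with what effect sizes) are drawn once from the global seed and shared
by every stratum, while allele frequencies, genotypes, covariates and noise
are stratum-specific.  The LAT stratum defaults to the larger sample size.

Genotypes are sums of two haplotypes produced by Gaussian-copula
thresholding: within an LD block the latent Gaussians follow an AR(1) with
correlation ``ld_rho``, so adjacent variants are correlated and blocks are
independent.  Methylation is additive on the raw beta scale,

    beta_ij = clip(mu_j + mqtl_beta_j * g_i + bw_beta_j * BW_i
                   + batch/sex/cell effects + noise, 0, 1),

with baseline levels ``mu_j`` drawn from a trimodal mixture favouring
0.1 / 0.5 / 0.9, the typical unmethylated / hemimethylated / methylated
modes of array data.  Birthweight is driven by gestational age and sex:

    BW_i = 3400 + 150 * (GA_i - 39) + 120 * I(male) + N(0, 400) grams,

with GA ~ N(39, 1.5) truncated below at 30 weeks so the downstream
gestational-age exclusion rule has subjects to act on.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (CELL_CLASSES, GenotypeMatrix, MethylationMatrix,
                         ISLAND_RELATIONS, validate_sample_table,
                         write_genotypes, write_methylation, write_samples)

STRATA = ("NLW", "LAT")

_ISLAND_PROBS = (0.31, 0.12, 0.12, 0.05, 0.05, 0.35)  # array-like composition
_CELL_ALPHA = np.array([2.5, 7.0, 1.5, 3.0, 3.0, 30.0, 4.0])  # Gran-dominated


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Effect sizes are on the methylation beta scale: ``mqtl_effect_sd`` in
    beta-units per effect allele, ``bw_effect_sd`` in beta-units per 1000 g
    of birthweight.  ``mqtl_effect_fixed`` and ``bw_effect_fixed``, when
    set, plant every corresponding effect at exactly that magnitude
    (random sign) instead of drawing it from the normal distribution.  ``mqtl_bw_effect`` (grams per allele) adds a
    direct genotype effect on birthweight at causal SNPs, creating the
    genotype-birthweight confounding scenario; it defaults to 0.
    """

    n_samples: dict = field(default_factory=lambda: {"NLW": 150, "LAT": 250})
    n_variants: int = 2000
    n_cpgs: int = 500
    chrom_length: int = 80_000_000
    maf_range: dict = field(default_factory=lambda: {"NLW": (0.05, 0.5),
                                                     "LAT": (0.08, 0.5)})
    ld_block_size: int = 10
    ld_rho: float = 0.8
    frac_cpgs_with_mqtl: float = 0.2
    mqtl_effect_sd: float = 0.05
    mqtl_effect_fixed: float | None = None
    frac_cpgs_bw_assoc: float = 0.05
    bw_effect_sd: float = 0.02
    bw_effect_fixed: float | None = None
    noise_sd: float = 0.02
    n_batches: int = 2
    frac_cpgs_cell_assoc: float = 0.2
    mqtl_bw_effect: float = 0.0
    cis_window_bp: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_cpgs_with_mqtl", "frac_cpgs_bw_assoc",
                     "frac_cpgs_cell_assoc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for s, n in self.n_samples.items():
            if n < 30:
                raise ValueError(f"need at least 30 samples per stratum ({s}: {n})")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("maf_range",):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class TruthTable:
    """Planted parameters: the oracle downstream recovery is judged against.

    ``cpgs`` has one row per CpG: causal_snp_id ('' if none), mqtl_beta
    (beta-units/allele), bw_beta (beta-units per gram).  ``cell_props``
    maps stratum -> samples x 7 DataFrame of true cell proportions.
    """

    cpgs: pd.DataFrame
    cell_props: dict = field(default_factory=dict)


def _rng(seed: int, *keys: str) -> np.random.Generator:
    """Stable named substream: scan order and parallelism never change draws."""
    words = [seed] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# shared genome layout
# ---------------------------------------------------------------------------

def variant_layout(cfg: SimConfig) -> pd.DataFrame:
    """Variant ids/positions/alleles, shared by all strata."""
    rng = _rng(cfg.seed, "variant-layout")
    pos = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_variants,
                             replace=False)) + 1
    alleles = rng.choice(len(_ALLELE_PAIRS), size=cfg.n_variants)
    ea = [_ALLELE_PAIRS[a][0] for a in alleles]
    oa = [_ALLELE_PAIRS[a][1] for a in alleles]
    return pd.DataFrame({
        "id": [f"snp{j:05d}" for j in range(cfg.n_variants)],
        "chrom": "chr1", "pos": pos.astype(int),
        "effect_allele": ea, "other_allele": oa,
    })


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def cpg_layout(cfg: SimConfig) -> pd.DataFrame:
    """CpG ids/positions/island annotation, shared by all strata."""
    rng = _rng(cfg.seed, "cpg-layout")
    pos = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_cpgs,
                             replace=False)) + 1
    rel = rng.choice(ISLAND_RELATIONS, size=cfg.n_cpgs, p=_ISLAND_PROBS)
    return pd.DataFrame({
        "id": [f"cg{j:06d}" for j in range(cfg.n_cpgs)],
        "chrom": "chr1", "pos": pos.astype(int),
        "island_relation": rel, "platform": "BOTH",
    })


def plant_truth(cfg: SimConfig) -> TruthTable:
    """Draw the causal architecture once (shared across strata).

    Each mQTL CpG is assigned the nearest variant within the half cis
    window as its causal SNP; exactly round(frac * n_cpgs) CpGs carry a
    birthweight effect.
    """
    rng = _rng(cfg.seed, "truth")
    variants = variant_layout(cfg)
    cpgs = cpg_layout(cfg)
    n = cfg.n_cpgs
    n_mqtl = int(round(cfg.frac_cpgs_with_mqtl * n))
    n_bw = int(round(cfg.frac_cpgs_bw_assoc * n))

    vpos = variants["pos"].to_numpy()
    half = cfg.cis_window_bp // 2
    causal = np.full(n, "", dtype=object)
    mqtl_beta = np.zeros(n)
    candidates = []
    for i, p in enumerate(cpgs["pos"].to_numpy()):
        j = np.argmin(np.abs(vpos - p))
        if abs(int(vpos[j]) - int(p)) <= half:
            candidates.append((i, j))
    rng.shuffle(candidates)
    for i, j in candidates[:n_mqtl]:
        causal[i] = variants["id"].iloc[j]
        if cfg.mqtl_effect_fixed is not None:
            mqtl_beta[i] = cfg.mqtl_effect_fixed * rng.choice([-1.0, 1.0])
        else:
            mqtl_beta[i] = rng.normal(0.0, cfg.mqtl_effect_sd)

    bw_beta = np.zeros(n)
    bw_idx = rng.choice(n, size=n_bw, replace=False)
    # per-gram scale: bw_effect_sd / bw_effect_fixed are per 1000 g
    if cfg.bw_effect_fixed is not None:
        draws = (cfg.bw_effect_fixed / 1000.0) * rng.choice([-1.0, 1.0],
                                                            size=n_bw)
    else:
        draws = rng.normal(0.0, cfg.bw_effect_sd / 1000.0, size=n_bw)
        draws[draws == 0.0] = cfg.bw_effect_sd / 1000.0
    bw_beta[bw_idx] = draws

    truth = cpgs[["id"]].copy().rename(columns={"id": "cpg_id"})
    truth["causal_snp_id"] = causal
    truth["mqtl_beta"] = mqtl_beta
    truth["bw_beta"] = bw_beta
    return TruthTable(cpgs=truth)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig, stratum: str) -> GenotypeMatrix:
    """Dosages as sums of two copula-threshold haplotypes with block LD."""
    if stratum not in cfg.n_samples:
        raise ValueError(f"unknown stratum {stratum!r}")
    variants = variant_layout(cfg)
    rng = _rng(cfg.seed, "genotypes", stratum)
    n = cfg.n_samples[stratum]
    m = cfg.n_variants
    lo, hi = cfg.maf_range[stratum]
    # tightly linked variants share similar frequencies: one base frequency
    # per block with a small jitter, all clipped to the stratum's range
    n_blocks = -(-m // cfg.ld_block_size)
    base = rng.uniform(lo, hi, size=n_blocks)
    freq = np.clip(np.repeat(base, cfg.ld_block_size)[:m]
                   + rng.uniform(-0.05, 0.05, size=m), lo, hi)
    thresh = stats.norm.ppf(freq)
    # ld_rho targets the allele-level correlation; invert the arcsine
    # attenuation of dichotomized Gaussians (exact at frequency 1/2)
    rho = np.sin(np.pi * cfg.ld_rho / 2.0)

    def haplotypes() -> np.ndarray:
        z = np.empty((n, m))
        innov = rng.standard_normal((n, m))
        for j in range(m):
            if j % cfg.ld_block_size == 0:
                z[:, j] = innov[:, j]
            else:
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho ** 2) * innov[:, j]
        return (z < thresh).astype(float)

    dosages = haplotypes() + haplotypes()
    variants = variants.copy()
    variants["maf"] = np.minimum(dosages.mean(axis=0) / 2.0,
                                 1.0 - dosages.mean(axis=0) / 2.0)
    sample_ids = [f"{stratum}_{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, sample_ids, variants)


# ---------------------------------------------------------------------------
# phenotypes and methylation
# ---------------------------------------------------------------------------

def simulate_phenotypes(cfg: SimConfig, genotypes: GenotypeMatrix,
                        stratum: str, truth: TruthTable | None = None,
                        ) -> tuple[pd.DataFrame, MethylationMatrix, TruthTable]:
    """Sample table, methylation matrix and truth for one stratum.

    Pass the shared ``truth`` from :func:`plant_truth` when simulating
    several strata of one cohort; omitted, it is derived from the config
    seed (identical either way).
    """
    if truth is None:
        truth = plant_truth(cfg)
    rng = _rng(cfg.seed, "phenotypes", stratum)
    n = genotypes.n_samples
    cpgs = cpg_layout(cfg)
    m = cfg.n_cpgs

    sex = rng.choice(["F", "M"], size=n)
    ga = stats.truncnorm.rvs((30 - 39) / 1.5, np.inf, loc=39, scale=1.5,
                             size=n, random_state=rng)
    bw = 3400 + 150 * (ga - 39) + 120 * (sex == "M") + rng.normal(0, 400, n)

    causal_ids = truth.cpgs["causal_snp_id"].to_numpy()
    mqtl_beta = truth.cpgs["mqtl_beta"].to_numpy()
    bw_beta = truth.cpgs["bw_beta"].to_numpy()
    vindex = {v: j for j, v in enumerate(genotypes.variants["id"])}

    if cfg.mqtl_bw_effect != 0.0:
        for snp in pd.unique(causal_ids[causal_ids != ""]):
            bw = bw + cfg.mqtl_bw_effect * genotypes.dosages[:, vindex[snp]]
    bw = np.maximum(bw, 500.0)

    batch = rng.integers(cfg.n_batches, size=n)
    props = rng.dirichlet(_CELL_ALPHA, size=n)
    mean_props = _CELL_ALPHA / _CELL_ALPHA.sum()

    # baseline levels: trimodal mixture typical of array beta distributions
    mode = rng.choice([0.1, 0.5, 0.9], size=m, p=[0.4, 0.2, 0.4])
    mu = np.clip(mode + rng.normal(0, 0.05, m), 0.05, 0.95)

    batch_eff = rng.normal(0, 0.005, size=(cfg.n_batches, m))
    sex_eff = np.where(rng.random(m) < 0.1, rng.normal(0, 0.01, m), 0.0)
    cell_class = rng.integers(len(CELL_CLASSES), size=m)
    cell_load = np.where(rng.random(m) < cfg.frac_cpgs_cell_assoc,
                         rng.normal(0, 0.1, m), 0.0)

    betas = np.tile(mu, (n, 1))
    betas += batch_eff[batch]
    betas += np.outer(sex == "M", sex_eff)
    betas += (props[:, cell_class] - mean_props[cell_class]) * cell_load
    betas += np.outer(bw - 3400.0, bw_beta)
    has_mqtl = causal_ids != ""
    if has_mqtl.any():
        cols = np.array([vindex[s] for s in causal_ids[has_mqtl]])
        betas[:, has_mqtl] += genotypes.dosages[:, cols] * mqtl_beta[has_mqtl]
    betas += rng.normal(0, cfg.noise_sd, size=(n, m))
    betas = np.clip(betas, 0.0, 1.0)

    mwg = np.maximum(rng.normal(13, 5, n), 0.0)
    mwg[rng.random(n) < 0.02] = np.nan

    samples = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "sex": sex,
        "batch": [f"b{b}" for b in batch],
        "case_status": rng.integers(0, 2, n),
        "gestational_age": ga,
        "birthweight": bw,
        "maternal_weight_gain": mwg,
        "ancestry_group": stratum,
    })
    for i in range(1, 11):
        samples[f"pc{i}"] = rng.normal(0, 1, n)
    for ci, cls in enumerate(CELL_CLASSES):
        if cls == "Gran":
            continue
        samples[f"cell_{cls}"] = props[:, ci]
    validate_sample_table(samples)

    truth.cell_props[stratum] = pd.DataFrame(
        props, index=genotypes.sample_ids, columns=list(CELL_CLASSES))
    meth = MethylationMatrix(betas, list(genotypes.sample_ids), cpgs)
    return samples, meth, truth


def simulate_cohort(cfg: SimConfig) -> dict:
    """All strata at once: {stratum: {genotypes, methylation, samples}} + truth."""
    truth = plant_truth(cfg)
    out = {"truth": truth, "strata": {}}
    for stratum in cfg.n_samples:
        g = simulate_genotypes(cfg, stratum)
        samples, meth, truth = simulate_phenotypes(cfg, g, stratum, truth)
        out["strata"][stratum] = {"genotypes": g, "methylation": meth,
                                  "samples": samples}
    return out


# ---------------------------------------------------------------------------
# deconvolution reference
# ---------------------------------------------------------------------------

def simulate_reference(n_cpgs: int = 200, seed: int = 0) -> pd.DataFrame:
    """Cell-type reference profiles (CpGs x 7 classes, mean beta per class).

    Rows are discriminating CpGs: each is near-fully methylated in a random
    subset of classes and unmethylated in the rest, which keeps the class
    columns well separated (finite condition number).
    """
    rng = _rng(seed, "cell-reference")
    k = len(CELL_CLASSES)
    high = rng.random((n_cpgs, k)) < 0.5
    ref = np.where(high, rng.uniform(0.75, 0.95, (n_cpgs, k)),
                   rng.uniform(0.05, 0.25, (n_cpgs, k)))
    return pd.DataFrame(ref, index=[f"ref_cg{j:05d}" for j in range(n_cpgs)],
                        columns=list(CELL_CLASSES))


def simulate_mixture(reference: pd.DataFrame, proportions: np.ndarray,
                     noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Bulk profile R @ p with optional i.i.d. noise, clipped to [0, 1]."""
    rng = _rng(seed, "cell-mixture")
    y = reference.to_numpy(float) @ np.asarray(proportions, dtype=float)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=y.shape)
    return np.clip(y, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fixture output
# ---------------------------------------------------------------------------

def write_cohort(directory: str | Path, cohort: dict, force: bool = False,
                 genotype_format: str = "dosage_tsv") -> None:
    """Write every stratum's artifacts plus the truth table to a directory."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty (pass force=True)")
    directory.mkdir(parents=True, exist_ok=True)
    for stratum, data in cohort["strata"].items():
        if genotype_format == "vcf":
            from .io_formats import write_vcf
            write_vcf(data["genotypes"], directory / f"{stratum}.genotypes.vcf")
        else:
            write_genotypes(data["genotypes"],
                            directory / f"{stratum}.dosages.tsv")
        write_methylation(data["methylation"],
                          directory / f"{stratum}.methylation.tsv")
        write_samples(data["samples"], directory / f"{stratum}.samples.tsv")
    truth: TruthTable = cohort["truth"]
    truth.cpgs.to_csv(directory / "truth.cpgs.tsv", sep="\t", index=False,
                      na_rep="NA")
    for stratum, props in truth.cell_props.items():
        props.to_csv(directory / f"truth.cells.{stratum}.tsv", sep="\t",
                     na_rep="NA", index_label="sample_id")
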