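"""Readers, writers and validated containers for every on-disk artifact.

Coordinate conventions
----------------------
CpG and SNP positions are 1-based throughout, matching array manifests.
BED feature files keep their native 0-based half-open intervals; the
conversion is localized in :func:`read_features`: a CpG at 1-based position
``p`` overlaps the interval ``[start, end)`` iff ``start <= p - 1 < end``.

All tabular artifacts are tab-delimited UTF-8 TSV with ``NA`` for missing.
Genotype dosages count copies of the effect allele (0..2); missing dosages
are stored as NaN and mean-imputed per variant just before regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
PLATFORMS = ("K450", "EPIC", "BOTH")
CELL_CLASSES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran", "nRBC")
CELL_COVARIATE_COLUMNS = tuple(
    f"cell_{c}" for c in ("CD8T", "CD4T", "NK", "Bcell", "Mono", "nRBC"))

SAMPLE_REQUIRED_COLUMNS = (
    "sample_id", "sex", "batch", "case_status", "gestational_age",
    "birthweight", "ancestry_group",
) + tuple(f"pc{i}" for i in range(1, 11)) + CELL_COVARIATE_COLUMNS


class ParseError(ValueError):
    """Malformed record in an input file; the message names the line."""


class ValidationError(ValueError):
    """An input violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages`` is float (NaN = missing call), samples in rows following
    ``sample_ids``.  ``variants`` has columns id, chrom, pos (1-based),
    effect_allele, other_allele, maf and is sorted by (chrom, pos).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValidationError(f"{int(bad)} dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> pd.Index:
        return pd.Index(self.variants["id"])

    def dosage_of(self, snp_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(snp_id)
        return self.dosages[:, idx[0]]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, mask], list(self.sample_ids),
                              self.variants.loc[np.asarray(mask)].reset_index(drop=True))

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[idx], list(sample_ids),
                              self.variants.copy())


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta-value matrix with CpG metadata.

    Betas lie in [0, 1] (NaN allowed for missing probes).  ``cpgs`` has
    columns id, chrom, pos (1-based), island_relation, platform.
    """

    betas: np.ndarray
    sample_ids: list[str]
    cpgs: pd.DataFrame

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.sample_ids), len(self.cpgs)):
            raise ValidationError("beta matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.betas < 0) | (self.betas > 1))
        if bad:
            raise ValidationError(f"{int(bad)} beta values outside [0, 1]")
        unknown = set(self.cpgs["island_relation"]) - set(ISLAND_RELATIONS)
        if unknown:
            raise ValidationError(f"unknown island_relation values: {sorted(unknown)}")
        self.cpgs = self.cpgs.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    def beta_of(self, cpg_id: str) -> np.ndarray:
        idx = self.cpgs.index[self.cpgs["id"] == cpg_id]
        if len(idx) == 0:
            raise KeyError(cpg_id)
        return self.betas[:, idx[0]]

    def subset_samples(self, sample_ids: list[str]) -> "MethylationMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return MethylationMatrix(self.betas[idx], list(sample_ids), self.cpgs.copy())


@dataclass
class FeatureSet:
    """Per-chromosome interval index over one BED track."""

    name: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)
    n_intervals: int = 0

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position ``pos`` falls in any interval."""
        tree = self.trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlaps_point(pos - 1))

    def membership(self, chroms, positions) -> np.ndarray:
        """Vectorized :meth:`overlaps_point` over parallel arrays."""
        return np.array([self.overlaps_point(c, p)
                         for c, p in zip(chroms, positions)], dtype=bool)


@dataclass
class QcReport:
    """Counts of variants removed by each genotype QC filter, in order."""

    n_input: int
    removed_missingness: int
    removed_hwe: int
    removed_maf: int
    removed_imputation_r2: int
    n_output: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the covariate-table invariants and return the frame.

    Cell fractions must each lie in [0, 1] and sum to at most 1 per sample
    (granulocytes are the omitted remainder); gestational age and
    birthweight must be positive.
    """
    missing = [c for c in SAMPLE_REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    bad_sex = set(samples["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValidationError(f"sex values outside {{F, M}}: {sorted(bad_sex)}")
    cells = samples[list(CELL_COVARIATE_COLUMNS)].to_numpy(float)
    if np.any((cells < 0) | (cells > 1)):
        raise ValidationError("cell fractions outside [0, 1]")
    if np.any(cells.sum(axis=1) > 1 + 1e-9):
        raise ValidationError("cell fractions sum above 1")
    if np.any(samples["gestational_age"].to_numpy(float) <= 0):
        raise ValidationError("gestational_age must be positive")
    if np.any(samples["birthweight"].to_numpy(float) <= 0):
        raise ValidationError("birthweight must be positive")
    return samples


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str,
                                                              "batch": str})
    return validate_sample_table(df)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Per-variant minor-allele frequency from effect-allele dosages."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def _sort_variants(dosages: np.ndarray, variants: pd.DataFrame):
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    return dosages[:, order], variants.iloc[order].reset_index(drop=True)


def read_genotypes(path: str | Path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT or DS) or a dosage TSV.

    Multiallelic VCF records are skipped with a warning.  Variants come
    back sorted by (chrom, pos) with per-variant MAF computed from the
    dosages; sample order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols, meta = [], []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = rec.genotype.array()
            alleles = np.asarray(gts[:, :2], dtype=float)
            alleles[alleles < 0] = np.nan
            dose = alleles.sum(axis=1)
        with np.errstate(invalid="ignore"):
            if np.nansum((dose < 0) | (dose > 2)):
                raise ParseError(f"{path}: record {i + 1} ({rec.ID}): "
                                 "dosage outside [0, 2]")
        cols.append(dose)
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", str(rec.CHROM),
                     int(rec.POS), rec.ALT[0], rec.REF))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multiallelic record(s)")
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos",
                                           "effect_allele", "other_allele"])
    variants["maf"] = compute_maf(dosages)
    dosages, variants = _sort_variants(dosages, variants)
    g = GenotypeMatrix(dosages, sample_ids, variants)
    g.n_skipped_records = n_skipped
    return g


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    dosages = df.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nansum((dosages < 0) | (dosages > 2)):
            raise ValidationError(f"{path}: dosage outside [0, 2]")
    variants = pd.DataFrame({"id": df.columns})
    manifest = path.with_suffix(".variants.tsv")
    if manifest.exists():
        vm = pd.read_csv(manifest, sep="\t", na_values=["NA"],
                         dtype={"id": str, "chrom": str})
        variants = variants.merge(vm, on="id", how="left")
    else:
        variants["chrom"] = "NA"
        variants["pos"] = np.arange(1, len(df.columns) + 1)
        variants["effect_allele"] = "A"
        variants["other_allele"] = "G"
    variants["maf"] = compute_maf(dosages)
    if "pos" in variants:
        order = np.lexsort((variants["pos"].to_numpy(),
                            variants["chrom"].to_numpy()))
        dosages = dosages[:, order]
        variants = variants.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(dosages, [str(s) for s in df.index], variants)


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage TSV plus a sibling ``.variants.tsv`` manifest."""
    path = Path(path)
    pd.DataFrame(g.dosages, index=pd.Index(g.sample_ids, name="sample_id"),
                 columns=g.variants["id"]).to_csv(path, sep="\t", na_rep="NA")
    g.variants.to_csv(path.with_suffix(".variants.tsv"), sep="\t",
                      index=False, na_rep="NA")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal VCF 4.2 with DS (dosage) genotype fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Effect allele dosage">\n')
        chroms = pd.unique(g.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, v in g.variants.iterrows():
            ds = ["." if np.isnan(d) else f"{d:g}" for d in g.dosages[:, j]]
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['other_allele']}"
                     f"\t{v['effect_allele']}\t.\tPASS\t.\tDS\t" + "\t".join(ds)
                     + "\n")


def impute_missing_dosages(g: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing dosages per variant (post-QC gaps only)."""
    d = g.dosages.copy()
    if np.isnan(d).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(d, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = means[nan_c]
    return GenotypeMatrix(d, list(g.sample_ids), g.variants.copy())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg equilibrium P value from genotype counts.

    Conditional on allele counts, the heterozygote count follows the
    Levene-Haldane distribution; the P value sums the probabilities of all
    heterozygote counts no more likely than the observed one (the standard
    exact HWE test).  Computed with log factorials for stability.
    """
    from scipy.special import gammaln

    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    het_values = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | allele counts) up to a common constant
    homr = (rare - het_values) // 2
    homc = (n - het_values - homr)
    logp = (het_values * np.log(2.0)
            - gammaln(het_values + 1) - gammaln(homr + 1) - gammaln(homc + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[het_values == n_ab]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(prob[prob <= obs[0] * (1.0 + 1e-9)].sum())


def apply_genotype_qc(g: GenotypeMatrix, hwe_p_min: float = 1e-4,
                      maf_min: float = 0.01, miss_max: float = 0.05,
                      imp_r2_min: float = 0.6,
                      ) -> tuple[GenotypeMatrix, QcReport]:
    """Standard variant-level QC: missingness, HWE, MAF, imputation quality.

    Filters apply in order missingness -> HWE -> MAF -> imputation R2, each
    counted against the survivors of the previous one.  The HWE exact test
    runs on rounded hard calls; samples whose dosage at a site has
    fractional part above 0.1 are excluded from that site's HWE count.
    The imputation-R2 filter only applies when the variant metadata carries
    an ``imp_r2`` column.
    """
    d = g.dosages
    n = g.n_samples
    keep = np.ones(g.n_variants, dtype=bool)

    miss = np.isnan(d).sum(axis=0) / n
    fail_miss = miss > miss_max
    removed_miss = int(fail_miss.sum())
    keep &= ~fail_miss

    removed_hwe = 0
    hwe_fail = np.zeros(g.n_variants, dtype=bool)
    for j in np.where(keep)[0]:
        col = d[:, j]
        col = col[~np.isnan(col)]
        frac = np.abs(col - np.round(col))
        hard = np.round(col[frac <= 0.1]).astype(int)
        counts = np.bincount(hard, minlength=3)
        if hwe_exact_test(counts[0], counts[1], counts[2]) < hwe_p_min:
            hwe_fail[j] = True
            removed_hwe += 1
    keep &= ~hwe_fail

    maf = compute_maf(d)
    fail_maf = keep & (maf < maf_min)
    removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    removed_r2 = 0
    if "imp_r2" in g.variants.columns:
        r2 = g.variants["imp_r2"].to_numpy(float)
        fail_r2 = keep & ~np.isnan(r2) & (r2 <= imp_r2_min)
        removed_r2 = int(fail_r2.sum())
        keep &= ~fail_r2

    if not keep.any():
        raise ValidationError("genotype QC removed every variant")
    out = g.subset_variants(keep)
    report = QcReport(n_input=g.n_variants, removed_missingness=removed_miss,
                      removed_hwe=removed_hwe, removed_maf=removed_maf,
                      removed_imputation_r2=removed_r2,
                      n_output=out.n_variants)
    return out, report


# ---------------------------------------------------------------------------
# methylation and manifests
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path, manifest_path: str | Path | None = None,
                     ) -> MethylationMatrix:
    """Read a samples x CpGs beta TSV plus its CpG manifest."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    manifest_path = Path(manifest_path) if manifest_path else path.with_suffix(
        ".cpgs.tsv")
    cpgs = pd.read_csv(manifest_path, sep="\t", na_values=["NA"],
                       dtype={"id": str, "chrom": str})
    cpgs = cpgs.set_index("id").loc[df.columns].reset_index()
    return MethylationMatrix(df.to_numpy(float), [str(s) for s in df.index], cpgs)


def write_methylation(m: MethylationMatrix, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(m.betas, index=pd.Index(m.sample_ids, name="sample_id"),
                 columns=m.cpgs["id"]).to_csv(path, sep="\t", na_rep="NA")
    m.cpgs.to_csv(path.with_suffix(".cpgs.tsv"), sep="\t", index=False,
                  na_rep="NA")


# ---------------------------------------------------------------------------
# BED feature tracks
# ---------------------------------------------------------------------------

def read_features(path: str | Path, name: str | None = None) -> FeatureSet:
    """Read a BED3+ track into a per-chromosome interval index.

    BED is 0-based half-open; see the module docstring for the point-overlap
    convention.
    """
    path = Path(path)
    trees: dict[str, IntervalTree] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
            n += 1
    return FeatureSet(name=name or path.stem, trees=trees, n_intervals=n)
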