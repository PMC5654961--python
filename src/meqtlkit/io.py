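"""Readers and writers for the standard input/output formats.

Formats handled here:

* genotypes — VCF (GT hard calls, via cyvcf2) or a TSV dosage dialect with
  header ``snp_id  chrom  pos  <sample...>`` and integer dosages in {0,1,2};
* methylation — TSV with header ``cpg_id  chrom  pos  <sample...>`` and beta
  values on the 0-100 scale (0-1 inputs are auto-rescaled with a warning);
* GWAS summary statistics — TSV ``snp_id  chrom  pos  p  maf``;
* feature tracks — BED3+ (0-based half-open);
* meQTL lists — TSV ``snp_id  cpg_id  p`` plus optional extra columns;
* flat key=value analysis configuration files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FeatureTrack,
    GenotypeMatrix,
    MeqtlMap,
    MethylationMatrix,
    compute_maf,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_methylation",
    "write_methylation",
    "read_gwas",
    "write_gwas",
    "read_bed",
    "write_bed",
    "read_meqtl_list",
    "write_meqtl_map",
    "read_covariates",
    "AnalysisConfig",
    "read_config",
    "write_config",
    "align_samples",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path, format: str | None = None, impute_mean: bool = False
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV dosage dialect.

    ``format`` is inferred from the file suffix when omitted (``.vcf`` vs
    anything else).  Missing genotypes raise unless ``impute_mean`` is set, in
    which case they are replaced by the SNP's mean dosage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path, impute_mean=impute_mean)
    if format == "tsv":
        return _read_genotypes_tsv(path, impute_mean=impute_mean)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_vcf(path: Path, impute_mean: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # genotype tuples rather than gt_types: unambiguous about missingness
        dos = np.empty(len(samples), dtype=float)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dos[i] = np.nan
            else:
                dos[i] = (a > 0) + (b > 0)
        if np.isnan(dos).any():
            if not impute_mean:
                raise ValueError(
                    f"missing genotype at record {var.ID or f'{var.CHROM}:{var.POS}'}"
                )
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append(dos)
        meta.append((snp_id, normalize_chrom(var.CHROM), int(var.POS)))
    if n_multi:
        logger.info("skipped %d non-biallelic VCF records", n_multi)
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos"])
    snps["maf"] = compute_maf(dosages) if len(snps) else []
    return GenotypeMatrix(samples=samples, dosages=dosages, snps=snps)


def _read_genotypes_tsv(path: Path, impute_mean: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = ["snp_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"genotype TSV must start with columns {required}, got {list(df.columns[:3])}"
        )
    samples = list(df.columns[3:])
    dosages = df[samples].to_numpy(dtype=float).T  # samples x snps
    if np.isnan(dosages).any():
        if not impute_mean:
            bad = df.loc[np.isnan(dosages).any(axis=0), "snp_id"].iloc[0]
            raise ValueError(f"missing dosage at SNP {bad!r}")
        col_mean = np.nanmean(dosages, axis=0)
        idx = np.where(np.isnan(dosages))
        dosages[idx] = col_mean[idx[1]]
    finite = dosages[~np.isnan(dosages)]
    if ((finite < 0) | (finite > 2)).any() or not np.allclose(
        finite, np.round(finite)
    ):
        j = np.argwhere((dosages < 0) | (dosages > 2) | (dosages != np.round(dosages)))
        bad = df["snp_id"].iloc[j[0][1]] if len(j) else "?"
        raise ValueError(f"dosage out of range at SNP {bad!r} (must be integer in 0..2)")
    snps = df[required].copy()
    snps["chrom"] = snps["chrom"].map(normalize_chrom)
    snps["pos"] = snps["pos"].astype(int)
    snps["maf"] = compute_maf(dosages)
    return GenotypeMatrix(samples=samples, dosages=dosages, snps=snps)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dosage dialect (lossless for integer dosage matrices)."""
    dos = gm.dosages.T
    integral = bool(np.allclose(dos, np.round(dos)))
    body = pd.DataFrame(
        dos.astype(int) if integral else dos, columns=list(gm.samples)
    )
    out = pd.concat(
        [gm.snps[["snp_id", "chrom", "pos"]].reset_index(drop=True), body], axis=1
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path, snp_proximal: set | None = None) -> MethylationMatrix:
    """Read a beta-value matrix; ``snp_proximal`` optionally flags probe ids
    with an annotated SNP within 10 bp / at the single-base extension."""
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "chrom": str})
    required = ["cpg_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"methylation TSV must start with columns {required}, got {list(df.columns[:3])}"
        )
    samples = list(df.columns[3:])
    values = df[samples].to_numpy(dtype=float).T
    if values.size and np.nanmax(values) <= 1.0:
        logger.warning("methylation values all <= 1; rescaling to the 0-100 beta scale")
        values = values * 100.0
    if values.size and (np.nanmin(values) < 0 or np.nanmax(values) > 100):
        raise ValueError("methylation values outside [0, 100] after rescale")
    cpgs = df[required].copy()
    cpgs["chrom"] = cpgs["chrom"].map(normalize_chrom)
    cpgs["pos"] = cpgs["pos"].astype(int)
    cpgs["sd"] = values.std(axis=0, ddof=1) if len(samples) > 1 else 0.0
    prox = snp_proximal or set()
    cpgs["snp_proximal"] = cpgs["cpg_id"].isin(prox)
    return MethylationMatrix(samples=samples, values=values, cpgs=cpgs)


def write_methylation(mm: MethylationMatrix, path: str | Path) -> None:
    body = pd.DataFrame(mm.values.T, columns=list(mm.samples))
    out = pd.concat(
        [mm.cpgs[["cpg_id", "chrom", "pos"]].reset_index(drop=True), body], axis=1
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read GWAS summary statistics; p must lie in (0, 1], maf in (0, 0.5]."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos", "p", "maf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1), "snp_id"].iloc[0]
        raise ValueError(f"GWAS p out of (0, 1] at SNP {bad!r}")
    if ((df["maf"] <= 0) | (df["maf"] > 0.5)).any():
        bad = df.loc[(df["maf"] <= 0) | (df["maf"] > 0.5), "snp_id"].iloc[0]
        raise ValueError(f"GWAS maf out of (0, 0.5] at SNP {bad!r}")
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    return df


def write_gwas(df: pd.DataFrame, path: str | Path) -> None:
    df[["snp_id", "chrom", "pos", "p", "maf"]].to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


# ---------------------------------------------------------------------------
# BED feature tracks
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None, use_name_column: bool = False) -> FeatureTrack:
    """Read a BED3+ track.  Track name defaults to the file stem; with
    ``use_name_column`` the 4th column of the first data line overrides it."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    track_name = name or path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if use_name_column and len(parts) >= 4 and name is None:
                track_name = parts[3]
            intervals.append((chrom, start, end))
    return FeatureTrack(name=track_name, intervals=intervals)


def write_bed(track: FeatureTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# meQTL lists
# ---------------------------------------------------------------------------

def read_meqtl_list(path: str | Path, label: str | None = None) -> MeqtlMap:
    """Read an externally published (or previously written) meQTL list."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "cpg_id": str})
    missing = {"snp_id", "cpg_id"} - set(df.columns)
    if missing:
        raise ValueError(f"meQTL list missing columns: {sorted(missing)}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["snp_id", "cpg_id"]).reset_index(drop=True)
    if len(df) < n0:
        logger.info("deduplicated %d repeated (snp, cpg) rows", n0 - len(df))
    return MeqtlMap(records=df, provenance={"label": label or Path(path).stem})


def write_meqtl_map(m: MeqtlMap, path: str | Path) -> None:
    m.records.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate table: ``sample_id`` column plus PC1, PC2, sex."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "PC1", "PC2", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    return df


def align_samples(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    covariates: pd.DataFrame | None = None,
):
    """Restrict all inputs to the sample-ID intersection, in genotype order.

    Returns (genotypes, methylation, covariates) with identical sample order;
    covariates comes back as a DataFrame indexed like the sample list (or None).
    """
    common = set(genotypes.samples) & set(methylation.samples)
    if covariates is not None:
        common &= set(covariates["sample_id"])
    n_drop = (
        len(set(genotypes.samples) | set(methylation.samples)) - len(common)
    )
    if n_drop:
        logger.info("sample alignment dropped %d unmatched sample IDs", n_drop)
    if not common:
        raise ValueError("no samples shared across inputs")
    keep = [s for s in genotypes.samples if s in common]
    g_idx = np.array([genotypes.samples.index(s) for s in keep])
    m_idx = np.array([methylation.samples.index(s) for s in keep])
    gm = genotypes.subset_samples(g_idx)
    mm = methylation.subset_samples(m_idx)
    cov = None
    if covariates is not None:
        cov = covariates.set_index("sample_id").loc[keep].reset_index()
    return gm, mm, cov


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Flat pipeline configuration; serialized as ``key = value`` lines."""

    # input paths
    genotypes: str = ""
    methylation: str = ""
    covariates: str = ""
    gwas: str = ""
    genes: str = ""
    features_dir: str = ""
    blocks: str = ""
    go_terms: str = ""
    # query parameters
    sd_cutoff: float = 0.15
    maf_min: float = 0.05
    window_bp: int = 1_000_000
    # discovery / FDR
    fdr_level: float = 0.05
    n_permutations: int = 100
    chrom_subset: str = ""  # comma-separated, empty = all
    # enrichment
    n_null_sets: int = 1000
    gwas_p_threshold: float = 1e-4
    proxy_r2: float = 0.8
    prune_r2: float = 0.7
    prune_window_bp: int = 500_000
    maf_bin_width: float = 0.05
    opportunity_bin_width: int = 50
    # seeds, one per stochastic stage
    seed_simulate: int = 1
    seed_fdr: int = 2
    seed_nullsets: int = 3
    seed_downsample: int = 4

    def __post_init__(self) -> None:
        for name in ("fdr_level", "gwas_p_threshold", "proxy_r2", "prune_r2"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("window_bp", "prune_window_bp", "opportunity_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def chrom_subset_list(self) -> list[str] | None:
        if not self.chrom_subset:
            return None
        return [normalize_chrom(c.strip()) for c in self.chrom_subset.split(",")]


def read_config(path: str | Path) -> AnalysisConfig:
    kwargs: dict = {}
    types = {f.name: f.type for f in fields(AnalysisConfig)}
    defaults = AnalysisConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (x.strip() for x in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            target = type(getattr(defaults, key))
            kwargs[key] = target(value) if target is not str else value
    return AnalysisConfig(**kwargs)


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fields(cfg):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")
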