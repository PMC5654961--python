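"""Synthetic inputs with planted, parameterized structure.

Every pipeline stage is exercisable offline: LD-blocked diploid genotypes come
from a Gaussian copula (AR(1) latent correlation within a block, independent
blocks, HWE haplotype thresholding at the MAF quantile), methylation is
beta-valued with planted additive SNP effects plus covariate and Gaussian
noise structure, GWAS p-values carry a planted sub-threshold meQTL enrichment
factor, feature tracks plant a target-CpG odds ratio, and gene/GO annotations
have non-uniform probes per gene with one planted enriched term.

All generators are deterministic given the scenario seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .enrichment import stratify_snps
from .types import FeatureTrack, GenotypeMatrix, MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "simulate_genotypes",
    "simulate_snp_meta",
    "simulate_cpg_meta",
    "simulate_methylation",
    "choose_planted_pairs",
    "simulate_gwas",
    "simulate_annotations",
    "make_scenario",
    "SCENARIOS",
]


@dataclass
class ScenarioSpec:
    """Knobs for one synthetic data bundle."""

    n_samples: int = 150
    n_snps: int = 200
    n_cpgs: int = 200
    n_chroms: int = 2
    block_size: int = 10          # SNPs per LD block
    rho: float = 0.8              # latent AR(1) correlation within a block
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_step_bp: int = 5_000
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_planted: int = 0            # auto-chosen pairs when planted_pairs empty
    planted_slope: float = 5.0    # beta units per allele
    planted_window_bp: int = 50_000
    noise_sd: float = 10.0        # beta units
    pc_effects: tuple[float, float] = (2.0, 2.0)
    sex_effect: float = 2.0
    gwas_threshold: float = 1e-4
    enrichment_factor: float = 1.0
    n_disease: int = 100
    meqtl_baseline: float = 0.2   # fraction of SNPs that are true meQTLs (gwas scenarios)
    feature_odds: float = 1.0
    feature_baseline: float = 0.2
    target_frac: float = 0.25     # fraction of CpGs marked as meQTL targets (annotation scenarios)
    probes_per_gene: tuple = ((1, 2, 3, 4, 8), (0.35, 0.25, 0.2, 0.1, 0.1))
    n_go_terms: int = 40
    go_term_prob: float = 0.10
    plant_go_term: bool = False
    snp_proximal_frac: float = 0.0
    maf_bin_width: float = 0.05
    opportunity_bin_width: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.enrichment_factor * self.meqtl_baseline > 1:
            raise ValueError("enrichment_factor x baseline meQTL proportion exceeds 1")


def _chrom_of(i: int, per_chrom: int) -> str:
    return str(i // per_chrom + 1)


def simulate_snp_meta(spec: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    """SNP metadata alone (ids, positions, target MAFs), without dosages."""
    per_chrom = -(-spec.n_snps // spec.n_chroms)
    maf = rng.uniform(*spec.maf_range, size=spec.n_snps)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:06d}" for i in range(spec.n_snps)],
            "chrom": [_chrom_of(i, per_chrom) for i in range(spec.n_snps)],
            "pos": [
                (i % per_chrom) * spec.snp_step_bp + spec.snp_step_bp
                for i in range(spec.n_snps)
            ],
            "maf": maf,
        }
    )


def simulate_genotypes(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Gaussian-copula LD-blocked diploid genotypes.

    Within each block the latent haplotype variables follow an AR(1) process
    with parameter ``rho``; each SNP's allele indicator thresholds its latent
    value at the MAF quantile, and the dosage is the sum of two independent
    haplotypes (HWE).  Blocks are independent and never span chromosomes.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    meta = simulate_snp_meta(spec, rng)
    n_hap = 2 * spec.n_samples
    dosages = np.empty((spec.n_samples, spec.n_snps))
    maf = meta["maf"].to_numpy()
    chroms = meta["chrom"].to_numpy()
    start = 0
    while start < spec.n_snps:
        stop = min(start + spec.block_size, spec.n_snps)
        # truncate block at chromosome boundary
        while stop > start + 1 and chroms[stop - 1] != chroms[start]:
            stop -= 1
        width = stop - start
        z = np.empty((n_hap, width))
        z[:, 0] = rng.standard_normal(n_hap)
        for k in range(1, width):
            z[:, k] = spec.rho * z[:, k - 1] + np.sqrt(
                1 - spec.rho**2
            ) * rng.standard_normal(n_hap)
        thresh = stats.norm.ppf(maf[start:stop])
        alleles = (z < thresh).astype(float)
        dosages[:, start:stop] = alleles[: spec.n_samples] + alleles[spec.n_samples:]
        start = stop
    meta["maf"] = np.minimum(dosages.mean(axis=0) / 2, 1 - dosages.mean(axis=0) / 2)
    return GenotypeMatrix(samples=[f"S{i + 1:04d}" for i in range(spec.n_samples)],
                          dosages=dosages, snps=meta)


def simulate_cpg_meta(spec: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    """CpG metadata: positions interleaved with the SNP grid, offset by half a
    step so no CpG coincides with a SNP."""
    per_chrom = -(-spec.n_cpgs // spec.n_chroms)
    snps_per_chrom = -(-spec.n_snps // spec.n_chroms)
    span = snps_per_chrom * spec.snp_step_bp
    step = max(span // max(per_chrom, 1), 1)
    prox = rng.random(spec.n_cpgs) < spec.snp_proximal_frac
    return pd.DataFrame(
        {
            "cpg_id": [f"cg{i + 1:06d}" for i in range(spec.n_cpgs)],
            "chrom": [_chrom_of(i, per_chrom) for i in range(spec.n_cpgs)],
            "pos": [(i % per_chrom) * step + step // 2 + 1 for i in range(spec.n_cpgs)],
            "snp_proximal": prox,
        }
    )


def choose_planted_pairs(
    snp_meta: pd.DataFrame,
    cpg_meta: pd.DataFrame,
    n_pairs: int,
    slope: float,
    window_bp: int,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    """Pick cis SNP-CpG pairs (distinct CpGs) for effect planting."""
    cpg_order = rng.permutation(len(cpg_meta))
    pairs: list[tuple[str, str, float]] = []
    spos = snp_meta["pos"].to_numpy()
    schrom = snp_meta["chrom"].to_numpy()
    for ci in cpg_order:
        if len(pairs) >= n_pairs:
            break
        row = cpg_meta.iloc[ci]
        ok = np.flatnonzero(
            (schrom == row["chrom"]) & (np.abs(spos - row["pos"]) <= window_bp)
        )
        if len(ok) == 0:
            continue
        si = rng.choice(ok)
        pairs.append((snp_meta["snp_id"].iloc[si], row["cpg_id"], slope))
    if len(pairs) < n_pairs:
        raise ValueError(f"could only place {len(pairs)} of {n_pairs} planted pairs")
    return pairs


def simulate_methylation(
    genotypes: GenotypeMatrix,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
    cpg_meta: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Beta-valued methylation with planted additive SNP effects.

    ``y = mu_j + sum(planted beta * dosage) + g1*PC1 + g2*PC2 + d*sex + eps``
    with ``mu_j ~ U(20, 80)`` and ``eps ~ N(0, noise_sd^2)``; PCs are standard
    normal and sex is Bernoulli(0.5) (simulated, not derived from genotypes).
    Values are clipped to [0, 100]; the clip fraction is logged and a planted
    effect pushing more than 5% of its CpG's values to a bound warns.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    if cpg_meta is None:
        cpg_meta = simulate_cpg_meta(spec, rng)
    n, n_cpgs = genotypes.n_samples, len(cpg_meta)
    mu = rng.uniform(20, 80, size=n_cpgs)
    pcs = rng.standard_normal((n, 2))
    sex = rng.integers(0, 2, size=n).astype(float)
    y = np.tile(mu, (n, 1))
    y += pcs[:, [0]] * spec.pc_effects[0] + pcs[:, [1]] * spec.pc_effects[1]
    y += sex[:, None] * spec.sex_effect
    snp_col = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    cpg_col = {c: i for i, c in enumerate(cpg_meta["cpg_id"])}
    planted_cols: list[int] = []
    for snp_id, cpg_id, beta in spec.planted_pairs:
        y[:, cpg_col[cpg_id]] += beta * genotypes.dosages[:, snp_col[snp_id]]
        planted_cols.append(cpg_col[cpg_id])
    if spec.noise_sd > 0:
        y += rng.normal(0, spec.noise_sd, size=y.shape)
    clipped = (y < 0) | (y > 100)
    frac = clipped.mean()
    if frac > 0:
        logger.info("clipped %.3f%% of methylation values to [0, 100]", 100 * frac)
    for c in planted_cols:
        if clipped[:, c].mean() > 0.05:
            logger.warning(
                "planted effect at CpG column %d drives %.1f%% of values to the "
                "clip bounds", c, 100 * clipped[:, c].mean(),
            )
    y = np.clip(y, 0, 100)
    cpgs = cpg_meta.copy()
    cpgs["sd"] = y.std(axis=0, ddof=1)
    mm = MethylationMatrix(samples=list(genotypes.samples), values=y, cpgs=cpgs)
    cov = pd.DataFrame(
        {"sample_id": genotypes.samples, "PC1": pcs[:, 0], "PC2": pcs[:, 1], "sex": sex}
    )
    return mm, cov


def simulate_gwas(
    snp_meta: pd.DataFrame,
    meqtl_truth: set | np.ndarray,
    spec: ScenarioSpec,
    cpg_meta: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, frozenset]:
    """GWAS p-values with a planted meQTL enrichment in the disease SNP set.

    The disease set is chosen stratified on (MAF bin x CpG-opportunity bin) so
    that within each stratum the meQTL proportion among disease SNPs equals
    ``enrichment_factor`` times the stratum baseline.  Disease SNPs receive
    ``p ~ U(0, gwas_threshold)``, all others ``p ~ U(0, 1)``.

    Returns the summary table and the planted disease SNP id set.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    ids = snp_meta["snp_id"].to_numpy()
    if isinstance(meqtl_truth, (set, frozenset)):
        is_meqtl = np.isin(ids, list(meqtl_truth))
    else:
        is_meqtl = np.asarray(meqtl_truth, dtype=bool)
    if cpg_meta is None:
        cpg_meta = pd.DataFrame({"cpg_id": [], "chrom": [], "pos": []})
    strata = stratify_snps(
        snp_meta.reset_index(drop=True), cpg_meta, spec.planted_window_bp,
        maf_bin_width=spec.maf_bin_width,
        opportunity_bin_width=spec.opportunity_bin_width,
    )
    key = strata["maf_bin"].astype(str) + "|" + strata["opp_bin"].astype(str)
    f = spec.enrichment_factor
    n_total = len(ids)
    disease_idx: list[int] = []
    for k, grp_idx in pd.Series(np.arange(n_total)).groupby(key.to_numpy()):
        members = grp_idx.to_numpy()
        baseline = is_meqtl[members].mean()
        d_s = int(round(spec.n_disease * len(members) / n_total))
        if d_s == 0:
            continue
        target_prop = f * baseline
        if target_prop > 1:
            raise ValueError(
                f"enrichment factor {f} infeasible in stratum {k} "
                f"(baseline {baseline:.3f})"
            )
        k_s = int(round(target_prop * d_s))
        pos_pool = members[is_meqtl[members]]
        neg_pool = members[~is_meqtl[members]]
        k_s = min(k_s, len(pos_pool))
        n_neg = min(d_s - k_s, len(neg_pool))
        picked = np.concatenate([
            rng.choice(pos_pool, size=k_s, replace=False),
            rng.choice(neg_pool, size=n_neg, replace=False),
        ])
        disease_idx.extend(picked.tolist())
    disease_idx = np.array(sorted(disease_idx))
    p = rng.uniform(0, 1, size=n_total)
    p[disease_idx] = rng.uniform(0, spec.gwas_threshold, size=len(disease_idx))
    p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]
    gwas = snp_meta[["snp_id", "chrom", "pos", "maf"]].copy()
    gwas["p"] = p
    gwas = gwas[["snp_id", "chrom", "pos", "p", "maf"]]
    return gwas, frozenset(ids[disease_idx])


def simulate_annotations(
    cpg_meta: pd.DataFrame,
    target_truth: set | np.ndarray,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureTrack, pd.DataFrame, pd.DataFrame, str | None]:
    """Feature track, tiling gene annotation and GO term map.

    The feature covers target CpGs with probability ``p1`` and non-targets
    with ``p0 = feature_baseline`` where odds(p1)/odds(p0) = ``feature_odds``.
    Genes tile each chromosome contiguously with probes-per-gene drawn from
    the configured distribution, so every CpG's nearest gene is the gene it
    sits in.  When ``plant_go_term`` is set, one GO term is enriched for genes
    holding target CpGs; its id is returned.
    """
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    ids = cpg_meta["cpg_id"].to_numpy()
    if isinstance(target_truth, (set, frozenset)):
        is_target = np.isin(ids, list(target_truth))
    else:
        is_target = np.asarray(target_truth, dtype=bool)

    p0 = spec.feature_baseline
    odds1 = spec.feature_odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    covered = np.where(is_target, rng.random(len(ids)) < p1, rng.random(len(ids)) < p0)
    track = FeatureTrack(
        name="planted_feature",
        intervals=[
            (row["chrom"], row["pos"] - 1, row["pos"])
            for covered_i, (_, row) in zip(covered, cpg_meta.iterrows())
            if covered_i
        ],
    )

    # genes tile the CpG grid: consecutive CpGs per gene, boundaries at midpoints
    values, probs = spec.probes_per_gene
    gene_rows = []
    gene_of_cpg = np.empty(len(ids), dtype=object)
    gid = 0
    for chrom, grp in cpg_meta.groupby("chrom", sort=True):
        order = grp.sort_values("pos")
        pos = order["pos"].to_numpy()
        idx = order.index.to_numpy()
        i = 0
        prev_end = 0
        while i < len(pos):
            k = int(rng.choice(values, p=probs))
            j = min(i + k, len(pos))
            gid += 1
            gene_id = f"G{gid:05d}"
            start = prev_end + 1
            if j < len(pos):
                end = (pos[j - 1] + pos[j]) // 2
            else:
                end = pos[j - 1] + 1000
            gene_rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
                 "biotype": "protein_coding"}
            )
            gene_of_cpg[idx[i:j]] = gene_id
            prev_end = end
            i = j
    genes = pd.DataFrame(gene_rows)

    target_genes = set(gene_of_cpg[is_target])
    term_rows = []
    all_genes = genes["gene_id"].to_numpy()
    planted_id = None
    for t in range(spec.n_go_terms):
        term_id = f"GO:{t + 1:07d}"
        if spec.plant_go_term and t == 0:
            planted_id = term_id
            member = np.array(
                [g in target_genes and rng.random() < 0.8 or
                 g not in target_genes and rng.random() < 0.05
                 for g in all_genes]
            )
        else:
            member = rng.random(len(all_genes)) < spec.go_term_prob
        for g in all_genes[member]:
            term_rows.append({"term_id": term_id, "term_name": f"term {t + 1}", "gene_id": g})
    term_map = pd.DataFrame(term_rows, columns=["term_id", "term_name", "gene_id"])
    return track, genes, term_map, planted_id


def block_intervals(genotypes: GenotypeMatrix, spec: ScenarioSpec) -> list[tuple[str, int, int]]:
    """0-based half-open LD-block intervals tiling each chromosome, with
    boundaries at midpoints between the simulator's copula blocks."""
    meta = genotypes.snps
    out: list[tuple[str, int, int]] = []
    for chrom, grp in meta.groupby("chrom", sort=True):
        pos = grp.sort_values("pos")["pos"].to_numpy()
        n = len(pos)
        bounds = [0]
        for b in range(spec.block_size, n, spec.block_size):
            bounds.append(int((pos[b - 1] + pos[b]) // 2))
        bounds.append(int(pos[-1] + spec.snp_step_bp))
        for s, e in zip(bounds[:-1], bounds[1:]):
            out.append((str(chrom), s, e))
    return out


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

def _null_spec(seed: int) -> ScenarioSpec:
    return ScenarioSpec(n_samples=150, n_snps=200, n_cpgs=200, seed=seed)


def _planted_meqtl_spec(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        n_samples=339, n_snps=400, n_cpgs=400, n_planted=200,
        planted_slope=5.0, noise_sd=10.0, planted_window_bp=50_000, seed=seed,
    )


def _planted_enrichment_spec(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        n_samples=150, n_snps=2000, n_cpgs=400, n_chroms=4,
        enrichment_factor=2.0, n_disease=250, meqtl_baseline=0.2, seed=seed,
    )


def _planted_feature_spec(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        n_samples=100, n_snps=200, n_cpgs=5000, n_chroms=2,
        feature_odds=3.0, target_frac=0.25, seed=seed,
    )


def _planted_go_spec(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        n_samples=100, n_snps=200, n_cpgs=2000, n_chroms=2,
        target_frac=0.15, plant_go_term=True, seed=seed,
    )


SCENARIOS = {
    "null": _null_spec,
    "planted_meqtl": _planted_meqtl_spec,
    "planted_enrichment": _planted_enrichment_spec,
    "planted_feature": _planted_feature_spec,
    "planted_go": _planted_go_spec,
}


def make_scenario(name: str, outdir: str | Path, seed: int = 0) -> dict:
    """Write the full input bundle for a registered scenario.

    Files written (all plain text, the exact dialects read by the IO module):
    genotypes.tsv, methylation.tsv, covariates.tsv, gwas.tsv, disease_snps.tsv,
    meqtl_truth.tsv, planted_pairs.tsv, feature.bed, genes.tsv, go_terms.tsv,
    blocks.tsv, snp_proximal.tsv and manifest.txt.  Returns the manifest dict.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; registry: {sorted(SCENARIOS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SCENARIOS[name](seed)
    rng = np.random.default_rng(seed)

    gm = simulate_genotypes(spec, rng)
    cpg_meta = simulate_cpg_meta(spec, rng)
    if spec.n_planted and not spec.planted_pairs:
        spec = replace(spec, planted_pairs=choose_planted_pairs(
            gm.snps, cpg_meta, spec.n_planted, spec.planted_slope,
            spec.planted_window_bp, rng,
        ))
    mm, cov = simulate_methylation(gm, spec, rng, cpg_meta=cpg_meta)

    planted_snps = {s for s, _, _ in spec.planted_pairs}
    if name in ("planted_enrichment", "null"):
        is_meqtl = rng.random(spec.n_snps) < spec.meqtl_baseline
    else:
        is_meqtl = np.isin(gm.snps["snp_id"].to_numpy(), list(planted_snps))
    gwas, disease = simulate_gwas(gm.snps, is_meqtl, spec, cpg_meta=cpg_meta, rng=rng)

    planted_cpgs = {c for _, c, _ in spec.planted_pairs}
    if name in ("planted_feature", "planted_go"):
        is_target = rng.random(spec.n_cpgs) < spec.target_frac
    else:
        is_target = np.isin(cpg_meta["cpg_id"].to_numpy(), list(planted_cpgs))
    track, genes, term_map, planted_term = simulate_annotations(
        cpg_meta, is_target, spec, rng
    )

    mio.write_genotypes(gm, outdir / "genotypes.tsv")
    mio.write_methylation(mm, outdir / "methylation.tsv")
    cov.to_csv(outdir / "covariates.tsv", sep="\t", index=False, float_format="%.10g")
    mio.write_gwas(gwas, outdir / "gwas.tsv")
    pd.DataFrame({"snp_id": sorted(disease)}).to_csv(
        outdir / "disease_snps.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"snp_id": gm.snps["snp_id"], "is_meqtl": is_meqtl.astype(int)}
    ).to_csv(outdir / "meqtl_truth.tsv", sep="\t", index=False)
    pd.DataFrame(spec.planted_pairs, columns=["snp_id", "cpg_id", "slope"]).to_csv(
        outdir / "planted_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"cpg_id": cpg_meta["cpg_id"], "is_target": is_target.astype(int)}
    ).to_csv(outdir / "target_truth.tsv", sep="\t", index=False)
    mio.write_bed(track, outdir / "feature.bed")
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    term_map.to_csv(outdir / "go_terms.tsv", sep="\t", index=False)
    pd.DataFrame(block_intervals(gm, spec), columns=["chrom", "start", "end"]).to_csv(
        outdir / "blocks.tsv", sep="\t", index=False
    )
    prox = cpg_meta.loc[cpg_meta["snp_proximal"], ["cpg_id"]]
    prox.to_csv(outdir / "snp_proximal.tsv", sep="\t", index=False)

    manifest = {
        "scenario": name,
        "seed": seed,
        "n_samples": spec.n_samples,
        "n_snps": spec.n_snps,
        "n_cpgs": spec.n_cpgs,
        "n_planted_pairs": len(spec.planted_pairs),
        "planted_slope": spec.planted_slope,
        "noise_sd": spec.noise_sd,
        "enrichment_factor": spec.enrichment_factor,
        "feature_odds": spec.feature_odds,
        "gwas_threshold": spec.gwas_threshold,
        "planted_go_term": planted_term or "",
    }
    with open(outdir / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k} = {v}\n")
    return manifest
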