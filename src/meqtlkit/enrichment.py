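"""Enrichment of disease-associated SNPs for meQTL status.

Pipeline: expand index SNPs with LD proxies, thin the candidate SNPs by
GWAS-p-supervised LD pruning, stratify every SNP by MAF bin and by "CpG
opportunity" (the number of analyzable CpGs in its cis window), draw matched
null SNP sets with the disease set's exact stratum composition, and compare
the meQTL proportion of the disease set against the null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MeqtlMap

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "ld_r2",
    "find_proxies",
    "supervised_ld_prune",
    "compute_opportunity",
    "stratify_snps",
    "sample_null_sets",
    "enrichment_test",
    "expand_locus",
    "EXCLUDED_BIOTYPES",
]

#: gene biotypes dropped from locus-expansion reports (non-coding RNA classes)
EXCLUDED_BIOTYPES = frozenset(
    {"lincRNA", "lncRNA", "miRNA", "snRNA", "snoRNA", "scaRNA", "sRNA", "misc_RNA"}
)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of unphased dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        raise ValueError("zero dosage variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _standardized(panel: GenotypeMatrix) -> np.ndarray:
    """Columns standardized to unit norm (zero-variance columns -> 0)."""
    x = panel.dosages - panel.dosages.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", x, x))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, x / np.where(norm > 0, norm, 1.0), 0.0)
    return z


def find_proxies(
    index_snps,
    panel: GenotypeMatrix,
    r2_min: float = 0.8,
    window: int = 500_000,
) -> frozenset:
    """Index SNPs plus every panel SNP within ``window`` bp at r^2 >= r2_min
    to some index SNP.  Index SNPs absent from the panel are kept but logged."""
    if panel.n_snps == 0:
        raise ValueError("empty reference panel")
    meta = panel.snps
    id_to_col = {s: i for i, s in enumerate(meta["snp_id"])}
    z = _standardized(panel)
    chrom = meta["chrom"].to_numpy()
    pos = meta["pos"].to_numpy()
    out = set(index_snps)
    missing = [s for s in index_snps if s not in id_to_col]
    if missing:
        logger.info("%d index SNPs absent from panel; kept without proxies", len(missing))
    for snp in index_snps:
        col = id_to_col.get(snp)
        if col is None:
            continue
        near = np.flatnonzero(
            (chrom == chrom[col]) & (np.abs(pos - pos[col]) <= window)
        )
        r = z[:, near].T @ z[:, col]
        hits = near[r * r >= r2_min]
        out.update(meta["snp_id"].to_numpy()[hits])
    return frozenset(out)


def supervised_ld_prune(
    priority_p: dict | pd.Series,
    panel: GenotypeMatrix,
    r2_prune: float = 0.7,
    window: int = 500_000,
) -> list:
    """Greedy p-value-supervised LD pruning.

    Repeatedly keep the unresolved SNP with the smallest priority p (ties:
    smaller position, then lexicographic id) and remove all unresolved SNPs
    within ``window`` bp at r^2 > ``r2_prune`` to it.  Returns kept SNP ids in
    selection order; no two kept SNPs within the window exceed ``r2_prune``.
    """
    if isinstance(priority_p, pd.Series):
        priority_p = priority_p.to_dict()
    meta = panel.snps
    id_to_col = {s: i for i, s in enumerate(meta["snp_id"])}
    missing = set(priority_p) - set(id_to_col)
    if missing:
        raise ValueError(f"SNPs missing from panel: {sorted(missing)[:5]}")
    z = _standardized(panel)
    chrom = meta["chrom"].to_numpy()
    pos = meta["pos"].to_numpy()

    order = sorted(
        priority_p,
        key=lambda s: (priority_p[s], pos[id_to_col[s]], s),
    )
    unresolved = set(priority_p)
    kept: list = []
    for snp in order:
        if snp not in unresolved:
            continue
        kept.append(snp)
        unresolved.discard(snp)
        col = id_to_col[snp]
        cand = [s for s in unresolved
                if chrom[id_to_col[s]] == chrom[col]
                and abs(pos[id_to_col[s]] - pos[col]) <= window]
        if not cand:
            continue
        cols = np.array([id_to_col[s] for s in cand])
        r = z[:, cols].T @ z[:, col]
        for s, rv in zip(cand, r):
            if rv * rv > r2_prune:
                unresolved.discard(s)
    return kept


# ---------------------------------------------------------------------------
# stratification and null sets
# ---------------------------------------------------------------------------

def compute_opportunity(
    snp_meta: pd.DataFrame, cpg_meta: pd.DataFrame, window: int
) -> np.ndarray:
    """Per-SNP count of (sd-filtered) CpGs on the same chromosome within the
    discovery window — the SNP's opportunity to have been called a meQTL."""
    opp = np.zeros(len(snp_meta), dtype=int)
    cpg_chrom = cpg_meta["chrom"].to_numpy()
    cpg_pos = cpg_meta["pos"].to_numpy()
    for chrom, grp in snp_meta.groupby("chrom"):
        cpos = np.sort(cpg_pos[cpg_chrom == chrom])
        spos = grp["pos"].to_numpy()
        lo = np.searchsorted(cpos, spos - window, side="left")
        hi = np.searchsorted(cpos, spos + window, side="right")
        opp[grp.index.to_numpy()] = hi - lo
    return opp


def maf_bin_index(maf: float, width: float = 0.05) -> int:
    """Half-open MAF bins of the given width; the top bin is closed at 0.5.

    With the default width the bins are [floor, 0.05), [0.05, 0.10), ...,
    [0.45, 0.50]; everything below ``width`` (including the analysis MAF
    floor) lands in bin 0.
    """
    top = int(np.ceil(0.5 / width)) - 1
    return min(int(maf // width), top)


def opportunity_bin_label(idx: int, width: int = 50) -> str:
    return f"{idx * width}-{(idx + 1) * width - 1}"


def stratify_snps(
    snp_meta: pd.DataFrame,
    cpg_meta_filtered: pd.DataFrame,
    window: int,
    maf_bin_width: float = 0.05,
    opportunity_bin_width: int = 50,
    opportunity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign every SNP to its (MAF bin x opportunity bin) stratum.

    Returns a DataFrame indexed like ``snp_meta`` with columns ``snp_id,
    maf_bin, opp_bin, opp_label``; bins tile the domain by floor division.
    """
    if opportunity is None:
        opportunity = compute_opportunity(snp_meta, cpg_meta_filtered, window)
    maf_bin = np.array([maf_bin_index(m, maf_bin_width) for m in snp_meta["maf"]])
    opp_bin = np.asarray(opportunity) // opportunity_bin_width
    return pd.DataFrame(
        {
            "snp_id": snp_meta["snp_id"].to_numpy(),
            "maf_bin": maf_bin,
            "opp_bin": opp_bin,
            "opp_label": [opportunity_bin_label(i, opportunity_bin_width) for i in opp_bin],
        }
    )


def sample_null_sets(
    disease_set,
    candidate_pool,
    strata: pd.DataFrame,
    n_sets: int = 1000,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Draw ``n_sets`` null SNP sets with the disease set's exact stratum
    composition.

    Within one set, sampling inside a stratum is without replacement whenever
    the stratum pool is large enough, otherwise with replacement (logged).
    Sets are independent draws; repeats across sets are allowed.
    """
    strat = strata.set_index("snp_id")
    disease = list(disease_set)
    pool = [s for s in candidate_pool if s not in set(disease)]
    missing = [s for s in list(disease) + pool if s not in strat.index]
    if missing:
        raise ValueError(f"SNPs without stratum assignment: {missing[:5]}")

    key = strat["maf_bin"].astype(str) + "|" + strat["opp_bin"].astype(str)
    disease_key = key.loc[disease]
    pool_by_stratum: dict[str, np.ndarray] = {
        k: g.index.to_numpy() for k, g in key.loc[pool].groupby(key.loc[pool])
    }
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []  # one (n_sets, d_s) block per stratum
    for k, grp in disease_key.groupby(disease_key):
        d_s = len(grp)
        members = pool_by_stratum.get(k)
        if members is None or len(members) == 0:
            mb, ob = k.split("|")
            raise ValueError(
                f"no candidate-pool SNPs in stratum (maf_bin={mb}, opp_bin={ob})"
            )
        if len(members) >= d_s:
            keys = rng.random((n_sets, len(members)))
            pick = np.argpartition(keys, d_s - 1, axis=1)[:, :d_s]
        else:
            logger.warning(
                "stratum %s pool (%d) smaller than disease count (%d); "
                "sampling with replacement", k, len(members), d_s
            )
            pick = rng.integers(0, len(members), size=(n_sets, d_s))
        parts.append(members[pick])
    stacked = np.concatenate(parts, axis=1)
    return [stacked[i] for i in range(n_sets)]


@dataclass
class EnrichmentResult:
    """Observed meQTL proportion vs matched null sets."""

    observed_prop: float
    null_props: np.ndarray
    fold: float
    perm_p: float          # k / B, the primary definition
    perm_p_conservative: float  # (k + 1) / (B + 1)
    n_null_sets: int
    seed: int | None = None

    @property
    def perm_p_display(self) -> str:
        if self.perm_p == 0:
            return f"<{1 / self.n_null_sets:g}"
        return f"{self.perm_p:g}"


def enrichment_test(disease_set, null_sets, meqtl_snps, seed=None) -> EnrichmentResult:
    """Fold = observed meQTL proportion / mean null proportion; one-sided
    permutation p = (# null proportions >= observed) / (# null sets)."""
    disease = list(disease_set)
    if not disease or not null_sets:
        raise ValueError("disease set and null sets must be nonempty")
    meqtl = set(meqtl_snps)
    observed = float(np.mean([s in meqtl for s in disease]))
    null_props = np.array(
        [float(np.mean([s in meqtl for s in ns])) for ns in null_sets]
    )
    mean_null = null_props.mean()
    if mean_null == 0:
        raise ValueError("mean null meQTL proportion is 0; fold undefined")
    k = int((null_props >= observed).sum())
    B = len(null_sets)
    return EnrichmentResult(
        observed_prop=observed,
        null_props=null_props,
        fold=observed / mean_null,
        perm_p=k / B,
        perm_p_conservative=(k + 1) / (B + 1),
        n_null_sets=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# locus expansion
# ---------------------------------------------------------------------------

def expand_locus(
    disease_snps,
    meqtl_map: MeqtlMap,
    genes: pd.DataFrame,
    blocks: list[tuple[str, int, int]],
    snp_meta: pd.DataFrame | None = None,
    cpg_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-LD-block report of disease SNPs, their overlapping genes, their
    meQTL target CpGs and the genes those CpGs implicate.

    ``blocks`` are 0-based half-open intervals tiling the analyzed region;
    SNPs falling outside every block get a singleton block (logged).  Genes
    with excluded non-coding biotypes are dropped.  Positions are taken from
    ``snp_meta`` / ``cpg_meta`` when given, else from the map's records.
    """
    rec = meqtl_map.records
    if snp_meta is not None:
        snp_pos = dict(zip(snp_meta["snp_id"], zip(snp_meta["chrom"], snp_meta["pos"])))
    else:
        snp_pos = dict(zip(rec["snp_id"], zip(rec["snp_chrom"], rec["snp_pos"])))
    if cpg_meta is not None:
        cpg_pos = dict(zip(cpg_meta["cpg_id"], zip(cpg_meta["chrom"], cpg_meta["pos"])))
    else:
        cpg_pos = dict(zip(rec["cpg_id"], zip(rec["cpg_chrom"], rec["cpg_pos"])))

    g = genes[~genes["biotype"].isin(EXCLUDED_BIOTYPES)].reset_index(drop=True)

    def genes_at(chrom: str, pos: int) -> list[str]:
        hit = g[(g["chrom"] == chrom) & (g["start"] <= pos) & (pos <= g["end"])]
        return list(hit["gene_id"])

    def block_of(chrom: str, pos: int):
        for i, (bc, bs, be) in enumerate(blocks):
            if bc == chrom and bs <= pos - 1 < be:
                return i, (bc, bs, be)
        logger.info("SNP at %s:%d outside all blocks; singleton block assigned", chrom, pos)
        return None, (chrom, pos - 1, pos)

    per_block: dict = {}
    for snp in disease_snps:
        if snp not in snp_pos:
            continue
        chrom, pos = snp_pos[snp]
        key, interval = block_of(chrom, pos)
        entry = per_block.setdefault(
            (key, interval), {"snps": set(), "genes": set(), "cpgs": set()}
        )
        entry["snps"].add(snp)
        entry["genes"].update(genes_at(chrom, pos))
        for cpg in meqtl_map.targets_of([snp]):
            entry["cpgs"].add(cpg)
            if cpg in cpg_pos:
                cc, cp = cpg_pos[cpg]
                entry["genes"].update(genes_at(cc, cp))

    rows = []
    for (key, (chrom, start, end)), entry in sorted(
        per_block.items(), key=lambda kv: (kv[0][1][0], kv[0][1][1])
    ):
        rows.append(
            {
                "block_chrom": chrom,
                "block_start": start,
                "block_end": end,
                "snps": ",".join(sorted(entry["snps"])),
                "target_cpgs": ",".join(sorted(entry["cpgs"])),
                "genes": ",".join(sorted(entry["genes"])),
            }
        )
    return pd.DataFrame(rows)
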