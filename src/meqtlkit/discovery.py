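"""cis-meQTL discovery: query construction, additive regression, permutation
FDR calibration and map building.

Each beta-value trait (0-100 scale) is regressed on the SNP dosage plus an
intercept, two ancestry principal components and sex.  The per-pair fit uses
Frisch-Waugh residualization against the shared covariate block, which makes
a full permutation scan (one common sample shuffle of the genotype labels per
permutation, preserving LD) a handful of matrix products.

The false discovery rate at a candidate threshold ``p_o`` is estimated as
``mean(N_null) / N_obs`` where both counts are numbers of *distinct CpG sites*
with at least one association at ``p <= p_o``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import QueryParams, count_tests
from .types import GenotypeMatrix, MeqtlMap, MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CisQuery",
    "FdrCalibration",
    "build_query",
    "fit_meqtls",
    "permutation_fdr",
    "threshold_for_fdr",
    "build_meqtl_map",
    "partition_snp_overlap",
    "default_p_grid",
]

_CHUNK = 50_000  # pairs per vectorized block


@dataclass
class CisQuery:
    """Filtered matrices plus the cis pair list (indices into them)."""

    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    snp_idx: np.ndarray
    cpg_idx: np.ndarray
    distance_bp: np.ndarray
    params: QueryParams

    @property
    def n_pairs(self) -> int:
        return len(self.snp_idx)


@dataclass
class FdrCalibration:
    """Observed/null distinct-CpG counts and estimated FDR over a p grid."""

    p_grid: np.ndarray
    n_obs: np.ndarray
    mean_n_null: np.ndarray
    n_permutations: int
    seed: int | None = None
    fdr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore", invalid="ignore"):
            self.fdr = np.where(
                self.n_obs > 0, self.mean_n_null / np.maximum(self.n_obs, 1), np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_o": self.p_grid,
                "n_obs": self.n_obs,
                "mean_n_null": self.mean_n_null,
                "fdr": self.fdr,
            }
        )


def default_p_grid(n_points: int = 40, lo: float = 1e-12, hi: float = 1e-2) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n_points)


def build_query(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    params: QueryParams,
) -> CisQuery:
    """Apply the MAF/sd filters and enumerate same-chromosome pairs within the
    window.  The pair count equals :func:`meqtlkit.design.count_tests` on the
    same metadata by construction."""
    if genotypes.samples != methylation.samples:
        raise ValueError("genotypes and methylation must be sample-aligned")
    s_keep = np.flatnonzero(genotypes.snps["maf"].to_numpy() >= params.maf_min)
    c_keep = np.flatnonzero(methylation.cpgs["sd"].to_numpy() >= params.sd_cutoff)
    if len(s_keep) == 0:
        raise ValueError("no SNPs pass the MAF filter; relax maf_min")
    if len(c_keep) == 0:
        raise ValueError("no CpGs pass the sd filter; relax sd_cutoff")
    gm = genotypes.subset_snps(s_keep)
    mm = methylation.subset_cpgs(c_keep)

    snp_idx_parts, cpg_idx_parts, dist_parts = [], [], []
    cpg_chrom = mm.cpgs["chrom"].to_numpy()
    cpg_pos = mm.cpgs["pos"].to_numpy()
    for chrom, sgrp in gm.snps.groupby("chrom"):
        on_chrom = np.flatnonzero(cpg_chrom == chrom)
        if len(on_chrom) == 0:
            continue
        order = np.argsort(cpg_pos[on_chrom], kind="mergesort")
        cidx = on_chrom[order]
        cpos = cpg_pos[cidx]
        spos = sgrp["pos"].to_numpy()
        sidx = sgrp.index.to_numpy()
        lo = np.searchsorted(cpos, spos - params.window_bp, side="left")
        hi = np.searchsorted(cpos, spos + params.window_bp, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        rep_s = np.repeat(sidx, counts)
        offs = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        rep_c = cidx[offs]
        snp_idx_parts.append(rep_s)
        cpg_idx_parts.append(rep_c)
        dist_parts.append(np.abs(np.repeat(spos, counts) - cpos[offs]))
    if not snp_idx_parts:
        raise ValueError("no cis pairs under these parameters; widen the window")
    query = CisQuery(
        genotypes=gm,
        methylation=mm,
        snp_idx=np.concatenate(snp_idx_parts),
        cpg_idx=np.concatenate(cpg_idx_parts),
        distance_bp=np.concatenate(dist_parts),
        params=params,
    )
    assert query.n_pairs == count_tests(gm.snps, mm.cpgs, params)
    return query


# ---------------------------------------------------------------------------
# regression internals
# ---------------------------------------------------------------------------

def _covariate_q(covariates, n: int) -> tuple[np.ndarray, int]:
    """Orthonormal basis for the covariate block (intercept included).

    Returns ``(Q, n_declared)`` where ``Q`` spans the column space (rank-safe
    via SVD, so degenerate covariate columns cannot leak extra projection
    dimensions) and ``n_declared`` counts the declared nuisance columns used
    for the residual degrees of freedom.
    """
    if covariates is None:
        C = np.ones((n, 1))
    else:
        if isinstance(covariates, pd.DataFrame):
            cols = [c for c in covariates.columns if c != "sample_id"]
            C = covariates[cols].to_numpy(dtype=float)
        else:
            C = np.asarray(covariates, dtype=float)
        C = np.column_stack([np.ones(len(C)), C])
    if len(C) != n:
        raise ValueError("covariate rows do not match sample count")
    u, s, _ = np.linalg.svd(C, full_matrices=False)
    rank = int((s > s[0] * max(C.shape) * np.finfo(float).eps).sum()) if s.size else 0
    return u[:, :rank], C.shape[1]


def _residualize(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    return x - q @ (q.T @ x)


def _pair_stats(
    g_resid: np.ndarray,
    m_resid: np.ndarray,
    snp_idx: np.ndarray,
    cpg_idx: np.ndarray,
    df: int,
):
    """Per-pair slope/se/t/p for covariate-residualized matrices."""
    sgg = np.einsum("ij,ij->j", g_resid, g_resid)
    syy = np.einsum("ij,ij->j", m_resid, m_resid)
    n_pairs = len(snp_idx)
    slope = np.empty(n_pairs)
    se = np.empty(n_pairs)
    tstat = np.empty(n_pairs)
    pval = np.empty(n_pairs)
    skip = np.zeros(n_pairs, dtype=bool)
    eps = 1e-12
    for a in range(0, n_pairs, _CHUNK):
        b = min(a + _CHUNK, n_pairs)
        si, ci = snp_idx[a:b], cpg_idx[a:b]
        sgy = np.einsum("ij,ij->j", g_resid[:, si], m_resid[:, ci])
        v = sgg[si]
        bad = v <= eps
        v_safe = np.where(bad, 1.0, v)
        sl = sgy / v_safe
        rss = np.maximum(syy[ci] - sl * sgy, 0.0)
        sig2 = rss / df
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(sig2 / v_safe)
            t = np.where(s > 0, sl / np.where(s > 0, s, 1.0), np.inf * np.sign(sl))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        zero_resid = (s <= 0) & (np.abs(sl) > 0)
        p = np.where(zero_resid, np.finfo(float).tiny, p)
        p = np.where((s <= 0) & (np.abs(sl) == 0), 1.0, p)
        slope[a:b], se[a:b], tstat[a:b], pval[a:b] = sl, s, t, p
        skip[a:b] = bad
    return slope, se, tstat, pval, skip


def fit_meqtls(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    covariates,
    pairs: tuple[np.ndarray, np.ndarray],
    distance_bp: np.ndarray | None = None,
) -> pd.DataFrame:
    """OLS of methylation on dosage + intercept + covariates for every pair.

    Returns one row per pair with columns ``snp_id, cpg_id, snp_chrom,
    snp_pos, cpg_chrom, cpg_pos, distance_bp, slope, se, t, p``.  Pairs whose
    SNP has zero dosage variance are dropped (logged).
    """
    snp_idx, cpg_idx = (np.asarray(x) for x in pairs)
    n = genotypes.n_samples
    q, n_declared = _covariate_q(covariates, n)
    df = n - 1 - n_declared  # genotype + declared covariate block (incl. intercept)
    if df < 1:
        raise ValueError(f"not enough samples: n={n} with {n_declared} nuisance columns")
    g_resid = _residualize(genotypes.dosages, q)
    m_resid = _residualize(methylation.values, q)
    slope, se, tstat, pval, skip = _pair_stats(g_resid, m_resid, snp_idx, cpg_idx, df)
    if skip.any():
        logger.info("skipped %d pairs with zero genotype variance", int(skip.sum()))
    keep = ~skip
    snps = genotypes.snps
    cpgs = methylation.cpgs
    si, ci = snp_idx[keep], cpg_idx[keep]
    if distance_bp is None:
        dist = np.abs(
            snps["pos"].to_numpy()[si] - cpgs["pos"].to_numpy()[ci]
        )
    else:
        dist = np.asarray(distance_bp)[keep]
    return pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy()[si],
            "cpg_id": cpgs["cpg_id"].to_numpy()[ci],
            "snp_chrom": snps["chrom"].to_numpy()[si],
            "snp_pos": snps["pos"].to_numpy()[si],
            "cpg_chrom": cpgs["chrom"].to_numpy()[ci],
            "cpg_pos": cpgs["pos"].to_numpy()[ci],
            "distance_bp": dist,
            "slope": slope[keep],
            "se": se[keep],
            "t": tstat[keep],
            "p": pval[keep],
        }
    )


def _counts_per_grid(minp_per_cpg: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """# of CpGs whose best p is <= each grid point (ties included)."""
    finite = minp_per_cpg[np.isfinite(minp_per_cpg)]
    srt = np.sort(finite)
    return np.searchsorted(srt, grid, side="right")


def permutation_fdr(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    covariates,
    pairs: tuple[np.ndarray, np.ndarray],
    n_perm: int = 100,
    p_grid: np.ndarray | None = None,
    seed: int | None = None,
    chrom_subset: list[str] | None = None,
    permute_covariates: bool = False,
) -> FdrCalibration:
    """Estimate FDR(p_o) over a p grid by genotype-label permutation.

    One shared sample shuffle per permutation is applied to the genotype rows
    (methylation and, by default, covariates stay fixed) so that the genotype
    correlation structure is retained.  With ``permute_covariates`` the
    ancestry covariate rows travel with the genotypes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    if np.any(np.diff(p_grid) < 0):
        raise ValueError("p_grid must be sorted ascending")
    snp_idx, cpg_idx = (np.asarray(x) for x in pairs)
    if chrom_subset is not None:
        subset = set(chrom_subset)
        snp_chrom = genotypes.snps["chrom"].to_numpy()
        keep = np.isin(snp_chrom[snp_idx], list(subset))
        snp_idx, cpg_idx = snp_idx[keep], cpg_idx[keep]
        if len(snp_idx) == 0:
            raise ValueError("chromosome subset leaves no pairs")

    n = genotypes.n_samples
    q, n_declared = _covariate_q(covariates, n)
    df = n - 1 - n_declared
    g_resid = _residualize(genotypes.dosages, q)
    m_resid = _residualize(methylation.values, q)
    n_cpgs = methylation.n_cpgs

    def minp(gr, mr):
        _, _, _, pval, skip = _pair_stats(gr, mr, snp_idx, cpg_idx, df)
        out = np.full(n_cpgs, np.inf)
        np.minimum.at(out, cpg_idx[~skip], pval[~skip])
        return out

    n_obs = _counts_per_grid(minp(g_resid, m_resid), p_grid)
    if n_obs[-1] == 0:
        raise ValueError("no observed associations at any grid point")

    rng = np.random.default_rng(seed)
    null_sum = np.zeros(len(p_grid))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if permute_covariates:
            # genotypes and covariates shuffled together: residualized genotype
            # columns permute as rows; methylation must be re-residualized
            # against the permuted covariate basis.
            gp = g_resid[perm]
            mp = _residualize(methylation.values, q[perm])
        else:
            gp = _residualize(genotypes.dosages[perm], q)
            mp = m_resid
        null_sum += _counts_per_grid(minp(gp, mp), p_grid)
    return FdrCalibration(
        p_grid=p_grid,
        n_obs=n_obs,
        mean_n_null=null_sum / n_perm,
        n_permutations=n_perm,
        seed=seed,
    )


def threshold_for_fdr(calibration: FdrCalibration, level: float) -> float:
    """Largest grid ``p_o`` whose isotonic-adjusted FDR is <= ``level``.

    The raw empirical FDR curve need not be monotone; pool-adjacent-violators
    (nondecreasing in ``p_o``) is applied over the defined grid points first.
    """
    defined = np.flatnonzero(calibration.n_obs > 0)
    if len(defined) == 0:
        raise ValueError("calibration has no defined FDR values")
    from scipy.optimize import isotonic_regression

    adj = isotonic_regression(calibration.fdr[defined], increasing=True).x
    ok = np.flatnonzero(adj <= level)
    if len(ok) == 0:
        raise ValueError(
            f"no threshold achieves FDR <= {level}; minimum achievable = {adj.min():.4g}"
        )
    return float(calibration.p_grid[defined[ok[-1]]])


def build_meqtl_map(
    records: pd.DataFrame,
    p_o: float,
    provenance: dict | None = None,
    tested_snps=None,
    tested_cpgs=None,
) -> MeqtlMap:
    """Retain records with ``p <= p_o`` and derive the SNP/target sets."""
    if not 0 < p_o <= 1:
        raise ValueError("p_o must be in (0, 1]")
    kept = records[records["p"] <= p_o].reset_index(drop=True)
    if kept.empty:
        logger.info("meQTL map empty at p_o=%g", p_o)
    prov = dict(provenance or {})
    prov["p_o"] = p_o
    return MeqtlMap(
        records=kept,
        provenance=prov,
        tested_snps=frozenset(tested_snps) if tested_snps is not None else None,
        tested_cpgs=frozenset(tested_cpgs) if tested_cpgs is not None else None,
    )


def partition_snp_overlap(maps: dict[str, MeqtlMap], common_universe) -> dict[frozenset, int]:
    """Count universe SNPs by the exact subset of maps calling them meQTLs.

    Returns a dict keyed by frozenset of map names (the empty frozenset holds
    SNPs that are meQTLs in no map); values sum to ``len(common_universe)``.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    universe = set(common_universe)
    if not universe:
        raise ValueError("empty SNP universe")
    membership = {name: m.meqtl_snps & universe for name, m in maps.items()}
    out: dict[frozenset, int] = {}
    for snp in universe:
        key = frozenset(name for name, s in membership.items() if snp in s)
        out[key] = out.get(key, 0) + 1
    return out
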