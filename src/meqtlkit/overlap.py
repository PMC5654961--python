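"""Regulatory-feature overlap of meQTL-target CpGs.

Builds the seven target lists (four single tissues plus the reference
tissue's harmonized intersections with each other tissue), annotates CpGs
against BED feature tracks, and runs two Fisher 2x2 contrasts per
(list, feature) cell: targets vs non-target CpGs, and disease-SNP targets vs
targets of the remaining meQTL SNPs.  Cells are flagged at the family-wise
Bonferroni threshold alpha / (n_features x n_lists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, inf, nan

import numpy as np
import pandas as pd

from .design import QueryParams
from .discovery import (
    build_meqtl_map,
    build_query,
    fit_meqtls,
    permutation_fdr,
    threshold_for_fdr,
)
from .types import FeatureTrack, GenotypeMatrix, MeqtlMap, MethylationMatrix, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "TargetList",
    "annotate_overlap",
    "fisher_2x2",
    "build_target_lists",
    "harmonized_downsample",
    "overlap_battery",
    "bonferroni_threshold",
]


def annotate_overlap(cpg_meta: pd.DataFrame, track: FeatureTrack) -> np.ndarray:
    """Boolean per CpG: does the 1-based point fall inside any track interval?

    A CpG at 1-based position ``p`` overlaps iff some 0-based half-open
    interval contains ``p - 1``.  Chromosome labels are normalized on both
    sides (``chr1`` and ``1`` compare equal).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in track.intervals:
        by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    out = np.zeros(len(cpg_meta), dtype=bool)
    for chrom, grp in cpg_meta.groupby(cpg_meta["chrom"].map(normalize_chrom)):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        q = grp["pos"].to_numpy() - 1  # 0-based point
        j = np.searchsorted(starts, q, side="right") - 1
        ok = (j >= 0) & (q < ends[np.maximum(j, 0)])
        out[grp.index.to_numpy()] = ok
    return out


def fisher_2x2(a: int, b: int, c: int, d: int, or_kind: str = "sample"):
    """Two-sided Fisher exact test by probability ordering, exact arithmetic.

    Returns ``(odds_ratio, p)``.  The odds ratio is the sample value
    ``a*d / (b*c)`` by default (+inf when ``b*c == 0`` and ``a*d > 0``, NaN
    when both products vanish); ``or_kind='conditional'`` returns the
    conditional MLE instead.  All four margins must be positive.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, k1, k2 = a + b, c + d, a + c, b + d
    if min(r1, r2, k1, k2) == 0:
        raise ValueError("degenerate margin in 2x2 table")
    if or_kind == "sample":
        if b * c > 0:
            or_val = (a * d) / (b * c)
        elif a * d > 0:
            or_val = inf
        else:
            or_val = nan
    elif or_kind == "conditional":
        from scipy.stats.contingency import odds_ratio

        or_val = float(odds_ratio([[a, b], [c, d]], kind="conditional").statistic)
    else:
        raise ValueError(f"unknown or_kind {or_kind!r}")
    # exact integer enumeration over the hypergeometric support: sum point
    # probabilities <= that of the observed table (common denominator cancels)
    lo = max(0, k1 - r2)
    hi = min(r1, k1)
    numerators = [comb(r1, x) * comb(r2, k1 - x) for x in range(lo, hi + 1)]
    obs = numerators[a - lo]
    p = sum(v for v in numerators if v <= obs) / comb(r1 + r2, k1)
    return or_val, min(p, 1.0)


@dataclass
class TargetList:
    """One of the seven meQTL target-list categories."""

    name: str
    targets: frozenset
    universe: frozenset
    maps: tuple[MeqtlMap, ...] = ()

    def __post_init__(self) -> None:
        if not self.targets <= self.universe:
            raise ValueError(f"list {self.name!r}: targets not within universe")


def _universe_of(m: MeqtlMap) -> frozenset:
    if m.tested_cpgs is None:
        raise ValueError(
            f"map {m.provenance.get('label', '?')!r} lacks a tested-CpG universe"
        )
    return m.tested_cpgs


def build_target_lists(
    tissue_maps: dict[str, MeqtlMap],
    reference: str,
    harmonized: dict[str, tuple[MeqtlMap, MeqtlMap]] | None = None,
) -> dict[str, TargetList]:
    """Single-tissue lists plus reference-x-other harmonized intersections.

    ``harmonized[name]`` supplies the pair (down-sampled/re-screened reference
    map, other-tissue map) for the intersection list ``reference+name``; the
    intersection's targets are CpGs called in both and its universe is the
    CpGs tested in both.
    """
    if reference not in tissue_maps:
        raise ValueError(f"reference tissue {reference!r} not among maps")
    out: dict[str, TargetList] = {}
    for name, m in tissue_maps.items():
        out[name] = TargetList(
            name=name, targets=m.target_cpgs & _universe_of(m),
            universe=_universe_of(m), maps=(m,),
        )
    harmonized = harmonized or {}
    for other in tissue_maps:
        if other == reference:
            continue
        if other not in harmonized:
            raise ValueError(
                f"missing harmonized re-screen for intersection {reference}+{other}"
            )
        ref_h, oth = harmonized[other]
        inter = ref_h.target_cpgs & oth.target_cpgs
        universe = _universe_of(ref_h) & _universe_of(oth)
        if not inter:
            logger.info("intersection %s+%s has no shared targets", reference, other)
        out[f"{reference}+{other}"] = TargetList(
            name=f"{reference}+{other}", targets=frozenset(inter) & universe,
            universe=universe, maps=(ref_h, oth),
        )
    return out


def harmonized_downsample(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    covariates: pd.DataFrame,
    target_n: int,
    params: QueryParams,
    fdr_level: float = 0.05,
    seed: int | None = None,
    chrom_subset: list[str] | None = None,
    n_perm: int = 100,
    label: str = "harmonized",
) -> MeqtlMap:
    """Re-screen the reference tissue at another tissue's size and parameters.

    Samples are down-sampled without replacement (seeded; indices sorted so a
    full-size "subsample" is the identity), the query is rebuilt at the other
    tissue's parameters, the FDR threshold is calibrated on the chromosome
    subset and then applied genome-wide.
    """
    n = genotypes.n_samples
    if target_n > n:
        raise ValueError(f"target_n={target_n} exceeds available samples ({n})")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=target_n, replace=False))
    gm = genotypes.subset_samples(idx)
    mm = methylation.subset_samples(idx)
    cov = covariates.iloc[idx].reset_index(drop=True)
    query = build_query(gm, mm, params)
    records = fit_meqtls(
        query.genotypes, query.methylation, cov,
        (query.snp_idx, query.cpg_idx), query.distance_bp,
    )
    cal = permutation_fdr(
        query.genotypes, query.methylation, cov,
        (query.snp_idx, query.cpg_idx), seed=seed,
        chrom_subset=chrom_subset, n_perm=n_perm,
    )
    p_o = threshold_for_fdr(cal, fdr_level)
    return build_meqtl_map(
        records, p_o,
        provenance={
            "label": label, "target_n": target_n, "seed": seed,
            "params": params, "fdr_level": fdr_level,
            "chrom_subset": ",".join(chrom_subset or []),
        },
        tested_snps=query.genotypes.snps["snp_id"],
        tested_cpgs=query.methylation.cpgs["cpg_id"],
    )


def bonferroni_threshold(alpha: float, n_features: int, n_lists: int) -> float:
    """Family-wise per-test threshold alpha / (n_features x n_lists)."""
    if n_features <= 0 or n_lists <= 0:
        raise ValueError("n_features and n_lists must be positive")
    return alpha / (n_features * n_lists)


def overlap_battery(
    target_lists: dict[str, TargetList],
    feature_tracks: list[FeatureTrack],
    cpg_meta: pd.DataFrame,
    disease_targets: dict[str, frozenset] | None = None,
    alpha: float = 0.05,
    or_kind: str = "sample",
) -> pd.DataFrame:
    """Fisher contrasts for every (list, feature, mode) cell.

    Mode A (``targets_vs_nontargets``) compares the list's meQTL targets to
    the non-target CpGs of its universe.  Mode B
    (``disease_targets_vs_other_targets``) — run when ``disease_targets``
    provides the per-list disease-SNP target sets — compares those CpGs to the
    remaining targets of the list.  Degenerate margins yield missing cells
    with a reason instead of a p-value.
    """
    if not target_lists or not feature_tracks:
        raise ValueError("need at least one target list and one feature track")
    thr = bonferroni_threshold(alpha, len(feature_tracks), len(target_lists))
    id_index = pd.Index(cpg_meta["cpg_id"])
    overlap_by_track = {
        t.name: pd.Series(annotate_overlap(cpg_meta, t), index=id_index)
        for t in feature_tracks
    }
    rows = []

    def contrast(list_name, feature_name, mode, grp1, grp2, cov):
        a = int(cov.reindex(list(grp1)).fillna(False).sum())
        b = len(grp1) - a
        c = int(cov.reindex(list(grp2)).fillna(False).sum())
        d = len(grp2) - c
        row = {
            "list": list_name, "feature": feature_name, "mode": mode,
            "a": a, "b": b, "c": c, "d": d,
            "or": nan, "p": nan, "bonferroni": False, "note": "",
        }
        try:
            or_val, p = fisher_2x2(a, b, c, d, or_kind=or_kind)
            row["or"], row["p"] = or_val, p
            row["bonferroni"] = p <= thr
        except ValueError as err:
            row["note"] = str(err)
        rows.append(row)

    for name, tl in target_lists.items():
        nontargets = tl.universe - tl.targets
        for track in feature_tracks:
            cov = overlap_by_track[track.name]
            contrast(name, track.name, "targets_vs_nontargets",
                     tl.targets, nontargets, cov)
            if disease_targets is not None and name in disease_targets:
                dz = disease_targets[name] & tl.targets
                other = tl.targets - dz
                contrast(name, track.name, "disease_targets_vs_other_targets",
                         dz, other, cov)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thr
    return out
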