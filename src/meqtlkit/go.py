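"""GO enrichment of meQTL-target CpGs with probe-count bias correction.

CpG targets of disease SNPs are mapped to their nearest gene and tested for
term enrichment against the universe of all meQTL-target genes.  Because
genes carry very different numbers of probes, a gene's chance of entering the
selected set under the null is proportional to its probe count; the test uses
the Wallenius noncentral hypergeometric upper tail with the term's odds
parameter set to the ratio of mean in-term to mean out-of-term probe weight
(plain hypergeometric when all weights are equal).

Terms whose gene lists overlap a better-ranked retained term by more than
70% (min-set denominator) are dropped, and per-tissue scaled ranks (rank /
number of nominally significant retained terms) feed the cross-tissue table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import MeqtlMap

logger = logging.getLogger(__name__)

__all__ = [
    "GoResult",
    "select_disease_targets",
    "map_to_genes",
    "build_gene_universe",
    "go_test",
    "overlap_filter",
    "scaled_rank_table",
]


@dataclass
class GoResult:
    term_id: str
    term_name: str
    p: float
    n_selected_in_term: int
    n_universe_in_term: int
    rank: int | None = None
    scaled_rank: float | None = None


def select_disease_targets(
    meqtl_map: MeqtlMap,
    disease_snps_plus_proxies,
    cpg_meta: pd.DataFrame,
) -> tuple[frozenset, frozenset]:
    """(selected, universe) CpG sets for the GO test.

    Selected = CpG targets of any disease SNP or proxy; universe = all meQTL
    target CpGs.  Probes flagged ``snp_proximal`` (SNP within 10 bp of the CpG
    or at the single-base extension) are excluded from both.
    """
    prox = set(cpg_meta.loc[cpg_meta["snp_proximal"].astype(bool), "cpg_id"])
    universe = meqtl_map.target_cpgs - prox
    selected = meqtl_map.targets_of(disease_snps_plus_proxies) - prox
    if not selected:
        raise ValueError(
            "no disease-associated meQTL-target CpGs selected; relax the GWAS or meQTL threshold"
        )
    return frozenset(selected), frozenset(universe)


def map_to_genes(
    cpg_set,
    cpg_meta: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.Series:
    """Nearest gene per CpG (distance 0 inside the gene body, else distance to
    the nearer boundary; ties go to the gene with the smaller start).

    Returns a Series cpg_id -> gene_id; CpGs on chromosomes without genes are
    dropped with a log message.
    """
    if genes.empty:
        raise ValueError("gene annotation is empty")
    meta = cpg_meta.set_index("cpg_id")
    assigned: dict[str, str] = {}
    unmapped = 0
    by_chrom = {c: g.sort_values(["start", "gene_id"]).reset_index(drop=True)
                for c, g in genes.groupby("chrom")}
    for cpg in cpg_set:
        chrom, pos = meta.at[cpg, "chrom"], int(meta.at[cpg, "pos"])
        g = by_chrom.get(chrom)
        if g is None:
            unmapped += 1
            continue
        start = g["start"].to_numpy()
        end = g["end"].to_numpy()
        inside = (start <= pos) & (pos <= end)
        dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
        best = np.flatnonzero(dist == dist.min())
        # by_chrom frames are start-sorted, so the first minimum wins ties
        assigned[cpg] = g["gene_id"].iloc[best[0]]
    if unmapped:
        logger.info("%d CpGs on gene-less chromosomes left unmapped", unmapped)
    return pd.Series(assigned, name="gene_id")


def build_gene_universe(
    selected_cpgs,
    universe_cpgs,
    cpg_meta: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-level universe table: ``gene_id, probe_count, selected``.

    ``probe_count`` counts universe CpGs whose nearest gene is that gene; a
    gene is selected when any selected CpG maps to it.
    """
    mapping = map_to_genes(universe_cpgs, cpg_meta, genes)
    probe_count = mapping.value_counts()
    sel_genes = set(mapping.loc[mapping.index.isin(set(selected_cpgs))])
    out = pd.DataFrame(
        {
            "gene_id": probe_count.index,
            "probe_count": probe_count.to_numpy(),
            "selected": [g in sel_genes for g in probe_count.index],
        }
    ).sort_values("gene_id").reset_index(drop=True)
    return out


def go_test(universe: pd.DataFrame, term_map: pd.DataFrame) -> list[GoResult]:
    """Per-term upper-tail enrichment p with probe-count bias correction.

    ``universe`` needs columns ``gene_id, probe_count, selected``; ``term_map``
    needs ``term_id, gene_id`` (+ optional ``term_name``).  Terms with no
    universe genes are skipped.
    """
    genes = universe["gene_id"].to_numpy()
    weights = universe["probe_count"].to_numpy(dtype=float)
    selected = universe["selected"].to_numpy(dtype=bool)
    if (weights < 1).any():
        raise ValueError("probe_count must be >= 1 for universe genes")
    gene_set = set(genes)
    N = len(genes)
    n_draws = int(selected.sum())
    if n_draws > N:
        raise ValueError("selected count exceeds universe size")
    equal_weights = np.all(weights == weights[0])
    names = {}
    if "term_name" in term_map.columns:
        names = dict(zip(term_map["term_id"], term_map["term_name"]))
    results: list[GoResult] = []
    in_universe = {g: i for i, g in enumerate(genes)}
    for term_id, grp in term_map.groupby("term_id", sort=True):
        members = [in_universe[g] for g in set(grp["gene_id"]) & gene_set]
        m1 = len(members)
        if m1 == 0:
            continue
        mask = np.zeros(N, dtype=bool)
        mask[members] = True
        x = int((selected & mask).sum())
        if m1 == N:
            p = 1.0
        elif equal_weights:
            p = float(stats.hypergeom.sf(x - 1, N, m1, n_draws))
        else:
            omega = weights[mask].mean() / weights[~mask].mean()
            p = float(stats.nchypergeom_wallenius.sf(x - 1, N, m1, n_draws, omega))
        results.append(
            GoResult(
                term_id=term_id,
                term_name=names.get(term_id, term_id),
                p=min(max(p, 0.0), 1.0),
                n_selected_in_term=x,
                n_universe_in_term=m1,
            )
        )
    return sorted(results, key=lambda r: (r.p, r.term_id))


def overlap_filter(
    results: list[GoResult],
    gene_lists: dict[str, set],
    threshold: float = 0.70,
    nominal_p: float = 0.05,
) -> list[GoResult]:
    """Drop redundant terms: iterate nominally significant terms by ascending
    p (ties by term id) and drop any whose gene list overlaps a retained term
    by more than ``threshold`` of the smaller list.  Ranks and scaled ranks
    are assigned to the retained terms."""
    nominal = sorted(
        (r for r in results if r.p < nominal_p), key=lambda r: (r.p, r.term_id)
    )
    retained: list[GoResult] = []
    for r in nominal:
        mine = gene_lists[r.term_id]
        redundant = False
        for kept in retained:
            other = gene_lists[kept.term_id]
            inter = len(mine & other)
            denom = min(len(mine), len(other))
            if denom > 0 and inter / denom > threshold:
                redundant = True
                break
        if not redundant:
            retained.append(r)
    n = len(retained)
    for i, r in enumerate(retained, start=1):
        r.rank = i
        r.scaled_rank = i / n
    return retained


def scaled_rank_table(per_tissue_results: dict[str, list[GoResult]]) -> pd.DataFrame:
    """Cross-tissue table of terms retained in >= 2 tissues.

    Rows are grouped by tissue-presence pattern and ordered within a group by
    ascending sum of the available scaled ranks; absent tissues show NaN.
    """
    if len(per_tissue_results) < 2:
        raise ValueError("need results for at least two tissues")
    tissues = list(per_tissue_results)
    by_term: dict[str, dict] = {}
    for tissue, results in per_tissue_results.items():
        for r in results:
            entry = by_term.setdefault(r.term_id, {"term_name": r.term_name})
            entry[tissue] = r.scaled_rank
    rows = []
    for term_id, entry in by_term.items():
        present = [t for t in tissues if t in entry]
        if len(present) < 2:
            continue
        row = {"term_id": term_id, "term_name": entry["term_name"],
               "pattern": "+".join(present),
               "rank_sum": sum(entry[t] for t in present)}
        for t in tissues:
            row[t] = entry.get(t, np.nan)
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "pattern", "rank_sum", *tissues]
        )
    df = pd.DataFrame(rows)
    # more-tissues-first groups, then by rank sum within group
    df["_n"] = df["pattern"].str.count("\\+")
    df = df.sort_values(
        by=["_n", "pattern", "rank_sum", "term_id"], ascending=[False, True, True, True]
    ).drop(columns="_n").reset_index(drop=True)
    return df
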