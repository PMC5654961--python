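"""Screen design: test counting, additive-model power, hierarchical parameter
selection.

The query grid is searched for the most permissive parameter combination that
retains 80% power (by default) at a Bonferroni alpha derived from the number
of cis tests the combination implies.  "Most permissive" is hierarchical:
first admit the most CpGs (lowest sd cutoff), then the most SNPs (lowest MAF
threshold), then the widest window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QueryParams", "PowerSpec", "count_tests", "power_additive", "select_params"]


@dataclass(frozen=True)
class QueryParams:
    """CpG variability cutoff, SNP MAF floor and cis window half-width."""

    sd_cutoff: float
    maf_min: float
    window_bp: int

    def __post_init__(self) -> None:
        if self.sd_cutoff < 0:
            raise ValueError("sd_cutoff must be >= 0")
        if not 0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")


@dataclass(frozen=True)
class PowerSpec:
    n_samples: int
    effect_per_allele: float = 5.0
    residual_sd: float = 15.0
    target_power: float = 0.8
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def count_tests(snp_meta: pd.DataFrame, cpg_meta: pd.DataFrame, params: QueryParams) -> int:
    """Number of cis SNP-CpG pairs admitted by ``params``.

    A pair is counted when the SNP passes the MAF floor, the CpG passes the sd
    cutoff, both lie on the same chromosome and their positions differ by at
    most ``window_bp``.
    """
    if len(snp_meta) == 0 or len(cpg_meta) == 0:
        return 0
    snps = snp_meta[snp_meta["maf"] >= params.maf_min]
    cpgs = cpg_meta[cpg_meta["sd"] >= params.sd_cutoff]
    total = 0
    for chrom, sgrp in snps.groupby("chrom"):
        cpos = np.sort(cpgs.loc[cpgs["chrom"] == chrom, "pos"].to_numpy())
        if len(cpos) == 0:
            continue
        spos = sgrp["pos"].to_numpy()
        lo = np.searchsorted(cpos, spos - params.window_bp, side="left")
        hi = np.searchsorted(cpos, spos + params.window_bp, side="right")
        total += int((hi - lo).sum())
    return total


def power_additive(maf: float, spec: PowerSpec) -> float:
    """Two-sided Wald power for the additive single-SNP regression.

    Noncentrality ``lam = effect * sqrt(n * 2 * maf * (1 - maf)) / residual_sd``
    (HWE dosage variance); power = Phi(lam - z) + Phi(-lam - z) with
    ``z = z_{1 - alpha/2}``.
    """
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if spec.residual_sd <= 0:
        raise ValueError("residual_sd must be > 0")
    lam = (
        spec.effect_per_allele
        * np.sqrt(spec.n_samples * 2.0 * maf * (1.0 - maf))
        / spec.residual_sd
    )
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))


def evaluate_grid(
    candidate_grid: list[QueryParams],
    snp_meta: pd.DataFrame,
    cpg_meta: pd.DataFrame,
    spec: PowerSpec,
) -> pd.DataFrame:
    """Per-candidate test count, Bonferroni alpha and power at ``maf_min``."""
    rows = []
    for qp in candidate_grid:
        n_tests = count_tests(snp_meta, cpg_meta, qp)
        if n_tests > 0:
            alpha = spec.alpha / n_tests
            pw = power_additive(qp.maf_min, PowerSpec(
                n_samples=spec.n_samples,
                effect_per_allele=spec.effect_per_allele,
                residual_sd=spec.residual_sd,
                target_power=spec.target_power,
                alpha=alpha,
            ))
        else:
            alpha, pw = float("nan"), 0.0
        rows.append(
            {
                "sd_cutoff": qp.sd_cutoff,
                "maf_min": qp.maf_min,
                "window_bp": qp.window_bp,
                "n_tests": n_tests,
                "alpha": alpha,
                "power": pw,
                "passes": pw >= spec.target_power,
            }
        )
    return pd.DataFrame(rows)


def select_params(
    candidate_grid: list[QueryParams],
    snp_meta: pd.DataFrame,
    cpg_meta: pd.DataFrame,
    spec: PowerSpec,
) -> QueryParams:
    """Most permissive passing candidate (see module docstring for the order)."""
    if not candidate_grid:
        raise ValueError("candidate grid is empty")
    table = evaluate_grid(candidate_grid, snp_meta, cpg_meta, spec)
    passing = table[table["passes"]]
    if passing.empty:
        best = table["power"].max()
        raise ValueError(
            f"no candidate reaches target power {spec.target_power}; "
            f"best achieved power = {best:.4f}"
        )
    best = passing.sort_values(
        by=["sd_cutoff", "maf_min", "window_bp"],
        ascending=[True, True, False],
        kind="mergesort",
    ).iloc[0]
    return QueryParams(
        sd_cutoff=float(best["sd_cutoff"]),
        maf_min=float(best["maf_min"]),
        window_bp=int(best["window_bp"]),
    )
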