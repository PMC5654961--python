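"""Shared domain types for the meQTL pipeline.

Coordinate conventions (used everywhere in the package):

* Point features (SNPs, CpGs) carry 1-based positions.
* Interval features (BED tracks, LD blocks) are 0-based half-open.
* A 1-based point ``p`` lies inside a half-open interval ``[s, e)``
  iff ``s <= p - 1 < e``.  See :func:`point_in_interval`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MethylationMatrix",
    "FeatureTrack",
    "MeqtlMap",
    "normalize_chrom",
    "point_to_halfopen",
    "point_in_interval",
]


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome label: strip a leading ``chr``/``Chr`` prefix."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def point_to_halfopen(pos: int) -> tuple[int, int]:
    """Convert a 1-based point position to its 0-based half-open interval."""
    if pos < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos}")
    return pos - 1, pos


def point_in_interval(pos: int, start: int, end: int) -> bool:
    """Does 1-based point ``pos`` fall in half-open ``[start, end)``?"""
    return start <= pos - 1 < end


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix plus per-SNP metadata.

    Attributes
    ----------
    samples : list of sample identifiers, ordered as in the source file.
    dosages : float array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}`` (fractional values only after mean imputation).
    snps : DataFrame with columns ``snp_id, chrom, pos, maf``; ``maf`` is the
        minor-allele frequency computed from the dosages.
    """

    samples: list[str]
    dosages: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id: {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            dosages=self.dosages[idx],
            snps=self.snps.reset_index(drop=True),
        )

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            dosages=self.dosages[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
        )


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP column from a samples x SNPs dosage matrix."""
    freq = np.nanmean(np.asarray(dosages, dtype=float), axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta-value matrix (0-100 scale) plus per-CpG metadata.

    ``cpgs`` columns: ``cpg_id, chrom, pos, sd, snp_proximal``.  ``sd`` is the
    sample standard deviation (n-1 denominator) across samples; ``snp_proximal``
    flags probes annotated as having a SNP within 10 bp of the CpG or at the
    single-base extension.
    """

    samples: list[str]
    values: np.ndarray
    cpgs: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.cpgs)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.cpgs)} CpGs"
            )
        if self.cpgs["cpg_id"].duplicated().any():
            dup = self.cpgs.loc[self.cpgs["cpg_id"].duplicated(), "cpg_id"].iloc[0]
            raise ValueError(f"duplicate cpg_id: {dup!r}")
        if "sd" not in self.cpgs.columns:
            self.cpgs = self.cpgs.assign(sd=self.values.std(axis=0, ddof=1))
        if "snp_proximal" not in self.cpgs.columns:
            self.cpgs = self.cpgs.assign(snp_proximal=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    def subset_samples(self, idx: np.ndarray) -> "MethylationMatrix":
        vals = self.values[idx]
        cpgs = self.cpgs.copy()
        cpgs["sd"] = vals.std(axis=0, ddof=1)
        return MethylationMatrix(
            samples=[self.samples[i] for i in idx], values=vals, cpgs=cpgs
        )

    def subset_cpgs(self, idx: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            samples=list(self.samples),
            values=self.values[:, idx],
            cpgs=self.cpgs.iloc[idx].reset_index(drop=True),
        )


@dataclass
class FeatureTrack:
    """Named set of genomic intervals in 0-based half-open coordinates."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("track name must be nonempty")
        self.intervals = [
            (normalize_chrom(c), int(s), int(e)) for c, s, e in self.intervals
        ]
        for c, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"degenerate interval {c}:{s}-{e} (start >= end)")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class MeqtlMap:
    """Significant SNP-CpG association records plus derived sets.

    ``records`` requires at least ``snp_id, cpg_id, p`` columns; discovery adds
    positions, distance and regression statistics.  ``tested_snps`` /
    ``tested_cpgs`` optionally record the full query universe, needed by the
    cross-tissue overlap stages.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    tested_snps: frozenset | None = None
    tested_cpgs: frozenset | None = None

    def __post_init__(self) -> None:
        missing = {"snp_id", "cpg_id"} - set(self.records.columns)
        if missing:
            raise ValueError(f"meQTL records missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)

    @property
    def meqtl_snps(self) -> frozenset:
        return frozenset(self.records["snp_id"])

    @property
    def target_cpgs(self) -> frozenset:
        return frozenset(self.records["cpg_id"])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def mean_targets_per_snp(self) -> float:
        """Mean number of distinct CpG targets per meQTL SNP."""
        if not self.meqtl_snps:
            return float("nan")
        pairs = self.records[["snp_id", "cpg_id"]].drop_duplicates()
        return len(pairs) / len(self.meqtl_snps)

    def targets_of(self, snp_ids: Iterable) -> frozenset:
        """Distinct CpG targets of any SNP in ``snp_ids``."""
        wanted = set(snp_ids)
        mask = self.records["snp_id"].isin(wanted)
        return frozenset(self.records.loc[mask, "cpg_id"])
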