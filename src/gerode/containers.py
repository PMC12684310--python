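"""In-memory containers shared across the analysis modules.

The central object is :class:`GenotypeMatrix`, a dense samples x sites
matrix of derived-allele dosages with per-site annotations.  Sites are
polarised: each site carries exactly one ancestral and one derived allele,
and dosage counts copies of the derived allele.  Missing genotypes are
encoded as ``MISSING`` (-1), never as dosage 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype (distinct from dosage 0)
MISSING: int = -1

#: recognised functional-impact categories for load analyses
IMPACT_CATEGORIES = ("LOW", "MODERATE", "HIGH", "NONE")

#: recognised sampling cohorts, historical epoch first
COHORTS = ("historical", "founder_wildborn", "early_captive", "late_captive", "wild")

SITE_COLUMNS = ("chrom", "pos", "anc", "der", "impact")


@dataclass
class GenotypeMatrix:
    """Samples x polarised biallelic sites with derived-allele dosages.

    Parameters
    ----------
    sample_ids
        Sample identifiers, one per row of ``genotypes``.
    cohorts
        Per-sample cohort label (see :data:`COHORTS`; free labels allowed
        for outgroup panels).
    sites
        Per-site table with columns ``chrom, pos, anc, der, impact``;
        ``pos`` is 1-based.
    genotypes
        ``(n_samples, n_sites)`` int8 array of derived-allele dosages in
        {0, 1, 2} or :data:`MISSING`.
    depth, gq
        Optional per-genotype read depth and genotype quality, same shape
        as ``genotypes``.
    """

    sample_ids: list[str]
    cohorts: np.ndarray
    sites: pd.DataFrame
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cohorts = np.asarray(self.cohorts, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} genotype rows")
        if len(self.cohorts) != n:
            raise ValueError("cohorts length must match sample count")
        if len(self.sites) != m:
            raise ValueError(f"{len(self.sites)} site rows for {m} genotype columns")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites table lacks columns: {missing_cols}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing (-1)")
        self.sites = self.sites.reset_index(drop=True)
        for arr, name in ((self.depth, "depth"), (self.gq, "gq")):
            if arr is not None and arr.shape != self.genotypes.shape:
                raise ValueError(f"{name} must have the same shape as genotypes")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    # -- subsetting -----------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            cohorts=self.cohorts[index],
            sites=self.sites,
            genotypes=self.genotypes[index],
            depth=None if self.depth is None else self.depth[index],
            gq=None if self.gq is None else self.gq[index],
        )

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            cohorts=self.cohorts,
            sites=self.sites.iloc[mask].reset_index(drop=True),
            genotypes=self.genotypes[:, mask],
            depth=None if self.depth is None else self.depth[:, mask],
            gq=None if self.gq is None else self.gq[:, mask],
        )

    def by_cohort(self, *labels: str) -> "GenotypeMatrix":
        return self.take_samples(np.isin(self.cohorts, labels))

    def impact_mask(self, category: str) -> np.ndarray:
        if category not in IMPACT_CATEGORIES:
            raise ValueError(f"unknown impact category {category!r}")
        return (self.sites["impact"] == category).to_numpy()

    # -- summaries ------------------------------------------------------
    def allele_frequency(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site derived-allele frequency over non-missing genotypes.

        Returns ``(freq, called_chromosomes)``; frequency is NaN where no
        genotype is called.
        """
        called = self.genotypes != MISSING
        n_chrom = 2 * called.sum(axis=0)
        derived = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_chrom > 0, derived / np.maximum(n_chrom, 1), np.nan)
        return freq, n_chrom

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and list(self.cohorts) == list(other.cohorts)
            and self.sites[list(SITE_COLUMNS)].equals(other.sites[list(SITE_COLUMNS)])
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class ROHProfile:
    """Per-sample merged runs of homozygosity.

    ``intervals`` uses BED convention (0-based, half-open) and is kept
    sorted and non-overlapping; ``genome_length`` is the assayed autosome
    length in bp.
    """

    sample_id: str
    intervals: pd.DataFrame  # chrom, start, end
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        cols = ["chrom", "start", "end"]
        if list(self.intervals.columns[:3]) != cols:
            self.intervals = self.intervals.rename(
                columns=dict(zip(self.intervals.columns[:3], cols))
            )
        self.intervals = self.intervals.reset_index(drop=True)

    @property
    def total_length(self) -> int:
        if len(self.intervals) == 0:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())


@dataclass
class BinHetMatrix:
    """Binned per-sample heterozygosity, as emitted by an ROH caller.

    ``het`` is ``(n_bins, n_samples)``; ``groups`` labels each sample
    (e.g. ``wild`` / ``captive``).  ``partial`` flags terminal bins
    shorter than the nominal ``bin_size``.
    """

    bins: pd.DataFrame  # chrom, start, end
    sample_ids: list[str]
    groups: np.ndarray
    het: np.ndarray
    bin_size: int
    log_transformed: bool = False
    pseudocount: float = 0.0
    partial: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=object)
        self.het = np.asarray(self.het, dtype=float)
        if self.het.shape != (len(self.bins), len(self.sample_ids)):
            raise ValueError("het must be (n_bins, n_samples)")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("groups length must match sample count")
        if not self.log_transformed and np.nanmin(self.het, initial=0.0) < 0:
            raise ValueError("heterozygosity must be non-negative")
        if self.partial is None:
            width = (self.bins["end"] - self.bins["start"]).to_numpy()
            self.partial = width < self.bin_size
        self.bins = self.bins.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return self.het.shape[0]
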