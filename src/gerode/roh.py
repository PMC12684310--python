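"""Runs of homozygosity: F_ROH, tract-age conversion, stratification.

A ROH of physical length L Mb corresponds to a genetic length of
L * r centimorgans at recombination rate r (cM/Mb), and the expected
coalescence time of the underlying haplotypes is G = 100 / (2 * cM)
generations: older autozygous segments have been broken up by more
meioses and are therefore shorter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ROHProfile

#: default generation bins for tract-age stratification (open-ended last bin)
DEFAULT_GENERATION_BINS = ((0, 2), (2, 4), (4, 8), (8, 16), (16, np.inf))


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge half-open intervals per chromosome.

    Overlapping and book-ended intervals are unioned; merging is
    idempotent and order-insensitive.
    """
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if (intervals["end"] <= intervals["start"]).any():
        raise ValueError("intervals must satisfy start < end")
    out = []
    for chrom, sub in intervals.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur_start, cur_end = None, None
        for row in sub.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
            elif row.start <= cur_end:
                cur_end = max(cur_end, row.end)
            else:
                out.append((chrom, cur_start, cur_end))
                cur_start, cur_end = row.start, row.end
        out.append((chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def froh(profile: ROHProfile) -> float:
    """Fraction of the assayed genome inside (merged) ROH."""
    total = profile.total_length
    if total > profile.genome_length:
        raise ValueError(
            f"ROH total {total} exceeds genome length {profile.genome_length}"
        )
    return total / profile.genome_length


def roh_age(length_bp: float, rec_rate_cM_per_Mb: float) -> float:
    """Expected tract age in generations, G = 100 / (2 * cM).

    Monotone decreasing in length: long tracts reflect recent common
    ancestry of the two haplotypes.
    """
    if length_bp <= 0:
        raise ValueError("ROH length must be positive")
    if rec_rate_cM_per_Mb <= 0:
        raise ValueError("recombination rate must be positive")
    cM = (length_bp / 1e6) * rec_rate_cM_per_Mb
    return 100.0 / (2.0 * cM)


def age_to_length_bp(generations: float, rec_rate_cM_per_Mb: float) -> float:
    """Inverse of :func:`roh_age`: expected tract length (bp) for age G."""
    if generations <= 0 or rec_rate_cM_per_Mb <= 0:
        raise ValueError("generations and recombination rate must be positive")
    cM = 100.0 / (2.0 * generations)
    return cM / rec_rate_cM_per_Mb * 1e6


def stratify(
    profile: ROHProfile,
    rec_rate_cM_per_Mb: float = 3.42,
    size_threshold: int = 10_000_000,
    generation_bins=DEFAULT_GENERATION_BINS,
) -> pd.DataFrame:
    """Partition F_ROH by tract size class and tract-age generation bin.

    Each interval lands in exactly one size class (<= / > ``size_threshold``)
    and one generation bin (interval ``(lo, hi]`` on G); tracts older than
    the last bin go to an open-ended final bin with a warning.  Per-class
    F_ROH sums to the total by construction.
    """
    rows = []
    overflow = False
    for iv in profile.intervals.itertuples(index=False):
        length = iv.end - iv.start
        g = roh_age(length, rec_rate_cM_per_Mb)
        size_class = f">{size_threshold // 1_000_000}Mb" if length > size_threshold else f"<={size_threshold // 1_000_000}Mb"
        gen_bin = None
        for lo, hi in generation_bins:
            if lo < g <= hi:
                gen_bin = f"({lo},{hi}]"
                break
        if gen_bin is None:
            overflow = True
            lo, hi = generation_bins[-1]
            gen_bin = f"({lo},{hi}]"
        rows.append((size_class, gen_bin, length))
    if overflow:
        warnings.warn("tract age outside configured bins; assigned to the last bin")
    tbl = pd.DataFrame(rows, columns=["size_class", "generation_bin", "length"])
    if len(tbl) == 0:
        return pd.DataFrame(columns=["size_class", "generation_bin", "froh"])
    out = (
        tbl.groupby(["size_class", "generation_bin"], as_index=False)["length"]
        .sum()
        .assign(froh=lambda d: d["length"] / profile.genome_length)
        .drop(columns="length")
    )
    return out


def froh_table(profiles: dict[str, ROHProfile]) -> pd.DataFrame:
    """Per-sample F_ROH summary over a collection of profiles."""
    return pd.DataFrame(
        [(s, froh(p), p.total_length, len(p.intervals)) for s, p in profiles.items()],
        columns=["sample", "froh", "roh_bp", "n_roh"],
    )
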