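"""Temporal genetic-load dynamics from polarised genotype matrices.

Derived alleles at annotated sites are counted per sample (homozygotes
contribute two copies), moderate/high-impact counts are normalised by the
sample's total low-impact count to correct for variant-discovery power,
and temporal change is summarised by per-site frequency differences, a
binomial sign test, and the Rxy ratio of derived-allele frequency sums
with a delete-d jackknife for its uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .containers import MISSING, GenotypeMatrix, ROHProfile


# ---------------------------------------------------------------------------
# polarisation
# ---------------------------------------------------------------------------

@dataclass
class PolarisationReport:
    n_sites: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_sites if self.n_sites else float("nan")


def polarise(gm: GenotypeMatrix, outgroups: GenotypeMatrix) -> tuple[np.ndarray, PolarisationReport]:
    """Site mask keeping only sites where every outgroup is homozygous ancestral.

    Requiring consensus homozygous-reference outgroup genotypes (and a
    100% outgroup genotyping rate) guards the ancestral-allele call
    against lineage-specific substitutions.  Returns a boolean mask over
    ``gm`` sites and a report with the retained fraction.
    """
    if outgroups.n_samples == 0:
        raise ValueError("at least one outgroup sample is required to polarise")
    if outgroups.n_sites != gm.n_sites:
        raise ValueError("outgroup matrix must cover the same sites")
    all_called = (outgroups.genotypes != MISSING).all(axis=0)
    all_ancestral = (outgroups.genotypes == 0).all(axis=0)
    mask = all_called & all_ancestral
    return mask, PolarisationReport(n_sites=gm.n_sites, n_retained=int(mask.sum()))


# ---------------------------------------------------------------------------
# per-sample load counts
# ---------------------------------------------------------------------------

def count_load(gm: GenotypeMatrix, category: str) -> pd.DataFrame:
    """Per-sample derived-allele counts for one impact category.

    het counts heterozygous sites, hom counts homozygous-derived alleles
    (two per site), total = het + hom.  Missing genotypes contribute
    nothing.
    """
    mask = gm.impact_mask(category)
    if mask.sum() == 0:
        warnings.warn(f"no sites in category {category}; returning zero counts")
    sub = gm.genotypes[:, mask]
    het = (sub == 1).sum(axis=1)
    hom = 2 * (sub == 2).sum(axis=1)
    return pd.DataFrame(
        {
            "sample": gm.sample_ids,
            "cohort": gm.cohorts,
            "category": category,
            "het": het,
            "hom": hom,
            "total": het + hom,
        }
    )


def normalise_load(counts: pd.DataFrame, low_counts: pd.DataFrame) -> pd.DataFrame:
    """Divide het/hom/total by each sample's total low-impact count."""
    merged = counts.merge(
        low_counts[["sample", "total"]].rename(columns={"total": "low_total"}),
        on="sample",
    )
    for col in ("het", "hom", "total"):
        merged[f"{col}_norm"] = merged[col] / merged["low_total"]
    return merged


def apply_load_depth_window(gm: GenotypeMatrix, cfg: RunConfig) -> GenotypeMatrix:
    """Mask genotypes outside the stricter load-site depth window.

    The historical epoch uses a lower depth ceiling than the modern one
    (twice the respective average coverages); applied as per-genotype
    missingness on top of the global filters.
    """
    if gm.depth is None:
        return gm
    geno = gm.genotypes.copy()
    hist = gm.cohorts == "historical"
    dmax = np.where(hist, cfg.load_depth_max_historical, cfg.load_depth_max_modern)[:, None]
    bad = (gm.depth < cfg.load_depth_min) | (gm.depth > dmax)
    geno[bad & (geno != MISSING)] = MISSING
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        cohorts=gm.cohorts,
        sites=gm.sites,
        genotypes=geno,
        depth=gm.depth,
        gq=gm.gq,
    )


# ---------------------------------------------------------------------------
# epoch frequency table
# ---------------------------------------------------------------------------

HISTORICAL_COHORTS = ("historical",)
MODERN_COHORTS = ("founder_wildborn", "early_captive", "late_captive", "wild")


def frequency_table(
    gm: GenotypeMatrix,
    historical=HISTORICAL_COHORTS,
    modern=MODERN_COHORTS,
    shared_only: bool = False,
) -> pd.DataFrame:
    """Per-site derived-allele frequencies in the two sampling epochs.

    Frequencies are computed over non-missing genotypes only.  With
    ``shared_only`` the table is restricted to variants segregating
    (derived allele observed) in both epochs, the filtering mode that
    enriches for intermediate-frequency variants.
    """
    hist = gm.by_cohort(*historical)
    mod = gm.by_cohort(*modern)
    if hist.n_samples == 0 or mod.n_samples == 0:
        raise ValueError("both epochs need at least one sample")
    fh, nh = hist.allele_frequency()
    fm, nm = mod.allele_frequency()
    tbl = gm.sites[["chrom", "pos", "impact"]].copy()
    tbl["fh"], tbl["fm"] = fh, fm
    tbl["nchrom_h"], tbl["nchrom_m"] = nh, nm
    tbl["shared"] = (fh > 0) & (fm > 0)
    if shared_only:
        tbl = tbl[tbl["shared"]].reset_index(drop=True)
    return tbl


# ---------------------------------------------------------------------------
# frequency change
# ---------------------------------------------------------------------------

@dataclass
class DeltaSummary:
    category: str
    n_sites: int
    n_excluded: int
    mean_delta: float
    prop_positive: float
    deltas: np.ndarray = field(repr=False)


def delta_frequency(ft: pd.DataFrame, category: str) -> DeltaSummary:
    """Per-site Δfrequency = F_modern − F_historical for one category.

    Sites uncallable in either epoch are excluded and counted; the
    summary reports the mean Δ and the proportion of sites with Δ > 0.
    """
    sub = ft[ft["impact"] == category]
    callable_ = (sub["nchrom_h"] > 0) & (sub["nchrom_m"] > 0)
    deltas = (sub["fm"] - sub["fh"])[callable_].to_numpy()
    if len(deltas) == 0:
        raise ValueError(f"no callable sites for category {category}")
    return DeltaSummary(
        category=category,
        n_sites=int(callable_.sum()),
        n_excluded=int((~callable_).sum()),
        mean_delta=float(deltas.mean()),
        prop_positive=float((deltas > 0).mean()),
        deltas=deltas,
    )


def sign_binomial_test(deltas: np.ndarray) -> float:
    """Two-sided binomial sign test of #(Δ > 0) among nonzero Δ against 0.5."""
    deltas = np.asarray(deltas, dtype=float)
    nonzero = deltas[deltas != 0]
    if len(nonzero) == 0:
        warnings.warn("all frequency changes are zero; sign test p = 1")
        return 1.0
    k = int((nonzero > 0).sum())
    return float(stats.binomtest(k, len(nonzero), 0.5, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Rxy
# ---------------------------------------------------------------------------

@dataclass
class RxyResult:
    category: str
    low_category: str
    raw: float
    raw_low: float
    normalised: float
    n_sites: int
    replicates: np.ndarray | None = field(default=None, repr=False)
    var_replicates: float | None = None
    var_jackknife: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def _rxy_sums(ft: pd.DataFrame, category: str) -> tuple[float, float]:
    sub = ft[(ft["impact"] == category) & (ft["nchrom_h"] > 0) & (ft["nchrom_m"] > 0)]
    num = float((sub["fm"] * (1 - sub["fh"])).sum())
    den = float((sub["fh"] * (1 - sub["fm"])).sum())
    return num, den


def rxy(ft: pd.DataFrame, category: str, low_category: str = "LOW") -> RxyResult:
    """Rxy ratio-of-sums for one category, normalised by the low-impact ratio.

    Rxy = Σ_sites Fm(1−Fh) / Σ_sites Fh(1−Fm); values below 1 indicate a
    relative deficit of derived alleles of that category in the modern
    epoch.  Aggregating sums before the ratio keeps sites fixed in one
    epoch informative.
    """
    num, den = _rxy_sums(ft, category)
    if den == 0:
        raise ValueError(f"Rxy denominator zero: no historical derived alleles in {category}")
    lnum, lden = _rxy_sums(ft, low_category)
    if lden == 0 or lnum == 0:
        raise ValueError(f"Rxy normaliser degenerate for category {low_category}")
    raw = num / den
    raw_low = lnum / lden
    n_sites = int(((ft["impact"] == category) & (ft["nchrom_h"] > 0) & (ft["nchrom_m"] > 0)).sum())
    return RxyResult(
        category=category,
        low_category=low_category,
        raw=raw,
        raw_low=raw_low,
        normalised=raw / raw_low,
        n_sites=n_sites,
    )


def jackknife_rxy(
    ft: pd.DataFrame,
    category: str,
    low_category: str = "LOW",
    blocks: int = 100,
    frac: float = 0.01,
    seed: int | None = None,
) -> RxyResult:
    """Delete-d jackknife over sites for the normalised Rxy.

    Sites (category plus normaliser pooled) are partitioned into ``blocks``
    disjoint groups of ~``frac`` of the data by a seeded permutation; each
    replicate recomputes the normalised Rxy with one group excluded.
    Reports the raw replicate variance (the conventional error bar), a
    delete-d jackknife variance estimate scaled by (n−d)/(d·m), and a
    normal-approximation CI from the scaled estimate.
    """
    if seed is None:
        raise ValueError("jackknife requires a seed")
    point = rxy(ft, category, low_category)
    pool = ft[ft["impact"].isin([category, low_category])].reset_index(drop=True)
    n = len(pool)
    d = int(round(frac * n))
    if d < 1:
        raise ValueError(f"frac × sites = {frac * n:.2f} < 1: too few sites to jackknife")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    groups = np.array_split(perm, blocks)
    reps = []
    for grp in groups:
        keep = np.ones(n, dtype=bool)
        keep[grp] = False
        sub = pool[keep]
        num, den = _rxy_sums(sub, category)
        lnum, lden = _rxy_sums(sub, low_category)
        reps.append((num / den) / (lnum / lden))
    reps = np.array(reps)
    m = len(reps)
    d_eff = n / m  # average block size
    var_reps = float(reps.var(ddof=1))
    var_jack = float((n - d_eff) / (d_eff * m) * ((reps - reps.mean()) ** 2).sum())
    half = 1.959963984540054 * np.sqrt(var_jack)
    point.replicates = reps
    point.var_replicates = var_reps
    point.var_jackknife = var_jack
    point.ci_low = point.normalised - half
    point.ci_high = point.normalised + half
    return point


# ---------------------------------------------------------------------------
# homozygous load inside/outside ROH
# ---------------------------------------------------------------------------

def load_in_out_roh(
    gm: GenotypeMatrix,
    category: str,
    profiles: dict[str, ROHProfile],
) -> pd.DataFrame:
    """Split each sample's homozygous derived-allele count by ROH membership.

    Counts are normalised by the genome fraction inside (F_ROH) and
    outside (1 − F_ROH) ROH; a sample with F_ROH of exactly 0 or 1 gets
    NaN for the undefined side.  Raw in + out equals the total
    homozygous count.
    """
    from .roh import froh as _froh

    mask = gm.impact_mask(category)
    sites = gm.sites[mask]
    out_rows = []
    for i, sample in enumerate(gm.sample_ids):
        if sample not in profiles:
            continue
        prof = profiles[sample]
        in_roh = np.zeros(len(sites), dtype=bool)
        iv = prof.intervals
        for chrom, sub in sites.groupby("chrom", sort=False):
            civ = iv[iv["chrom"] == chrom]
            if len(civ) == 0:
                continue
            pos0 = sub["pos"].to_numpy() - 1  # BED half-open coordinates
            starts = civ["start"].to_numpy()
            ends = civ["end"].to_numpy()
            idx = np.searchsorted(starts, pos0, side="right") - 1
            hit = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
            in_roh[sites.index.get_indexer(sub.index)] = hit
        hom = gm.genotypes[i, mask] == 2
        in_count = 2 * int((hom & in_roh).sum())
        out_count = 2 * int((hom & ~in_roh).sum())
        f = _froh(prof)
        out_rows.append(
            {
                "sample": sample,
                "category": category,
                "froh": f,
                "hom_in": in_count,
                "hom_out": out_count,
                "hom_in_norm": in_count / f if f > 0 else np.nan,
                "hom_out_norm": out_count / (1 - f) if f < 1 else np.nan,
            }
        )
    return pd.DataFrame(out_rows)
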