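"""Readers and writers for the external formats the pipeline consumes.

Formats: VCF (genotypes, FORMAT DP/GQ honoured) or a wide TSV dialect for
genotype matrices; BED for ROH intervals (0-based half-open); TSV for
binned heterozygosity and CADD-style score tables; CSV for the studbook
pedigree.  All report writers emit plain TSV with a commented header
naming package version and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .config import RunConfig
from .containers import MISSING, BinHetMatrix, GenotypeMatrix, ROHProfile, SITE_COLUMNS


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def _normalise_cohort_map(cohort_map) -> dict:
    if isinstance(cohort_map, dict):
        return dict(cohort_map)
    if isinstance(cohort_map, pd.DataFrame):
        return dict(zip(cohort_map.iloc[:, 0], cohort_map.iloc[:, 1]))
    # assume a path to a two-column TSV: sample, cohort
    tbl = pd.read_csv(cohort_map, sep="\t", comment="#", header=None, dtype=str)
    return dict(zip(tbl.iloc[:, 0], tbl.iloc[:, 1]))


def read_genotypes(path, cohort_map) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or wide TSV.

    Dosages are computed relative to the declared derived allele (VCF ALT);
    missing genotypes are preserved as missing.  Multiallelic sites are
    rejected with the offending site named.
    """
    cmap = _normalise_cohort_map(cohort_map)
    path = str(path)
    if path.endswith((".tsv", ".txt")):
        gm = _read_genotypes_tsv(path)
    else:
        gm = _read_genotypes_vcf(path)
    unknown = [s for s in cmap if s not in gm.sample_ids]
    if unknown:
        raise ValueError(f"cohort map names unknown samples: {unknown}")
    uncovered = [s for s in gm.sample_ids if s not in cmap]
    if uncovered:
        raise ValueError(f"cohort map does not cover samples: {uncovered}")
    gm.cohorts = np.array([cmap[s] for s in gm.sample_ids], dtype=object)
    return gm


def _read_genotypes_vcf(path: str) -> GenotypeMatrix:
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosages, depths, gqs = [], [], [], []
    have_dp = have_gq = False
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic site {variant.CHROM}:{variant.POS} "
                f"({variant.REF},{','.join(variant.ALT)}): split or drop it first"
            )
        impact = variant.INFO.get("IMPACT") or "NONE"
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0], impact))
        gts = np.array([g[:2] for g in variant.genotypes])  # (n, 2) allele idx
        dose = gts.sum(axis=1).astype(np.int8)
        dose[(gts < 0).any(axis=1)] = MISSING
        dosages.append(dose)
        try:
            dp = variant.format("DP")
        except KeyError:
            dp = None
        try:
            gq = variant.format("GQ")
        except KeyError:
            gq = None
        if dp is not None:
            have_dp = True
            depths.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]))
        else:
            depths.append(np.zeros(len(samples), dtype=int))
        if gq is not None:
            have_gq = True
            gqs.append(np.where(gq[:, 0] < 0, 0, gq[:, 0]))
        else:
            gqs.append(np.zeros(len(samples), dtype=int))
    sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    geno = (
        np.array(dosages, dtype=np.int8).T
        if dosages
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        cohorts=np.array(["wild"] * len(samples), dtype=object),
        sites=sites,
        genotypes=geno,
        depth=np.array(depths).T if have_dp else None,
        gq=np.array(gqs).T if have_gq else None,
    )


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    tbl = pd.read_csv(path, sep="\t", comment="#")
    meta = list(SITE_COLUMNS)
    samples = [c for c in tbl.columns if c not in meta]
    geno = (
        tbl[samples]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(MISSING)
        .to_numpy()
        .astype(np.int8)
        .T
    )
    return GenotypeMatrix(
        sample_ids=samples,
        cohorts=np.array(["wild"] * len(samples), dtype=object),
        sites=tbl[meta].copy(),
        genotypes=geno,
    )


def write_genotypes_vcf(gm: GenotypeMatrix, path, contig_lengths: dict | None = None) -> None:
    """Write a genotype matrix as an uncompressed VCF.

    REF holds the ancestral allele and ALT the single derived allele;
    the impact category goes to INFO/IMPACT and DP/GQ to FORMAT when
    present.
    """
    sites = gm.sites
    if contig_lengths is None:
        contig_lengths = (
            sites.groupby("chrom", sort=False)["pos"].max().astype(int).to_dict()
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=gerode-{__version__}\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length) + 1}>\n")
        fh.write('##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted functional impact">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if gm.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT" + (":DP" if gm.depth is not None else "") + (":GQ" if gm.gq is not None else "")
        for j in range(gm.n_sites):
            row = sites.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                cell = gt_code[int(gm.genotypes[i, j])]
                if gm.depth is not None:
                    cell += f":{int(gm.depth[i, j])}"
                if gm.gq is not None:
                    cell += f":{int(gm.gq[i, j])}"
                cells.append(cell)
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.anc}\t{row.der}\t.\tPASS\t"
                f"IMPACT={row.impact}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    tbl = gm.sites[list(SITE_COLUMNS)].copy()
    for i, sample in enumerate(gm.sample_ids):
        tbl[sample] = gm.genotypes[i]
    tbl.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site/genotype filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_sites_in: int
    n_sites_kept: int
    n_sites_dropped_rate: int
    n_genotypes_masked_depth: int
    n_genotypes_masked_gq: int

    def __post_init__(self) -> None:
        assert self.n_sites_kept + self.n_sites_dropped_rate == self.n_sites_in


def apply_site_filters(gm: GenotypeMatrix, cfg: RunConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply per-genotype depth/GQ thresholds, then a site genotyping-rate cut.

    Genotypes failing a per-genotype threshold are set to missing; sites
    called in fewer than ``cfg.genotyping_rate`` of samples are dropped.
    """
    geno = gm.genotypes.copy()
    masked_depth = masked_gq = 0
    if gm.depth is not None:
        bad = (gm.depth < cfg.depth_min) | (gm.depth > cfg.depth_max)
        bad &= geno != MISSING
        masked_depth = int(bad.sum())
        geno[bad] = MISSING
    if gm.gq is not None:
        bad = (gm.gq < cfg.gq_min) & (geno != MISSING)
        masked_gq = int(bad.sum())
        geno[bad] = MISSING
    rate = (geno != MISSING).mean(axis=0)
    keep = rate >= cfg.genotyping_rate
    filtered = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        cohorts=gm.cohorts,
        sites=gm.sites,
        genotypes=geno,
        depth=gm.depth,
        gq=gm.gq,
    ).take_sites(keep)
    report = FilterReport(
        n_sites_in=gm.n_sites,
        n_sites_kept=int(keep.sum()),
        n_sites_dropped_rate=int((~keep).sum()),
        n_genotypes_masked_depth=masked_depth,
        n_genotypes_masked_gq=masked_gq,
    )
    if report.n_sites_kept == 0:
        warnings.warn("all sites removed by filters; returning an empty matrix")
    return filtered, report


# ---------------------------------------------------------------------------
# ROH BED, binned heterozygosity, CADD scores, pedigree CSV
# ---------------------------------------------------------------------------

def read_roh(path, genome_length: int) -> dict[str, ROHProfile]:
    """Read per-sample ROH intervals from a 4-column BED (chrom, start, end, sample).

    Unsorted or overlapping intervals are merged with a warning.
    """
    from .roh import merge_intervals  # local import: avoid a cycle

    bed = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "sample"],
        dtype={"chrom": str, "start": int, "end": int, "sample": str},
    )
    profiles = {}
    for sample, sub in bed.groupby("sample", sort=False):
        merged = merge_intervals(sub[["chrom", "start", "end"]])
        if len(merged) < len(sub):
            warnings.warn(f"overlapping/adjacent ROH intervals merged for {sample}")
        profiles[sample] = ROHProfile(sample, merged, genome_length)
    return profiles


def write_roh_bed(profiles: dict[str, ROHProfile], path) -> None:
    with open(path, "w") as fh:
        for sample, prof in profiles.items():
            for row in prof.intervals.itertuples(index=False):
                fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{sample}\n")


def read_bin_het(path, group_map) -> BinHetMatrix:
    """Read a long-format binned-heterozygosity TSV.

    Expected columns: chrom, start, end, sample, heterozygosity.
    ``group_map`` maps sample id to its comparison group.
    """
    tbl = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "sample", "heterozygosity"}
    if not required.issubset(tbl.columns):
        raise ValueError(f"bin-het table needs columns {sorted(required)}")
    gmap = _normalise_cohort_map(group_map)
    wide = tbl.pivot_table(
        index=["chrom", "start", "end"],
        columns="sample",
        values="heterozygosity",
        sort=False,
    )
    bins = wide.index.to_frame(index=False)
    samples = list(wide.columns)
    missing = [s for s in samples if s not in gmap]
    if missing:
        raise ValueError(f"group map does not cover samples: {missing}")
    sizes = (bins["end"] - bins["start"]).to_numpy()
    return BinHetMatrix(
        bins=bins,
        sample_ids=samples,
        groups=np.array([gmap[s] for s in samples], dtype=object),
        het=wide.to_numpy(),
        bin_size=int(np.max(sizes)),
    )


def write_bin_het(bh: BinHetMatrix, path) -> None:
    records = []
    for b, row in enumerate(bh.bins.itertuples(index=False)):
        for s, sample in enumerate(bh.sample_ids):
            records.append((row.chrom, int(row.start), int(row.end), sample, bh.het[b, s]))
    pd.DataFrame(
        records, columns=["chrom", "start", "end", "sample", "heterozygosity"]
    ).to_csv(path, sep="\t", index=False)


def read_cadd(path) -> pd.DataFrame:
    """Read a per-site deleteriousness score TSV (chrom, pos, ref, alt, score)."""
    tbl = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt", "score"]
    missing = [c for c in required if c not in tbl.columns]
    if missing:
        raise ValueError(f"score table lacks columns {missing}")
    score = pd.to_numeric(tbl["score"], errors="coerce")
    if score.isna().any():
        line = int(score.index[score.isna()][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"non-numeric score at line {line} of {path}")
    tbl["score"] = score.astype(float)
    return tbl[required]


def read_pedigree(path):
    """Read a studbook CSV (id, sire, dam, sex, cohort) into a Pedigree.

    Unknown parents may be blank, 'NA' or '0'.  A cyclic pedigree raises
    with the cycle listed.
    """
    from .pedigree import Pedigree

    tbl = pd.read_csv(path, dtype=str, comment="#")
    required = ["id", "sire", "dam"]
    missing = [c for c in required if c not in tbl.columns]
    if missing:
        raise ValueError(f"pedigree table lacks columns {missing}")
    for col in ("sire", "dam"):
        tbl[col] = tbl[col].replace({"0": None, "NA": None, "": None})
        tbl[col] = tbl[col].where(tbl[col].notna(), None)
    return Pedigree(tbl)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def write_report(df: pd.DataFrame, path, seed=None) -> None:
    """Write a TSV report with a commented provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# gerode {__version__}\tseed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
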