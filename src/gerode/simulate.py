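"""Forward simulators generating every input the analysis consumes.

Three generators, all seeded and reproducible:

* :func:`simulate_wf` — a discrete-generation diploid Wright-Fisher
  engine with per-site selection and dominance (fitness 1, 1−hs, 1−s for
  dosage 0, 1, 2), multiplicative fitness across unlinked sites,
  multinomial reproduction with random mating (selfing allowed, the
  idealised WF model), recurrent ancestral→derived mutation, and diploid
  individuals sampled without replacement at declared epochs.  The
  default configuration emulates a two-epoch study design: a historical
  sample of 16 taken before a collapse to ~20 breeders, and a modern
  sample of 37 taken nine generations later after demographic recovery.
* :func:`simulate_pedigree` — a captive breeding programme: founder
  pairs, per-generation mating under a random or minimum-kinship policy,
  and genotypes gene-dropped from founder haplotypes with realised IBD
  recorded.
* :func:`simulate_roh_and_bins` — per-sample ROH tracts of a target age
  (tract length exponential with mean 100/(2G) cM) and the matching
  binned-heterozygosity matrix, optionally with injected group-private
  low-heterozygosity regions of stated effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, BinHetMatrix, GenotypeMatrix, ROHProfile
from .pedigree import Pedigree, kinship
from .roh import age_to_length_bp, merge_intervals


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CategoryModel:
    """Per-impact-category site counts and selection-coefficient range."""

    n_sites: int
    s_range: tuple[float, float]  # uniform; (0, 0) for neutral
    h_override: float | None = None  # fixed h instead of the s-dependent rule


@dataclass
class SimConfig:
    """Wright-Fisher study-design configuration.

    ``n_trajectory`` is a list of (generation, diploid N) breakpoints,
    linearly interpolated; ``sample_plan`` lists (epoch, cohort, n,
    generation) draws.  Dominance follows h(s) = 0.5 / (1 + h_k·s), a
    declining function making strongly deleterious mutations nearly
    recessive; a category may override it with a fixed h.
    """

    n_trajectory: list = field(
        default_factory=lambda: [(0, 150), (3, 150), (5, 20), (7, 20), (9, 80), (12, 150)]
    )
    categories: dict = field(
        default_factory=lambda: {
            "LOW": CategoryModel(2000, (0.0, 0.0)),
            "MODERATE": CategoryModel(1000, (0.005, 0.05)),
            "HIGH": CategoryModel(500, (0.2, 0.8)),
        }
    )
    sample_plan: list = field(
        default_factory=lambda: [
            ("historical", "historical", 16, 3),
            ("modern", "founder_wildborn", 6, 12),
            ("modern", "early_captive", 6, 12),
            ("modern", "late_captive", 6, 12),
            ("modern", "wild", 19, 12),
        ]
    )
    mutation_rate: float = 1e-5
    h_k: float = 50.0
    #: deleterious variants start rare; neutral sites follow a 1/q spectrum
    init_freq_max_deleterious: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        gens = [g for g, _ in self.n_trajectory]
        if gens != sorted(gens):
            raise ValueError("trajectory breakpoints must be in generation order")
        if any(n < 2 for _, n in self.n_trajectory):
            raise ValueError("diploid N must be at least 2 everywhere")
        g_max = gens[-1]
        for epoch, cohort, n, g in self.sample_plan:
            if not 0 <= g <= g_max:
                raise ValueError(f"sampling generation {g} outside trajectory [0, {g_max}]")
        for name, cm in self.categories.items():
            lo, hi = cm.s_range
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"s range for {name} must satisfy 0 <= lo <= hi <= 1")

    def n_at(self, g: int) -> int:
        gens = np.array([p[0] for p in self.n_trajectory], dtype=float)
        sizes = np.array([p[1] for p in self.n_trajectory], dtype=float)
        return int(round(float(np.interp(g, gens, sizes))))

    @property
    def g_max(self) -> int:
        return self.n_trajectory[-1][0]

    def h_rule(self, s: np.ndarray) -> np.ndarray:
        return 0.5 / (1.0 + self.h_k * np.asarray(s, dtype=float))


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated genotype matrices."""

    sites: pd.DataFrame  # category, s, h, q0
    freq_path: np.ndarray  # (g_max + 1, L)
    n_path: list
    sampled: dict  # epoch -> list of (cohort, individual index)


# ---------------------------------------------------------------------------
# Wright-Fisher engine
# ---------------------------------------------------------------------------

def _neutral_sfs_freqs(rng, n_sites: int, two_n: int, q_max: float = 0.5) -> np.ndarray:
    """Initial frequencies from a 1/q spectrum on {1, .., 2N·q_max}/2N."""
    counts = np.arange(1, max(int(two_n * q_max), 2))
    weights = 1.0 / counts
    draw = rng.choice(counts, size=n_sites, p=weights / weights.sum())
    return draw / two_n


def _site_table(cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    two_n0 = 2 * cfg.n_at(0)
    for name, cm in cfg.categories.items():
        lo, hi = cm.s_range
        s = rng.uniform(lo, hi, size=cm.n_sites) if hi > lo else np.full(cm.n_sites, lo)
        h = np.full(cm.n_sites, cm.h_override) if cm.h_override is not None else cfg.h_rule(s)
        q_max = 0.5 if hi == 0 else cfg.init_freq_max_deleterious
        q0 = _neutral_sfs_freqs(rng, cm.n_sites, two_n0, q_max)
        for k in range(cm.n_sites):
            rows.append((name, s[k], h[k], q0[k]))
    tbl = pd.DataFrame(rows, columns=["category", "s", "h", "q0"])
    tbl["chrom"] = "chr1"
    tbl["pos"] = np.arange(1, len(tbl) + 1) * 10_000  # unlinked by construction
    tbl["anc"], tbl["der"] = "A", "T"
    return tbl


def simulate_wf(cfg: SimConfig) -> tuple[dict[str, GenotypeMatrix], SimTruth]:
    """Run the Wright-Fisher engine and draw the planned epoch samples.

    Each site segregates independently (free recombination, linkage
    equilibrium): selection acts on the realised genotype counts with
    fitnesses 1, 1−hs, 1−s, the post-selection gamete frequency is
    perturbed by recurrent ancestral→derived mutation, and the next
    generation of N diploid individuals forms by random union of
    gametes, so each individual's dosage is Binomial(2, q').  Returns
    one GenotypeMatrix per epoch (sites shared across epochs,
    ``impact`` set to the simulated category) plus the ground truth.
    """
    if cfg.seed is None:
        raise ValueError("SimConfig.seed is mandatory")
    rng = np.random.default_rng(cfg.seed)
    sites = _site_table(cfg, rng)
    L = len(sites)
    s = sites["s"].to_numpy()
    h = sites["h"].to_numpy()
    w_het = 1.0 - h * s
    w_hom = 1.0 - s

    n0 = cfg.n_at(0)
    pop = rng.binomial(2, sites["q0"].to_numpy()[None, :].repeat(n0, axis=0)).astype(np.int8)
    freq_path = np.empty((cfg.g_max + 1, L))
    freq_path[0] = pop.mean(axis=0) / 2.0
    n_path = [n0]

    plan_by_gen: dict[int, list] = {}
    for epoch, cohort, n, g in cfg.sample_plan:
        plan_by_gen.setdefault(g, []).append((epoch, cohort, n))
    samples: dict[str, dict] = {}

    def draw_samples(g: int, pop: np.ndarray) -> None:
        requests = plan_by_gen.get(g, [])
        total = sum(n for _, _, n in requests)
        if total == 0:
            return
        if total > pop.shape[0]:
            raise ValueError(
                f"sample size {total} exceeds population size {pop.shape[0]} at generation {g}"
            )
        chosen = rng.choice(pop.shape[0], size=total, replace=False)
        offset = 0
        for epoch, cohort, n in requests:
            idx = chosen[offset : offset + n]
            offset += n
            store = samples.setdefault(epoch, {"genotypes": [], "cohorts": [], "ids": [], "index": []})
            for k, i in enumerate(idx):
                store["genotypes"].append(pop[i].copy())
                store["cohorts"].append(cohort)
                store["ids"].append(f"{epoch}_{cohort}_{k}")
                store["index"].append((cohort, int(i)))

    draw_samples(0, pop)
    for g in range(1, cfg.g_max + 1):
        n_next = cfg.n_at(g)
        n_het = (pop == 1).sum(axis=0)
        n_hom = (pop == 2).sum(axis=0)
        n_anc = pop.shape[0] - n_het - n_hom
        # derived-gamete output of the selected parental pool, per site
        num = n_hom * w_hom + 0.5 * n_het * w_het
        den = n_anc + n_het * w_het + n_hom * w_hom
        if np.any(den == 0):
            raise RuntimeError("population fitness collapsed to zero at some site")
        q = num / den
        if cfg.mutation_rate > 0:
            q = q + cfg.mutation_rate * (1.0 - q)
        pop = rng.binomial(2, q[None, :].repeat(n_next, axis=0)).astype(np.int8)
        freq_path[g] = pop.mean(axis=0) / 2.0
        n_path.append(n_next)
        draw_samples(g, pop)

    site_cols = sites.rename(columns={"category": "impact"})[["chrom", "pos", "anc", "der", "impact"]]
    matrices = {}
    sampled = {}
    for epoch, store in samples.items():
        matrices[epoch] = GenotypeMatrix(
            sample_ids=store["ids"],
            cohorts=np.array(store["cohorts"], dtype=object),
            sites=site_cols.copy(),
            genotypes=np.array(store["genotypes"], dtype=np.int8),
        )
        sampled[epoch] = store["index"]
    truth = SimTruth(
        sites=sites[["category", "s", "h", "q0", "chrom", "pos"]],
        freq_path=freq_path,
        n_path=n_path,
        sampled=sampled,
    )
    return matrices, truth


def merge_epoch_matrices(matrices: dict[str, GenotypeMatrix]) -> GenotypeMatrix:
    """Stack per-epoch samples over the shared site set."""
    mats = list(matrices.values())
    first = mats[0]
    for m in mats[1:]:
        if not first.sites[["chrom", "pos"]].equals(m.sites[["chrom", "pos"]]):
            raise ValueError("epoch matrices must share the same sites")
    return GenotypeMatrix(
        sample_ids=[s for m in mats for s in m.sample_ids],
        cohorts=np.concatenate([m.cohorts for m in mats]),
        sites=first.sites.copy(),
        genotypes=np.vstack([m.genotypes for m in mats]),
    )


def expected_heterozygosity(freqs: np.ndarray) -> float:
    """Mean 2q(1−q) across sites for one generation of the frequency path."""
    return float((2.0 * freqs * (1.0 - freqs)).mean())


# ---------------------------------------------------------------------------
# captive pedigree with gene dropping
# ---------------------------------------------------------------------------

def simulate_pedigree(
    founders: int,
    generations: int,
    policy: str = "random",
    seed: int | None = None,
    offspring_per_pair: int = 2,
    n_breeding_pairs: int | None = None,
    n_sites: int = 200,
    founder_freq_range: tuple[float, float] = (0.05, 0.5),
    kinship_cap: float = 0.125,
) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    """Simulate a captive breeding programme and gene-drop genotypes.

    Founders are unrelated and non-inbred; each generation breeding
    pairs are formed under the mating policy (``random`` or
    ``min-kinship``, the latter greedily selecting the least-related
    available mates) and every pair leaves ``offspring_per_pair``
    offspring.  By default every individual breeds once
    (``n_breeding_pairs = n // 2``); restricting ``n_breeding_pairs``
    lets the policy also decide *who* breeds, the channel through which
    kinship-minimising management equalises founder representation.  If
    every available pair exceeds ``kinship_cap`` the least-related pair
    is used with a warning.  Genotypes at ``n_sites`` unlinked biallelic
    sites descend from founder haplotypes by Mendelian sampling;
    per-individual realised IBD (fraction of loci autozygous for founder
    haplotype labels) is returned alongside.
    """
    if founders < 2:
        raise ValueError("need at least two founders")
    if seed is None:
        raise ValueError("simulate_pedigree requires a seed")
    if policy not in ("random", "min-kinship"):
        raise ValueError(f"unknown mating policy {policy!r}")
    rng = np.random.default_rng(seed)

    q0 = rng.uniform(*founder_freq_range, size=n_sites)
    # two haplotypes per individual: allele (0/1) and founder-haplotype label
    alleles: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    rows = []
    current = []
    for k in range(founders):
        ind = f"F{k}"
        alleles[ind] = rng.binomial(1, q0, size=(2, n_sites)).astype(np.int8)
        labels[ind] = np.tile(np.array([[2 * k], [2 * k + 1]]), (1, n_sites))
        rows.append({"id": ind, "sire": None, "dam": None, "cohort": "founder"})
        current.append(ind)

    counter = 0
    for g in range(1, generations + 1):
        pool = list(current)
        rng.shuffle(pool)
        max_pairs = len(pool) // 2 if n_breeding_pairs is None else n_breeding_pairs
        pairs = []
        if policy == "random":
            while len(pool) >= 2 and len(pairs) < max_pairs:
                pairs.append((pool.pop(), pool.pop()))
        else:
            # mean-kinship management: breed the individuals least related
            # to the cohort, pairing each with its least-related partner
            ped_so_far = Pedigree(pd.DataFrame(rows))
            phi = kinship(ped_so_far).loc[pool, pool]
            n = len(pool)
            mean_kin = (phi.to_numpy().sum(axis=1) - np.diag(phi)) / max(n - 1, 1)
            # sequential selection: each new breeder minimises kinship to
            # those already chosen, which spreads picks across lineages
            first = pool[int(np.argmin(mean_kin))]
            breeders = [first]
            candidates = [p for p in pool if p != first]
            while len(breeders) < min(2 * max_pairs, n) and candidates:
                scores = np.array(
                    [phi.loc[c, breeders].to_numpy().mean() for c in candidates]
                )
                breeders.append(candidates.pop(int(np.argmin(scores))))
            while len(breeders) >= 2 and len(pairs) < max_pairs:
                a = breeders.pop(0)
                thetas = np.array([float(phi.loc[a, b]) for b in breeders])
                j = int(np.argmin(thetas))
                if thetas[j] > kinship_cap:
                    warnings.warn(
                        f"all available mates for {a} exceed kinship cap {kinship_cap}; "
                        f"using least-related partner (theta={thetas[j]:.3f})"
                    )
                pairs.append((a, breeders.pop(j)))
        nxt = []
        for a, b in pairs:
            for _ in range(offspring_per_pair):
                ind = f"I{counter}"
                counter += 1
                pick_a = rng.integers(0, 2, size=n_sites)
                pick_b = rng.integers(0, 2, size=n_sites)
                alleles[ind] = np.stack(
                    [
                        alleles[a][pick_a, np.arange(n_sites)],
                        alleles[b][pick_b, np.arange(n_sites)],
                    ]
                ).astype(np.int8)
                labels[ind] = np.stack(
                    [
                        labels[a][pick_a, np.arange(n_sites)],
                        labels[b][pick_b, np.arange(n_sites)],
                    ]
                )
                rows.append({"id": ind, "sire": a, "dam": b, "cohort": f"gen{g}"})
                nxt.append(ind)
        current = nxt

    ped = Pedigree(pd.DataFrame(rows))
    ids = list(ped.table["id"])
    geno = np.array([alleles[i].sum(axis=0) for i in ids], dtype=np.int8)
    ibd = pd.DataFrame(
        {
            "id": ids,
            "ibd_fraction": [float((labels[i][0] == labels[i][1]).mean()) for i in ids],
        }
    )
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 10_000,
            "anc": "A",
            "der": "T",
            "impact": "NONE",
        }
    )
    gm = GenotypeMatrix(
        sample_ids=ids,
        cohorts=ped.table["cohort"].to_numpy(dtype=object),
        sites=sites,
        genotypes=geno,
    )
    return ped, gm, ibd


# ---------------------------------------------------------------------------
# ROH tracts and binned heterozygosity
# ---------------------------------------------------------------------------

def simulate_roh_and_bins(
    n_per_group: dict[str, int],
    genome_length: int = 1_000_000_000,
    bin_size: int = 1_000_000,
    target_froh: float | dict = 0.10,
    tract_age_g: float = 4.0,
    rec_rate_cM_per_Mb: float = 3.42,
    baseline_het: float = 0.0008,
    bin_sd_log: float = 0.3,
    sample_sd_log: float = 0.2,
    roh_het_factor: float = 0.05,
    injected_low_het: dict | None = None,
    seed: int | None = None,
) -> tuple[dict[str, ROHProfile], BinHetMatrix, dict]:
    """Generate per-sample ROH tracts and the matching bin-het matrix.

    Tract lengths are exponential with mean 100/(2·G) cM (converted at
    the given recombination rate) and placed uniformly until the target
    F_ROH is reached.  Bin heterozygosity is a shared lognormal per-bin
    baseline times per-sample lognormal noise, suppressed to
    ``roh_het_factor`` of baseline in proportion to ROH overlap.
    ``injected_low_het`` maps group -> (n_bins, effect) to depress that
    group's heterozygosity by ``effect`` (e.g. 0.8 for −80%) in randomly
    chosen bins, creating variation private to the other group.
    """
    if seed is None:
        raise ValueError("simulate_roh_and_bins requires a seed")
    rng = np.random.default_rng(seed)
    n_bins = genome_length // bin_size
    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
        }
    )
    mean_tract_bp = age_to_length_bp(tract_age_g, rec_rate_cM_per_Mb)

    sample_ids, groups = [], []
    for group, n in n_per_group.items():
        for k in range(n):
            sample_ids.append(f"{group}_{k}")
            groups.append(group)

    profiles: dict[str, ROHProfile] = {}
    overlap = np.zeros((n_bins, len(sample_ids)))
    for idx, (sample, group) in enumerate(zip(sample_ids, groups)):
        target = target_froh[group] if isinstance(target_froh, dict) else target_froh
        if not 0 <= target <= 1:
            raise ValueError(f"target F_ROH {target} outside [0, 1]")
        intervals = []
        total = 0
        while total < target * genome_length:
            length = int(rng.exponential(mean_tract_bp)) + 1
            start = int(rng.integers(0, max(genome_length - length, 1)))
            intervals.append(("chr1", start, start + length))
            total += length
        merged = (
            merge_intervals(pd.DataFrame(intervals, columns=["chrom", "start", "end"]))
            if intervals
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        profiles[sample] = ROHProfile(sample, merged, genome_length)
        for iv in merged.itertuples(index=False):
            first, last = iv.start // bin_size, min((iv.end - 1) // bin_size, n_bins - 1)
            for b in range(first, last + 1):
                lo = max(iv.start, b * bin_size)
                hi = min(iv.end, (b + 1) * bin_size)
                overlap[b, idx] += (hi - lo) / bin_size

    overlap = np.clip(overlap, 0.0, 1.0)
    bin_baseline = baseline_het * np.exp(rng.normal(0.0, bin_sd_log, size=n_bins))
    noise = np.exp(rng.normal(0.0, sample_sd_log, size=(n_bins, len(sample_ids))))
    het = bin_baseline[:, None] * noise
    het *= 1.0 - overlap * (1.0 - roh_het_factor)

    truth = {"private_bins": {}}
    if injected_low_het:
        group_arr = np.array(groups, dtype=object)
        for group, (k, effect) in injected_low_het.items():
            chosen = rng.choice(n_bins, size=k, replace=False)
            cols = np.flatnonzero(group_arr == group)
            het[np.ix_(chosen, cols)] *= 1.0 - effect
            truth["private_bins"][group] = np.sort(chosen)

    bh = BinHetMatrix(
        bins=bins,
        sample_ids=sample_ids,
        groups=np.array(groups, dtype=object),
        het=het,
        bin_size=bin_size,
    )
    return profiles, bh, truth
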