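# Methods

This note documents the models implemented in `gerode`, the defaults they
ship with, and the design decisions taken where conventions diverge. It
states no empirical result that the test suite does not itself compute.

## Data model and conventions

Genotypes are derived-allele dosages in {0, 1, 2} relative to a declared
ancestral/derived polarisation; missing is a distinct state (−1), never
dosage 0, and every aggregation skips missing genotypes explicitly. VCF
positions are 1-based; BED intervals and all internal interval arithmetic
are 0-based half-open. Filter defaults follow the consuming study design:
per-genotype depth 4–50 and genotype quality ≥ 30, site genotyping rate
≥ 40%, and a stricter depth window for load sites (5–20 modern, 5–16
historical, i.e., roughly twice the respective mean coverages) applied as
per-genotype missingness.

## Load dynamics

Sites are polarised by requiring every outgroup genotype to be homozygous
for the reference (ancestral) allele with a 100% outgroup genotyping rate;
the retained fraction is reported. Load counts per sample and impact
category count heterozygous sites once and homozygous-derived sites twice;
moderate/high counts are normalised by the sample's total low-impact count
so that differences in variant-discovery power between epochs cancel to
first order.

R_xy aggregates as a ratio of sums across sites (Σ F_m(1−F_h) over
Σ F_h(1−F_m)) rather than a mean of per-site ratios: sums keep sites fixed
in one epoch informative and avoid division by small per-site terms. The
normalised value divides by the low-impact ratio. Uncertainty comes from a
delete-d jackknife: sites (focal plus normaliser categories pooled) are
partitioned by a seeded permutation into 100 blocks of ~1% each and the
normalised R_xy is recomputed leaving each block out. Two summaries are
reported: the raw replicate variance (the conventional error bar for this
statistic) and a delete-d jackknife variance estimate scaled by
(n−d)/(d·m), from which a normal-approximation CI is built. The raw
replicate spread is ~d/n of the full sampling variance and would be
misleading as a CI; the scaled estimate has approximately nominal coverage
(checked by simulation in the test suite). The binomial test on Δfrequency
is implemented as a two-sided sign test on the nonzero per-site changes
against 0.5 — the construction is a declared choice, since only "a binomial
test" is conventionally specified for this statistic.

Homozygous load inside/outside ROH divides each sample's homozygous
derived-allele counts (alleles, i.e., sites × 2) by F_ROH and 1 − F_ROH
respectively; a sample with F_ROH of exactly 0 or 1 reports the undefined
side as NaN.

## CADD-rank load decomposition

The PHRED relation score = −10·log10(n_i/N) is inverted exactly;
N defaults to 3,073,805,640 potential mutations (all chicken chromosomes).
The selection proxy is s = 1/n_i, used as-is — it is a rank transform, not
an estimate of the distribution of fitness effects, and comparisons between
individuals should be read with that caveat. Dominance is assigned by
score bin under a negative s–h relationship; the published rule leaves the
boundaries 10, 20, 30 unassigned, so bins are taken left-closed:
[0,10) → 0.3, [10,20) → 0.15, [20,30) → 0.02, [30,∞) → 0, which keeps h
monotone in s. Site eligibility for the decomposition requires a score, a
complete genotype column, and a non-fixed site, with a report of the
counts. Loads are sums over sites (the formulas are written as sums);
GL = RL + ML is an algebraic identity and is asserted, not assumed.

## Cross prediction

Offspring genotype distributions are exact Mendelian transmissions (the
derived allele is transmitted with probability dosage/2 from each parent,
independently). Hypothetical crosses report expectations over segregation
rather than sampled offspring — expectation is the reproducible summary —
with a seeded sampling mode available for distribution plots. Sites missing
in either parent are dropped pairwise and counted. Cross ranking minimises
expected realised load; that objective is a declared default (a weighted
objective could be substituted). Reduction summaries compare best and worst
crosses within and between classes and the best cross against the mean of
the top-k pairs chosen by pedigree kinship alone.

## ROH analysis

F_ROH is the merged-interval fraction of the assayed genome. Tract age uses
G = 100/(2·cM) with cM = Mb × r at r = 3.42 cM/Mb by default; generation
bins default to (0,2], (2,4], (4,8], (8,16], (16,∞) — powers of two
matching the conventional labelling — and are configurable because the
binning is a presentation choice. Tracts older than the last bin fall into
it with a warning, so per-class F_ROH always sums to the total.

## Per-bin private-variation test

Binned heterozygosity is log2-transformed with a pseudocount of half the
smallest positive value (the test input transform is a declared choice;
the flag and pseudocount are recorded in the output metadata). Terminal
bins shorter than 50% of the nominal size are excluded. Per-bin pooled
two-group variances s_g² with d_g degrees of freedom are shrunk toward a
prior: conditional on the true bin variance, d_g·s_g²/σ² is χ²(d_g), and
σ² carries a scaled inverse-χ²(d0, s0²) prior whose parameters are fitted
by matching the mean and variance of log s_g² to the implied log-F
predictive distribution (trigamma inversion by Newton iteration). The
moderated statistic is t = Δmean / (s̃·√(1/n1+1/n2)) with
s̃² = (d0·s0² + d_g·s_g²)/(d0+d_g) and d0+d_g degrees of freedom; when the
log-variance spread does not exceed χ² noise, d0 is reported infinite, the
prior variance is the plain average, and the statistic becomes a pooled
z-test. The implementation is cross-checked in the test suite against R
limma's `lmFit`/`eBayes` on an identical matrix.

Significance uses raw p < α (α = 0.05) with no multiple-testing
correction, matching the statistic's established usage for this screen; a
Benjamini–Hochberg helper is provided but off by default. A significant
bin is called private to the group with the *higher* heterozygosity — that
group retains variation the other has lost. Reported fractions are of the
binned genome length.

## Effective sizes

Nef = 1/(2ΔF) with ΔF = (Ft − F0)/t; Ft is the individual-weighted mean
over the pooled contemporary samples (not an unweighted mean of group
means). NeV derives from F̂ = (p1−p2)²/(p̄(1−p̄)) averaged over SNPs not
fixed in the pooled sample (mean-of-ratios; a per-SNP construction is the
declared default). The expected sampling contribution to F̂ is
1/(2S0) + 1/(2St) for diploid sample sizes S0, St; writing it as "1/S with
S the harmonic mean of chromosome counts" halves it and biases NeV low, so
the full correction is used. Two sampling designs are supported following
the temporal method's derivations: plan II (samples independent of the
breeding population), NeV = t/(2(F̂−corr)); and plan I (individuals drawn
without replacement from the census itself, the design of the simulators
here and of typical managed-population studies), where the hypergeometric
reduction of sampling variance contributes ≈ −1/N and, under N ≈ Ne,
the inversion resolves to NeV = (t−2)/(2(F̂−corr)). Plan I is the default;
its calibration at N = 100, t = 4, samples of 16 and 37, and 5,000
unlinked SNPs is part of the acceptance tests. The
heterozygosity-loss-equivalent Ne inverts H_t/H_0 = (1 − 1/2Ne)^t exactly.

## Pedigree kinship

Kinship uses the standard tabular recursion in topological order:
φ(i,i) = ½(1 + φ(sire_i, dam_i)) and φ(i,j) = ½(φ(sire_i,j) + φ(dam_i,j)),
with an unknown parent contributing zero (treated as a unique founder).
Founders are assumed unrelated and non-inbred. F_i = φ(sire_i, dam_i).
Relatedness classes follow the conventional bands (0 unrelated; up to
0.0625 third degree or higher; to 0.1875 second; to 0.375 first), with
boundary values assigned to the more-related class; coefficients above
0.375 are labelled self-or-duplicate. The recursion is validated against a
Monte-Carlo gene-dropping oracle in the tests.

## Synthetic-data generators

The Wright–Fisher engine evolves each site independently (free
recombination, linkage equilibrium): selection acts on realised genotype
counts with fitnesses 1, 1−hs, 1−s; recurrent ancestral→derived mutation
(no back-mutation) perturbs the post-selection gamete frequency; and the
next generation forms by random union of gametes, so individual dosages
are Binomial(2, q′) and the neutral heterozygosity decay is exactly
(1 − 1/(2N)) per generation (selfing is allowed, the idealised monoecious
model). Site independence is a deliberate choice: the statistics this
package implements do not use intra-chromosomal LD, and the temporal-Ne
theory and the closed-form oracles in the tests are derived under
independent loci. Pedigree-mediated cross-site drift correlation present
in real data is therefore absent; calibration results quantify estimator
behaviour under the model's own assumptions, not under linked inheritance.

The default emulation profile mirrors the two-epoch study design: a
decline through a bottleneck of 20 diploids with recovery
((0,150), (3,150), (5,20), (7,20), (9,80), (12,150) breakpoints, linear
interpolation), a historical sample of 16 at the pre-bottleneck
generation and 37 modern samples (6 founders-wildborn, 6 early-captive,
6 late-captive, 19 wild) nine generations later. Per-category site counts
default to 2000 LOW (s = 0), 1000 MODERATE (s ~ U(0.005, 0.05)) and 500
HIGH (s ~ U(0.2, 0.8)); no quantitative s distributions are published for
this system, so these are declared parameters spanning nearly-neutral to
strongly deleterious. Dominance follows h(s) = 0.5/(1 + 50s) — a declining
relationship making strongly deleterious mutations nearly recessive —
unless a category overrides it. Initial frequencies follow a 1/q neutral
spectrum, truncated at 0.2 for deleterious categories (such variants are
rare at equilibrium).

The pedigree simulator breeds a founder cohort for a set number of
generations; by default every individual breeds once (equalised
contributions, as managed programmes aim for), and `n_breeding_pairs`
restricts breeding so the policy also selects who breeds. The
`min-kinship` policy selects breeders sequentially, each minimising mean
kinship to the already-selected set (which spreads picks across lineages;
selecting by population mean kinship alone collapses onto the single
least-related family), then pairs each with its least-related available
partner, falling back with a warning when every option exceeds the kinship
cap (0.125 default). Genotypes are gene-dropped from founder haplotypes
and realised IBD (autozygosity of founder-haplotype labels) is recorded.

The ROH/bin generator draws tract lengths exponentially with mean
100/(2G) cM for a target age G, places them uniformly until a target F_ROH
is reached (realised F_ROH overshoots by ~half a tract, negligible at
genome scale), and builds bin heterozygosity as a shared lognormal per-bin
baseline (0.0008 het/bp, σ_log = 0.3 across bins) times per-sample
lognormal noise (σ_log = 0.2), suppressed to 5% of baseline in proportion
to ROH overlap. Injected private-variation regions depress one group's
heterozygosity by a stated factor in randomly chosen bins, with the truth
returned for power analyses.

## Problem sizes used in the tests

Calibration experiments are sized to be decisive yet quick: 1,000 bins for
the moderated-test type-I/power checks (with 10,000-bin KS uniformity),
10,000 simulated variances for prior recovery, 25 replicates of 5,000 SNPs
for temporal-Ne recovery, 4 × 5,000 independent sites over 200 generations
for the neutral-decay identity, and 7 replicates of the default
bottleneck profile for the purging regime. Tolerances are set at roughly
four standard errors of the corresponding Monte-Carlo estimate.

## Known limitations

The s = 1/n_i proxy compresses the unknown distribution of fitness
effects; load components are comparable within an analysis, not across
score sets. The WF engine omits linkage, population structure and
overlapping generations. The ROH generator produces tracts with
independent placement, not a coalescent tract-length process, so age
stratification tests recover the construction, not a demographic
inference. Pedigree kinship inherits the founder-unrelatedness assumption
of all studbook analyses; cryptic founder relatedness biases it downward.
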