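# Methods

`umscan` analyzes Illumina Infinium methylation microarrays at the level of
raw two-channel fluorescence, where genetic artifacts are visible before any
normalization hides them. This note documents the statistical model behind
each component, the tunable parameters with their defaults, what the
synthetic cohort generator does and does not emulate, and the numerical
choices a maintainer would want written down.

## The U/M plane

Every probe yields, per sample, an unmethylated (U) and a methylated (M)
fluorescence mean plus the across-bead standard deviations of each channel
(σ̂_U, σ̂_M), as stored in the scanner's raw files. Type II probes read both
epialleles from one bead address (green = M, red = U); type I probes use two
addresses (A = unmethylated design, B = methylated design) in a single
design-time channel, and their single-base extension (SBE) happens one base
past the CpG on the extension side. Plotting U against M instead of the
methylation ratio β = M/(M+U+100) separates states the ratio conflates:
probe failure (background-only signal, points clumped at the origin) is
indistinguishable from intermediate methylation on the β scale but obvious
in the plane. Between-array variation in total brightness stretches fully
methylated and unmethylated samples into vertical and horizontal lines and
intermediate samples into diagonals.

Derived scales use the conventional offsets: β = M/(M+U+100) (strictly
below 1, no division by zero) and M-value = log2((M+1)/(U+1)) (unbounded,
preferred for correlations). Quantile normalization of the M-value matrix
uses the mean-of-order-statistics reference with average-tie handling;
missing entries are excluded from ranking and the reference is built from
complete rows. QN is applied before any correlation-based statistic because
co-twins are typically processed on the same chip and raw batch structure
otherwise manufactures twin correlation.

## Noise statistics: R̂, CV_logT, BC, cor_MZ

The per-entry noise-to-signal ratio is

    R̂ = (σ̂_M + σ̂_U + 100) / (Û + M̂ + 100)

and the coefficient of variation of the log total signal is

    CV_logT = 1 / ( ln(μ_T)/R̂ − R̂/2 ),   μ_T = U + M + 100.

Natural log is used throughout: the identity CV_logT ≈ σ_lnT/μ_lnT holds
only in base e (for a lognormal total with coefficient of variation R the
two agree to O(R³); the test suite verifies < 5% relative error for
R ∈ {0.05, 0.1, 0.2}). μ_T reuses the +100 offset of R̂'s denominator.
Entries with a non-positive denominator (unphysically large R̂) are set to
missing and counted in the log.

Failure ambivalence is summarized per probe by the bimodality coefficient
of CV_logT across samples,

    BC = (g1² + 1) / ( g2 + 3(n−1)²/((n−2)(n−3)) ),

with g1 = m3/m2^1.5 and g2 = m4/m2² − 3 computed from biased central
moments (the finite-sample correction term fixes the convention; the suite
checks BC against an independent raw-moment implementation to 1e-12, and
that 1e5 uniform draws give 5/9 ± 0.02). BC needs n ≥ 4 and a non-constant
vector; otherwise it is missing. The genetic control is the Pearson
correlation of CV_logT between monozygotic co-twins across pairs
(cor_MZ); within-pair ordering is fixed by lexicographic sample-id sort so
the statistic is reproducible. A probe is flagged as genetics-related,
ambivalent failure when **both** BC > 5/9 (the uniform distribution's
expected BC) and cor_MZ > 0.8 (a deliberately conservative control), with
strict inequalities; missing inputs never flag.

## Cluster calling

**Known K (bGMM).** A bivariate Gaussian mixture with full covariances is
fitted by EM, best of 10 restarts by log-likelihood, each restart seeded by
k-means++. Numerical choices: a ridge of 1e-6·trace(Σ) (plus an absolute
1e-10) is added to every covariance update; convergence at relative
log-likelihood change < 1e-8 or 500 iterations; a component whose
responsibility mass vanishes aborts the restart, and if every restart
degenerates the fit raises. The EM monotonicity guarantee is asserted at
every iteration with slack 100·ridge in relative terms — the ridge makes
the M-step inexact by exactly that order, so a larger decrease indicates a
bug. Components are relabeled by ascending centroid beta
(M_c/(M_c+U_c+100)), giving a reproducible unmethylated→methylated
genotype axis; hard assignments are maximum-posterior. Assignments are
invariant to a joint positive rescaling of both channels.

**Unknown K (dbscan K-caller).** Points are first divided by the 99th
percentile of U+M across samples and clipped to [0, 1.5], making eps
dimensionless, robust to bright outliers, and the call invariant to joint
rescaling and sample permutation; dbscan then runs with the calibrated
defaults min_pts = 12, eps = 0.035, and the call is the number of non-noise
clusters (0 is possible). Noise points are excluded from the count and
from downstream genotype counting. The exact preprocessing used upstream
of published calibrations is not public; the p99/clip rule is this
package's choice and the calibration harness can re-derive (eps, min_pts)
on any labeled training suite: the task is scored as multi-class
classification over K = 1..3 (calls and truths above 3 binned to 3, calls
of 0 counted as errors) by macro F1, ties broken toward smaller eps then
larger min_pts. On the synthetic 943-cloud suite (516/205/212/10 clouds of
K = 1..4 at 852 samples) the default grid point attains macro-F1 = 1.0.

**Benchmark scores.** Twin assignment agreement is the mean over probes of
ρ² between co-twin cluster labels (ordered labels; probes with constant,
fully concordant labels contribute 1, other undefined cases are excluded
with a log entry); K accuracy is the fraction of exact K matches.

## Genetic interpretation

**MAF from cluster counts.** With clusters mapped to genotypes AA/AB/BB,
only twin pairs assigned concordantly are counted, one genotype per pair,
and MAF = (2·n_BB + n_AB)/(2·(n_AA+n_AB+n_BB)). A frequency above 0.5 is
mirrored and flagged rather than silently accepted, because the
cluster-genotype map may be written with either allele as reference.

**Haplotype frequencies.** For a CpG flanked by two SNPs the ten unordered
diplotypes of four haplotypes map onto U/M clusters; cluster probabilities
are the Hardy-Weinberg sums Σ(2−δ_ij)p_i p_j and the multinomial
log-likelihood of the observed counts is maximized over the 4-simplex via
a softmax reparameterization with 10 Nelder-Mead starts. A multinomial
likelihood was chosen over least squares as the statistically sharper
objective for count data; the suite verifies the optimizer meets or beats
a 0.01-step grid search over the simplex within 1e-3 log-likelihood.
Haplotypes appearing only in empty clusters are reported non-identifiable
with their mass spread flat, with a warning.

**Mechanistic CpG/SBE-SNP classifier.** The category of a variant at the
CpG C, the CpG G, or the type I SBE site is a pure function of
(infinium type, strand, site, ref, alt), derived by simulating bisulfite
conversion of both alleles on the targeted strand. Coordinates are 1-based
plus-strand; for minus-strand probes the alleles are reverse-complemented
onto the targeted strand and the C/G site roles swap (the CpG is
palindromic). Site geometry: the type II probe's 3'-terminal base pairs the
CpG G and extension reads the C itself; type I probes terminate on the C
and extend at the adjacent base (plus-strand coordinate cpg−1, or cpg+2
for minus-strand probes). The resulting rules:

| type | site | allele change (targeted strand) | category |
|------|------|--------------------------------|----------|
| I | CpG C | C→T | SNP_EQ_U (alt is identical to the converted unmethylated template) |
| I | CpG C | C→G | SNP_EQ_M (alt pairs the methylated-design probe's terminal C) |
| I | CpG C | C→A | SNP_EQ_PF (terminal mismatch on both designs) |
| I | CpG G | any | SNP_EQ_U, flagged `near_3prime_mismatch` (CpG destroyed ⇒ reads unmethylated; one mismatch at the penultimate probe base) |
| I | SBE | exactly one allele is G post-conversion | CHANNEL_SWITCH (template G reads green, A/T/C-converted read red) |
| I | SBE | otherwise | NO_CHANNEL_CHANGE (C↔T additionally flagged `bisulfite_indistinguishable`) |
| II | CpG C | C→T, C→A | SNP_EQ_U (extension incorporates a red-labelled base) |
| II | CpG C | C→G | SNP_EQ_M (green-labelled) |
| II | CpG G | any | SNP_EQ_PF (3'-terminal mismatch) |

Counting strand-resolved rows this enumeration yields 18 category rows
(type I: 3+1+2 per strand; type II: 2+1 per strand), against the 16 of the
published strand-resolved classification whose exact table is only
available as a figure; the most likely difference is a merge of the two
type II unmethylated-mimicking allele changes, which this engine also
treats as one category. The full 84-entry (type, strand, site, ref, alt)
enumeration is frozen in the test suite as a regression oracle. The type I
CpG-G rule is the one genuinely under-determined case: the mismatch sits
one base in from the 3' terminus, which impairs but does not abolish
hybridization of the 50-mer, so epiallele mimicry (U) with a flag was
chosen over failure; the flag preserves the information for downstream
filtering.

Expected cluster counts attach per category: mimicking categories
(SNP_EQ_U/M) are context-dependent — 1 cluster in a region whose
methylation state matches the mimicked epiallele, 3 otherwise; failure is
2 (the half-intensity heterozygotes merge with full-intensity homozygotes
along the brightness axis in realistically spread cohorts); channel switch
3; no-change and unaffected 1. One documented override: on type I probes
with ≥ 1 internal CpG, an unmethylated-mimicking variant inside a
methylated region converts to probe failure with expected K = 2, because
the alt chromosome presents a mixed template (converted at the target,
protected at the internal CpGs) that neither probe design can bind.

**Probe-body SNPs.** Outside the CpG/SBE sites only failure is possible:
risk is confined to ≤ 15 bases from the 3' end, and C/T alleles on
plus-strand probes (G/A on minus-strand probes) are bisulfite-masked —
outside CpG context both alleles read T after conversion — and therefore
harmless at any distance.

**Indels** are resolved only as failure candidates when a deletion removes
the CpG; all other indels return `UNRESOLVED_INDEL` rather than a guessed
category. Triallelic sites are classified per alt allele; alleles the assay
cannot distinguish post-bisulfite are flagged as collapsed.

## meQTL vs artifact: co-methylation

A variant mimicking an epiallele and a strong meQTL both produce trimodal,
highly twin-correlated methylation at their own probe. The discriminating
evidence is regional: genuine cis effects drive neighboring CpGs
(co-methylation, operative to roughly 1 kb), artifacts do not. For a target
probe, neighbors are probes on the same chromosome within ±1 kb
(target-centered window; a block-centered mode generalizes it); r² is the
squared Pearson correlation of QN M-values over pairwise-complete
observations, with neighbors under 30 complete pairs skipped. The verdict
is MEQTL_LIKE when the mean neighbor r² reaches 0.25 (|r| ≥ 0.5),
ARTIFACT_LIKE below that with at least one neighbor, INDETERMINATE with
none. The 0.25 threshold is this package's default — no published cutoff
exists — and is exposed as a parameter. Two caveats are built into the
tests: probes without neighbors in range are undecidable, and in regions
where nearby probes are themselves artifacts in linkage disequilibrium
(e.g. HLA), artifact-artifact co-methylation defeats the evidence — the
simulator's LD mode reproduces this degradation as a negative control.

meQTL allele frequency can also be read from methylation levels directly:
samples are clustered by average-linkage hierarchical clustering on
Euclidean distances over the probe block, the tree is cut at k = 3, groups
are ordered by mean beta and treated as genotype doses of the methylated
epiallele. Average linkage is a documented choice (ecosystem defaults for
agglomerative clustering differ). Candidate cis variants in the window are
then ranked by Euclidean distance between measured and reported
per-population MAF vectors; candidates missing a population are excluded
with a warning.

## The synthetic cohort generator

The generator is the package's study-condition bench: every statistic is
validated against cohorts with known truth. It emulates, per probe
pattern, the cluster geometries described above: constant and intermediate
methylation, 3-cluster SNPs (plain, epiallele-mimicking, channel-switch,
triallelic with collapsed alleles), genotype-dependent failure,
two-SNP/four-cluster haplotype systems, Y-probe "exclamation marks",
X-inactivation V-shapes, X-hypermethylation with halved male intensity,
and co-methylated meQTL blocks. Twins share every genotype draw; genotypes
follow Hardy-Weinberg proportions (chi-square checked in the suite).

Signal model, per sample: cluster center (pattern and genotype) → + a
background offset → × a lognormal per-array factor (log-sd 0.08) → × a
bounded log-uniform per-probe brightness jitter (log-sd 0.13, shared by
both channels, emulating DNA input/amplification variation that blurs
points along rays from the origin) → + Gaussian read noise, truncated at
zero. The across-bead SD emitted for each channel scales like shot noise,
σ = noise_sd·sqrt(mean/scale) with a background floor, and is jittered as a
chi-distributed estimate from a 14-bead pool; the read noise of the
reported mean is σ/sqrt(14), **not** σ — conflating the stored bead SD
with the mean's sampling noise is a subtle error that both fragments
density clusters and dilutes the twin correlation of CV_logT, and the
distinction is deliberate and load-bearing.

Defaults (chosen once, in a single design pass, so that each pattern's
K-call matches its designed K in ≥ 90% of replicates at 852 samples and
the failure-flag control holds): intensity scale 4000, bead-SD scale 300,
background (250, 60), pattern MAF 0.5 (the high-MAF regime in which
cluster counting is well-posed, matching the control-SNP probes used for
benchmarking; frequency-estimation checks explicitly pass 0.3), two-SNP
haplotype frequencies (0.6, 0.13, 0.27, 0) — adjacent cis SNPs, so the
double-mutant haplotype is absent, and the half-intensity diplotypes
ray-merge into the axis clusters leaving four visible clusters.

What the generator does **not** emulate, hence what green tests do not
show about real data: dye-specific bias between channels, spatial chip
artifacts, cross-reactive hybridization, cell-type heterogeneity,
out-of-band signal of type I probes, non-Gaussian heavy-tailed outliers,
and population structure beyond a single HWE pool. Conclusions about
detection rates transfer to real cohorts only to the extent that genotype
clusters are as separated and arrays as well behaved as simulated.

## Scan orchestration

The epigenome-wide scan computes CV_logT, BC, cor_MZ (when twin pairing is
available — its absence is a warning, not an error), the K-call, and the
ambivalent-failure flag for every probe, merging variant classifications
and co-methylation verdicts when inputs are provided. The report keeps
exactly one row per input probe (probes a step cannot handle carry a note
instead of disappearing) and a metadata block with all thresholds, the
seed, and the package version, sufficient to replay the run. A single seed
governs every stochastic step.

## Problem sizes

The test suite and the acceptance script run entirely on simulated
cohorts at the scale the statistics were designed for: 852 samples
(426 twin pairs) for cluster counting and benchmarking, 400 pairs for
frequency recovery and noise controls, 200 replicate probes per modal-K
estimate, 943 clouds for calibration, 100 meQTL/artifact regions for the
discriminator, and a 0.01-step simplex grid (176,851 points) as the
haplotype brute-force oracle.

## Known limitations

- The co-methylation verdict inherits both assumptions discussed above:
  neighbor availability and neighbor integrity under LD.
- The type I CpG-G category and the expected-K attachments for rare
  categories rest on hybridization-energy reasoning, not on a fitted
  thermodynamic model.
- Indel classification is deliberately coarse (failure candidate vs
  unresolved).
- IDAT ingestion is out of scope; the package's ingestion boundary is the
  four plain-text intensity matrices plus manifest and cohort tables.
- Quantile normalization presumes a genome-scale probe set; on toy
  matrices of a handful of probes it rank-couples rows (visible in one
  example script, where twin correlations are therefore computed on raw
  M-values).
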