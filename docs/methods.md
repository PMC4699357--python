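# Methods

## The synthetic twin methylome

The generator (`popmeth.simulate`) emulates a two-tissue (adipose, blood)
WGBS study of MZ/DZ twins and singletons. Defaults mirror a realistic
design: 7 MZ pairs + 6 DZ pairs + 8 singletons per tissue, mean coverage 4
reads per site per strand, bimodal baseline methylation (logit means −3 and
+3, weights 0.3/0.7 — most of the genome highly methylated, a low-methylated
minority), and a 0.6 % bisulfite conversion-failure rate.

**Liability model.** Site *s*, individual *j* has latent liability
`baseline_s + A + C + E` with component SDs `liability_sd·√a2`, `·√c2`,
`·√e2`. A is one draw shared by MZ co-twins and correlated 0.5 in DZ
co-twins (half-shared construction — additive model only); C is shared
within a pair; E is drawn independently per individual *and per tissue*
(non-shared environment is tissue-specific), while A and C are shared
across tissues. The methylation level is the logistic transform of the
liability. On the liability scale the twin covariance structure is exact:
ICC_MZ = a²+c², ICC_DZ = a²/2+c². The logistic link keeps levels in [0,1]
but attenuates correlations on the level scale; with the default bimodal
baseline the h² bias on levels reaches ≈ 0.1 at a² = 0.9, which is why the
variance-decomposition recovery experiments operate on the latent values
(the package decomposes whatever levels it is given; the attenuation is a
property of any bounded transform of a liability, not of the estimator).

**Per-site ACE mixture.** The per-site (a², c², e²) distribution is a
three-archetype mixture — 60 % environment-dominated (0.05, 0.05, 0.90),
35 % heritable (0.60, 0.05, 0.35), 5 % shared-environment
(0.10, 0.50, 0.40) — chosen to echo a population methylome in which
non-shared environment dominates, a substantial minority of variable sites
is heritable, and family environment is a minor contributor. It is fully
configurable (`ace_archetypes`, or an explicit per-site array).

**Planted truth classes** (disjoint; everything else is "background"):

| class | default fraction | emulates |
|---|---|---|
| `snp` | 1 % | variants ablating a cytosine; apparent methylation is genotype-coded (dosage/2 × latent level, alleles drawn with MZ-identical, DZ-transmitted genotypes, MAF ~ U(0.1, 0.5)) |
| `artifact` | 0.5 % | alignment artifact loci; per-strand coverage ~ Poisson(12 × mean), far past mean + 5 SD |
| `celltype` | 1 % | blood composition-driven CpGs: level 0.95 in one driving cell type vs 0.05 elsewhere, mixed through per-sample Dirichlet cell fractions (mean 0.60/0.30/0.07/0.03, concentration 20 — realistic inter-individual spread); the driving type is drawn 0.45/0.45/0.05/0.05, reflecting that the granulocyte–lymphocyte balance carries most blood heterogeneity |
| `invariant_zero` / `invariant_one` | 8 % / 12 % | truly static CpGs at exactly 0 %/100 % — CGI-core promoters and deep gene bodies; without them a simulated methylome has essentially no invariable sites, unlike real data |

Per-pair environmental DMRs are planted as a logit shift (+/−3) in one
co-twin of the first MZ pair over a run of consecutive background CpGs.
CpH sites are truly unmethylated except a small planted fraction (0.4 %)
laid out in clusters within ±250 bp of highly methylated CpGs, emulating
the CpG-proximal, clustered character of somatic non-CpG methylation.
Coverage is Poisson per strand by default; a negative-binomial option
(`negative_binomial_dispersion`) exists for overdispersion robustness
checks. A methylated C always reads methylated; an unmethylated C reads
methylated with the conversion-failure probability.

**What the generator does not emulate:** read-level artifacts (mapping,
clonal reads), linkage between neighboring CpGs beyond planted regions,
age effects, and realistic genome annotation geometry (CGIs and genes in
the enrichment script are independent synthetic tracks — enrichment against
them is a null check, and the planted-signal tests instead validate the
machinery). Passing tests therefore demonstrate correctness of the
algorithms and their truth-recovery behavior under the stated noise model,
not performance on real methylomes.

## Numerical and design choices

**Fisher's exact test** is computed as the sum of hypergeometric
probabilities ≤ the observed table's (relative tie gate 1+1e-7), via
`scipy.stats.hypergeom` over the table's support, memoized because
population scans re-test the same low-count tables millions of times. A
unit test cross-checks against `scipy.stats.fisher_exact` and an exhaustive
enumeration oracle; when the inclusion set covers the whole support the
p-value is returned as exactly 1.

**Strand filter boundary.** The ≤ 20-point strand difference is inclusive;
the comparison carries a 1e-9 epsilon so that count ratios that are exactly
20 points apart in rational arithmetic are kept despite float noise.

**Study blacklist** statistics (mean + 1.5 SD per sample) are computed on
pre-filter pooled CpG-unit coverage, so artifact loci are visible before
other rules remove them. Per-CpG-unit pooled coverage is used; a per-strand
variant would flag the same simulated loci.

**Segmentation** replaces FDR-calibrated cutoff machinery with explicit
minimum-run sizes: runs of ≥ 30 consecutive low CpGs are UMRs, runs of
4–29 are LMRs. The defaults reproduce the characteristic size contrast
(UMRs ~120 CpGs near 0 %, LMRs ~11 CpGs at 5–45 %) on planted regions and
are configurable. PMD detection is intentionally absent.

**pDMR scoring.** The combination of variability and consistency is not
uniquely determined by a verbal description of "weighting"; the default is
`mean_sd × max(consistency, 0)` — multiplicative weighting with hard
exclusion of anti-consistent windows — with an `sd_thresholded` alternative
(`score = mean_sd if consistency > 0 else 0`) selectable per call. Windows
are anchored at retained CpGs (a sliding window over a sparse site list is
otherwise ill-defined); a window whose CpG set is a subset of another
candidate's is discarded. Spearman ties get average ranks; an individual
with a constant profile contributes correlation 0. Because each individual
is correlated against a mean profile that includes itself, the null
consistency has a small positive bias of order 1/m (m = individuals
scoring the window); the permutation-null test bounds the mean by 1/m
rather than by Monte-Carlo error. Quantile ties are resolved
deterministically by genomic order; selection keeps ⌈q·n⌉ windows.

**ICC** is the one-way random-effects form (MSB − MSW)/(MSB + (k−1)MSW)
with k = 2, cross-checked against pingouin's ICC(1,1). h²/c²/e² are
reported raw (the identity h²+c²+e² = 1 holds exactly) together with a
clamped [0,1]-renormalized view, because threshold summaries ("fraction
with h² > 0.3") depend on the clamping convention.

**eDMR permutation FDR** keeps the observed eDMC count and direction mix
and reassigns positions uniformly over the tested site map (within
chromosome by default; a genome-wide option exists). This null preserves
site density — the key driver of chance clustering — without re-running
per-site tests. FDR = mean permuted in-region eDMC fraction / observed
fraction.

**Drift analysis** ranks sites by between-pair variance of pair means over
mean within-pair variance (levels, not counts), keeps the top 50 % in the
reference tissue, excludes eDMCs, pools counts within pair × tissue,
Fisher-tests pair 1 vs pair 2 per tissue, and applies a two-sided exact
binomial test to the direction-concordant count among sites significant in
both tissues.

**CpH calling** requires > 50 % methylation (strict) at ≥ 4 reads in ≥ 2
individuals; the highCpH-lowCpG flag uses ≥ 50 % on the nearest CpG
(boundary conventions kept deliberately as stated, though they differ at
exactly 50 %). Nearest-CpG ties break downstream. Conversion efficiency is
100 × (1 − methylated CpH reads / CpH reads) per sample, which assumes
genuine CpH methylation is negligible; the recovery experiment therefore
simulates without planted CpH methylation to isolate the estimand.

**Coordinates.** Everything internal is 0-based half-open (BED-native); the
cytosine report's 1-based positions are converted at the file boundary. A
CpG unit is addressed by its forward-strand C; single-strand-covered units
are kept by I/O (flagged) and fail the strand filter downstream.

## Problem sizes

The validation suite and the reproduction script run simulations sized for
single-core minutes: cohorts of a few hundred to 2,000 pairs × 2,000 sites
for variance-component recovery, 50,000-site maps with 1,000 permutations
for the eDMR FDR, 100-replicate planted-vs-decoy and segmentation-recovery
experiments, and exhaustive Fisher enumeration up to row margins of 30.
These sizes were chosen so that Monte-Carlo error is comfortably below the
assertion tolerances.

## Known limitations

Falconer estimators inherit twin-design assumptions (no dominance, no
gene–environment interaction, equal environments); estimates on bounded
level scales are attenuated (see above); the pDMR score combination rule is
a modeling choice among defensible alternatives and both provided rules are
deterministic but not equivalent; the permutation FDR is an expectation
ratio, not a per-region q-value; and enrichment p-values are unconditional
Fisher tests that treat sites as exchangeable, ignoring spatial
autocorrelation of methylation.
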