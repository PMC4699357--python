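# popmeth

Population-scale analysis of whole-genome bisulfite sequencing (WGBS)
methylomes with twin structure: site-level quality control, detection of
static and variable CpGs, a consistency-scored sliding-window caller for
population differentially methylated regions (pDMRs), twin-based
genetic/environmental variance decomposition, within-pair environmental DMR
(eDMR) detection with permutation FDR, inter-tissue drift testing, genomic
feature enrichment, and non-CpG (CpH) methylation characterization.

The package is aimed at epigenomics researchers working with low-pass WGBS
across many individuals — a regime where single-sample DMR callers are
underpowered and population information (variance across individuals,
consistency of regional profiles, twin relatedness) carries the signal.
Because population WGBS datasets are access-controlled, the package ships a
synthetic twin-methylome generator with known ground truth; every analysis
stage is exercised and validated against what was planted.

## The statistics at the core

**Site QC.** A CpG is kept when both strands carry ≥ 2 reads and the
absolute strand difference in methylation is ≤ 20 percentage points;
loci covered above the sample mean + 1.5 SD of coverage in ≥ 2 samples are
blacklisted cohort-wide; CpGs overlapping annotated variants at either
cytosine are removed.

**pDMCs.** For samples *i*, *j* detecting a CpG, the pooled counts form a
2×2 table tested with Fisher's exact test (two-sided); a site is a pDMC
when any pairwise comparison has p < 0.05.

**pDMRs.** With per-CpG population SDs computed over ≥ 3 detecting
individuals, 500-bp windows anchored at each retained CpG (subset windows
eliminated) are scored by

    score = mean SD × max(consistency, 0),
    consistency = (1/m) Σᵢ rᵢ

where rᵢ is the Spearman correlation between individual *i*'s profile over
the window's CpGs and the across-individual mean profile. The top decile of
windows (≥ 3 CpGs) is merged (0-bp merge) into pDMR calls. Anti-consistent
windows — high variance but incoherent profiles — are excluded by the
`max(·, 0)` truncation.

**Twin decomposition.** Per site, one-way random-effects intra-class
correlations in monozygotic (MZ) and dizygotic (DZ) pairs give
Falconer-style estimates h² = 2(ICC_MZ − ICC_DZ), c² = ICC_MZ − h²,
e² = 1 − ICC_MZ.

**eDMRs.** Within an MZ pair, per-site Fisher tests give eDMCs (non-shared
environmental differences); ≥ 3 unidirectional eDMCs within ± 500 bp form
an eDMR; significance of clustering is assessed by permuting eDMC positions
over the tested site map.

**Drift.** Sites differential between two twin pairs in one tissue are
re-tested in a second tissue; the count of direction-concordant sites
against a fair-coin null (two-sided exact binomial) measures how strongly
genetic effects constrain inter-tissue divergence.

## Worked example

```python
from popmeth import io, filtering, pdmr
from popmeth.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_cpg=3000, n_cph=2000,
                                          mean_coverage=6.0, seed=1))
units = {s: io.pair_strands(rec) for s, rec in cohort.samples.items()
         if s.endswith("adipose")}
cfg = filtering.FilterConfig()
flagged = filtering.study_blacklist(units, cfg)
filtered = {s: filtering.apply_all_filters(u, cfg, flagged)[0]
            for s, u in units.items()}
matrix = io.build_population_matrix(filtered, min_detected=3)
calls = pdmr.call_pdmr(matrix, window=500, quantile=0.10)
print(len(calls), calls["consistency"].mean().round(2))
```

prints `45 0.84`: 45 merged pDMR calls from the top decile of scored
windows, with mean within-region consistency 0.84 — regions whose CpGs vary
across individuals *coherently*, which is what separates reproducible
population variation from noise.

The numbered scripts under `analysis/` run the full narrative on the same
seeded cohort (simulation → QC → segmentation → variability → pDMR → twin
decomposition → enrichment → CpH) and write their tables under `results/`.
For example `analysis/06_twin_decomposition.py` reports

```
ACE decomposition at 1257 CpGs: 33% with h2>0.3, 21% with e2>0.9
drift: 160 CpGs significant in both tissues, 149 concordant (93%),
binomial p = 4.58e-32
```

— on a cohort simulated with a 35 % heritable site class, the decomposition
recovers a similar heritable fraction, and the inter-tissue concordance
test detects the genetic constraint planted across tissues.

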