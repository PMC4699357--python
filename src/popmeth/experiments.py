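"""Self-contained simulation experiments exercising the pipeline end to end.

Each function generates its own data with the package's synthetic cohort
generator (or a stated closed-form input), runs the relevant pipeline stage
and returns summary numbers.  They back both the validation suite and the
reproduction script, so the problem sizes are chosen to finish in minutes
on a single core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import filtering, io, pdmr, segmentation
from .cph import cohort_conversion_efficiency
from .simulate import SimulationConfig, simulate_cohort, \
    simulate_latent_methylation
from .twin import VarianceDecomposition, call_edmr, edmr_permutation_fdr, \
    exact_binomial_two_sided, icc

# printed direction-concordance counts from the inter-tissue drift analysis:
# tissue-shared DMCs (265 concordant of 378) and per-pair cross-tissue eDMC
# re-tests (555/1,098 and 640/1,228)
DRIFT_CONCORDANCE_COUNTS = {
    "tissue_shared_dmc": (265, 378),
    "edmc_mz2": (555, 1098),
    "edmc_mz3": (640, 1228),
}


def binomial_concordance_stats() -> dict:
    """Two-sided exact binomial tests of the drift concordance counts."""
    out = {}
    for name, (k, n) in DRIFT_CONCORDANCE_COUNTS.items():
        out[f"p_{name}"] = exact_binomial_two_sided(k, n, 0.5)
        out[f"fraction_{name}"] = k / n
    return out


def ace_recovery(seed: int = 0, n_pairs: int = 200, n_sites: int = 2000,
                 a2_values=(0.0, 0.3, 0.6, 0.9)) -> dict:
    """Falconer h2 recovery from simulated twin cohorts.

    For each additive-genetic fraction, a cohort of ``n_pairs`` MZ and
    ``n_pairs`` DZ pairs is simulated and per-site h2 estimated from the
    one-way ICCs of the latent (liability-scale) methylation values; the
    mean estimate over sites is compared with the generating value.
    """
    out = {"per_a2": {}}
    max_abs_bias = 0.0
    identity_ok = True
    for j, a2 in enumerate(a2_values):
        cfg = SimulationConfig(n_mz_pairs=n_pairs, n_dz_pairs=n_pairs,
                               n_singletons=0, seed=seed + 17 * j + 1)
        lat = simulate_latent_methylation(
            cfg, ace=np.array([a2, 0.0, 1.0 - a2]), n_sites=n_sites,
            tissues=("adipose",))
        liab = lat["liability_adipose"]
        cols: dict[str, list[int]] = {}
        for c, ind in enumerate(lat["individuals"]):
            cols.setdefault(ind.pair_id, []).append(c)
        mz = np.array([v for p, v in cols.items() if p.startswith("MZ")])
        dz = np.array([v for p, v in cols.items() if p.startswith("DZ")])
        h2s = np.empty(n_sites)
        for s in range(n_sites):
            d = VarianceDecomposition(icc(liab[s][mz]), icc(liab[s][dz]),
                                      n_pairs, n_pairs)
            h2s[s] = d.h2
            identity_ok &= abs(d.h2 + d.c2 + d.e2 - 1.0) < 1e-12
        bias = float(np.mean(h2s) - a2)
        out["per_a2"][a2] = {"mean_h2": float(np.mean(h2s)), "bias": bias}
        max_abs_bias = max(max_abs_bias, abs(bias))
    out["max_abs_bias"] = max_abs_bias
    out["identity_exact"] = bool(identity_ok)
    return out


def pdmr_rank_success(seed: int = 0, n_replicates: int = 100,
                      n_individuals: int = 10) -> float:
    """Fraction of replicates where a planted variable-and-consistent window
    outscores an equal-SD but per-CpG-shuffled (inconsistent) decoy."""
    wins = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 100_003 + rep)
        offsets = np.linspace(-0.3, 0.3, n_individuals)
        prof = rng.uniform(0.4, 0.6, 5)
        planted = prof[:, None] + offsets[None, :]
        decoy = planted.copy()
        for i in range(decoy.shape[0]):
            rng.shuffle(decoy[i])
        lv = np.clip(np.vstack([planted, decoy]), 0, 1)
        pos = np.concatenate([100 + np.arange(5) * 50,
                              10_000 + np.arange(5) * 50])
        det = np.ones_like(lv, bool)
        sites = pd.DataFrame({"chrom": "chr1", "pos": pos})
        m = io.PopulationMatrix(sites, [f"s{j}" for j in range(n_individuals)],
                                lv, np.full(lv.shape, 10.0), det)
        sub, sd = pdmr.per_cpg_sd(m)
        scored = pdmr.score_windows(pdmr.scan_windows(sub), sub, sd)
        by_start = {w.start: w.score for w in scored}
        if by_start.get(100, -np.inf) > by_start.get(10_000, -np.inf):
            wins += 1
    return wins / n_replicates


def _clustered_site_map(rng, n_sites: int, spacing: float = 250.0
                        ) -> np.ndarray:
    gaps = rng.exponential(spacing, size=n_sites).astype(int) + 2
    return np.cumsum(gaps)


def edmr_fdr_experiment(seed: int = 0, n_sites: int = 50_000,
                        n_perm: int = 1000) -> dict:
    """Permutation FDR for planted vs null eDMC clustering.

    Planted case: 100 scattered eDMCs plus eight clusters of five adjacent
    same-direction eDMCs on a 50k-site map; null case: 2,500 uniformly
    scattered eDMCs with random directions on the same kind of map.
    """
    rng = np.random.default_rng(seed)
    pos = _clustered_site_map(rng, n_sites)
    sites = pd.DataFrame({"chrom": "chr1", "pos": pos})

    scatter = rng.choice(pos, 100, replace=False)
    cluster_pos = []
    for k in range(8):
        start = rng.integers(0, n_sites - 6)
        cluster_pos.append(pos[start:start + 5])
    planted = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.concatenate([scatter] + cluster_pos),
        "direction": "a_higher", "edmc": True})
    planted_out = edmr_permutation_fdr(planted, sites, n_perm=n_perm,
                                       seed=seed + 1)

    null_pos = rng.choice(pos, 2500, replace=False)
    null = pd.DataFrame({
        "chrom": "chr1", "pos": null_pos,
        "direction": rng.choice(["a_higher", "b_higher"], 2500),
        "edmc": True})
    null_out = edmr_permutation_fdr(null, sites, n_perm=n_perm,
                                    seed=seed + 2)
    return {"planted_fdr": planted_out["fdr"],
            "planted_n_edmr": planted_out["n_edmr"],
            "null_fdr": null_out["fdr"]}


def filter_recovery(seed: int = 0) -> dict:
    """Recall of planted artifact loci and SNP-ablated CpGs by the QC
    filters on a simulated cohort."""
    cfg = SimulationConfig(n_cpg=2000, n_cph=100, n_mz_pairs=4, n_dz_pairs=3,
                           n_singletons=3, mean_coverage=6.0,
                           snp_fraction=0.02, blacklist_fraction=0.01,
                           seed=seed + 5)
    cohort = simulate_cohort(cfg)
    units = {r["sample"]: io.pair_strands(cohort.samples[r["sample"]])
             for _, r in cohort.metadata.iterrows()
             if r["tissue"] == "adipose"}
    fc = filtering.FilterConfig()
    flagged = filtering.study_blacklist(units, fc)
    artifact_truth = set(cohort.truth.artifact_loci["pos"])
    artifact_recall = (len(artifact_truth & set(flagged["start"]))
                       / len(artifact_truth))

    snps = cohort.truth.snp_sites
    snp_bed = pd.DataFrame({"chrom": snps["chrom"], "start": snps["pos"],
                            "end": snps["pos"] + 1, "name": "."})
    fc2 = filtering.FilterConfig(snp_positions=snp_bed)
    snp_truth = set(snps["pos"])
    remaining = set()
    for sid, u in units.items():
        out, _ = filtering.apply_all_filters(u, fc2,
                                             study_blacklist_intervals=flagged)
        remaining |= snp_truth & set(out["pos"])
    snp_recall = 1.0 - len(remaining) / len(snp_truth)
    return {"artifact_recall": artifact_recall, "snp_recall": snp_recall,
            "cohort": cohort, "units": units}


def conversion_recovery(seed: int = 0) -> dict:
    """Median bisulfite conversion efficiency on a simulated cohort with
    0.6 % conversion failure."""
    # genuine CpH methylation switched off: the estimator attributes all
    # apparently methylated CpH reads to conversion failure
    cfg = SimulationConfig(n_cpg=500, n_cph=5000, n_mz_pairs=4, n_dz_pairs=3,
                           n_singletons=3, mean_coverage=6.0,
                           conversion_failure_rate=0.006,
                           cph_methylated_fraction=0.0, seed=seed + 9)
    cohort = simulate_cohort(cfg)
    adipose = {sid: rec for sid, rec in cohort.samples.items()
               if sid.endswith("adipose")}
    conv = cohort_conversion_efficiency(adipose)
    return {"median_efficiency": conv["median"],
            "expected": 100 * (1 - cfg.conversion_failure_rate)}


def segmentation_recovery(seed: int = 0, n_replicates: int = 100,
                          pooled_coverage: int = 200) -> dict:
    """Recovery rate of planted UMR/LMR segments under count noise.

    Each replicate plants a 120-CpG near-zero region and an 11-CpG region
    at 5-45 % methylation inside a highly methylated background, emits
    binomial counts at cohort-merged coverage, segments, and checks that a
    UMR call and an LMR call overlap their plants with correct class.
    """
    hits_umr = hits_lmr = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 99_991 + rep)
        blocks = [
            ("bg", rng.uniform(0.7, 1.0, 40)),
            ("umr", rng.uniform(0.0, 0.03, 120)),
            ("bg", rng.uniform(0.7, 1.0, 40)),
            ("lmr", rng.uniform(0.05, 0.45, 11)),
            ("bg", rng.uniform(0.7, 1.0, 40)),
        ]
        levels = np.concatenate([b for _, b in blocks])
        labels = np.concatenate([[name] * len(b) for name, b in blocks])
        pos = np.arange(len(levels)) * 20
        meth = rng.binomial(pooled_coverage, levels)
        sites = pd.DataFrame({"chrom": "chr1", "pos": pos, "meth": meth,
                              "cov": pooled_coverage, "n_samples": 3})
        sites["level"] = sites["meth"] / sites["cov"]
        merged = segmentation.MergedTissueMethylome(sites, "adipose")
        segs = segmentation.segment_low_methylation(merged)

        def recovered(label, cls):
            lo = pos[labels == label].min()
            hi = pos[labels == label].max() + 2
            sub = segs[(segs["class"] == cls) & (segs["start"] < hi)
                       & (segs["end"] > lo)]
            return len(sub) > 0

        hits_umr += recovered("umr", "UMR")
        hits_lmr += recovered("lmr", "LMR")
    return {"umr_recovery": hits_umr / n_replicates,
            "lmr_recovery": hits_lmr / n_replicates}
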