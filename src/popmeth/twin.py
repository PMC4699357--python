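"""Twin-based variance decomposition and environmental DMR detection.

The classical twin design partitions trait variance into additive genetic
(A), shared environmental (C) and non-shared environmental (E) components
via intra-class correlations (ICC): monozygotic (MZ) co-twins share all
genetic and shared-environment variance, dizygotic (DZ) co-twins share half
the additive-genetic variance, so Falconer-style estimators give

    h2 = 2 * (ICC_MZ - ICC_DZ),   c2 = ICC_MZ - h2,   e2 = 1 - ICC_MZ.

ICC is the one-way random-effects form ICC(1,1) = (MSB - MSW) /
(MSB + (k-1) * MSW) with k = 2 members per pair.

Within-MZ-pair differential CpGs (eDMCs) capture non-shared environment
directly: co-twins are genetically identical, so any significant difference
is environmental or stochastic.  Runs of three or more unidirectional eDMCs
within +/-500 bp define eDMRs; their excess over chance clustering is
quantified with a permutation FDR that scatters the observed eDMCs over the
tested site map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PopulationMatrix
from .variability import fisher_dmc


def icc(pairs: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) for an (n_pairs, 2) value array.

    Formula: (MSB - MSW) / (MSB + (k-1) MSW) with k=2.  Returns NaN when
    fewer than two complete pairs remain or total variance is zero.
    """
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[~np.isnan(pairs).any(axis=1)]
    n = len(pairs)
    if n < 2:
        return np.nan
    k = pairs.shape[1]
    grand = pairs.mean()
    pair_means = pairs.mean(axis=1)
    msb = k * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((pairs - pair_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return np.nan
    return float((msb - msw) / denom)


@dataclass
class VarianceDecomposition:
    icc_mz: float
    icc_dz: float
    n_mz_pairs: int
    n_dz_pairs: int

    @property
    def h2(self) -> float:
        return 2.0 * (self.icc_mz - self.icc_dz)

    @property
    def c2(self) -> float:
        return self.icc_mz - self.h2

    @property
    def e2(self) -> float:
        return 1.0 - self.icc_mz

    def clamped(self) -> tuple[float, float, float]:
        """Convenience view: components clipped to [0,1] and renormalized."""
        raw = np.clip([self.h2, self.c2, self.e2], 0.0, 1.0)
        total = raw.sum()
        if total == 0:
            return (np.nan, np.nan, np.nan)
        return tuple(raw / total)


def ace_decompose(matrix: PopulationMatrix, metadata: pd.DataFrame,
                  min_pairs: int = 5) -> pd.DataFrame:
    """Per-site ICC_MZ / ICC_DZ and Falconer ACE estimates.

    ``metadata`` must map each matrix sample to pair id and zygosity; only
    sites with complete data in >= min_pairs MZ and >= min_pairs DZ pairs
    are decomposed.  h2/c2/e2 are reported unclamped (h2+c2+e2 = 1 by
    construction); clamped [0,1]-renormalized columns are provided alongside.
    """
    meta = metadata.set_index("sample")
    pair_cols: dict[str, dict[str, list[int]]] = {"MZ": {}, "DZ": {}}
    for j, s in enumerate(matrix.samples):
        if s not in meta.index:
            continue
        zyg = meta.loc[s, "zygosity"]
        pid = meta.loc[s, "pair"]
        if zyg in pair_cols and isinstance(pid, str) and pid != "NA":
            pair_cols[zyg].setdefault(pid, []).append(j)
    mz_pairs = [cols for cols in pair_cols["MZ"].values() if len(cols) == 2]
    dz_pairs = [cols for cols in pair_cols["DZ"].values() if len(cols) == 2]

    rows = []
    for i in range(matrix.n_sites):
        det = matrix.detected[i]

        def collect(pairs):
            vals = [[matrix.levels[i, a], matrix.levels[i, b]]
                    for a, b in pairs if det[a] and det[b]]
            return np.array(vals) if vals else np.empty((0, 2))

        mz = collect(mz_pairs)
        dz = collect(dz_pairs)
        if len(mz) < min_pairs or len(dz) < min_pairs:
            continue
        icc_mz = icc(mz)
        icc_dz = icc(dz)
        if np.isnan(icc_mz) or np.isnan(icc_dz):
            continue
        d = VarianceDecomposition(icc_mz, icc_dz, len(mz), len(dz))
        ch2, cc2, ce2 = d.clamped()
        rows.append({
            "chrom": matrix.sites["chrom"].iloc[i],
            "pos": matrix.sites["pos"].iloc[i],
            "icc_mz": icc_mz, "icc_dz": icc_dz,
            "h2": d.h2, "c2": d.c2, "e2": d.e2,
            "h2_clamped": ch2, "c2_clamped": cc2, "e2_clamped": ce2,
            "n_mz_pairs": len(mz), "n_dz_pairs": len(dz)})
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "icc_mz", "icc_dz", "h2", "c2", "e2",
        "h2_clamped", "c2_clamped", "e2_clamped", "n_mz_pairs", "n_dz_pairs"])


def ace_summary(decomp: pd.DataFrame, use_clamped: bool = True) -> dict:
    """Cohort fractions of sites with large A, C or E contributions."""
    if decomp.empty:
        return {"n_sites": 0}
    suffix = "_clamped" if use_clamped else ""
    return {
        "n_sites": len(decomp),
        "frac_h2_gt_0.3": float((decomp[f"h2{suffix}"] > 0.3).mean()),
        "frac_c2_gt_0.3": float((decomp[f"c2{suffix}"] > 0.3).mean()),
        "frac_e2_gt_0.9": float((decomp[f"e2{suffix}"] > 0.9).mean())}


def call_edmc(units_a: pd.DataFrame, units_b: pd.DataFrame,
              alpha: float = 0.05) -> pd.DataFrame:
    """Within-MZ-pair differential CpGs over shared covered sites.

    Fisher two-sided p per site on pooled counts; eDMC iff p < alpha, with
    the direction of the co-twin difference recorded.
    """
    a = units_a[units_a["cov"] > 0][["chrom", "pos", "meth", "cov"]]
    b = units_b[units_b["cov"] > 0][["chrom", "pos", "meth", "cov"]]
    m = pd.merge(a, b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    ps = np.empty(len(m))
    deltas = np.empty(len(m))
    for r, (ma, ca, mb, cb) in enumerate(zip(m["meth_a"], m["cov_a"],
                                             m["meth_b"], m["cov_b"])):
        ps[r], deltas[r] = fisher_dmc(int(ma), int(ca - ma),
                                      int(mb), int(cb - mb))
    m["p"] = ps
    m["delta"] = deltas
    m["level_a"] = m["meth_a"] / m["cov_a"]
    m["level_b"] = m["meth_b"] / m["cov_b"]
    m["direction"] = np.where(m["level_a"] > m["level_b"], "a_higher",
                              np.where(m["level_a"] < m["level_b"],
                                       "b_higher", "equal"))
    m["edmc"] = m["p"] < alpha
    return m


def call_edmr(edmcs: pd.DataFrame, flank: int = 500,
              min_edmc: int = 3) -> pd.DataFrame:
    """Cluster directional eDMCs into eDMRs.

    Each eDMC's +/-``flank`` bp window is a candidate; candidates containing
    >= ``min_edmc`` same-direction eDMCs become eDMRs, trimmed to the span
    of their constituent eDMCs; overlapping same-direction eDMRs are merged.
    """
    sig = edmcs[edmcs["edmc"] & (edmcs["direction"] != "equal")]
    calls = []
    for (chrom, direction), group in sig.groupby(["chrom", "direction"],
                                                 sort=False):
        pos = np.sort(group["pos"].to_numpy())
        for p in pos:
            inside = pos[(pos >= p - flank) & (pos <= p + flank)]
            if len(inside) >= min_edmc:
                calls.append({"chrom": chrom, "start": int(inside.min()),
                              "end": int(inside.max() + 2),
                              "direction": direction,
                              "n_edmc": int(len(inside))})
    if not calls:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction",
                                     "n_edmc"])
    calls.sort(key=lambda c: (c["chrom"], c["direction"], c["start"], c["end"]))
    merged = []
    for c in calls:
        if merged and merged[-1]["chrom"] == c["chrom"] \
                and merged[-1]["direction"] == c["direction"] \
                and c["start"] <= merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], c["end"])
            merged[-1]["n_edmc"] = max(merged[-1]["n_edmc"], c["n_edmc"])
        else:
            merged.append(dict(c))
    out = pd.DataFrame(merged)
    return out.sort_values(["chrom", "start"], ignore_index=True)


def edmr_permutation_fdr(edmcs: pd.DataFrame, tested_sites: pd.DataFrame,
                         n_perm: int = 1000, seed: int = 0,
                         flank: int = 500, min_edmc: int = 3,
                         per_chromosome: bool = True) -> dict:
    """Permutation FDR for eDMR clustering.

    The observed statistic is the fraction of eDMCs that fall inside called
    eDMRs.  Each permutation reassigns the observed eDMCs (keeping their
    count and direction mix) uniformly at random over the tested site map
    (within chromosome by default), recalls eDMRs and recomputes the
    fraction.  FDR = mean permuted fraction / observed fraction.
    """
    rng = np.random.default_rng(seed)
    sig = edmcs[edmcs["edmc"] & (edmcs["direction"] != "equal")]
    n_edmc = len(sig)
    if n_edmc == 0:
        raise ValueError("no observed eDMCs")
    observed = call_edmr(edmcs, flank=flank, min_edmc=min_edmc)
    obs_frac = _fraction_in_regions(sig, observed)
    if obs_frac == 0:
        return {"fdr": np.nan, "observed_fraction": 0.0,
                "null_fraction_mean": np.nan, "n_perm": n_perm}

    if per_chromosome:
        groups = [(chrom, g["pos"].to_numpy(),
                   sig[sig["chrom"] == chrom]["direction"].to_numpy())
                  for chrom, g in tested_sites.groupby("chrom", sort=False)]
    else:
        groups = [("*", tested_sites["pos"].to_numpy(),
                   sig["direction"].to_numpy())]

    null_fracs = np.empty(n_perm)
    for t in range(n_perm):
        frames = []
        for chrom, site_pos, directions in groups:
            k = len(directions)
            if k == 0:
                continue
            picked = rng.choice(len(site_pos), size=min(k, len(site_pos)),
                                replace=False)
            frames.append(pd.DataFrame({
                "chrom": chrom if chrom != "*" else
                tested_sites["chrom"].to_numpy()[picked],
                "pos": site_pos[picked],
                "direction": directions[:len(picked)],
                "edmc": True}))
        perm = pd.concat(frames, ignore_index=True)
        perm_regions = call_edmr(perm, flank=flank, min_edmc=min_edmc)
        null_fracs[t] = _fraction_in_regions(perm, perm_regions)
    null_mean = float(null_fracs.mean())
    return {"fdr": null_mean / obs_frac, "observed_fraction": float(obs_frac),
            "null_fraction_mean": null_mean, "n_perm": n_perm,
            "n_edmr": len(observed)}


def _fraction_in_regions(edmcs: pd.DataFrame, regions: pd.DataFrame) -> float:
    sig = edmcs[edmcs["edmc"]]
    if len(sig) == 0:
        return 0.0
    if len(regions) == 0:
        return 0.0
    n_in = 0
    for chrom, group in sig.groupby("chrom", sort=False):
        reg = regions[regions["chrom"] == chrom]
        if reg.empty:
            continue
        pos = group["pos"].to_numpy()
        for s, e in zip(reg["start"], reg["end"]):
            n_in += int(((pos >= s) & (pos < e)).sum())
    return n_in / len(sig)


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial probability (sum of outcomes with
    probability <= that of the observed count)."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n > 0")
    return float(stats.binomtest(k, n, p0).pvalue)


def drift_analysis(pair_units: dict[tuple, pd.DataFrame],
                   edmc_exclude: pd.DataFrame | None = None,
                   alpha: float = 0.05,
                   top_variance_fraction: float = 0.5,
                   reference_tissue: str = "adipose",
                   other_tissue: str = "blood") -> dict:
    """Inter-tissue drift concordance between two twin pairs.

    ``pair_units`` maps (pair, tissue, member) -> filtered CpG units for the
    four samples of each tissue (two pairs x two co-twins).  Steps: restrict
    to sites covered in all eight samples; keep the top fraction of sites by
    the between-pair / within-pair variance ratio in the reference tissue;
    drop excluded (eDMC) positions; pool counts within pair x tissue; Fisher
    test pair 1 vs pair 2 per tissue; among sites significant in both
    tissues count direction-concordant ones and test against 0.5 with the
    two-sided exact binomial.
    """
    keys = list(pair_units)
    pairs = sorted({k[0] for k in keys})
    if len(pairs) != 2:
        raise ValueError("drift analysis needs exactly two pairs")
    tissues = (reference_tissue, other_tissue)

    # site intersection across all samples
    common: pd.DataFrame | None = None
    for key, units in pair_units.items():
        covered = units[units["cov"] > 0][["chrom", "pos"]]
        common = covered if common is None else pd.merge(common, covered)
    if common is None or len(common) < 2:
        return {"n_sites": 0, "n_tested": 0, "n_concordant": np.nan,
                "concordant_fraction": np.nan, "binomial_p": np.nan}

    def level_map(key):
        u = pair_units[key]
        m = pd.merge(common, u, on=["chrom", "pos"])
        return m["level"].to_numpy(), m["meth"].to_numpy(), m["cov"].to_numpy()

    # variance ratio in the reference tissue: between-pair variance of pair
    # means over mean within-pair variance
    ref = {(p, mem): level_map((p, reference_tissue, mem))[0]
           for p in pairs for mem in (0, 1)}
    pair_mean = {p: (ref[(p, 0)] + ref[(p, 1)]) / 2 for p in pairs}
    between = np.var(np.stack([pair_mean[p] for p in pairs]), axis=0, ddof=0)
    within = np.mean(np.stack(
        [((ref[(p, 0)] - ref[(p, 1)]) ** 2) / 2 for p in pairs]), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(within > 0, between / within, np.inf)
    n_keep = int(np.ceil(top_variance_fraction * len(common)))
    keep_idx = np.argsort(-ratio, kind="stable")[:n_keep]
    mask = np.zeros(len(common), dtype=bool)
    mask[keep_idx] = True

    if edmc_exclude is not None and len(edmc_exclude):
        excl = set(zip(edmc_exclude["chrom"], edmc_exclude["pos"]))
        in_excl = np.array([(c, p) in excl for c, p in
                            zip(common["chrom"], common["pos"])])
        mask &= ~in_excl

    sel = np.flatnonzero(mask)
    results = {}
    for tissue in tissues:
        pooled = {}
        for p in pairs:
            meths, covs = 0, 0
            for mem in (0, 1):
                _, me, cv = level_map((p, tissue, mem))
                meths = meths + me[sel]
                covs = covs + cv[sel]
            pooled[p] = (meths, covs)
        m1, c1 = pooled[pairs[0]]
        m2, c2 = pooled[pairs[1]]
        ps = np.empty(len(sel))
        for r in range(len(sel)):
            ps[r], _ = fisher_dmc(int(m1[r]), int(c1[r] - m1[r]),
                                  int(m2[r]), int(c2[r] - m2[r]))
        with np.errstate(invalid="ignore"):
            sign = np.sign(m1 / c1 - m2 / c2)
        results[tissue] = {"p": ps, "sign": sign}

    both_sig = ((results[reference_tissue]["p"] < alpha)
                & (results[other_tissue]["p"] < alpha)
                & (results[reference_tissue]["sign"] != 0)
                & (results[other_tissue]["sign"] != 0))
    n_tested = int(both_sig.sum())
    if n_tested == 0:
        return {"n_sites": int(mask.sum()), "n_tested": 0,
                "n_concordant": np.nan, "concordant_fraction": np.nan,
                "binomial_p": np.nan}
    concord = (results[reference_tissue]["sign"][both_sig]
               == results[other_tissue]["sign"][both_sig])
    k = int(concord.sum())
    return {"n_sites": int(mask.sum()), "n_tested": n_tested,
            "n_concordant": k, "concordant_fraction": k / n_tested,
            "binomial_p": exact_binomial_two_sided(k, n_tested, 0.5)}
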