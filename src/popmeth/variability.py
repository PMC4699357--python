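"""Population methylation variability: invariable CpGs, pairwise
differential CpGs (pDMCs), SNP-confounding profiles, and blood cell-type
composition checks.

Differential calling is per-site Fisher's exact testing of pooled methylated
vs unmethylated counts between every pair of samples detecting the site; a
site is a pDMC when at least one comparison is nominally significant
(p < 0.05).  No multiple-testing correction is applied at this stage — FDR
control enters later through the permutation procedure for environmental
DMR clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import PopulationMatrix


@lru_cache(maxsize=1 << 20)
def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact probability of the 2x2 table [[a,b],[c,d]].

    Uses the standard rule: sum of hypergeometric probabilities of all
    tables (with the same margins) no more likely than the observed one,
    with the conventional 1+1e-7 relative gate for floating-point ties.
    Results are memoized: population-scale scans re-test the same low-count
    tables constantly.
    """
    n1, n2 = a + b, c + d
    k = a + c
    lo = max(0, k - n2)
    hi = min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n1 + n2, k, n1)
    p_obs = pmf[a - lo]
    include = pmf <= p_obs * (1 + 1e-7)
    if include.all():
        return 1.0
    return float(min(1.0, pmf[include].sum()))


def fisher_dmc(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int
               ) -> tuple[float, float]:
    """Two-sided Fisher's exact test between two pooled CpG count pairs.

    Returns ``(p, delta)`` where delta is the absolute methylation
    difference in percentage points.  Raises ``ValueError`` on zero coverage.
    """
    cov_a = meth_a + unmeth_a
    cov_b = meth_b + unmeth_b
    if cov_a == 0 or cov_b == 0:
        raise ValueError("fisher_dmc requires coverage > 0 in both samples")
    p = fisher_two_sided(meth_a, unmeth_a, meth_b, unmeth_b)
    delta = abs(meth_a / cov_a - meth_b / cov_b) * 100.0
    return float(p), float(delta)


def call_invariable(matrix: PopulationMatrix, min_detected: int = 2,
                    atol: float = 0.0) -> pd.DataFrame:
    """Sites detected in >= min_detected samples whose pooled levels are all
    identical (SD exactly zero by default).

    Classes: ``unmethylated`` (constant 0), ``fully_methylated`` (constant 1),
    ``other_constant``.
    """
    nd = matrix.n_detected()
    out_rows = []
    for i in np.flatnonzero(nd >= min_detected):
        lv = matrix.levels[i][matrix.detected[i]]
        if np.ptp(lv) <= atol:
            level = float(lv[0])
            if level == 0.0:
                cls = "unmethylated"
            elif level == 1.0:
                cls = "fully_methylated"
            else:
                cls = "other_constant"
            out_rows.append({
                "chrom": matrix.sites["chrom"].iloc[i],
                "pos": matrix.sites["pos"].iloc[i],
                "n_detected": int(nd[i]), "level": level, "class": cls})
    return pd.DataFrame(out_rows, columns=["chrom", "pos", "n_detected",
                                           "level", "class"])


def tissue_status(invariable_a: pd.DataFrame, invariable_b: pd.DataFrame,
                  label_a: str = "adipose", label_b: str = "blood"
                  ) -> pd.DataFrame:
    """Mark invariable sites as tissue-specific or shared across tissues."""
    a = invariable_a.assign(_in_a=True)
    b = invariable_b.assign(_in_b=True)
    merged = pd.merge(a, b[["chrom", "pos", "_in_b"]], on=["chrom", "pos"],
                      how="outer")
    merged["_in_a"] = merged["_in_a"].notna() & merged["_in_a"].eq(True)
    merged["_in_b"] = merged["_in_b"].notna() & merged["_in_b"].eq(True)
    merged["tissue_status"] = np.select(
        [merged["_in_a"] & merged["_in_b"], merged["_in_a"]],
        ["shared", f"{label_a}-specific"], default=f"{label_b}-specific")
    return merged.drop(columns=["_in_a", "_in_b"])


def call_pdmc(matrix: PopulationMatrix, alpha: float = 0.05,
              extreme_delta: float = 60.0) -> tuple[pd.DataFrame, dict]:
    """Flag each site as a pDMC if any pairwise Fisher test has p < alpha.

    Returns the per-site table (pdmc flag, minimum p, maximum delta, number
    of significant comparisons) and a summary dict.
    """
    meth = np.rint(np.nan_to_num(matrix.levels) * matrix.coverage).astype(int)
    cov = np.rint(matrix.coverage).astype(int)
    rows = []
    for i in range(matrix.n_sites):
        det = np.flatnonzero(matrix.detected[i] & (cov[i] > 0))
        best_p, best_delta, n_sig = 1.0, 0.0, 0
        for a, b in combinations(det.tolist(), 2):
            ma, ca = int(meth[i, a]), int(cov[i, a])
            mb, cb = int(meth[i, b]), int(cov[i, b])
            p = fisher_two_sided(ma, ca - ma, mb, cb - mb)
            delta = abs(ma / ca - mb / cb) * 100.0
            best_p = min(best_p, p)
            best_delta = max(best_delta, delta)
            if p < alpha:
                n_sig += 1
        rows.append({
            "chrom": matrix.sites["chrom"].iloc[i],
            "pos": matrix.sites["pos"].iloc[i],
            "n_detected": len(det), "min_p": best_p, "max_delta": best_delta,
            "n_significant": n_sig, "pdmc": n_sig >= 1})
    table = pd.DataFrame(rows, columns=["chrom", "pos", "n_detected", "min_p",
                                        "max_delta", "n_significant", "pdmc"])
    called = table[table["pdmc"]]
    summary = {
        "n_sites": len(table),
        "n_pdmc": int(table["pdmc"].sum()),
        "pdmc_fraction": float(table["pdmc"].mean()) if len(table) else np.nan,
        "median_max_delta": (float(called["max_delta"].median())
                             if len(called) else np.nan),
        "fraction_extreme_delta": (float((called["max_delta"]
                                          > extreme_delta).mean())
                                   if len(called) else np.nan)}
    return table, summary


def snp_confound_profile(pdmc_table: pd.DataFrame,
                         snp_overlap: np.ndarray | pd.Series,
                         bin_width: float = 10.0) -> pd.DataFrame:
    """Fraction of pDMCs overlapping an annotated SNP per max-delta bin.

    Bins of ``bin_width`` percentage points over [0, 100]; the last bin is
    closed at 100.  Empty bins report NaN.
    """
    called = pdmc_table[pdmc_table["pdmc"]].reset_index(drop=True)
    snp = np.asarray(snp_overlap, dtype=bool)
    if len(snp) != len(pdmc_table):
        raise ValueError("snp_overlap must align with pdmc_table rows")
    snp = snp[pdmc_table["pdmc"].to_numpy()]
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi >= 100.0:
            in_bin = (called["max_delta"] >= lo) & (called["max_delta"] <= hi)
        else:
            in_bin = (called["max_delta"] >= lo) & (called["max_delta"] < hi)
        n = int(in_bin.sum())
        frac = float(snp[in_bin.to_numpy()].mean()) if n else np.nan
        rows.append({"delta_lo": lo, "delta_hi": hi, "n_pdmc": n,
                     "snp_fraction": frac})
    return pd.DataFrame(rows)


def cell_composition_correlation(matrix: PopulationMatrix,
                                 cell_fractions: pd.DataFrame,
                                 min_individuals: int = 10,
                                 r_threshold: float = 0.5,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Pearson-correlate site methylation with blood cell-type proportions.

    ``cell_fractions`` is indexed by sample id with one column per cell type.
    A site is flagged when, for any cell type, |R| > ``r_threshold`` with
    two-sided p < ``alpha``, using only samples detecting the site, and only
    when at least ``min_individuals`` such samples exist.  Zero-variance
    sites or fractions leave the correlation undefined and unflagged.
    """
    cell_types = list(cell_fractions.columns)
    col_of = {s: k for k, s in enumerate(matrix.samples)}
    sample_ids = [s for s in matrix.samples if s in cell_fractions.index]
    cols = np.array([col_of[s] for s in sample_ids])
    fr = cell_fractions.loc[sample_ids].to_numpy()
    rows = []
    for i in range(matrix.n_sites):
        det = matrix.detected[i, cols]
        rec = {"chrom": matrix.sites["chrom"].iloc[i],
               "pos": matrix.sites["pos"].iloc[i],
               "n_used": int(det.sum()), "flagged": False}
        for ct in cell_types:
            rec[f"r_{ct}"] = np.nan
            rec[f"p_{ct}"] = np.nan
        if det.sum() >= min_individuals:
            lv = matrix.levels[i, cols[det]]
            for k, ct in enumerate(cell_types):
                x = fr[det, k]
                if np.std(lv) == 0 or np.std(x) == 0:
                    continue
                r, p = stats.pearsonr(lv, x)
                rec[f"r_{ct}"] = float(r)
                rec[f"p_{ct}"] = float(p)
                if abs(r) > r_threshold and p < alpha:
                    rec["flagged"] = True
        rows.append(rec)
    return pd.DataFrame(rows)
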