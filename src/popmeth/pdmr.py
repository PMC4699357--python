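"""Population DMR scan: variability-weighted, consistency-scored windows.

The algorithm detects clustered inter-individual methylation variability:

1. keep CpGs covered in at least three individuals and compute the per-CpG
   SD of methylation levels across the population;
2. scan each chromosome with 500-bp windows anchored at retained CpGs,
   discarding single-CpG windows and windows whose CpG set is a subset of a
   larger candidate's;
3. score each window by its average per-CpG SD and by a consistency score —
   the mean, over individuals covering >= 2 window CpGs, of the Spearman
   correlation between the individual's profile and the across-individual
   average profile;
4. rank windows by ``mean_sd * max(consistency, 0)`` (anti-consistent
   windows are treated as noise), keep the top quantile, drop windows with
   fewer than three CpGs, and merge the surviving intervals with a
   zero-base-pair merge.

Windows whose profiles disagree across individuals are thereby excluded even
when their marginal variability is high, which is the device that separates
population-consistent regions from noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PopulationMatrix


def per_cpg_sd(matrix: PopulationMatrix, min_individuals: int = 3
               ) -> tuple[PopulationMatrix, np.ndarray]:
    """Restrict to sites detected in >= min_individuals and return their SDs.

    SD is the sample standard deviation (ddof=1) of methylation levels over
    detecting individuals only.
    """
    keep = matrix.n_detected() >= min_individuals
    sub = matrix.subset(keep)
    sd = np.empty(sub.n_sites)
    for i in range(sub.n_sites):
        lv = sub.levels[i][sub.detected[i]]
        sd[i] = np.std(lv, ddof=1)
    return sub, sd


@dataclass
class ScoredWindow:
    chrom: str
    start: int              # first CpG position
    end: int                # last CpG dinucleotide end
    site_idx: tuple         # row indices into the matrix
    m: int = 0              # individuals scoring the window
    mean_sd: float = np.nan
    consistency: float = np.nan
    score: float = np.nan


def scan_windows(matrix: PopulationMatrix, window: int = 500) -> list[ScoredWindow]:
    """Candidate windows anchored at retained CpGs with subset elimination.

    Each retained CpG anchors one window containing all retained CpGs within
    [anchor, anchor + window).  Single-CpG windows are discarded; a window
    whose CpG set is a subset of another candidate's set is discarded.
    """
    out: list[ScoredWindow] = []
    sites = matrix.sites
    for chrom in sites["chrom"].unique():
        rows = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        pos = sites["pos"].to_numpy()[rows]
        order = np.argsort(pos)
        rows, pos = rows[order], pos[order]
        spans = []
        for k in range(len(pos)):
            j = np.searchsorted(pos, pos[k] + window, side="left")
            if j - k >= 2:
                spans.append((k, j))
        # subset elimination: with contiguous index ranges, (k1,j1) is a
        # subset of (k2,j2) iff k2 <= k1 and j1 <= j2
        keep = []
        for a, (k1, j1) in enumerate(spans):
            dominated = any((k2 <= k1 and j1 <= j2) and (k2, j2) != (k1, j1)
                            for (k2, j2) in spans)
            if not dominated:
                keep.append((k1, j1))
        for k, j in keep:
            out.append(ScoredWindow(
                chrom=chrom, start=int(pos[k]), end=int(pos[j - 1] + 2),
                site_idx=tuple(int(r) for r in rows[k:j])))
    return out


def consistency_score(levels: np.ndarray, detected: np.ndarray) -> tuple[float, int]:
    """Mean Spearman correlation of individual profiles vs the mean profile.

    ``levels``/``detected`` are (n_cpg, n_individuals) for one window.  The
    average profile at each CpG uses all individuals detected there.  Each
    individual covering >= 2 window CpGs contributes one Spearman correlation
    against the average profile restricted to its covered CpGs; the score is
    the mean of those correlations.  Individuals whose correlation is
    undefined (constant profile) contribute 0.  Returns (r_bar, m); when
    fewer than two individuals qualify, r_bar is NaN and the window is
    unscorable.
    """
    with np.errstate(invalid="ignore"):
        mean_profile = np.nanmean(np.where(detected, levels, np.nan), axis=1)
    rs = []
    for j in range(levels.shape[1]):
        cov = detected[:, j]
        if cov.sum() < 2:
            continue
        x = levels[cov, j]
        y = mean_profile[cov]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rs.append(0.0)
            continue
        r = stats.spearmanr(x, y).statistic
        rs.append(0.0 if np.isnan(r) else float(r))
    if len(rs) < 2:
        return np.nan, len(rs)
    return float(np.mean(rs)), len(rs)


def score_windows(windows: list[ScoredWindow], matrix: PopulationMatrix,
                  sd: np.ndarray, rule: str = "product") -> list[ScoredWindow]:
    """Attach mean SD, consistency and the combined ranking score.

    ``rule='product'`` (default): score = mean_sd * max(consistency, 0).
    ``rule='sd_thresholded'``: score = mean_sd when consistency > 0 else 0.
    Unscorable windows (m < 2) are dropped.
    """
    scored = []
    for w in windows:
        idx = np.array(w.site_idx)
        r_bar, m = consistency_score(matrix.levels[idx], matrix.detected[idx])
        if np.isnan(r_bar):
            continue
        w.m = m
        w.mean_sd = float(np.mean(sd[idx]))
        w.consistency = r_bar
        if rule == "product":
            w.score = w.mean_sd * max(r_bar, 0.0)
        elif rule == "sd_thresholded":
            w.score = w.mean_sd if r_bar > 0 else 0.0
        else:
            raise ValueError(f"unknown score rule {rule!r}")
        scored.append(w)
    return scored


def rank_and_select(windows: list[ScoredWindow], quantile: float = 0.10,
                    min_cpg: int = 3) -> pd.DataFrame:
    """Top-quantile selection, <3-CpG filter, zero-bp merge into pDMR calls.

    Windows are ranked by score descending (ties broken by genomic order for
    determinism); ceil(quantile * n) windows are kept, windows with fewer
    than ``min_cpg`` CpGs removed, and overlapping-or-bookended intervals
    merged.  Returns the merged calls with constituent statistics.
    """
    if not windows:
        raise ValueError("no scored windows to select from")
    n_top = int(np.ceil(quantile * len(windows)))
    order = sorted(range(len(windows)),
                   key=lambda i: (-windows[i].score, windows[i].chrom,
                                  windows[i].start))
    top = [windows[i] for i in order[:n_top]]
    top = [w for w in top if len(w.site_idx) >= min_cpg]
    top.sort(key=lambda w: (w.chrom, w.start, w.end))
    calls = []
    for w in top:
        if calls and calls[-1]["chrom"] == w.chrom \
                and w.start <= calls[-1]["end"]:  # zero-bp merge: bookended too
            prev = calls[-1]
            prev["end"] = max(prev["end"], w.end)
            prev["site_idx"] = tuple(sorted(set(prev["site_idx"])
                                            | set(w.site_idx)))
            prev["mean_sd"] = max(prev["mean_sd"], w.mean_sd)
            prev["consistency"] = max(prev["consistency"], w.consistency)
            prev["score"] = max(prev["score"], w.score)
            prev["n_windows"] += 1
        else:
            calls.append({"chrom": w.chrom, "start": w.start, "end": w.end,
                          "site_idx": w.site_idx, "mean_sd": w.mean_sd,
                          "consistency": w.consistency, "score": w.score,
                          "n_windows": 1})
    df = pd.DataFrame(calls, columns=["chrom", "start", "end", "site_idx",
                                      "mean_sd", "consistency", "score",
                                      "n_windows"])
    df["n_cpg"] = df["site_idx"].map(len)
    return df


def call_pdmr(matrix: PopulationMatrix, window: int = 500,
              quantile: float = 0.10, min_individuals: int = 3,
              min_cpg: int = 3, rule: str = "product") -> pd.DataFrame:
    """Full pDMR pipeline: SD -> window scan -> scoring -> selection."""
    sub, sd = per_cpg_sd(matrix, min_individuals=min_individuals)
    wins = scan_windows(sub, window=window)
    scored = score_windows(wins, sub, sd, rule=rule)
    if not scored:
        return pd.DataFrame(columns=["chrom", "start", "end", "site_idx",
                                     "mean_sd", "consistency", "score",
                                     "n_windows", "n_cpg"])
    return rank_and_select(scored, quantile=quantile, min_cpg=min_cpg)


def stratify_by_level(calls: pd.DataFrame, matrix: PopulationMatrix,
                      cut: float = 0.5) -> pd.DataFrame:
    """Partition calls into low- (< cut) and high-methylated (>= cut) pDMRs.

    Region methylation is the coverage-weighted mean over constituent CpGs
    and detecting individuals.
    """
    out = calls.copy()
    means = []
    for idx in calls["site_idx"]:
        rows = np.array(idx)
        cov = matrix.coverage[rows] * matrix.detected[rows]
        meth = matrix.levels[rows] * cov
        means.append(meth.sum() / cov.sum() if cov.sum() else np.nan)
    out["region_level"] = means
    out["stratum"] = np.where(np.array(means) < cut, "low", "high")
    return out
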