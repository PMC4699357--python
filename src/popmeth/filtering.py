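"""Site-level quality control for population bisulfite methylomes.

Four rules, applied in a fixed order to each sample's CpG units:

1. strand concordance — keep a CpG only when both strands carry at least two
   reads and the absolute methylation difference between strands is at most
   20 percentage points;
2. external blacklist removal (ENCODE-style artifact intervals);
3. study-specific high-coverage blacklist — a locus whose pooled coverage
   exceeds the sample mean plus 1.5 standard deviations in at least two
   samples is removed cohort-wide;
4. SNP removal — a CpG is dropped when either of its two cytosines overlaps
   an annotated variant position.

Optionally restricts to autosomes.  The filter chain is idempotent and every
rule's removal count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = {f"chr{i}" for i in range(1, 23)}


@dataclass
class FilterConfig:
    min_reads_per_strand: int = 2
    max_strand_diff: float = 20.0      # percentage points, inclusive boundary
    coverage_sd_multiplier: float = 1.5
    min_samples_flagged: int = 2
    autosomes_only: bool = False
    blacklist: pd.DataFrame | None = None      # BED intervals
    snp_positions: pd.DataFrame | None = None  # BED intervals (1-bp or wider)

    def __post_init__(self):
        if self.min_reads_per_strand < 0 or self.coverage_sd_multiplier <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.max_strand_diff <= 100:
            raise ValueError("max_strand_diff must be in [0, 100]")


@dataclass
class FilterReport:
    n_input: int = 0
    removed_strand: int = 0
    removed_blacklist: int = 0
    removed_study_blacklist: int = 0
    removed_snp: int = 0
    removed_non_autosome: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def strand_concordance_mask(units: pd.DataFrame,
                            config: FilterConfig) -> np.ndarray:
    """True where a unit passes the >=2-reads-per-strand / <=20-point rule."""
    cov_f = units["cov_fwd"].to_numpy()
    cov_r = units["cov_rev"].to_numpy()
    ok_cov = (cov_f >= config.min_reads_per_strand) & \
             (cov_r >= config.min_reads_per_strand)
    with np.errstate(invalid="ignore", divide="ignore"):
        lv_f = np.where(cov_f > 0, units["meth_fwd"] / cov_f, np.nan)
        lv_r = np.where(cov_r > 0, units["meth_rev"] / cov_r, np.nan)
        diff = np.abs(lv_f - lv_r) * 100.0
    # inclusive boundary; guard float error at exactly the threshold
    ok_diff = np.where(np.isnan(diff), False,
                       diff <= config.max_strand_diff + 1e-9)
    return ok_cov & ok_diff


def strand_concordance_filter(units: pd.DataFrame,
                              config: FilterConfig | None = None
                              ) -> pd.DataFrame:
    config = config or FilterConfig()
    return units[strand_concordance_mask(units, config)].reset_index(drop=True)


def study_blacklist(sample_units: dict[str, pd.DataFrame],
                    config: FilterConfig | None = None) -> pd.DataFrame:
    """Flag loci with outlying coverage in >= min_samples_flagged samples.

    Per sample, a locus is outlying when its pooled (both-strand) coverage
    exceeds that sample's mean coverage plus ``coverage_sd_multiplier`` times
    the coverage SD.  Statistics are taken over the sample's covered CpG
    units before any other filtering, so artifact loci are visible.  Returns
    flagged CpG positions as 2-bp BED intervals covering the dinucleotide.
    """
    config = config or FilterConfig()
    if len(sample_units) < 2:
        raise ValueError("study blacklist needs at least two samples")
    counts: dict[tuple, int] = {}
    for sid, units in sample_units.items():
        covered = units[units["cov"] > 0]
        if len(covered) < 2:
            raise ValueError(f"sample {sid}: <2 covered sites, SD undefined")
        cov = covered["cov"].to_numpy(dtype=float)
        thr = cov.mean() + config.coverage_sd_multiplier * cov.std(ddof=1)
        flagged = covered[cov > thr]
        for chrom, pos in zip(flagged["chrom"], flagged["pos"]):
            counts[(chrom, pos)] = counts.get((chrom, pos), 0) + 1
    rows = [(c, p, p + 2, "high_coverage") for (c, p), n in sorted(counts.items())
            if n >= config.min_samples_flagged]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _overlap_mask(units: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """True where either cytosine of a unit (pos, pos+1) lies in an interval."""
    mask = np.zeros(len(units), dtype=bool)
    if intervals is None or len(intervals) == 0 or len(units) == 0:
        return mask
    for chrom, group in units.groupby("chrom", sort=False):
        iv = intervals[intervals["chrom"] == chrom]
        if iv.empty:
            continue
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # running max of ends for sorted-start queries
        run_end = np.maximum.accumulate(ends)
        pos = group["pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for cpos in (pos, pos + 1):
            # interval contains cpos iff start <= cpos < end
            k = np.searchsorted(starts, cpos, side="right")
            has_prior = k > 0
            prior_end = np.where(has_prior, run_end[np.maximum(k - 1, 0)], 0)
            hit |= has_prior & (prior_end > cpos)
        mask[units.index.get_indexer(group.index)] = hit
    return mask


def remove_intervals(units: pd.DataFrame,
                     intervals: pd.DataFrame | None) -> pd.DataFrame:
    """Drop CpG units overlapping any interval with either cytosine."""
    if intervals is None or len(intervals) == 0:
        return units.reset_index(drop=True)
    units = units.reset_index(drop=True)
    return units[~_overlap_mask(units, intervals)].reset_index(drop=True)


def apply_all_filters(units: pd.DataFrame, config: FilterConfig,
                      study_blacklist_intervals: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full chain strand -> blacklist -> study blacklist -> SNP ->
    autosome and report per-rule removal counts."""
    report = FilterReport(n_input=len(units))
    units = units.reset_index(drop=True)

    keep = strand_concordance_mask(units, config)
    report.removed_strand = int((~keep).sum())
    units = units[keep].reset_index(drop=True)

    for intervals, attr in ((config.blacklist, "removed_blacklist"),
                            (study_blacklist_intervals,
                             "removed_study_blacklist"),
                            (config.snp_positions, "removed_snp")):
        before = len(units)
        units = remove_intervals(units, intervals)
        setattr(report, attr, before - len(units))

    if config.autosomes_only:
        before = len(units)
        units = units[units["chrom"].isin(AUTOSOMES)].reset_index(drop=True)
        report.removed_non_autosome = before - len(units)

    report.n_kept = len(units)
    return units, report
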