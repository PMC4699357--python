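"""Non-CpG (CpH) methylation detection and characterization.

CpH methylation is strand-asymmetric and, in differentiated tissues, rare;
most apparent CpH methylation is incomplete bisulfite conversion.  Calling
is therefore stringent: a CpH is methylated only at > 50 % methylation with
>= 4 reads in two or more individuals.  The module also estimates bisulfite
conversion efficiency from the CpH background, relates methylated CpHs to
their nearest detected CpG, flags highCpH-lowCpG sites (methylated CpH next
to an unmethylated CpG neighborhood) and their within-individual clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def cph_records(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["context"].isin(("CHG", "CHH"))]


def call_methylated_cph(sample_records: dict[str, pd.DataFrame],
                        min_coverage: int = 4, level_cutoff: float = 0.5,
                        min_individuals: int = 2) -> pd.DataFrame:
    """Strand-specific CpH sites methylated in >= 2 individuals.

    Per sample, a site counts as methylated when coverage >= min_coverage
    and level > level_cutoff (strict).  Returns one row per called site
    with dinucleotide context (CpA/CpT/CpC from the trinucleotide) and the
    CpHpG/CpHpH class.
    """
    counts: dict[tuple, dict] = {}
    for sid, rec in sample_records.items():
        ch = cph_records(rec)
        cov = ch["meth"] + ch["unmeth"]
        with np.errstate(invalid="ignore"):
            lvl = np.where(cov > 0, ch["meth"] / cov, np.nan)
        called = ch[(cov >= min_coverage) & (lvl > level_cutoff)]
        for chrom, pos, strand, ctx, tri in zip(
                called["chrom"], called["pos"], called["strand"],
                called["context"], called["trinucleotide"]):
            key = (chrom, pos, strand)
            if key not in counts:
                counts[key] = {"context": ctx, "trinucleotide": tri, "n": 0}
            counts[key]["n"] += 1
    rows = []
    for (chrom, pos, strand), v in sorted(counts.items()):
        if v["n"] < min_individuals:
            continue
        tri = v["trinucleotide"]
        dinuc = f"Cp{tri[1]}" if len(tri) >= 2 and tri[1] in "ACT" else "unknown"
        if len(tri) >= 3:
            tri_class = "CpHpG" if tri[2] == "G" else "CpHpH"
        else:
            tri_class = "unknown"
        rows.append({"chrom": chrom, "pos": pos, "strand": strand,
                     "context": v["context"], "dinucleotide": dinuc,
                     "tri_class": tri_class,
                     "n_individuals_methylated": v["n"]})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "dinucleotide", "tri_class",
                                       "n_individuals_methylated"])


def conversion_efficiency(records: pd.DataFrame) -> float:
    """Per-sample bisulfite conversion efficiency in percent.

    100 * (1 - methylated CpH reads / total CpH reads); assumes genuine CpH
    methylation is negligible, so apparently methylated CpH reads measure
    conversion failure.
    """
    ch = cph_records(records)
    total = int(ch["meth"].sum() + ch["unmeth"].sum())
    if total == 0:
        raise ValueError("no CpH reads")
    return 100.0 * (1.0 - ch["meth"].sum() / total)


def cohort_conversion_efficiency(sample_records: dict[str, pd.DataFrame]
                                 ) -> dict:
    per_sample = {sid: conversion_efficiency(rec)
                  for sid, rec in sample_records.items()}
    vals = np.array(list(per_sample.values()))
    return {"per_sample": per_sample, "median": float(np.median(vals)),
            "min": float(vals.min()), "max": float(vals.max())}


def cph_cpg_proximity(calls: pd.DataFrame, cpg_sites: pd.DataFrame
                      ) -> pd.DataFrame:
    """Nearest detected CpG (by absolute distance, ties downstream) per call.

    ``cpg_sites`` columns: chrom, pos, level (population mean or pooled).
    Adds nearest_cpg_pos / nearest_cpg_distance / nearest_cpg_level; a
    chromosome without CpGs leaves them NaN.
    """
    out = calls.copy()
    out["nearest_cpg_pos"] = np.nan
    out["nearest_cpg_distance"] = np.nan
    out["nearest_cpg_level"] = np.nan
    for chrom, group in calls.groupby("chrom", sort=False):
        cp = cpg_sites[cpg_sites["chrom"] == chrom].sort_values("pos")
        if cp.empty:
            continue
        cpos = cp["pos"].to_numpy()
        clev = cp["level"].to_numpy()
        idx = calls.index.get_indexer(group.index)
        qpos = group["pos"].to_numpy()
        right = np.searchsorted(cpos, qpos)
        left = np.clip(right - 1, 0, len(cpos) - 1)
        right = np.clip(right, 0, len(cpos) - 1)
        d_left = np.abs(qpos - cpos[left])
        d_right = np.abs(cpos[right] - qpos)
        use_right = d_right <= d_left  # tie -> downstream CpG
        best = np.where(use_right, right, left)
        out.iloc[idx, out.columns.get_loc("nearest_cpg_pos")] = cpos[best]
        out.iloc[idx, out.columns.get_loc("nearest_cpg_distance")] = \
            np.abs(cpos[best] - qpos)
        out.iloc[idx, out.columns.get_loc("nearest_cpg_level")] = clev[best]
    return out


def classify_high_cph_low_cpg(calls: pd.DataFrame,
                              level_cut: float = 0.5) -> pd.DataFrame:
    """Flag methylated CpHs whose nearest CpG is < 50 % methylated."""
    out = calls.copy()
    out["high_cph_low_cpg"] = out["nearest_cpg_level"] < level_cut
    out.loc[out["nearest_cpg_level"].isna(), "high_cph_low_cpg"] = False
    return out


def cluster_cph(calls: pd.DataFrame, window: int = 500,
                min_sites: int = 3,
                flag_col: str = "high_cph_low_cpg") -> pd.DataFrame:
    """Mark flagged sites with >= min_sites flagged sites within +/-window.

    The count includes the site itself; clustering is evaluated on the
    flagged subset per chromosome.
    """
    out = calls.copy()
    out["clustered"] = False
    flagged = out[out[flag_col].astype(bool)] if flag_col in out else out
    for chrom, group in flagged.groupby("chrom", sort=False):
        pos = np.sort(group["pos"].to_numpy())
        idx = calls.index.get_indexer(group.index)
        for local_i, p in zip(idx, group["pos"].to_numpy()):
            n_near = int(((pos >= p - window) & (pos <= p + window)).sum())
            out.iloc[local_i, out.columns.get_loc("clustered")] = \
                n_near >= min_sites
    return out


def cph_summary(calls: pd.DataFrame) -> dict:
    """Context/strand breakdown of a call set."""
    if calls.empty:
        return {"n_calls": 0}
    dinuc = calls["dinucleotide"].value_counts(normalize=True).to_dict()
    known = calls[calls["tri_class"] != "unknown"]
    tri = known["tri_class"].value_counts(normalize=True).to_dict() \
        if len(known) else {}
    strand = calls["strand"].value_counts().to_dict()
    return {"n_calls": len(calls), "dinucleotide_fractions": dinuc,
            "tri_class_fractions": tri, "strand_counts": strand}


def cph_of_total_methylation(sample_records: dict[str, pd.DataFrame],
                             cpg_units: dict[str, pd.DataFrame],
                             min_coverage: int = 4,
                             level_cutoff: float = 0.5) -> dict:
    """Per-individual share of methylated cytosines that are CpH.

    ratio = methylated CpHs / (methylated CpHs + CpGs with level > cutoff),
    applying the same coverage floor to both.
    """
    out = {}
    for sid, rec in sample_records.items():
        ch = cph_records(rec)
        cov = ch["meth"] + ch["unmeth"]
        with np.errstate(invalid="ignore"):
            lvl = np.where(cov > 0, ch["meth"] / cov, np.nan)
        n_cph = int(((cov >= min_coverage) & (lvl > level_cutoff)).sum())
        units = cpg_units[sid]
        ucov = units["cov"]
        n_cpg = int(((ucov >= min_coverage)
                     & (units["level"] > level_cutoff)).sum())
        out[sid] = n_cph / (n_cph + n_cpg) if (n_cph + n_cpg) else np.nan
    return out
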