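"""Reading, writing and assembly of methylome data structures.

All internal coordinates are 0-based half-open (BED-native).  The Bismark-
style cytosine report uses 1-based positions; the conversion happens at the
file boundary and nowhere else.  A CpG dinucleotide is addressed by the
position of its forward-strand cytosine.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REPORT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context",
                  "trinucleotide"]


def _opener(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_cytosine_report(path) -> pd.DataFrame:
    """Parse a cytosine report into a record table with 0-based positions.

    Columns: chrom, pos (0-based C position), strand, meth, unmeth, context,
    trinucleotide.  Malformed lines raise ``ValueError`` with the line number.
    """
    rows = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 tab-separated "
                                 f"fields, got {len(parts)}")
            try:
                pos = int(parts[1]) - 1
                meth, unmeth = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if parts[2] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {parts[2]!r}")
            if meth < 0 or unmeth < 0 or pos < 0:
                raise ValueError(f"{path}:{lineno}: negative field")
            tri = parts[6] if len(parts) > 6 else ""
            rows.append((parts[0], pos, parts[2], meth, unmeth, parts[5], tri))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["pos"] = out["pos"] + 1
    out[REPORT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def pair_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Pair CG-context records into CpG units keyed by the forward-strand C.

    A unit at forward position p pairs the + record at p with the - record at
    p+1.  Units missing one mate are kept and flagged ``both_strands=False``
    with zero counts on the missing strand.  Duplicate (pos, strand) entries
    raise ``ValueError``.
    """
    cg = records[records["context"] == "CG"]
    if cg.duplicated(subset=["chrom", "pos", "strand"]).any():
        dup = cg[cg.duplicated(subset=["chrom", "pos", "strand"])].iloc[0]
        raise ValueError(f"duplicate record at {dup['chrom']}:{dup['pos']} "
                         f"{dup['strand']}")
    fwd = cg[cg["strand"] == "+"].copy()
    rev = cg[cg["strand"] == "-"].copy()
    fwd = fwd.rename(columns={"meth": "meth_fwd", "unmeth": "unmeth_fwd"})
    rev = rev.rename(columns={"meth": "meth_rev", "unmeth": "unmeth_rev"})
    rev = rev.assign(pos=rev["pos"] - 1)  # reverse C sits at fwd pos + 1
    merged = pd.merge(
        fwd[["chrom", "pos", "meth_fwd", "unmeth_fwd"]],
        rev[["chrom", "pos", "meth_rev", "unmeth_rev"]],
        on=["chrom", "pos"], how="outer")
    merged["both_strands"] = (merged["meth_fwd"].notna()
                              & merged["meth_rev"].notna())
    for c in ("meth_fwd", "unmeth_fwd", "meth_rev", "unmeth_rev"):
        merged[c] = merged[c].fillna(0).astype(int)
    merged = merged.sort_values(["chrom", "pos"], ignore_index=True)
    merged["cov_fwd"] = merged["meth_fwd"] + merged["unmeth_fwd"]
    merged["cov_rev"] = merged["meth_rev"] + merged["unmeth_rev"]
    merged["meth"] = merged["meth_fwd"] + merged["meth_rev"]
    merged["cov"] = merged["cov_fwd"] + merged["cov_rev"]
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["level"] = np.where(merged["cov"] > 0,
                                   merged["meth"] / merged["cov"], np.nan)
    return merged


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; intervals are 0-based half-open, kept as given."""
    rows = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path, sort: bool = False) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in intervals.columns]
    out = intervals[cols]
    if sort:
        out = out.sort_values(["chrom", "start", "end"])
    out.to_csv(path, sep="\t", index=False, header=False)


def write_bedgraph(units: pd.DataFrame, path) -> None:
    """Export pooled CpG levels as bedGraph (chrom, start, end, level)."""
    covered = units[units["cov"] > 0]
    pd.DataFrame({
        "chrom": covered["chrom"], "start": covered["pos"],
        "end": covered["pos"] + 2, "level": covered["level"].round(6),
    }).to_csv(path, sep="\t", index=False, header=False)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    cell_cols = [c for c in ("neutrophils", "lymphocytes", "monocytes",
                             "eosinophils") if c in meta.columns]
    if cell_cols:
        fr = meta[cell_cols].dropna()
        if ((fr < 0).any().any()
                or (fr.sum(axis=1) > 1 + 1e-6).any()):
            raise ValueError("cell fractions must be >= 0 and sum to <= 1")
    return meta


@dataclass
class PopulationMatrix:
    """Site-by-sample methylation levels and coverages.

    ``sites`` indexes rows (chrom, pos of the forward-strand C); ``levels``
    and ``coverage`` are (n_sites, n_samples) arrays; ``detected`` marks the
    entries where the site passed filtering in that sample.
    """

    sites: pd.DataFrame           # chrom, pos
    samples: list[str]
    levels: np.ndarray
    coverage: np.ndarray
    detected: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def n_detected(self) -> np.ndarray:
        return self.detected.sum(axis=1)

    def subset(self, row_mask) -> "PopulationMatrix":
        idx = np.asarray(row_mask)
        return PopulationMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            levels=self.levels[idx], coverage=self.coverage[idx],
            detected=self.detected[idx])

    def select_samples(self, keep: list[str]) -> "PopulationMatrix":
        cols = [self.samples.index(s) for s in keep]
        return PopulationMatrix(
            sites=self.sites.copy(), samples=list(keep),
            levels=self.levels[:, cols], coverage=self.coverage[:, cols],
            detected=self.detected[:, cols])


def build_population_matrix(sample_units: dict[str, pd.DataFrame],
                            min_detected: int = 2) -> PopulationMatrix:
    """Assemble filtered per-sample CpG units into a population matrix.

    A site is detected in a sample iff it appears in that sample's (already
    filtered) unit table with pooled coverage > 0; only sites detected in at
    least ``min_detected`` samples are retained.
    """
    if min_detected < 1:
        raise ValueError("min_detected must be >= 1")
    samples = list(sample_units)
    frames = []
    for sid in samples:
        u = sample_units[sid]
        u = u[u["cov"] > 0]
        frames.append(pd.DataFrame({
            "chrom": u["chrom"], "pos": u["pos"], "sample": sid,
            "level": u["level"], "cov": u["cov"]}))
    if not frames:
        empty = pd.DataFrame(columns=["chrom", "pos"])
        return PopulationMatrix(empty, samples, np.zeros((0, 0)),
                                np.zeros((0, 0)), np.zeros((0, 0), bool))
    long = pd.concat(frames, ignore_index=True)
    lv = long.pivot_table(index=["chrom", "pos"], columns="sample",
                          values="level", aggfunc="first")
    cv = long.pivot_table(index=["chrom", "pos"], columns="sample",
                          values="cov", aggfunc="first")
    lv = lv.reindex(columns=samples)
    cv = cv.reindex(columns=samples)
    detected = cv.notna().to_numpy()
    keep = detected.sum(axis=1) >= min_detected
    sites = lv.index.to_frame(index=False, name=["chrom", "pos"])[keep]
    return PopulationMatrix(
        sites=sites.reset_index(drop=True), samples=samples,
        levels=lv.to_numpy()[keep], coverage=np.nan_to_num(cv.to_numpy())[keep],
        detected=detected[keep])
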