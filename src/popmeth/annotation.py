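"""Genomic feature annotation and enrichment testing.

Sites and regions are classified against three schemes:

* CGI-relational classes with precedence island > shore (within 2 kb) >
  shelf (2-4 kb) > open sea, with north/south by the upstream/downstream
  side of the nearest island;
* genic classes in the fixed precedence order TSS1500 (201-1500 bp upstream
  of the TSS, strand-aware), TSS200 (<= 200 bp upstream), 5'UTR, exon 1,
  other exons, introns, 3'UTR, intergenic;
* histone-mark classes built from read-interval tracks binned at 100 bp,
  library-size normalized, input subtracted and ranked — promoter bins are
  top H3K4me3 bins within 1 kb of a TSS, enhancer bins are top H3K4me1 bins
  not overlapping a top H3K4me3 bin.

Enrichment of a query set in a feature against a stated background is the
ratio of in-feature fractions with a two-sided Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variability import fisher_two_sided

CGI_CLASSES = ("island", "N_shore", "S_shore", "N_shelf", "S_shelf",
               "open_sea")
GENIC_CLASSES = ("TSS1500", "TSS200", "UTR5", "exon1", "other_exon",
                 "intron", "UTR3", "intergenic")


def classify_cgi(positions: pd.DataFrame, cgi: pd.DataFrame,
                 shore: int = 2000, shelf: int = 4000) -> pd.Series:
    """CGI-relational class per site (rows of ``positions``: chrom, pos)."""
    out = np.full(len(positions), "open_sea", dtype=object)
    for chrom, group in positions.groupby("chrom", sort=False):
        iv = cgi[cgi["chrom"] == chrom].sort_values("start")
        idx = positions.index.get_indexer(group.index)
        if iv.empty:
            continue
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        pos = group["pos"].to_numpy()
        cls = np.full(len(pos), "open_sea", dtype=object)
        # signed distance to the nearest island: 0 inside, <0 upstream (north)
        dist = np.full(len(pos), np.inf)
        side = np.zeros(len(pos))  # -1 north of island, +1 south
        for s, e in zip(starts, ends):
            d = np.where(pos < s, pos - s, np.where(pos >= e, pos - e + 1, 0))
            better = np.abs(d) < np.abs(dist)
            dist = np.where(better, d, dist)
            side = np.where(better, np.sign(d), side)
        inside = dist == 0
        ad = np.abs(dist)
        cls[inside] = "island"
        sh = ~inside & (ad <= shore)
        cls[sh & (side < 0)] = "N_shore"
        cls[sh & (side > 0)] = "S_shore"
        sf = ~inside & (ad > shore) & (ad <= shelf)
        cls[sf & (side < 0)] = "N_shelf"
        cls[sf & (side > 0)] = "S_shelf"
        out[idx] = cls
    return pd.Series(out, index=positions.index, name="cgi_class")


@dataclass
class GeneModel:
    """Minimal transcript table: one row per transcript.

    Columns: gene, chrom, strand, tx_start, tx_end, cds_start, cds_end,
    exon_starts, exon_ends (comma-separated, BED convention).
    """

    table: pd.DataFrame

    @classmethod
    def from_tsv(cls, path) -> "GeneModel":
        return cls(pd.read_csv(path, sep="\t"))

    def tss(self) -> pd.DataFrame:
        t = self.table
        pos = np.where(t["strand"] == "+", t["tx_start"], t["tx_end"] - 1)
        return pd.DataFrame({"chrom": t["chrom"], "pos": pos,
                             "gene": t["gene"]})


def _parse_exons(row) -> list[tuple[int, int]]:
    starts = [int(x) for x in str(row["exon_starts"]).rstrip(",").split(",")]
    ends = [int(x) for x in str(row["exon_ends"]).rstrip(",").split(",")]
    return list(zip(starts, ends))


def _classify_one_genic(pos: int, row) -> str:
    """Class of a single position against a single transcript, or ''. """
    strand = row["strand"]
    tx_start, tx_end = row["tx_start"], row["tx_end"]
    cds_start, cds_end = row["cds_start"], row["cds_end"]
    exons = _parse_exons(row)
    # upstream distance in bp: 1 = immediately before the TSS
    if strand == "+":
        upstream = tx_start - pos
    else:
        upstream = pos - (tx_end - 1)
    if 200 < upstream <= 1500:
        return "TSS1500"
    if 1 <= upstream <= 200:
        return "TSS200"
    if not (tx_start <= pos < tx_end):
        return ""
    in_exon = any(s <= pos < e for s, e in exons)
    # UTRs: outside the CDS but inside the transcript, on exonic sequence
    if in_exon and cds_start < cds_end:
        if strand == "+":
            if pos < cds_start:
                return "UTR5"
            if pos >= cds_end:
                return "UTR3"
        else:
            if pos >= cds_end:
                return "UTR5"
            if pos < cds_start:
                return "UTR3"
    if in_exon:
        first = exons[0] if strand == "+" else exons[-1]
        if first[0] <= pos < first[1]:
            return "exon1"
        return "other_exon"
    return "intron"


def classify_genic(positions: pd.DataFrame, genes: GeneModel) -> pd.Series:
    """Genic class per site with promoter-proximal precedence across
    overlapping transcripts."""
    rank = {c: r for r, c in enumerate(GENIC_CLASSES)}
    out = np.full(len(positions), "intergenic", dtype=object)
    gt = genes.table
    for chrom, group in positions.groupby("chrom", sort=False):
        tx = gt[gt["chrom"] == chrom]
        if tx.empty:
            continue
        idx = positions.index.get_indexer(group.index)
        for local_i, pos in zip(idx, group["pos"].to_numpy()):
            best = "intergenic"
            for _, row in tx.iterrows():
                if not (row["tx_start"] - 1500 <= pos
                        < row["tx_end"] + 1500):
                    continue
                c = _classify_one_genic(int(pos), row)
                if c and rank[c] < rank[best]:
                    best = c
            out[local_i] = best
    return pd.Series(out, index=positions.index, name="genic_class")


def rank_chip_bins(donor_reads: dict[str, pd.DataFrame],
                   donor_input: dict[str, pd.DataFrame],
                   genome_length: int, bin_size: int = 100,
                   top: float = 0.01, min_donors: int = 3) -> pd.DataFrame:
    """Rank 100-bp bins by input-subtracted normalized signal per donor and
    keep bins in the top quantile in >= min_donors donors.

    ``donor_reads``/``donor_input`` map donor id -> BED-like read interval
    frames (one interval per aligned read); a read counts in the bin of its
    start position.  Per donor, bin counts are divided by the donor's total
    reads (signal and input separately) and the normalized input subtracted.
    Zero-signal ties never enter the top set.  Returns the bin table with
    per-donor top flags and the reproducible ``selected`` column.
    """
    n_bins = int(np.ceil(genome_length / bin_size))
    donors = list(donor_reads)
    if len(donors) < min_donors:
        raise ValueError("need at least min_donors donors")
    signal = np.zeros((n_bins, len(donors)))
    for d, donor in enumerate(donors):
        reads = donor_reads[donor]
        inp = donor_input[donor]
        if len(reads) == 0:
            raise ValueError(f"donor {donor} has zero reads")
        for frame, sign in ((reads, +1.0), (inp, -1.0)):
            if len(frame) == 0:
                continue
            bins = (frame["start"].to_numpy() // bin_size).astype(int)
            counts = np.bincount(bins, minlength=n_bins)[:n_bins]
            signal[:, d] += sign * counts / len(frame)
    n_top = int(np.ceil(top * n_bins))
    top_flags = np.zeros((n_bins, len(donors)), dtype=bool)
    for d in range(len(donors)):
        # rank by signal desc, ties broken by genomic coordinate; exclude
        # bins with non-positive signal (uniform/zero tracks select nothing)
        order = np.lexsort((np.arange(n_bins), -signal[:, d]))
        picked = [b for b in order[:n_top] if signal[b, d] > 0]
        top_flags[np.array(picked, dtype=int), d] = True
    reproducible = top_flags.sum(axis=1) >= min_donors
    out = pd.DataFrame({
        "bin": np.arange(n_bins),
        "start": np.arange(n_bins) * bin_size,
        "end": np.minimum((np.arange(n_bins) + 1) * bin_size, genome_length),
        "n_donors_top": top_flags.sum(axis=1),
        "selected": reproducible})
    for d, donor in enumerate(donors):
        out[f"signal_{donor}"] = signal[:, d]
    return out


def define_promoters_enhancers(h3k4me3_bins: pd.DataFrame,
                               h3k4me1_bins: pd.DataFrame,
                               tss: pd.DataFrame,
                               tss_window: int = 1000) -> dict:
    """Promoter bins: selected H3K4me3 bins within ``tss_window`` of a TSS.
    Enhancer bins: selected H3K4me1 bins not overlapping a selected
    H3K4me3 bin."""
    me3 = h3k4me3_bins[h3k4me3_bins["selected"]]
    me1 = h3k4me1_bins[h3k4me1_bins["selected"]]
    tss_pos = np.sort(tss["pos"].to_numpy())
    if len(tss_pos):
        centers_near = []
        for s, e in zip(me3["start"], me3["end"]):
            lo = np.searchsorted(tss_pos, s - tss_window, side="left")
            hi = np.searchsorted(tss_pos, e + tss_window, side="right")
            near = any(tss_pos[k] >= s - tss_window
                       and tss_pos[k] < e + tss_window
                       for k in range(lo, hi))
            centers_near.append(near)
        promoters = me3[np.array(centers_near, dtype=bool)] if len(me3) \
            else me3
    else:
        promoters = me3.iloc[0:0]
    me3_set = set(me3["bin"])
    enhancers = me1[~me1["bin"].isin(me3_set)]
    return {"promoter_bins": promoters.reset_index(drop=True),
            "enhancer_bins": enhancers.reset_index(drop=True)}


def enrichment(query_in_feature: int, query_total: int,
               background_in_feature: int, background_total: int
               ) -> tuple[float, float]:
    """Fold change and two-sided Fisher p of a query vs background split.

    fold = (query fraction in feature) / (background fraction in feature);
    the 2x2 table is [in/out of feature] x [query/background].  Returns
    (fold, p); fold is NaN when the background fraction is zero.
    """
    if query_total == 0 or background_total == 0:
        raise ValueError("empty query or background")
    qf = query_in_feature / query_total
    bf = background_in_feature / background_total
    fold = qf / bf if bf > 0 else np.nan
    p = fisher_two_sided(
        query_in_feature, query_total - query_in_feature,
        background_in_feature, background_total - background_in_feature)
    return float(fold) if not np.isnan(fold) else np.nan, float(p)


def enrichment_by_class(query_classes: pd.Series,
                        background_classes: pd.Series) -> pd.DataFrame:
    """Per-class fold enrichment of query sites against background sites."""
    rows = []
    classes = sorted(set(query_classes) | set(background_classes))
    nq, nb = len(query_classes), len(background_classes)
    for c in classes:
        qin = int((query_classes == c).sum())
        bin_ = int((background_classes == c).sum())
        fold, p = enrichment(qin, nq, bin_, nb)
        rows.append({"feature": c, "query_in": qin, "background_in": bin_,
                     "fold": fold, "p": p})
    return pd.DataFrame(rows)
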