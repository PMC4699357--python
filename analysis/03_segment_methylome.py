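"""Merged-tissue methylomes and UMR/LMR segmentation.

Pools filtered counts per tissue (sites detected in >= 3 individuals),
segments regions of consecutive low-methylated CpGs and compares segment
classes across tissues.
"""

from common import RESULTS, filtered_units, get_cohort
from popmeth import io, segmentation

cohort = get_cohort()
RESULTS.mkdir(exist_ok=True)

segments = {}
for tissue in ("adipose", "blood"):
    units, _ = filtered_units(cohort, tissue)
    merged = segmentation.merge_tissue(units, min_individuals=3,
                                       tissue=tissue)
    segs = segmentation.segment_low_methylation(merged)
    segs.to_csv(RESULTS / f"segments_{tissue}.tsv", sep="\t", index=False)
    io.write_bed(segs.assign(name=segs["class"]),
                 RESULTS / f"segments_{tissue}.bed")
    segments[tissue] = segs
    counts = segs["class"].value_counts().to_dict()
    print(f"{tissue}: {len(merged.sites)} pooled CpGs -> "
          f"{counts.get('UMR', 0)} UMRs, {counts.get('LMR', 0)} LMRs")

for a, b in (("adipose", "blood"), ("blood", "adipose")):
    frac = segmentation.region_overlap_fraction(segments[a], segments[b])
    print(f"fraction of {a} segments overlapping {b}: {frac:.2f}")
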