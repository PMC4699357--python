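"""Non-CpG methylation: stringent calling, conversion efficiency,
CpG-proximity and clustering.
"""

import json

import pandas as pd

from common import RESULTS, filtered_units, get_cohort
from popmeth import cph

cohort = get_cohort()
RESULTS.mkdir(exist_ok=True)

adipose = {sid: rec for sid, rec in cohort.samples.items()
           if sid.endswith("adipose")}
conv = cph.cohort_conversion_efficiency(adipose)
print(f"median bisulfite conversion efficiency: {conv['median']:.2f} % "
      f"(range {conv['min']:.2f}-{conv['max']:.2f})")

calls = cph.call_methylated_cph(adipose)
summary = cph.cph_summary(calls)
print(f"methylated CpHs: {summary['n_calls']} "
      f"(dinucleotide mix {summary.get('dinucleotide_fractions', {})})")

units, _ = filtered_units(cohort, "adipose")
frames = []
for u in units.values():
    frames.append(u[["chrom", "pos", "level"]])
pooled = (pd.concat(frames).groupby(["chrom", "pos"], as_index=False)
          .mean())
calls = cph.cph_cpg_proximity(calls, pooled)
calls = cph.classify_high_cph_low_cpg(calls)
calls = cph.cluster_cph(calls, flag_col="high_cph_low_cpg")
calls.to_csv(RESULTS / "cph_calls.tsv", sep="\t", index=False)

if len(calls):
    near_high = (calls["nearest_cpg_level"] >= 0.5).mean()
    print(f"fraction of methylated CpHs whose nearest CpG is >=50 % "
          f"methylated: {near_high:.0%}; "
          f"mean distance {calls['nearest_cpg_distance'].mean():.0f} bp; "
          f"{int(calls['high_cph_low_cpg'].sum())} highCpH-lowCpG, "
          f"{int(calls['clustered'].sum())} clustered")

out = {"conversion": {k: conv[k] for k in ("median", "min", "max")},
       "n_calls": int(summary["n_calls"])}
with open(RESULTS / "cph_summary.json", "w") as fh:
    json.dump(out, fh, indent=1)
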