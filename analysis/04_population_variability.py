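"""Invariable CpGs, population differential CpGs and their confounders.

Builds the per-tissue population matrices, calls invariable sites and
pairwise-Fisher pDMCs, profiles SNP confounding by effect size, and tests
blood cell-composition correlation.
"""

import json

import numpy as np

from common import RESULTS, filtered_units, get_cohort
from popmeth import io, variability

cohort = get_cohort()
RESULTS.mkdir(exist_ok=True)
out = {}

matrices = {}
invariable = {}
for tissue in ("adipose", "blood"):
    units, _ = filtered_units(cohort, tissue)
    m = io.build_population_matrix(units, min_detected=2)
    matrices[tissue] = m
    inv = variability.call_invariable(m, min_detected=2)
    invariable[tissue] = inv
    table, summary = variability.call_pdmc(m)
    table.to_csv(RESULTS / f"pdmc_{tissue}.tsv", sep="\t", index=False)
    out[tissue] = {"n_sites": m.n_sites, "n_invariable": len(inv),
                   "invariable_fraction": len(inv) / m.n_sites,
                   **summary}
    print(f"{tissue}: {m.n_sites} CpGs detected in >=2 individuals; "
          f"{len(inv)} invariable ({len(inv) / m.n_sites:.1%}), "
          f"{summary['n_pdmc']} pDMCs ({summary['pdmc_fraction']:.1%})")

    if tissue == "blood":
        # SNP confounding is profiled on data WITHOUT SNP removal: the
        # question is how much genotype-coded signal masquerades as
        # differential methylation
        from common import tissue_units
        from popmeth import filtering
        raw = {sid: filtering.strand_concordance_filter(u)
               for sid, u in tissue_units(cohort, tissue).items()}
        m_raw = io.build_population_matrix(raw, min_detected=2)
        table_raw, _ = variability.call_pdmc(m_raw)
        snp_pos = set(cohort.truth.snp_sites["pos"])
        snp = m_raw.sites["pos"].isin(snp_pos).to_numpy()
        prof = variability.snp_confound_profile(table_raw, snp,
                                                bin_width=20.0)
        prof.to_csv(RESULTS / "snp_confound_profile.tsv", sep="\t",
                    index=False)
        filled = prof.dropna(subset=["snp_fraction"])
        print("SNP fraction by delta bin:",
              {f"{int(r['delta_lo'])}-{int(r['delta_hi'])}":
               round(float(r["snp_fraction"]), 3)
               for _, r in filled.iterrows()})

        meta = cohort.metadata.set_index("sample")
        cells = meta.loc[m.samples, ["neutrophils", "lymphocytes",
                                     "monocytes", "eosinophils"]]
        cc = variability.cell_composition_correlation(m, cells)
        out["blood"]["n_cell_flagged"] = int(cc["flagged"].sum())
        print(f"blood CpGs flagged for cell-composition correlation: "
              f"{int(cc['flagged'].sum())}")

status = variability.tissue_status(invariable["adipose"],
                                   invariable["blood"])
out["invariable_tissue_status"] = \
    status["tissue_status"].value_counts().to_dict()
print("invariable tissue status:", out["invariable_tissue_status"])

with open(RESULTS / "variability_summary.json", "w") as fh:
    json.dump(out, fh, indent=1, default=float)
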