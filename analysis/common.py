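"""Shared cohort and paths for the numbered analysis scripts.

All scripts analyse the same simulated two-tissue twin cohort (seeded, so
every run is reproducible) and write small summary tables under results/.
"""

from pathlib import Path

import pandas as pd

from popmeth import filtering, io
from popmeth.simulate import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

COHORT_CONFIG = SimulationConfig(
    n_cpg=3000, n_cph=2000, mean_coverage=6.0, seed=1)


def get_cohort():
    return simulate_cohort(COHORT_CONFIG)


def tissue_units(cohort, tissue):
    """Strand-paired CpG units for every sample of one tissue."""
    return {row["sample"]: io.pair_strands(cohort.samples[row["sample"]])
            for _, row in cohort.metadata.iterrows()
            if row["tissue"] == tissue}


def filtered_units(cohort, tissue):
    """Units of one tissue through the full QC chain (strand, study
    blacklist, SNP removal)."""
    units = tissue_units(cohort, tissue)
    snps = cohort.truth.snp_sites
    snp_bed = pd.DataFrame({"chrom": snps["chrom"], "start": snps["pos"],
                            "end": snps["pos"] + 1, "name": "."})
    cfg = filtering.FilterConfig(snp_positions=snp_bed)
    flagged = filtering.study_blacklist(units, cfg)
    out, reports = {}, {}
    for sid, u in units.items():
        out[sid], reports[sid] = filtering.apply_all_filters(
            u, cfg, study_blacklist_intervals=flagged)
    return out, reports
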