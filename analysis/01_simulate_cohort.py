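"""Simulate the study cohort and record its design and ground truth.

Generates the seeded two-tissue twin cohort used by all downstream analysis
scripts and writes the sample metadata and truth tables.
"""

from common import RESULTS, get_cohort

cohort = get_cohort()
outdir = RESULTS / "cohort"
outdir.mkdir(parents=True, exist_ok=True)

cohort.metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)
cohort.truth.write(outdir)

n_ind = len(cohort.individuals)
by_zyg = cohort.metadata[cohort.metadata["tissue"] == "adipose"][
    "zygosity"].value_counts()
print(f"simulated {n_ind} individuals x 2 tissues "
      f"({len(cohort.metadata)} samples)")
print(f"adipose zygosity counts: {by_zyg.to_dict()}")
print(f"CpGs: {cohort.config.n_cpg}, CpHs: {cohort.config.n_cph}, "
      f"mean strand coverage: {cohort.config.mean_coverage}")
print("planted truth:",
      cohort.truth.ace["category"].value_counts().to_dict())
print(f"wrote metadata and truth tables to {outdir}")
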