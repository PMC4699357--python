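import numpy as np
import pandas as pd
import pytest

from popmeth import filtering, io
from popmeth.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete two-tissue twin cohort with every planted
    confounder, shared across tests (read-only)."""
    cfg = SimulationConfig(n_cpg=600, n_cph=800, n_mz_pairs=4, n_dz_pairs=3,
                           n_singletons=2, mean_coverage=6.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def adipose_units(small_cohort):
    """Strand-paired CpG units for every adipose sample."""
    out = {}
    for _, row in small_cohort.metadata.iterrows():
        if row["tissue"] == "adipose":
            out[row["sample"]] = io.pair_strands(
                small_cohort.samples[row["sample"]])
    return out


@pytest.fixture(scope="session")
def filtered_adipose(small_cohort, adipose_units):
    """Adipose units through the full QC chain, with reports."""
    snps = small_cohort.truth.snp_sites
    snp_bed = pd.DataFrame({"chrom": snps["chrom"], "start": snps["pos"],
                            "end": snps["pos"] + 1, "name": "."})
    cfg = filtering.FilterConfig(snp_positions=snp_bed)
    sb = filtering.study_blacklist(adipose_units, cfg)
    filtered, reports = {}, {}
    for sid, u in adipose_units.items():
        filtered[sid], reports[sid] = filtering.apply_all_filters(
            u, cfg, study_blacklist_intervals=sb)
    return {"units": filtered, "reports": reports, "study_blacklist": sb,
            "snp_bed": snp_bed}


def units_from_counts(rows):
    """Helper: build a CpG unit table from (chrom, pos, mf, uf, mr, ur)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_fwd", "unmeth_fwd",
                                     "meth_rev", "unmeth_rev"])
    df["both_strands"] = True
    df["cov_fwd"] = df["meth_fwd"] + df["unmeth_fwd"]
    df["cov_rev"] = df["meth_rev"] + df["unmeth_rev"]
    df["meth"] = df["meth_fwd"] + df["meth_rev"]
    df["cov"] = df["cov_fwd"] + df["cov_rev"]
    with np.errstate(invalid="ignore"):
        df["level"] = np.where(df["cov"] > 0, df["meth"] / df["cov"], np.nan)
    return df
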