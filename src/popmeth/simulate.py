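"""Synthetic twin-structured two-tissue bisulfite methylome generator.

Emulates the study design that the rest of the pipeline analyses: a twin
cohort (MZ and DZ pairs plus singletons) profiled by whole-genome bisulfite
sequencing in two tissues (adipose and blood).  Per-site methylation is
generated on a logistic liability scale with additive-genetic (A), shared-
environment (C) and non-shared-environment (E) components, so every
downstream statistic — strand filters, differential CpGs, consistency-scored
regions, twin ICC decompositions, CpH background — has a known ground truth.

Confounders are planted explicitly: SNP-ablated CpGs whose apparent
methylation is genotype-coded, artifact loci with grossly inflated coverage,
blood cell-type-driven sites mixed through per-sample cell fractions, and
incomplete bisulfite conversion that leaves a background of apparently
methylated CpH sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

TISSUES = ("adipose", "blood")
CELL_TYPES = ("neutrophils", "lymphocytes", "monocytes", "eosinophils")

# archetype mixture for per-site (a2, c2, e2): mostly non-shared environment,
# a substantial heritable class, a small shared-environment class
DEFAULT_ACE_ARCHETYPES = (
    (0.60, (0.05, 0.05, 0.90)),
    (0.35, (0.60, 0.05, 0.35)),
    (0.05, (0.10, 0.50, 0.40)),
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical seed + config is bit-reproducible."""

    n_mz_pairs: int = 7
    n_dz_pairs: int = 6
    n_singletons: int = 8
    genome_length: int = 1_000_000
    chrom: str = "chr1"
    n_cpg: int = 2_000
    n_cph: int = 4_000
    mean_coverage: float = 4.0          # reads per site per strand
    baseline_weights: tuple = (0.30, 0.70)   # low / high methylation modes
    baseline_logit_means: tuple = (-3.0, 3.0)
    baseline_logit_sd: float = 0.6
    liability_sd: float = 1.2           # SD of A+C+E when a2+c2+e2 = 1
    ace_archetypes: tuple = DEFAULT_ACE_ARCHETYPES
    snp_fraction: float = 0.01
    blacklist_fraction: float = 0.005
    invariant_zero_fraction: float = 0.08   # truly 0 % CpGs (CGI-core-like)
    invariant_one_fraction: float = 0.12    # truly 100 % CpGs
    artifact_coverage_multiplier: float = 12.0
    conversion_failure_rate: float = 0.006
    celltype_fraction: float = 0.01     # blood cell-type-driven CpGs
    celltype_contrast: tuple = (0.05, 0.95)  # level in other vs driving type
    celltype_target_weights: tuple = (0.45, 0.45, 0.05, 0.05)
    cell_dirichlet_mean: tuple = (0.60, 0.30, 0.07, 0.03)
    cell_dirichlet_conc: float = 20.0
    n_edmr_plants: int = 2              # per tissue, planted in the first MZ pair
    edmr_n_cpg: int = 6
    edmr_logit_effect: float = 3.0
    cph_methylated_fraction: float = 0.004
    cph_cluster_size: int = 4
    negative_binomial_dispersion: float | None = None  # None -> Poisson coverage
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_fraction", "blacklist_fraction", "conversion_failure_rate",
                     "celltype_fraction", "cph_methylated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for w, (a2, c2, e2) in self.ace_archetypes:
            if min(a2, c2, e2) < 0 or a2 + c2 + e2 > 1 + 1e-9:
                raise ValueError(f"ace fractions ({a2},{c2},{e2}) invalid: "
                                 "must be non-negative with a2+c2+e2 <= 1")
        if abs(sum(f for f, _ in self.ace_archetypes) - 1.0) > 1e-9:
            raise ValueError("ace_archetypes weights must sum to 1")
        if not np.isclose(sum(self.cell_dirichlet_mean), 1.0):
            raise ValueError("cell_dirichlet_mean must sum to 1")


@dataclass
class Individual:
    ind_id: str
    pair_id: str | None
    zygosity: str       # MZ / DZ / NA
    member: int         # 0/1 within pair, 0 for singletons


@dataclass
class GroundTruth:
    """Truth tables for every planted feature of a simulated cohort."""

    ace: pd.DataFrame            # site, a2, c2, e2, category
    snp_sites: pd.DataFrame      # chrom, pos, maf
    artifact_loci: pd.DataFrame  # chrom, pos
    celltype_sites: pd.DataFrame  # chrom, pos, cell_type
    edmr_intervals: pd.DataFrame  # chrom, start, end, tissue, pair, direction

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("ace", "snp_sites", "artifact_loci", "celltype_sites",
                     "edmr_intervals"):
            getattr(self, name).to_csv(outdir / f"truth_{name}.tsv",
                                       sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        frames = {}
        for name in ("ace", "snp_sites", "artifact_loci", "celltype_sites",
                     "edmr_intervals"):
            frames[name] = pd.read_csv(outdir / f"truth_{name}.tsv", sep="\t")
        return cls(**frames)


def write_truth(truth: GroundTruth, outdir: str | Path) -> None:
    truth.write(outdir)


def build_individuals(config: SimulationConfig) -> list[Individual]:
    inds = []
    for i in range(config.n_mz_pairs):
        for m in range(2):
            inds.append(Individual(f"MZ{i + 1}{'ab'[m]}", f"MZ{i + 1}", "MZ", m))
    for i in range(config.n_dz_pairs):
        for m in range(2):
            inds.append(Individual(f"DZ{i + 1}{'ab'[m]}", f"DZ{i + 1}", "DZ", m))
    for i in range(config.n_singletons):
        inds.append(Individual(f"S{i + 1}", None, "NA", 0))
    return inds


def sample_ace_fractions(config: SimulationConfig, rng: np.random.Generator,
                         n_sites: int) -> np.ndarray:
    """Draw per-site (a2, c2, e2) triples from the archetype mixture."""
    weights = np.array([w for w, _ in config.ace_archetypes])
    triples = np.array([t for _, t in config.ace_archetypes])
    idx = rng.choice(len(weights), size=n_sites, p=weights)
    return triples[idx]


def simulate_latent_methylation(config: SimulationConfig,
                                rng: np.random.Generator | None = None,
                                ace: np.ndarray | None = None,
                                n_sites: int | None = None,
                                baseline: np.ndarray | None = None,
                                tissues: tuple = TISSUES) -> dict:
    """Simulate per-site, per-individual latent methylation levels in [0,1].

    The liability for individual *j* at site *s* is
    ``baseline_s + A_sj + C_sj + E_sj`` with component variances proportional
    to the site's (a2, c2, e2); A is perfectly correlated within MZ pairs and
    0.5-correlated within DZ pairs, C is shared within a pair, E is drawn
    independently per individual and per tissue.  Levels are the logistic
    transform of the liability.

    Returns a dict with ``individuals``, ``ace``, ``baseline``, and per-tissue
    ``liability`` / ``levels`` arrays of shape (n_sites, n_individuals).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_sites is None:
        n_sites = config.n_cpg
    inds = build_individuals(config)
    n_ind = len(inds)

    if ace is None:
        ace = sample_ace_fractions(config, rng, n_sites)
    else:
        ace = np.asarray(ace, dtype=float)
        if ace.ndim == 1:
            ace = np.tile(ace, (n_sites, 1))
        if np.any(ace.sum(axis=1) > 1 + 1e-9) or np.any(ace < 0):
            raise ValueError("per-site a2+c2+e2 must be <= 1 with all parts >= 0")

    if baseline is None:
        mode = rng.choice(2, size=n_sites, p=np.asarray(config.baseline_weights))
        baseline = (np.asarray(config.baseline_logit_means)[mode]
                    + rng.normal(0.0, config.baseline_logit_sd, size=n_sites))

    sd = config.liability_sd
    a_sd = np.sqrt(ace[:, 0])[:, None] * sd
    c_sd = np.sqrt(ace[:, 1])[:, None] * sd
    e_sd = np.sqrt(ace[:, 2])[:, None] * sd

    # genetic and shared-environment draws are shared across tissues
    a_part = np.zeros((n_sites, n_ind))
    c_part = np.zeros((n_sites, n_ind))
    pair_members: dict[str, list[int]] = {}
    for j, ind in enumerate(inds):
        if ind.pair_id is not None:
            pair_members.setdefault(ind.pair_id, []).append(j)
    singleton_cols = [j for j, ind in enumerate(inds) if ind.pair_id is None]
    for pid, cols in pair_members.items():
        zyg = inds[cols[0]].zygosity
        shared = rng.normal(size=n_sites)
        if zyg == "MZ":
            for j in cols:
                a_part[:, j] = shared
        else:  # DZ: corr(A) = 0.5 via half-shared, half-individual draws
            for j in cols:
                own = rng.normal(size=n_sites)
                a_part[:, j] = np.sqrt(0.5) * shared + np.sqrt(0.5) * own
        c_shared = rng.normal(size=n_sites)
        for j in cols:
            c_part[:, j] = c_shared
    for j in singleton_cols:
        a_part[:, j] = rng.normal(size=n_sites)
        c_part[:, j] = rng.normal(size=n_sites)

    out = {"individuals": inds, "ace": ace, "baseline": baseline}
    for tissue in tissues:
        e_part = rng.normal(size=(n_sites, n_ind))
        liab = (baseline[:, None] + a_sd * a_part + c_sd * c_part
                + e_sd * e_part)
        out[f"liability_{tissue}"] = liab
        out[f"levels_{tissue}"] = _sigmoid(liab)
    return out


def _draw_snp_dosage(config: SimulationConfig, rng: np.random.Generator,
                     inds: list[Individual], n_snp: int) -> tuple[np.ndarray, np.ndarray]:
    """Intact-allele dosage (0/1/2) per SNP site and individual.

    MZ co-twins share the genotype; DZ co-twins each inherit one allele from
    each of two simulated parents; singletons are Hardy-Weinberg draws.
    """
    maf = rng.uniform(0.1, 0.5, size=n_snp)  # frequency of the ablating allele
    n_ind = len(inds)
    dosage = np.zeros((n_snp, n_ind), dtype=int)
    pair_members: dict[str, list[int]] = {}
    for j, ind in enumerate(inds):
        if ind.pair_id is not None:
            pair_members.setdefault(ind.pair_id, []).append(j)

    def hw_draw():
        # counts of intact alleles out of 2
        return (rng.random((n_snp, 2)) > maf[:, None]).sum(axis=1)

    for pid, cols in pair_members.items():
        zyg = inds[cols[0]].zygosity
        if zyg == "MZ":
            g = hw_draw()
            for j in cols:
                dosage[:, j] = g
        else:
            # parental alleles: 1 = intact
            p1 = rng.random((n_snp, 2)) > maf[:, None]
            p2 = rng.random((n_snp, 2)) > maf[:, None]
            for j in cols:
                pick1 = rng.integers(0, 2, size=n_snp)
                pick2 = rng.integers(0, 2, size=n_snp)
                dosage[:, j] = (p1[np.arange(n_snp), pick1].astype(int)
                                + p2[np.arange(n_snp), pick2].astype(int))
    for j, ind in enumerate(inds):
        if ind.pair_id is None:
            dosage[:, j] = hw_draw()
    return dosage, maf


def _coverage(rng: np.random.Generator, mean: float, size,
              dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean, size=size)
    # negative binomial with mean `mean` and dispersion r (var = m + m^2/r)
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


@dataclass
class SimulatedCohort:
    """In-memory result of a full cohort simulation."""

    config: SimulationConfig
    individuals: list[Individual]
    metadata: pd.DataFrame                 # one row per tissue sample
    samples: dict[str, pd.DataFrame]       # sample id -> cytosine records
    truth: GroundTruth
    cpg_pos: np.ndarray
    latent: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        for sid, df in self.samples.items():
            out = df.copy()
            out["pos"] = out["pos"] + 1  # cytosine reports are 1-based
            out.to_csv(outdir / f"{sid}.cytosine_report.txt", sep="\t",
                       index=False, header=False)
        self.truth.write(outdir)
        snp = self.truth.snp_sites
        _write_bed(outdir / "snps.bed",
                   snp["chrom"], snp["pos"], snp["pos"] + 1)
        art = self.truth.artifact_loci
        _write_bed(outdir / "blacklist.bed",
                   art["chrom"], art["pos"], art["pos"] + 2)
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, default=list)


def _write_bed(path, chroms, starts, ends):
    pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}).to_csv(
        path, sep="\t", index=False, header=False)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator: latent levels -> stranded read counts + truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cpg

    # CpG dinucleotide positions (forward-strand C), min spacing 2 bp
    cpg_pos = np.sort(rng.choice(config.genome_length // 2 - 2, size=n,
                                 replace=False)) * 2
    latent = simulate_latent_methylation(config, rng=rng)
    inds = latent["individuals"]
    n_ind = len(inds)

    # planted confounders and static sites: disjoint site categories
    n_snp = int(round(config.snp_fraction * n))
    n_art = int(round(config.blacklist_fraction * n))
    n_cell = int(round(config.celltype_fraction * n))
    n_inv0 = int(round(config.invariant_zero_fraction * n))
    n_inv1 = int(round(config.invariant_one_fraction * n))
    special = rng.choice(n, size=n_snp + n_art + n_cell + n_inv0 + n_inv1,
                         replace=False)
    snp_idx = np.sort(special[:n_snp])
    art_idx = np.sort(special[n_snp:n_snp + n_art])
    cell_idx = np.sort(special[n_snp + n_art:n_snp + n_art + n_cell])
    inv0_idx = np.sort(special[n_snp + n_art + n_cell:
                               n_snp + n_art + n_cell + n_inv0])
    inv1_idx = np.sort(special[n_snp + n_art + n_cell + n_inv0:])

    # static sites: no variance on any scale, exactly 0 or 1
    for tissue in TISSUES:
        latent[f"levels_{tissue}"][inv0_idx] = 0.0
        latent[f"levels_{tissue}"][inv1_idx] = 1.0

    dosage, maf = _draw_snp_dosage(config, rng, inds, n_snp)
    cell_target = rng.choice(len(CELL_TYPES), size=n_cell,
                             p=np.asarray(config.celltype_target_weights))

    # per-sample blood cell fractions
    alpha = np.asarray(config.cell_dirichlet_mean) * config.cell_dirichlet_conc
    cell_fracs = rng.dirichlet(alpha, size=n_ind)

    category = np.full(n, "background", dtype=object)
    category[snp_idx] = "snp"
    category[art_idx] = "artifact"
    category[cell_idx] = "celltype"
    category[inv0_idx] = "invariant_zero"
    category[inv1_idx] = "invariant_one"

    # planted within-MZ-pair environmental DMRs (first MZ pair, member 0 up)
    edmr_rows = []
    edmr_shift = {t: np.zeros((n, n_ind)) for t in TISSUES}
    if config.n_mz_pairs >= 1 and config.n_edmr_plants > 0:
        target_cols = [j for j, ind in enumerate(inds) if ind.pair_id == "MZ1"]
        bg_idx = np.flatnonzero(category == "background")
        for tissue in TISSUES:
            for k in range(config.n_edmr_plants):
                # a run of consecutive background CpGs
                ok = False
                for _ in range(50):
                    s0 = rng.integers(0, n - config.edmr_n_cpg)
                    run = np.arange(s0, s0 + config.edmr_n_cpg)
                    if np.all(np.isin(run, bg_idx)):
                        ok = True
                        break
                if not ok:
                    continue
                direction = 1 if rng.random() < 0.5 else -1
                edmr_shift[tissue][run, target_cols[0]] = (
                    direction * config.edmr_logit_effect)
                edmr_rows.append({
                    "chrom": config.chrom,
                    "start": int(cpg_pos[run[0]]),
                    "end": int(cpg_pos[run[-1]] + 2),
                    "tissue": tissue, "pair": "MZ1",
                    "direction": "up" if direction > 0 else "down"})

    # CpH sites: strand-specific, mostly unmethylated (conversion background)
    cph = _simulate_cph_sites(config, rng, cpg_pos, latent)

    samples: dict[str, pd.DataFrame] = {}
    meta_rows = []

    for tissue in TISSUES:
        if np.any(edmr_shift[tissue]):
            with np.errstate(divide="ignore"):  # exact 0/1 static sites
                logit = np.log(latent[f"levels_{tissue}"]
                               / (1 - latent[f"levels_{tissue}"]))
            levels = _sigmoid(logit + edmr_shift[tissue])
        else:
            levels = latent[f"levels_{tissue}"]
        for j, ind in enumerate(inds):
            sid = f"{ind.ind_id}_{tissue}"
            lvl = levels[:, j].copy()

            if tissue == "blood" and n_cell:
                # cell-type-driven sites: full cell-specific contrast mixed
                # through the sample's cell fractions
                lo, hi = config.celltype_contrast
                mixed = np.zeros(n_cell)
                for c in range(len(CELL_TYPES)):
                    lv = np.where(cell_target == c, hi, lo)
                    mixed += cell_fracs[j, c] * lv
                lvl[cell_idx] = mixed

            # SNP sites: reads from ablated alleles report unmethylated
            if n_snp:
                lvl[snp_idx] = (dosage[:, j] / 2.0) * lvl[snp_idx]

            p_read = lvl + (1 - lvl) * config.conversion_failure_rate

            cov_f = _coverage(rng, config.mean_coverage, n,
                              config.negative_binomial_dispersion)
            cov_r = _coverage(rng, config.mean_coverage, n,
                              config.negative_binomial_dispersion)
            if n_art:
                # inflated far past mean + 5 SD of the Poisson background
                art_mean = (config.artifact_coverage_multiplier
                            * config.mean_coverage)
                cov_f[art_idx] = rng.poisson(art_mean, size=n_art)
                cov_r[art_idx] = rng.poisson(art_mean, size=n_art)
            meth_f = rng.binomial(cov_f, p_read)
            meth_r = rng.binomial(cov_r, p_read)

            cpg_df = pd.DataFrame({
                "chrom": config.chrom,
                "pos": np.concatenate([cpg_pos, cpg_pos + 1]),
                "strand": ["+"] * n + ["-"] * n,
                "meth": np.concatenate([meth_f, meth_r]),
                "unmeth": np.concatenate([cov_f - meth_f, cov_r - meth_r]),
                "context": "CG",
                "trinucleotide": "CGN",
            })
            cph_df = _emit_cph_counts(config, rng, cph)
            df = pd.concat([cpg_df, cph_df], ignore_index=True)
            df = df.sort_values(["pos", "strand"], kind="mergesort",
                                ignore_index=True)
            samples[sid] = df

            row = {"sample": sid, "individual": ind.ind_id, "tissue": tissue,
                   "pair": ind.pair_id if ind.pair_id else "NA",
                   "zygosity": ind.zygosity,
                   "mean_coverage": float(2 * config.mean_coverage)}
            if tissue == "blood":
                for c, name in enumerate(CELL_TYPES):
                    row[name] = float(cell_fracs[j, c])
            meta_rows.append(row)

    truth = GroundTruth(
        ace=pd.DataFrame({"chrom": config.chrom, "pos": cpg_pos,
                          "a2": latent["ace"][:, 0], "c2": latent["ace"][:, 1],
                          "e2": latent["ace"][:, 2], "category": category}),
        snp_sites=pd.DataFrame({"chrom": config.chrom, "pos": cpg_pos[snp_idx],
                                "maf": maf}),
        artifact_loci=pd.DataFrame({"chrom": config.chrom,
                                    "pos": cpg_pos[art_idx]}),
        celltype_sites=pd.DataFrame({
            "chrom": config.chrom, "pos": cpg_pos[cell_idx],
            "cell_type": [CELL_TYPES[c] for c in cell_target]}),
        edmr_intervals=pd.DataFrame(
            edmr_rows, columns=["chrom", "start", "end", "tissue", "pair",
                                "direction"]),
    )
    metadata = pd.DataFrame(meta_rows)
    return SimulatedCohort(config=config, individuals=inds, metadata=metadata,
                           samples=samples, truth=truth, cpg_pos=cpg_pos,
                           latent=latent)


def _simulate_cph_sites(config, rng, cpg_pos, latent):
    """CpH site map: positions, strands, contexts, true levels.

    Background CpHs are truly unmethylated (their apparent signal is
    conversion failure only); a small planted fraction is genuinely
    methylated, laid out in clusters next to highly methylated CpGs to
    emulate the CpG-proximal, clustered character of somatic non-CpG
    methylation.
    """
    n_bg = config.n_cph
    n_meth = int(round(config.cph_methylated_fraction * n_bg))
    occupied = set(cpg_pos.tolist()) | set((cpg_pos + 1).tolist())

    bg_pos: list[int] = []
    while len(bg_pos) < n_bg:
        cand = rng.integers(0, config.genome_length, size=n_bg)
        for p in cand:
            if p not in occupied:
                occupied.add(int(p))
                bg_pos.append(int(p))
                if len(bg_pos) == n_bg:
                    break

    meth_pos: list[int] = []
    if n_meth:
        mean_cpg = latent["levels_adipose"].mean(axis=1)
        high = np.flatnonzero(mean_cpg >= 0.5)
        n_clusters = max(1, round(n_meth / config.cph_cluster_size))
        anchors = rng.choice(high, size=min(n_clusters, len(high)),
                             replace=False)
        for a in anchors:
            offsets = rng.integers(-250, 251, size=config.cph_cluster_size)
            for off in offsets:
                p = int(cpg_pos[a] + off)
                if 0 <= p < config.genome_length and p not in occupied:
                    occupied.add(p)
                    meth_pos.append(p)
                if len(meth_pos) >= n_meth:
                    break
            if len(meth_pos) >= n_meth:
                break

    pos = np.array(sorted(bg_pos + meth_pos))
    level = np.zeros(len(pos))
    if meth_pos:
        planted = np.isin(pos, np.array(meth_pos))
        level[planted] = rng.uniform(0.7, 0.95, size=int(planted.sum()))

    n_cph = len(pos)
    strand = np.where(rng.random(n_cph) < 0.5, "+", "-")
    # dinucleotide mix CpA > CpT > CpC; trinucleotide ~1/3 CpHpG, 2/3 CpHpH
    h = rng.choice(list("ACT"), size=n_cph, p=[0.5, 0.2, 0.3])
    is_chg = rng.random(n_cph) < (1 / 3)
    third = np.where(is_chg, "G", rng.choice(list("ACT"), size=n_cph))
    context = np.where(is_chg, "CHG", "CHH")
    tri = np.char.add(np.char.add("C", h.astype(str)), third.astype(str))
    return {"pos": pos, "strand": strand, "context": context, "tri": tri,
            "level": level}


def _emit_cph_counts(config, rng, cph):
    p_read = cph["level"] + (1 - cph["level"]) * config.conversion_failure_rate
    cov = _coverage(rng, config.mean_coverage, len(cph["pos"]),
                    config.negative_binomial_dispersion)
    meth = rng.binomial(cov, p_read)
    return pd.DataFrame({
        "chrom": config.chrom, "pos": cph["pos"], "strand": cph["strand"],
        "meth": meth, "unmeth": cov - meth, "context": cph["context"],
        "trinucleotide": cph["tri"]})
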