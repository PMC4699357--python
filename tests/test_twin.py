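"""ICC/ACE decomposition, eDMC/eDMR calling, permutation FDR and drift."""

import numpy as np
import pandas as pd
import pytest

from popmeth import io, twin
from popmeth.simulate import SimulationConfig, simulate_cohort, \
    simulate_latent_methylation

from conftest import units_from_counts


class TestIcc:
    def test_zero_within_pair_variance_gives_one(self):
        pairs = np.array([[0.2, 0.2], [0.8, 0.8], [0.5, 0.5]])
        assert twin.icc(pairs) == pytest.approx(1.0)

    def test_shuffled_members_near_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.random(2000)
        pairs = vals.reshape(-1, 2)  # unrelated members
        assert abs(twin.icc(pairs)) < 0.1

    def test_matches_mean_squares_oracle(self):
        pairs = np.array([[0.1, 0.3], [0.5, 0.4], [0.9, 0.7],
                          [0.2, 0.2], [0.6, 0.8]])
        n, k = pairs.shape
        grand = pairs.mean()
        msb = k * ((pairs.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msw = ((pairs - pairs.mean(axis=1, keepdims=True)) ** 2).sum() / n
        assert twin.icc(pairs) == pytest.approx((msb - msw) / (msb + msw))

    def test_matches_pingouin_icc1(self):
        """Cross-check against an independent ICC implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        pairs = rng.random((12, 2))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile([0, 1], 12),
            "ratings": pairs.ravel()})
        ref = pingouin.intraclass_corr(df, targets="targets",
                                       raters="raters", ratings="ratings")
        icc1 = ref[ref["Type"] == "ICC(1,1)"]["ICC"].iloc[0]
        assert twin.icc(pairs) == pytest.approx(icc1, abs=1e-6)

    def test_undefined_cases(self):
        assert np.isnan(twin.icc(np.array([[0.5, 0.5]])))  # one pair
        assert np.isnan(twin.icc(np.full((4, 2), 0.3)))    # zero variance


class TestAceFormulas:
    @pytest.mark.parametrize("icc_mz,icc_dz,expected", [
        (1.0, 0.5, (1.0, 0.0, 0.0)),
        (0.4, 0.4, (0.0, 0.4, 0.6)),
        (0.6, 0.4, (0.4, 0.2, 0.4)),
    ])
    def test_falconer_estimates(self, icc_mz, icc_dz, expected):
        d = twin.VarianceDecomposition(icc_mz, icc_dz, 5, 5)
        assert (d.h2, d.c2, d.e2) == pytest.approx(expected)

    def test_identity_holds_exactly_even_when_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            mz, dz = rng.uniform(-1, 1, 2)
            d = twin.VarianceDecomposition(mz, dz, 5, 5)
            assert d.h2 + d.c2 + d.e2 == pytest.approx(1.0, abs=1e-12)

    def test_parameter_recovery_on_latent_cohort(self):
        """mean (h2, c2, e2) estimates within +/-0.1 of the generating
        fractions at 200 pairs per group."""
        a2, c2, e2 = 0.6, 0.1, 0.3
        cfg = SimulationConfig(n_mz_pairs=200, n_dz_pairs=200,
                               n_singletons=0, seed=9)
        lat = simulate_latent_methylation(cfg, ace=np.array([a2, c2, e2]),
                                          n_sites=400, tissues=("adipose",))
        inds = lat["individuals"]
        liab = lat["liability_adipose"]
        cols = {}
        for j, ind in enumerate(inds):
            cols.setdefault(ind.pair_id, []).append(j)
        mz = [c for p, c in cols.items() if p.startswith("MZ")]
        dz = [c for p, c in cols.items() if p.startswith("DZ")]
        h2s, c2s, e2s = [], [], []
        for i in range(liab.shape[0]):
            d = twin.VarianceDecomposition(
                twin.icc(liab[i][np.array(mz)]),
                twin.icc(liab[i][np.array(dz)]), 200, 200)
            h2s.append(d.h2)
            c2s.append(d.c2)
            e2s.append(d.e2)
        assert np.mean(h2s) == pytest.approx(a2, abs=0.1)
        assert np.mean(c2s) == pytest.approx(c2, abs=0.1)
        assert np.mean(e2s) == pytest.approx(e2, abs=0.1)

    def test_ace_decompose_matrix_path(self, small_cohort, adipose_units):
        m = io.build_population_matrix(adipose_units, min_detected=3)
        dec = twin.ace_decompose(m, small_cohort.metadata, min_pairs=3)
        if len(dec):
            assert np.allclose(dec["h2"] + dec["c2"] + dec["e2"], 1.0)
            s = twin.ace_summary(dec)
            assert 0 <= s["frac_e2_gt_0.9"] <= 1


class TestEdmc:
    def make_pair(self, rows_a, rows_b):
        return (units_from_counts(rows_a), units_from_counts(rows_b))

    def test_identical_counts_no_edmc(self):
        a, b = self.make_pair([("chr1", 100, 5, 5, 5, 5)],
                              [("chr1", 100, 5, 5, 5, 5)])
        out = twin.call_edmc(a, b)
        assert not out["edmc"].any()

    def test_extreme_difference_called_with_direction(self):
        a, b = self.make_pair([("chr1", 100, 10, 0, 10, 0)],
                              [("chr1", 100, 0, 10, 0, 10)])
        out = twin.call_edmc(a, b)
        assert out.iloc[0]["edmc"]
        assert out.iloc[0]["direction"] == "a_higher"
        assert out.iloc[0]["p"] < 1e-8

    def test_flags_match_sitewise_recount(self, small_cohort, adipose_units):
        sids = ["MZ1a_adipose", "MZ1b_adipose"]
        a, b = adipose_units[sids[0]], adipose_units[sids[1]]
        out = twin.call_edmc(a, b)
        from popmeth.variability import fisher_dmc
        for _, row in out.sample(n=min(50, len(out)),
                                 random_state=1).iterrows():
            p, _ = fisher_dmc(int(row["meth_a"]),
                              int(row["cov_a"] - row["meth_a"]),
                              int(row["meth_b"]),
                              int(row["cov_b"] - row["meth_b"]))
            assert row["edmc"] == (p < 0.05)


class TestEdmr:
    def edmcs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "direction",
                                           "edmc"])

    def test_two_edmcs_insufficient(self):
        e = self.edmcs([("chr1", 100, "a_higher", True),
                        ("chr1", 200, "a_higher", True)])
        assert len(twin.call_edmr(e)) == 0

    def test_three_same_direction_one_edmr(self):
        e = self.edmcs([("chr1", 100, "a_higher", True),
                        ("chr1", 200, "a_higher", True),
                        ("chr1", 300, "a_higher", True)])
        out = twin.call_edmr(e)
        assert len(out) == 1
        assert out.iloc[0]["n_edmc"] == 3

    def test_mixed_direction_no_edmr(self):
        e = self.edmcs([("chr1", 100, "a_higher", True),
                        ("chr1", 200, "b_higher", True),
                        ("chr1", 300, "a_higher", True)])
        assert len(twin.call_edmr(e)) == 0

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(100_000, 50, replace=False))
        e = self.edmcs([("chr1", int(p), "a_higher", True) for p in pos])
        base = twin.call_edmr(e)
        shifted = self.edmcs([("chr1", int(p) + 777, "a_higher", True)
                              for p in pos])
        out = twin.call_edmr(shifted)
        assert (out["start"] - base["start"] == 777).all()
        assert (out["end"] - base["end"] == 777).all()


class TestPermutationFdr:
    def site_map(self, n=5000, span=2_500_000, seed=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "chrom": "chr1",
            "pos": np.sort(rng.choice(span, n, replace=False))})

    def test_planted_cluster_low_fdr(self):
        sites = self.site_map()
        rng = np.random.default_rng(5)
        scatter = rng.choice(sites["pos"], 80, replace=False)
        cluster = sites["pos"].iloc[100:110].to_numpy()  # dense run
        edmcs = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.concatenate([scatter, cluster]),
            "direction": "a_higher", "edmc": True})
        out = twin.edmr_permutation_fdr(edmcs, sites, n_perm=200, seed=6)
        assert out["fdr"] < 0.05

    def test_null_scatter_fdr_near_one(self):
        """eDMCs uniform over a dense site map: clusters arise by chance at
        the same rate in data and permutations."""
        sites = self.site_map(n=2000, span=400_000, seed=7)
        rng = np.random.default_rng(8)
        pos = rng.choice(sites["pos"], 400, replace=False)
        edmcs = pd.DataFrame({"chrom": "chr1", "pos": pos,
                              "direction": rng.choice(
                                  ["a_higher", "b_higher"], 400),
                              "edmc": True})
        out = twin.edmr_permutation_fdr(edmcs, sites, n_perm=200, seed=9)
        assert 0.4 <= out["fdr"] <= 2.5

    def test_fixed_seed_reproducible(self):
        sites = self.site_map(n=1000, span=200_000, seed=10)
        rng = np.random.default_rng(11)
        pos = rng.choice(sites["pos"], 200, replace=False)
        edmcs = pd.DataFrame({"chrom": "chr1", "pos": pos,
                              "direction": "a_higher", "edmc": True})
        a = twin.edmr_permutation_fdr(edmcs, sites, n_perm=50, seed=12)
        b = twin.edmr_permutation_fdr(edmcs, sites, n_perm=50, seed=12)
        assert a == b


class TestExactBinomial:
    def test_all_successes_closed_form(self):
        assert twin.exact_binomial_two_sided(10, 10) == \
            pytest.approx(2 / 1024)

    def test_balanced_count_is_one(self):
        assert twin.exact_binomial_two_sided(5, 10) == pytest.approx(1.0)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            twin.exact_binomial_two_sided(3, 0)


class TestDrift:
    def drift_units(self, a2, seed, mean_coverage=12.0):
        cfg = SimulationConfig(
            n_mz_pairs=2, n_dz_pairs=0, n_singletons=0, n_cpg=400, n_cph=10,
            mean_coverage=mean_coverage, snp_fraction=0.0,
            blacklist_fraction=0.0, celltype_fraction=0.0, n_edmr_plants=0,
            ace_archetypes=((1.0, (a2, 0.0, 1.0 - a2)),), seed=seed)
        cohort = simulate_cohort(cfg)
        units = {}
        for _, row in cohort.metadata.iterrows():
            member = 0 if row["individual"].endswith("a") else 1
            units[(row["pair"], row["tissue"], member)] = \
                io.pair_strands(cohort.samples[row["sample"]])
        return units

    def test_genetic_limit_concordant(self):
        """With almost fully genetic variation, inter-pair differences are
        shared across tissues: concordance near 1, binomial p tiny."""
        units = self.drift_units(a2=0.97, seed=13)
        out = twin.drift_analysis(units)
        assert out["n_tested"] > 10
        assert out["concordant_fraction"] > 0.9
        assert out["binomial_p"] < 1e-3

    def test_pure_environment_near_half(self):
        units = self.drift_units(a2=0.0, seed=14)
        out = twin.drift_analysis(units)
        if out["n_tested"] >= 20:
            assert abs(out["concordant_fraction"] - 0.5) < 0.25
            assert out["binomial_p"] > 1e-4
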