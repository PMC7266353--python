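"""Statistics: IBD, ancestry fractions, mutations, SFS, LD."""

import numpy as np
import pandas as pd
import pytest

from wfcoal.demography import DemographicModel, Population, Pulse, SimConfig
from wfcoal.dtwf import run_dtwf
from wfcoal.genome import ConfigurationError, GeneticMap
from wfcoal.hudson import run_hudson
from wfcoal.stats import (ancestry_fractions, drop_mutations, extract_ibd,
                          ibd_grid_scan, lineage_counts, pairwise_r2, sfs)

from conftest import make_config


class TestLineageCounts:
    def test_generation_zero_equals_samples(self, two_chrom_map):
        g = run_dtwf(make_config(12, two_chrom_map, n=20, seed=1))
        tr = lineage_counts(g)
        assert tr.iloc[0].generation == 0
        assert tr.iloc[0].lineages == 12

    def test_requires_trace(self, point_map):
        g = run_hudson(make_config(2, point_map, n=10, seed=1,
                                   record_lineage_counts=False))
        with pytest.raises(ConfigurationError):
            lineage_counts(g)


class TestExtractIBD:
    def test_two_samples_one_chromosome(self, point_map):
        gm = GeneticMap((1.0,))
        g = run_dtwf(make_config(2, gm, n=1, seed=4))  # coalesce immediately
        rec, summ = extract_ibd(g, max_gen=5, min_cm=0.0)
        assert summ.total_cm.iloc[0] == pytest.approx(100.0)
        assert rec.tmrca.min() >= 1

    def test_min_cm_filter(self, two_chrom_map):
        g = run_dtwf(make_config(8, two_chrom_map, n=15, seed=5))
        rec_all, _ = extract_ibd(g, max_gen=30, min_cm=0.0)
        rec_5, _ = extract_ibd(g, max_gen=30, min_cm=5.0)
        assert (rec_5.length_cm >= 5.0).all()
        assert len(rec_5) <= len(rec_all)
        kept = rec_all[rec_all.length_cm >= 5.0]
        assert len(kept) == len(rec_5)

    def test_max_gen_must_be_positive(self, two_chrom_map):
        g = run_dtwf(make_config(4, two_chrom_map, n=15, seed=5))
        with pytest.raises(ConfigurationError):
            extract_ibd(g, max_gen=0)

    def test_symmetry_and_pair_order(self, two_chrom_map):
        g = run_dtwf(make_config(8, two_chrom_map, n=15, seed=6))
        rec, _ = extract_ibd(g, max_gen=20, min_cm=0.0)
        assert (rec.sample_a < rec.sample_b).all()

    def test_pair_total_bounded_by_genome(self, two_chrom_map):
        g = run_dtwf(make_config(8, two_chrom_map, n=15, seed=7))
        _, summ = extract_ibd(g, max_gen=50, min_cm=0.0)
        assert (summ.total_cm <= 100 * two_chrom_map.total_length + 1e-6).all()

    def test_pair_intervals_non_overlapping(self, two_chrom_map):
        g = run_dtwf(make_config(8, two_chrom_map, n=15, seed=8))
        rec, _ = extract_ibd(g, max_gen=50, min_cm=0.0)
        for _, grp in rec.groupby(["sample_a", "sample_b"]):
            grp = grp.sort_values("left")
            assert (grp.left.to_numpy()[1:] >= grp.right.to_numpy()[:-1] - 1e-12).all()

    @pytest.mark.parametrize("model_fn", [run_hudson, run_dtwf])
    def test_matches_grid_scan_oracle(self, model_fn, two_chrom_map):
        """extract_ibd equals the brute-force per-interval MRCA scan."""
        for seed in range(4):
            g = model_fn(make_config(6, two_chrom_map, n=30, seed=seed))
            rec, _ = extract_ibd(g, max_gen=40, min_cm=0.0)
            oracle = ibd_grid_scan(g, max_gen=40)
            glen = np.array([g.map.genetic_length(l, r, g.spacer)
                             for l, r in zip(oracle.left, oracle.right)])
            oracle = oracle[glen > 1e-12].reset_index(drop=True)
            a = rec[["sample_a", "sample_b", "left", "right", "mrca", "tmrca"]]
            assert len(a) == len(oracle)
            assert np.allclose(a[["left", "right", "tmrca"]].to_numpy(),
                               oracle[["left", "right", "tmrca"]].to_numpy())
            assert (a.mrca.to_numpy() == oracle.mrca.to_numpy()).all()


def _pulse_config(model, g, f, n_samples=40, n=60, seed=1, gmap=None):
    gmap = gmap or GeneticMap((1.0, 0.8), hudson_spacer=0.3)
    demog = DemographicModel(
        populations=(Population(n), Population(n)),
        events=(Pulse(time=g, dest=0, source=1, fraction=f),))
    return SimConfig(samples={0: n_samples}, map=gmap, demography=demog,
                     seed=seed, model=model, end_time=g,
                     record_lineage_counts=False)


class TestAncestryFractions:
    @pytest.mark.parametrize("f,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_fractions(self, f, expected):
        g = run_dtwf(_pulse_config("dtwf", 3.0, f))
        fr, var = ancestry_fractions(g, 3.0, migrant_population=1)
        assert np.allclose(fr.to_numpy(), expected)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_fractions_in_unit_interval_and_mean_near_f(self):
        vals = []
        for seed in range(30):
            g = run_dtwf(_pulse_config("dtwf", 2.0, 0.3, seed=seed))
            fr, _ = ancestry_fractions(g, 2.0, migrant_population=1)
            assert ((fr >= 0) & (fr <= 1)).all()
            vals.append(fr.mean())
        # cohort mean is an unbiased estimator of f; the per-replicate
        # spread is dominated by the few migrant coins at small N
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.3) < 3.5 * se + 0.01

    def test_missing_census_raises(self, two_chrom_map):
        g = run_dtwf(make_config(4, two_chrom_map, n=20, seed=1))
        with pytest.raises(ConfigurationError):
            ancestry_fractions(g, 3.0, 1)

    def test_hudson_census_also_works(self):
        g = run_hudson(_pulse_config("hudson", 2.0, 0.3))
        fr, var = ancestry_fractions(g, 2.0, migrant_population=1)
        assert ((fr >= 0) & (fr <= 1)).all()
        assert 0.0 < var < 0.3 * 0.7


class TestMutationsSFS:
    def test_zero_rate_empty(self, two_chrom_map):
        g = run_dtwf(make_config(4, two_chrom_map, n=20, seed=2))
        sites = drop_mutations(g, 0.0, np.random.default_rng(0))
        assert len(sites) == 0
        assert sfs(sites, 4).sum() == 0

    def test_n2_all_singletons_and_pi(self, point_map):
        """n=2: every variant is a singleton; E[pi] = 4 N mu L."""
        gm = GeneticMap((0.01,))
        mu, n_pop = 2.0, 200
        pis = []
        for seed in range(150):
            g = run_hudson(make_config(2, gm, n=n_pop, seed=seed,
                                       record_lineage_counts=False))
            sites = drop_mutations(g, mu, np.random.default_rng(seed))
            if len(sites):
                assert (sites["count"] == 1).all()
            pis.append(len(sites))
        expected = 4 * n_pop * mu * 0.01
        assert np.mean(pis) == pytest.approx(expected, rel=0.15)

    def test_segregating_sites_match_branch_mass(self, two_chrom_map):
        g = run_dtwf(make_config(10, two_chrom_map, n=20, seed=3))
        times = g.nodes.time.to_numpy()
        mass = sum(g.map.genetic_length(l, r, g.spacer) * (times[p] - times[c])
                   for l, r, p, c in zip(g.edges.left, g.edges.right,
                                         g.edges.parent, g.edges.child))
        mu = 0.5
        counts = [len(drop_mutations(g, mu, np.random.default_rng(s)))
                  for s in range(60)]
        assert np.mean(counts) == pytest.approx(mu * mass, rel=0.1)

    def test_sfs_histogram(self):
        sites = pd.DataFrame({"count": [1, 1, 2, 3, 1],
                              "position": np.arange(5) * 0.1,
                              "chromosome": 0, "node": 0,
                              "carriers": [(0,)] * 5})
        out = sfs(sites, 4)
        assert list(out) == [3, 1, 1]


class TestPairwiseR2:
    def _fake_sites(self, geno, positions, chroms):
        rows = []
        for i in range(geno.shape[0]):
            carriers = tuple(np.nonzero(geno[i])[0])
            rows.append((positions[i], chroms[i], 0, len(carriers), carriers))
        return pd.DataFrame(rows, columns=["position", "chromosome", "node",
                                           "count", "carriers"])

    def _geneal(self, n):
        gm = GeneticMap((1.0, 1.0))
        return run_dtwf(make_config(n, gm, n=10, seed=1))

    def test_monomorphic_empty(self):
        g = self._geneal(4)
        sites = self._fake_sites(np.zeros((0, 4)), [], [])
        out = pairwise_r2(sites, g, [0, 1])
        assert len(out) == 0

    def test_perfect_ld_r2_one(self):
        g = self._geneal(4)
        geno = np.array([[1, 1, 0, 0], [1, 1, 0, 0]])
        sites = self._fake_sites(geno, [0.1, 0.2], [0, 0])
        out = pairwise_r2(sites, g, [0, 1])
        assert out.mean_r2.iloc[0] == pytest.approx(1.0)

    def test_independent_sites_mean_r2_one_over_n(self):
        """Two unlinked fair-coin sites over n haplotypes: E[r^2] ~ 1/n."""
        rng = np.random.default_rng(0)
        n = 40
        g = self._geneal(n)
        vals = []
        for _ in range(600):
            geno = rng.integers(0, 2, size=(2, n)).astype(float)
            if geno[0].std() == 0 or geno[1].std() == 0:
                continue
            sites = self._fake_sites(geno, [0.1, 1.5], [0, 1])
            out = pairwise_r2(sites, g, [0, 0.5])
            vals.append(out.mean_r2.iloc[0])
        assert np.mean(vals) == pytest.approx(1.0 / n, rel=0.2)

    def test_cross_chromosome_binned_unlinked(self):
        g = self._geneal(4)
        geno = np.array([[1, 0, 0, 1], [1, 1, 0, 0]])
        sites = self._fake_sites(geno, [0.5, 1.5], [0, 1])
        out = pairwise_r2(sites, g, [0, 1])
        assert np.isinf(out.bin_left.iloc[0])
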