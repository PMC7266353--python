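"""Discrete Wright-Fisher engine: meiosis laws, caps, TMRCA, hybrid."""

import numpy as np
import pytest
from scipy import stats as sps

from wfcoal.core import Lineage
from wfcoal.demography import DemographicModel, Population, Pulse, SimConfig
from wfcoal.dtwf import draw_meiosis, run_dtwf, run_hybrid, split_by_meiosis
from wfcoal.genome import GeneticMap
from wfcoal.hudson import run_hudson

from conftest import make_config


class TestDrawMeiosis:
    def test_zero_span(self):
        gm = GeneticMap((1.0,))
        d = draw_meiosis((0.3, 0.3), gm, np.random.default_rng(0))
        assert d.breakpoints.size == 0

    def test_poisson_breakpoint_count(self):
        gm = GeneticMap((2.5,))
        rng = np.random.default_rng(1)
        counts = [draw_meiosis((0.0, 2.5), gm, rng).breakpoints.size
                  for _ in range(4000)]
        counts = np.asarray(counts)
        assert counts.mean() == pytest.approx(2.5, rel=0.05)
        # chi-square against Poisson(2.5)
        kmax = 9
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = sps.poisson(2.5).pmf(np.arange(kmax))
        pmf = np.append(pmf, 1 - pmf.sum())
        chi = sps.chisquare(obs, 4000 * pmf)
        assert chi.pvalue > 0.01

    def test_phase_fair_coin(self):
        gm = GeneticMap((1.0,))
        rng = np.random.default_rng(2)
        phases = [draw_meiosis((0.0, 1.0), gm, rng).phase for _ in range(4000)]
        p = sps.binomtest(sum(phases), 4000, 0.5).pvalue
        assert p > 0.01

    def test_boundaries_only_inside_span(self):
        gm = GeneticMap((1.0, 1.0, 1.0))
        rng = np.random.default_rng(3)
        d = draw_meiosis((0.5, 1.5), gm, rng)
        assert list(d.boundaries) == [1.0]


class TestSplitByMeiosis:
    def _draw(self, bps, phase, boundaries=(), coins=()):
        from wfcoal.dtwf import MeiosisDraw
        return MeiosisDraw(np.asarray(bps, dtype=float), phase,
                           np.asarray(boundaries, dtype=float),
                           np.asarray(coins, dtype=int))

    def test_no_breakpoints_all_to_phase(self):
        lin = Lineage([(0.0, 1.0, 5)], 0)
        a, b = split_by_meiosis(lin, self._draw([], 0))
        assert a == [(0.0, 1.0, 5)] and b == []

    def test_single_breakpoint_alternation(self):
        lin = Lineage([(0.0, 1.0, 5)], 0)
        a, b = split_by_meiosis(lin, self._draw([0.5], 0))
        assert a == [(0.0, 0.5, 5)] and b == [(0.5, 1.0, 5)]

    def test_union_equals_input_no_duplication(self):
        rng = np.random.default_rng(4)
        gm = GeneticMap((1.0, 1.0))
        for _ in range(50):
            segs = sorted(rng.uniform(0, 2, size=6))
            lin = Lineage([(segs[0], segs[1], 1), (segs[2], segs[3], 2),
                           (segs[4], segs[5], 3)], 0)
            d = draw_meiosis((lin.left, lin.right), gm, rng)
            a, b = split_by_meiosis(lin, d)
            got = sorted(a + b)
            merged = []
            for l, r, node in got:
                if merged and merged[-1][1] == l and merged[-1][2] == node:
                    merged[-1] = (merged[-1][0], r, node)
                else:
                    merged.append((l, r, node))
            assert merged == lin.segs

    def test_independent_assortment_quarter_each(self):
        """Two chromosomes, no crossovers: the four haplotype assignments
        are equally likely."""
        gm = GeneticMap((1.0, 1.0))
        rng = np.random.default_rng(5)
        lin = Lineage([(0.0, 2.0, 0)], 0)
        counts = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}
        n = 4000
        for _ in range(n):
            d = self._draw([], int(rng.integers(2)), [1.0], [int(rng.integers(2))])
            a, b = split_by_meiosis(lin, d)
            first = 0 if any(l < 1.0 for l, r, _ in a) else 1
            second = 0 if any(r > 1.0 for l, r, _ in a) else 1
            counts[(first, second)] += 1
        chi = sps.chisquare(list(counts.values()))
        assert chi.pvalue > 0.01


class TestDTWFGeneration:
    def test_single_parent_coalescence_rate(self, point_map):
        """N=1: two lineages coalesce per generation w.p. 1/2;
        mean coalescence time ~ geometric mean 2."""
        times = [run_dtwf(make_config(2, point_map, n=1, seed=s,
                                      record_lineage_counts=False)).nodes.time.max()
                 for s in range(1000)]
        assert np.mean(times) == pytest.approx(2.0, rel=0.1)

    def test_geometric_tmrca(self, point_map):
        n_pop = 100
        times = np.asarray([
            run_dtwf(make_config(2, point_map, n=n_pop, seed=s,
                                 record_lineage_counts=False)).nodes.time.max()
            for s in range(1200)], dtype=int)
        p = 1.0 / (2 * n_pop)
        assert times.mean() == pytest.approx(1 / p, rel=0.1)
        kmax = int(np.quantile(times, 0.95))
        edges = np.linspace(1, kmax, 12).astype(int)
        obs, _ = np.histogram(times, bins=np.append(edges, 10 ** 9))
        geo = sps.geom(p)
        exp = np.diff(np.append(geo.cdf(edges - 1), 1.0)) * times.size
        chi = sps.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi.pvalue > 0.01

    def test_all_node_times_integers(self, two_chrom_map):
        g = run_dtwf(make_config(5, two_chrom_map, n=30, seed=7))
        times = g.nodes.time.to_numpy()
        assert np.allclose(times, np.round(times))

    def test_lineage_count_capped_and_coalesces(self, two_chrom_map):
        """Counts may grow (meiosis spreads one genome over two parental
        haplotypes) but never beyond 2N, and reach 0 at the grand MRCA."""
        for seed in range(3):
            cfg = make_config(40, two_chrom_map, n=30, seed=seed)
            g = run_dtwf(cfg)
            counts = g.trace.lineages.to_numpy()
            assert np.all(counts[1:] <= 2 * 30)
            assert counts[-1] <= 1

    def test_single_lineage_stops(self, point_map):
        g = run_dtwf(make_config(1, point_map, n=10, seed=1))
        assert g.num_nodes == 1
        assert len(g.edges) == 0

    def test_same_seed_identical_tables(self, two_chrom_map):
        g1 = run_dtwf(make_config(6, two_chrom_map, n=25, seed=11))
        g2 = run_dtwf(make_config(6, two_chrom_map, n=25, seed=11))
        assert g1.nodes.equals(g2.nodes) and g1.edges.equals(g2.edges)

    def test_half_sib_whole_genome_ibd_cluster(self, human22):
        """Small N: pairs sharing a parent exist and share IBD across the
        whole genome (the isolated high-sharing cluster)."""
        from wfcoal.stats import extract_ibd
        cfg = make_config(30, human22, n=50, seed=2, end_time=1.0,
                          record_lineage_counts=False)
        g = run_dtwf(cfg)
        rec, summ = extract_ibd(g, max_gen=1, min_cm=0.0)
        assert len(summ) > 0
        top = summ.total_cm.max()
        # a same-parent pair shares about half the genome
        assert top > 0.3 * 100 * human22.total_length


class TestHybrid:
    def test_switch_time_zero_is_hudson(self, point_map):
        times_h = [run_hudson(make_config(2, point_map, n=80, seed=s,
                                          record_lineage_counts=False)).nodes.time.max()
                   for s in range(250)]
        times_y = [run_hybrid(make_config(2, point_map, n=80, seed=s + 10_000,
                                          model="hybrid", switch_time=0.0,
                                          record_lineage_counts=False)).nodes.time.max()
                   for s in range(250)]
        ks = sps.ks_2samp(times_h, times_y)
        assert ks.pvalue > 0.01

    def test_large_switch_time_is_dtwf(self, point_map):
        times_d = [run_dtwf(make_config(2, point_map, n=60, seed=s,
                                        record_lineage_counts=False)).nodes.time.max()
                   for s in range(250)]
        times_y = [run_hybrid(make_config(2, point_map, n=60, seed=s + 20_000,
                                          model="hybrid", switch_time=1e8,
                                          record_lineage_counts=False)).nodes.time.max()
                   for s in range(250)]
        ks = sps.ks_2samp(times_d, times_y)
        assert ks.pvalue > 0.01
        assert all(t == int(t) for t in times_y)

    def test_seam_times(self, two_chrom_map):
        """Nodes below the switch are integer-timed, above real-timed, and
        the genealogy is a valid single tree everywhere."""
        T = 10.0
        g = run_hybrid(make_config(8, two_chrom_map, n=40, seed=3,
                                   model="hybrid", switch_time=T))
        t = g.nodes.time.to_numpy()
        internal = t[t > 0]
        below = internal[internal <= T]
        assert np.allclose(below, np.round(below))
        assert (internal > T).any()
        ptimes = g.nodes.time.to_numpy()[g.edges.parent.to_numpy()]
        ctimes = g.nodes.time.to_numpy()[g.edges.child.to_numpy()]
        assert np.all(ptimes > ctimes)

    def test_recent_tmrca_matches_pure_dtwf(self, point_map):
        """TMRCAs below the switch come from identical WF dynamics."""
        T = 50.0
        rec_h, rec_d = [], []
        for s in range(200):
            gh = run_hybrid(make_config(2, point_map, n=40, seed=s,
                                        model="hybrid", switch_time=T,
                                        record_lineage_counts=False))
            gd = run_dtwf(make_config(2, point_map, n=40, seed=s + 5_000,
                                      record_lineage_counts=False))
            th, td = gh.nodes.time.max(), gd.nodes.time.max()
            if th <= T:
                rec_h.append(th)
            if td <= T:
                rec_d.append(td)
        ks = sps.ks_2samp(rec_h, rec_d)
        assert ks.pvalue > 0.01
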