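"""Table/config/VCF/newick round trips and the command-line interface."""

import io
import os

import numpy as np
import pytest
from click.testing import CliRunner

from wfcoal.cli import main as cli_main
from wfcoal.demography import (DemographicModel, Population, Pulse, SimConfig,
                               SizeChange)
from wfcoal.dtwf import run_dtwf
from wfcoal.fileio import read_config, write_config, write_newick, write_vcf
from wfcoal.genome import ConfigurationError, GeneticMap
from wfcoal.hudson import run_hudson
from wfcoal.stats import drop_mutations, extract_ibd, sfs
from wfcoal.tables import ParseError, read_tables, write_tables

from conftest import make_config


class TestTablesRoundTrip:
    def test_write_read_write_byte_identical(self, two_chrom_map, tmp_path):
        g = run_hudson(make_config(6, two_chrom_map, n=40, seed=2))
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_tables(g, str(p1))
        g2 = read_tables(str(p1))
        write_tables(g2, str(p2))
        for fname in ("metadata.tsv", "nodes.tsv", "edges.tsv", "trace.tsv"):
            assert (p1 / fname).read_bytes() == (p2 / fname).read_bytes()

    def test_empty_edge_table_round_trips(self, point_map, tmp_path):
        g = run_dtwf(make_config(1, point_map, n=5, seed=1))
        write_tables(g, str(tmp_path / "t"))
        g2 = read_tables(str(tmp_path / "t"))
        assert len(g2.edges) == 0
        assert g2.num_samples == 1

    def test_ibd_equal_before_and_after_round_trip(self, two_chrom_map, tmp_path):
        g = run_dtwf(make_config(12, two_chrom_map, n=30, seed=3))
        rec1, _ = extract_ibd(g, max_gen=10, min_cm=0.0)
        write_tables(g, str(tmp_path / "t"))
        rec2, _ = extract_ibd(read_tables(str(tmp_path / "t")), max_gen=10, min_cm=0.0)
        assert rec1.equals(rec2)

    def test_malformed_file_reports_line(self, two_chrom_map, tmp_path):
        g = run_dtwf(make_config(3, two_chrom_map, n=10, seed=1))
        write_tables(g, str(tmp_path / "t"))
        bad = tmp_path / "t" / "edges.tsv"
        bad.write_text(bad.read_text() + "oops\n")
        with pytest.raises(ParseError):
            read_tables(str(tmp_path / "t"))


class TestConfigRoundTrip:
    def test_bit_exact(self, tmp_path):
        cfg = SimConfig(
            samples={0: 7, 1: 3},
            map=GeneticMap((1.25, 0.37), hudson_spacer=0.45, bp_per_morgan=5e7),
            demography=DemographicModel(
                populations=(Population(123.0, 0.001), Population(55.0)),
                migration=((0.0, 0.02), (0.01, 0.0)),
                events=(SizeChange(10.0, 0, 99.0),
                        Pulse(5.0, 0, 1, 0.25))),
            model="hybrid", switch_time=50.0, seed=42, mutation_rate=0.3)
        p1, p2 = tmp_path / "c1.toml", tmp_path / "c2.toml"
        write_config(cfg, str(p1))
        cfg2 = read_config(str(p1))
        write_config(cfg2, str(p2))
        assert p1.read_bytes() == p2.read_bytes()
        assert cfg2 == cfg


class TestVCF:
    def test_header_only_for_zero_sites(self, two_chrom_map, tmp_path):
        import pandas as pd
        g = run_dtwf(make_config(4, two_chrom_map, n=10, seed=1))
        sites = drop_mutations(g, 0.0, np.random.default_rng(0))
        out = tmp_path / "z.vcf"
        write_vcf(g, sites, str(out))
        lines = out.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert sum(1 for l in lines if not l.startswith("#")) == 0

    def test_allele_counts_match_sfs_input(self, two_chrom_map, tmp_path):
        g = run_dtwf(make_config(8, two_chrom_map, n=20, seed=2))
        sites = drop_mutations(g, 1.0, np.random.default_rng(1))
        out = tmp_path / "s.vcf"
        write_vcf(g, sites, str(out))
        acs = []
        for line in out.read_text().splitlines():
            if line.startswith("#"):
                continue
            acs.append(sum(int(x) for x in line.split("\t")[9:]))
        spectrum = sfs(sites, 8)
        vcf_spectrum = np.bincount(acs, minlength=8)[1:8]
        assert list(vcf_spectrum) == list(spectrum)

    def test_singleton_record(self, point_map, tmp_path):
        import pandas as pd
        g = run_hudson(make_config(2, GeneticMap((0.05,)), n=100, seed=7))
        rng = np.random.default_rng(3)
        sites = drop_mutations(g, 5.0, rng)
        singles = sites[sites["count"] == 1]
        if len(singles):
            out = tmp_path / "one.vcf"
            write_vcf(g, singles.head(1), str(out))
            data = [l for l in out.read_text().splitlines() if not l.startswith("#")]
            assert len(data) == 1
            assert sorted(data[0].split("\t")[9:]) == ["0", "1"]


class TestNewick:
    def test_two_samples_shape(self, point_map):
        g = run_hudson(make_config(2, point_map, n=50, seed=1))
        t = g.nodes.time.max()
        nw = write_newick(g, 0.0)
        assert nw.startswith("(") and nw.endswith(";")
        assert f"{round(t, 6)}" in nw

    def test_biopython_parses_and_leaves_match(self, two_chrom_map):
        from Bio import Phylo
        g = run_dtwf(make_config(7, two_chrom_map, n=25, seed=2))
        for pos in (0.1, 0.9, 1.3):
            nw = write_newick(g, pos)
            tree = Phylo.read(io.StringIO(nw), "newick")
            leaves = {leaf.name for leaf in tree.get_terminals()}
            assert leaves == {f"n{s}" for s in g.sample_ids}

    def test_position_out_of_range(self, two_chrom_map):
        g = run_dtwf(make_config(4, two_chrom_map, n=25, seed=2))
        with pytest.raises(ConfigurationError):
            write_newick(g, 100.0)

    def test_uncoalesced_position_rejected(self, two_chrom_map):
        g = run_dtwf(make_config(6, two_chrom_map, n=25, seed=3, end_time=1.0))
        with pytest.raises(ConfigurationError):
            write_newick(g, 0.5)


class TestCLI:
    def test_simulate_deterministic(self, tmp_path):
        runner = CliRunner()
        args = ["simulate", "--model", "dtwf", "--samples", "8", "--Ne", "50",
                "--map", "0.5,0.5", "--seed", "3"]
        r1 = runner.invoke(cli_main, args + ["--out", str(tmp_path / "r1")])
        r2 = runner.invoke(cli_main, args + ["--out", str(tmp_path / "r2")])
        assert r1.exit_code == 0 and r2.exit_code == 0
        for f in ("nodes.tsv", "edges.tsv"):
            assert (tmp_path / "r1" / f).read_bytes() == (tmp_path / "r2" / f).read_bytes()

    def test_hybrid_switch_runs_both_engines(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "simulate", "--model", "hybrid", "--switch-time", "20",
            "--samples", "6", "--Ne", "30", "--map", "0.5", "--seed", "1",
            "--out", str(tmp_path / "h")])
        assert r.exit_code == 0
        g = read_tables(str(tmp_path / "h"))
        t = g.nodes.time.to_numpy()
        assert g.model == "hybrid"
        below = t[(t > 0) & (t <= 20)]
        assert np.allclose(below, np.round(below))

    def test_missing_samples_usage_error(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--out", "/tmp/x"])
        assert r.exit_code == 2

    def test_stats_and_theory_subcommands(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--model", "dtwf", "--samples",
                                     "6", "--Ne", "30", "--map", "0.6,0.6",
                                     "--seed", "2", "--out", str(out)])
        assert r.exit_code == 0
        r = runner.invoke(cli_main, ["stats", "ibd", "--tables", str(out),
                                     "--max-gen", "10", "--min-cm", "0",
                                     "--out", str(tmp_path / "ibd.tsv")])
        assert r.exit_code == 0
        assert (tmp_path / "ibd.tsv").exists()
        r = runner.invoke(cli_main, ["stats", "lineages", "--tables", str(out),
                                     "--out", str(tmp_path / "lin.tsv")])
        assert r.exit_code == 0
        r = runner.invoke(cli_main, ["theory", "ibd-expect", "-m", "4",
                                     "--map", "1.0,1.0"])
        assert r.exit_code == 0 and "expected_segments" in r.output
        r = runner.invoke(cli_main, ["theory", "ancestry-var", "-f", "0.3",
                                     "-n", "80", "--map", "1.0"])
        assert r.exit_code == 0

    def test_fixtures_human22(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "h22.tsv"
        r = runner.invoke(cli_main, ["fixtures", "human22", "--out", str(out)])
        assert r.exit_code == 0
        rows = [l for l in out.read_text().splitlines()[1:] if l]
        assert len(rows) == 22
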