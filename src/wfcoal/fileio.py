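"""Config files, VCF and newick output.

The config dialect is a TOML subset (read with :mod:`tomllib`, written by
a deterministic writer so that configs round-trip byte-identically).
Physical coordinates for VCF output come from the map's uniform
``bp_per_morgan`` scale (default 1 cM/Mb).
"""

from __future__ import annotations

import math
import tomllib

import numpy as np

from .demography import (DemographicModel, GrowthChange, Population, Pulse,
                         SimConfig, SizeChange)
from .genome import ConfigurationError, GeneticMap
from .tables import Genealogy

__all__ = ["write_config", "read_config", "write_vcf", "write_newick"]


def _fmt_val(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, int):
        return str(v)
    if isinstance(v, str):
        return '"%s"' % v
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_val(x) for x in v) + "]"
    raise TypeError(type(v))


def write_config(config: SimConfig, path: str) -> None:
    lines = ["# wfcoal config 1"]
    lines.append(f"model = {_fmt_val(config.model)}")
    lines.append(f"switch_time = {_fmt_val(float(config.switch_time))}")
    lines.append(f"seed = {_fmt_val(int(config.seed))}")
    lines.append(f"mutation_rate = {_fmt_val(float(config.mutation_rate))}")
    lines.append(f"record_lineage_counts = {_fmt_val(config.record_lineage_counts)}")
    if config.end_time is not None:
        lines.append(f"end_time = {_fmt_val(float(config.end_time))}")
    lines.append(f"samples = {_fmt_val([[p, k] for p, k in config.samples])}")
    lines.append("")
    lines.append("[map]")
    lines.append(f"chromosome_lengths = {_fmt_val(list(config.map.chromosome_lengths))}")
    lines.append(f"hudson_spacer = {_fmt_val(float(config.map.hudson_spacer))}")
    lines.append(f"bp_per_morgan = {_fmt_val(float(config.map.bp_per_morgan))}")
    lines.append("")
    lines.append("[demography]")
    mig = [list(row) for row in config.demography.migration]
    lines.append(f"migration = {_fmt_val(mig)}")
    for pop in config.demography.populations:
        lines.append("")
        lines.append("[[demography.populations]]")
        lines.append(f"initial_size = {_fmt_val(float(pop.initial_size))}")
        lines.append(f"growth_rate = {_fmt_val(float(pop.growth_rate))}")
    for ev in config.demography.events:
        lines.append("")
        lines.append("[[demography.events]]")
        lines.append(f"kind = {_fmt_val(ev.kind)}")
        lines.append(f"time = {_fmt_val(float(ev.time))}")
        if ev.kind == "size_change":
            lines.append(f"population = {_fmt_val(int(ev.population))}")
            lines.append(f"new_size = {_fmt_val(float(ev.new_size))}")
        elif ev.kind == "growth_change":
            lines.append(f"population = {_fmt_val(int(ev.population))}")
            lines.append(f"new_rate = {_fmt_val(float(ev.new_rate))}")
        elif ev.kind == "pulse":
            lines.append(f"dest = {_fmt_val(int(ev.dest))}")
            lines.append(f"source = {_fmt_val(int(ev.source))}")
            lines.append(f"fraction = {_fmt_val(float(ev.fraction))}")
            lines.append(f"record_census = {_fmt_val(ev.record_census)}")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def read_config(path: str) -> SimConfig:
    with open(path, "rb") as f:
        data = tomllib.load(f)
    try:
        gmap = GeneticMap(
            chromosome_lengths=tuple(data["map"]["chromosome_lengths"]),
            hudson_spacer=data["map"].get("hudson_spacer", 0.5),
            bp_per_morgan=data["map"].get("bp_per_morgan", 1e8),
        )
        events = []
        for ev in data.get("demography", {}).get("events", []):
            kind = ev["kind"]
            if kind == "size_change":
                events.append(SizeChange(ev["time"], ev["population"], ev["new_size"]))
            elif kind == "growth_change":
                events.append(GrowthChange(ev["time"], ev["population"], ev["new_rate"]))
            elif kind == "pulse":
                events.append(Pulse(ev["time"], ev["dest"], ev["source"],
                                    ev["fraction"], ev.get("record_census", True)))
            else:
                raise ConfigurationError(f"unknown event kind {kind!r}")
        demog = DemographicModel(
            populations=tuple(Population(p["initial_size"], p.get("growth_rate", 0.0))
                              for p in data["demography"]["populations"]),
            migration=tuple(tuple(row) for row in data["demography"].get("migration", [])),
            events=tuple(events),
        )
        return SimConfig(
            samples=tuple((int(p), int(k)) for p, k in data["samples"]),
            map=gmap,
            demography=demog,
            model=data.get("model", "hudson"),
            switch_time=data.get("switch_time", 0.0),
            seed=data.get("seed", 1),
            mutation_rate=data.get("mutation_rate", 0.0),
            record_lineage_counts=data.get("record_lineage_counts", True),
            end_time=data.get("end_time"),
        )
    except KeyError as e:
        raise ConfigurationError(f"missing config key: {e}") from e


# ---------------------------------------------------------------------------

def write_vcf(g: Genealogy, sites, path: str, log=None) -> None:
    """Write a site table as VCF 4.2 with haploid sample columns.

    CHROM comes from the chromosome index (1-based), POS from the
    genetic-to-physical scaling; collisions after rounding are shifted
    deterministically by +1 bp (with a warning if a logger is given).
    """
    samples = [int(s) for s in g.sample_ids]
    bpm = g.map.bp_per_morgan
    recs = []
    used: set[tuple[int, int]] = set()
    for row in sites.itertuples(index=False):
        chrom, pos = g.map.to_physical(row.position, g.spacer)
        while (chrom, pos) in used:
            pos += 1
            if log is not None:
                log.warning("position collision at chr%d:%d; shifted +1", chrom + 1, pos)
        used.add((chrom, pos))
        recs.append((chrom, pos, set(row.carriers)))
    recs.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write("##source=wfcoal\n")
        for i, l in enumerate(g.map.chromosome_lengths):
            f.write(f"##contig=<ID={i+1},length={int(math.ceil(l * bpm)) + 1}>\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(f"n{s}" for s in samples) + "\n")
        for chrom, pos, carriers in recs:
            gts = "\t".join("1" if s in carriers else "0" for s in samples)
            f.write(f"{chrom+1}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_newick(g: Genealogy, position: float, precision: int = 6) -> str:
    """Newick string of the marginal tree at ``position``, branch lengths
    in generations. Requires the position to have fully coalesced."""
    if not (0.0 <= position < g.axis_length):
        raise ConfigurationError("position outside the simulated axis")
    edges = g.edges
    sel = (edges.left.to_numpy() <= position) & (edges.right.to_numpy() > position)
    parent = edges.parent.to_numpy()[sel]
    child = edges.child.to_numpy()[sel]
    times = g.nodes.time.to_numpy()
    children: dict[int, list[int]] = {}
    parent_of = {}
    for p, c in zip(parent, child):
        children.setdefault(int(p), []).append(int(c))
        parent_of[int(c)] = int(p)
    samples = set(int(s) for s in g.sample_ids)
    roots = {u for u in set(map(int, parent)) | samples if u not in parent_of}
    if len(roots) != 1:
        raise ConfigurationError(
            f"position {position} has {len(roots)} roots; not fully coalesced")
    root = roots.pop()

    def label(u: int) -> str:
        return f"n{u}" if u in samples else ""

    out: list[str] = []
    # iterative post-order build
    stack: list[tuple[int, int]] = [(root, 0)]
    frag: dict[int, str] = {}
    order: list[int] = []
    while stack:
        u, state = stack.pop()
        if state == 0 and u in children:
            stack.append((u, 1))
            for c in children[u]:
                stack.append((c, 0))
        else:
            order.append(u)
            kids = children.get(u, [])
            if kids:
                inner = ",".join(
                    f"{frag[c]}:{round(times[u] - times[c], precision)}"
                    for c in sorted(kids))
                frag[u] = f"({inner}){label(u)}"
            else:
                frag[u] = label(u)
    return frag[root] + ";"
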