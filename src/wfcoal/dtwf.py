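"""Backwards-in-time discrete Wright-Fisher model, and the hybrid model.

Instead of drawing exponential waiting times, the engine iterates explicit
generations. Within each generation the order of operations is fixed:

1. demographic events scheduled at the current generation are applied
   (size/growth changes; admixture pulses route lineages to the source
   population with probability f and record census nodes);
2. each lineage migrates according to the backward migration matrix;
3. each lineage draws a uniform diploid parent in its population and a
   meiosis: crossover breakpoints form a Poisson process at rate equal to
   the genetic span in Morgans, material alternates between the parent's
   two haplotypes starting from a fair phase coin, and each chromosome
   boundary re-draws the haplotype with an independent fair coin
   (independent assortment);
4. all material landing on the same (parent, haplotype) coalesces,
   possibly as a simultaneous multi-way merge.

Each gamete therefore has exactly one diploid parent, and the number of
extant lineages can never exceed the haploid population size 2N(t) —
the two properties the linear-rate coalescent lacks.

Parent choice is non-monogamous with no selfing prevention, which
overestimates half-sibs relative to real human cohorts (a deliberate
property of the model, not a bug).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    NODE_IS_CENSUS,
    Lineage,
    OverlapMap,
    TableBuilder,
    merge_many,
    new_sample_lineages,
)
from .demography import DemographicModel, Pulse, SimConfig
from .genome import ConfigurationError, GeneticMap
from .hudson import HudsonEngine
from .tables import Genealogy, finalize_tables

__all__ = ["MeiosisDraw", "draw_meiosis", "split_by_meiosis",
           "run_dtwf", "run_hybrid", "DTWFEngine"]

_EMPTY = np.empty(0)
_EMPTY_INT = np.empty(0, dtype=np.int64)


@dataclass
class MeiosisDraw:
    """One meiosis: crossover breakpoints, starting phase, assortment coins.

    ``breakpoints`` are strictly increasing positions within the spanned
    interval; their count is Poisson with mean equal to the spanned
    genetic length. ``boundary_coins`` maps each chromosome boundary
    inside the span to the haplotype (0/1) chosen there.
    """

    breakpoints: np.ndarray
    phase: int
    boundaries: np.ndarray
    boundary_coins: np.ndarray


def draw_meiosis(span: tuple[float, float], genetic_map: GeneticMap, rng,
                 spacer: float = 0.0) -> MeiosisDraw:
    """Draw breakpoints, phase and assortment coins for one transmission."""
    a, b = span
    rate = genetic_map.genetic_length(a, b, spacer)
    n = rng.poisson(rate) if rate > 0 else 0
    if n:
        bps = np.sort(rng.uniform(a, b, size=n)) if spacer == 0.0 else \
            _positions_excluding_gaps(a, b, n, genetic_map, spacer, rng)
    else:
        bps = np.empty(0)
    if genetic_map.num_chromosomes > 1:
        all_bounds = genetic_map.boundaries(spacer)
        inside = all_bounds[(all_bounds > a) & (all_bounds < b)]
        coins = rng.integers(0, 2, size=inside.size)
    else:
        inside = _EMPTY
        coins = _EMPTY_INT
    phase = int(rng.integers(0, 2))
    return MeiosisDraw(breakpoints=bps, phase=phase, boundaries=inside,
                       boundary_coins=coins)


def _positions_excluding_gaps(a, b, n, genetic_map, spacer, rng):
    starts = genetic_map.starts(spacer)
    ends = genetic_map.ends(spacer)
    lo = np.clip(starts, a, b)
    hi = np.clip(ends, a, b)
    w = np.clip(hi - lo, 0.0, None)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    u = rng.uniform(0.0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return np.sort(lo[idx] + (u - cum[idx]))


def split_by_meiosis(lineage: Lineage, draw: MeiosisDraw):
    """Partition a lineage's material between the two parental haplotypes.

    Starting from ``draw.phase``, the haplotype flips at every breakpoint
    and is re-drawn from the assortment coin at every chromosome boundary.
    The union of the two outputs equals the input segments exactly.
    """
    cuts = []  # (position, kind, coin); kind 0 = crossover, 1 = boundary
    for x in draw.breakpoints:
        cuts.append((float(x), 0, 0))
    for x, c in zip(draw.boundaries, draw.boundary_coins):
        cuts.append((float(x), 1, int(c)))
    cuts.sort()
    out = ([], [])
    hap = draw.phase
    ci = 0
    for l, r, node in lineage.segs:
        pos = l
        while True:
            while ci < len(cuts) and cuts[ci][0] <= pos:
                _, kind, coin = cuts[ci]
                hap = (1 - hap) if kind == 0 else coin
                ci += 1
            nxt = cuts[ci][0] if ci < len(cuts) else math.inf
            end = min(r, nxt)
            if end > pos:
                segs = out[hap]
                if segs and segs[-1][1] == pos and segs[-1][2] == node:
                    segs[-1] = (segs[-1][0], end, node)
                else:
                    segs.append((pos, end, node))
            pos = end
            if pos >= r:
                break
    return out


class DTWFEngine:
    """Generation-by-generation backwards Wright-Fisher simulation."""

    def __init__(self, genetic_map: GeneticMap, demography: DemographicModel,
                 rng, lineages, tables: TableBuilder, overlap: OverlapMap,
                 record_trace: bool = True):
        self.map = genetic_map
        self.demography = demography
        self.rng = rng
        self.tables = tables
        self.overlap = overlap
        self.record_trace = record_trace
        self.trace: list[tuple[float, int]] = []
        self.time = 0.0
        # per-population size state: (n_base, alpha, t_ref)
        self.pop_state = [[float(p.initial_size), float(p.growth_rate), 0.0]
                          for p in demography.populations]
        self.pop_lineages: list[list[Lineage]] = [[] for _ in demography.populations]
        for lin in lineages:
            self.pop_lineages[lin.population].append(lin)
        self.pending = list(demography.events)
        self._indiv_counter = 0
        self._boundaries = genetic_map.boundaries(0.0)

    @property
    def num_lineages(self) -> int:
        return sum(len(p) for p in self.pop_lineages)

    def pop_size_at(self, pop: int, t: float) -> int:
        n_base, alpha, t_ref = self.pop_state[pop]
        n = n_base * math.exp(-alpha * (t - t_ref))
        n = max(1, int(round(n)))
        return n

    # -- per-generation steps -------------------------------------------

    def _apply_events_at(self, t: float) -> None:
        while self.pending and self.pending[0].time <= t:
            ev = self.pending.pop(0)
            if ev.kind == "size_change":
                self.pop_state[ev.population] = [float(ev.new_size),
                                                 self.pop_state[ev.population][1], t]
            elif ev.kind == "growth_change":
                cur = self.pop_size_at(ev.population, t)
                self.pop_state[ev.population] = [float(cur), float(ev.new_rate), t]
            elif ev.kind == "pulse":
                self._apply_pulse(ev, t)
            else:
                raise ConfigurationError(f"unknown event kind {ev.kind}")

    def _apply_pulse(self, ev: Pulse, t: float) -> None:
        # migrants are diploid individuals: both haplotypes of one parent
        # share the migration coin (falls back to one coin per lineage for
        # lineages without parent identity, e.g. at t=0)
        dest = self.pop_lineages[ev.dest]
        stay, move = [], []
        coins: dict = {}
        for lin in dest:
            key = lin.individual
            if key is None:
                migrates = self.rng.uniform() < ev.fraction
            elif key in coins:
                migrates = coins[key]
            else:
                migrates = coins[key] = bool(self.rng.uniform() < ev.fraction)
            (move if migrates else stay).append(lin)
        for lin in move:
            lin.population = ev.source
        self.pop_lineages[ev.dest] = stay
        self.pop_lineages[ev.source].extend(move)
        if ev.record_census:
            for pop in self.pop_lineages:
                for lin in pop:
                    cnode = self.tables.add_node(t, lin.population, NODE_IS_CENSUS)
                    for l, r, node in lin.segs:
                        self.tables.add_edge(l, r, cnode, node)
                    lin.segs = [(l, r, cnode) for l, r, _ in lin.segs]

    def _migrate(self) -> None:
        mig = self.demography.migration
        npop = len(self.pop_lineages)
        if all(mig[i][j] == 0.0 for i in range(npop) for j in range(npop) if i != j):
            return
        # decide destinations for every lineage first, then rebuild lists,
        # so nobody migrates twice within one generation
        moves: list[tuple[Lineage, int]] = []
        for i in range(npop):
            rates = mig[i]
            out = sum(rates[j] for j in range(npop) if j != i)
            if out == 0.0 or not self.pop_lineages[i]:
                continue
            u = self.rng.uniform(size=len(self.pop_lineages[i]))
            for lin, ui in zip(self.pop_lineages[i], u):
                if ui < out:
                    acc = 0.0
                    for j in range(npop):
                        if j == i:
                            continue
                        acc += rates[j]
                        if ui < acc:
                            moves.append((lin, j))
                            break
        for lin, dest in moves:
            self.pop_lineages[lin.population].remove(lin)
            lin.population = dest
            self.pop_lineages[dest].append(lin)

    def step(self) -> None:
        """Advance one generation: events, migration, meiosis, coalescence."""
        t = self.time
        self._apply_events_at(t)
        self._migrate()
        t_next = t + 1.0
        new_pop_lineages: list[list[Lineage]] = [[] for _ in self.pop_lineages]
        for pop_index, lins in enumerate(self.pop_lineages):
            if not lins:
                continue
            n_next = self.pop_size_at(pop_index, t_next)
            parents = self.rng.integers(0, n_next, size=len(lins))
            buckets: dict[int, tuple[list, list]] = {}
            for lin, parent in zip(lins, parents):
                draw = draw_meiosis((lin.left, lin.right), self.map, self.rng)
                hap_a, hap_b = split_by_meiosis(lin, draw)
                bucket = buckets.setdefault(int(parent), ([], []))
                if hap_a:
                    bucket[0].append(Lineage(hap_a, pop_index))
                if hap_b:
                    bucket[1].append(Lineage(hap_b, pop_index))
            for parent, (contrib_a, contrib_b) in buckets.items():
                needs_node = len(contrib_a) > 1 or len(contrib_b) > 1
                indiv = -1
                if needs_node:
                    indiv = self._indiv_counter
                    self._indiv_counter += 1
                parent_key = (pop_index, parent)
                for contrib in (contrib_a, contrib_b):
                    if not contrib:
                        continue
                    if len(contrib) == 1:
                        contrib[0].individual = parent_key
                        new_pop_lineages[pop_index].append(contrib[0])
                        continue
                    merged = merge_many(contrib, t_next, pop_index, self.tables,
                                        self.overlap, individual=indiv)
                    if merged is not None and merged.segs:
                        merged.individual = parent_key
                        new_pop_lineages[pop_index].append(merged)
        self.pop_lineages = new_pop_lineages
        self.time = t_next
        if self.record_trace:
            self.trace.append((t_next, self.num_lineages))

    def run(self, end_time: float | None = None) -> None:
        if self.record_trace:
            self.trace.append((self.time, self.num_lineages))
        while True:
            k = self.num_lineages
            if k == 0:
                break
            if k == 1 and not self.pending:
                break
            if end_time is not None and self.time >= end_time:
                break
            # make sure pulses/censuses scheduled exactly at end_time or at
            # the final generation are applied even if we stop here
            self.step()
        if end_time is not None and self.time >= end_time:
            self._apply_events_at(self.time)

    def extant_lineages(self) -> list[Lineage]:
        return [lin for pop in self.pop_lineages for lin in pop if lin.segs]


def _setup(config: SimConfig):
    rng = np.random.default_rng(config.seed)
    lineages, tables, overlap = new_sample_lineages(
        dict(config.samples), config.map, spacer=0.0)
    return rng, lineages, tables, overlap


def run_dtwf(config: SimConfig) -> Genealogy:
    """Simulate a complete genealogy under the discrete Wright-Fisher model."""
    rng, lineages, tables, overlap = _setup(config)
    eng = DTWFEngine(config.map, config.demography, rng, lineages, tables,
                     overlap, record_trace=config.record_lineage_counts)
    eng.run(end_time=config.end_time)
    return finalize_tables(tables, config.map, 0.0, eng.trace,
                           model="dtwf", seed=config.seed)


def run_hybrid(config: SimConfig) -> Genealogy:
    """Wright-Fisher dynamics for ``switch_time`` generations, Hudson after.

    The whole run uses the compact (spacer-free) axis so the hand-over is
    seamless: node times below the switch are integers, above it real.
    """
    rng, lineages, tables, overlap = _setup(config)
    T = config.switch_time
    trace: list[tuple[float, int]] = []
    if T > 0:
        eng = DTWFEngine(config.map, config.demography, rng, lineages, tables,
                         overlap, record_trace=config.record_lineage_counts)
        wf_end = T if config.end_time is None else min(T, config.end_time)
        eng.run(end_time=wf_end)
        trace = eng.trace
        lineages = eng.extant_lineages()
        start = eng.time
    else:
        start = 0.0
    done = not lineages or (config.end_time is not None and start >= config.end_time)
    if not done:
        heng = HudsonEngine(config.map, config.demography, rng, lineages,
                            tables, overlap, start_time=start, spacer=0.0,
                            record_trace=config.record_lineage_counts,
                            include_start_events=(start == 0.0))
        if trace:
            heng.trace = trace[:-1]
            heng.record_trace = config.record_lineage_counts
        heng.run(end_time=config.end_time)
        trace = heng.trace
    return finalize_tables(tables, config.map, 0.0, trace,
                           model="hybrid", seed=config.seed)
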