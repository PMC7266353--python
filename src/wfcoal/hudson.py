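"""Hudson's coalescent with recombination over ancestral segments.

Backwards-in-time continuous model: recombination splits a lineage at a
rate equal to the genetic span of its ancestral material (trapped gaps
included), common-ancestor events merge uniformly chosen pairs within a
population at rate C(k,2)/(2N(t)), and migration moves single lineages
between populations. Exponential population size change is handled by
closed-form inversion of the integrated coalescence rate, so waiting
times are exact under N(t) = N0*exp(-alpha*t).

Multiple chromosomes are represented by concatenation with an inert
spacer (``map.hudson_spacer`` Morgans) between chromosomes: a linear
crossover-rate model cannot represent true independent assortment, and
the spacer is the configurable approximation of it. This is exactly the
model whose large-sample pathologies (lineage counts far exceeding the
haploid population size) the Wright-Fisher engine corrects.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    NODE_IS_CENSUS,
    Lineage,
    OverlapMap,
    TableBuilder,
    merge_lineages,
    new_sample_lineages,
)
from .demography import DemographicModel, Pulse, SimConfig
from .genome import ConfigurationError
from .tables import Genealogy, finalize_tables

__all__ = ["run_hudson", "total_recomb_mass", "apply_recombination", "HudsonEngine"]


def total_recomb_mass(lineages) -> float:
    """Total recombination rate: sum of lineage spans in Morgans."""
    return float(sum(lin.span for lin in lineages))


def apply_recombination(lineage: Lineage, breakpoint: float):
    """Split a lineage at ``breakpoint``, strictly inside its span.

    Segments (or parts of segments) left of the breakpoint form one
    lineage, the rest the other; both keep the population. A breakpoint
    inside a trapped gap splits cleanly between segments.
    """
    if not (lineage.left < breakpoint < lineage.right):
        raise AssertionError("breakpoint outside lineage span")
    left_segs, right_segs = [], []
    for l, r, node in lineage.segs:
        if r <= breakpoint:
            left_segs.append((l, r, node))
        elif l >= breakpoint:
            right_segs.append((l, r, node))
        else:
            left_segs.append((l, breakpoint, node))
            right_segs.append((breakpoint, r, node))
    return (Lineage(left_segs, lineage.population),
            Lineage(right_segs, lineage.population))


class _Fenwick:
    """Binary indexed tree over lineage slots, for span-weighted sampling."""

    def __init__(self, capacity: int):
        self.n = capacity
        self.tree = np.zeros(capacity + 1)
        self.values = np.zeros(capacity)

    def set(self, i: int, v: float) -> None:
        delta = v - self.values[i]
        if delta == 0.0:
            return
        self.values[i] = v
        j = i + 1
        while j <= self.n:
            self.tree[j] += delta
            j += j & (-j)

    def total(self) -> float:
        return float(self.values.sum()) if self.n < 64 else self._prefix(self.n)

    def _prefix(self, j: int) -> float:
        s = 0.0
        while j > 0:
            s += self.tree[j]
            j -= j & (-j)
        return float(s)

    def find(self, u: float) -> int:
        """Smallest index i with cumulative sum > u."""
        idx = 0
        bit = 1 << (self.n.bit_length())
        while bit:
            nxt = idx + bit
            if nxt <= self.n and self.tree[nxt] <= u:
                u -= self.tree[nxt]
                idx = nxt
            bit >>= 1
        return idx  # 0-based slot

    def grow(self, capacity: int) -> "_Fenwick":
        f = _Fenwick(capacity)
        for i, v in enumerate(self.values):
            if v:
                f.set(i, v)
        return f


class _PopState:
    __slots__ = ("n_base", "alpha", "t_ref", "slots", "pos")

    def __init__(self, n_base, alpha, t_ref):
        self.n_base = float(n_base)
        self.alpha = float(alpha)
        self.t_ref = float(t_ref)
        self.slots: list[int] = []     # lineage slot ids in this population
        self.pos: dict[int, int] = {}  # slot id -> index in self.slots

    def size_at(self, t: float) -> float:
        return self.n_base * math.exp(-self.alpha * (t - self.t_ref))

    def add(self, slot: int) -> None:
        self.pos[slot] = len(self.slots)
        self.slots.append(slot)

    def remove(self, slot: int) -> None:
        i = self.pos.pop(slot)
        last = self.slots.pop()
        if last != slot:
            self.slots[i] = last
            self.pos[last] = i


class HudsonEngine:
    """Continuous-time coalescent-with-recombination event loop.

    Can be started fresh (from sample lineages) or from the hand-over
    state of a Wright-Fisher run (the hybrid model).
    """

    def __init__(self, genetic_map, demography: DemographicModel, rng,
                 lineages, tables: TableBuilder, overlap: OverlapMap,
                 start_time: float = 0.0, spacer: float = 0.0,
                 record_trace: bool = True, include_start_events: bool = True):
        self.map = genetic_map
        self.demography = demography
        self.rng = rng
        self.tables = tables
        self.overlap = overlap
        self.spacer = spacer
        self.time = float(start_time)
        self.record_trace = record_trace
        self.trace: list[tuple[float, int]] = []

        self.pops = [_PopState(p.initial_size, p.growth_rate, 0.0)
                     for p in demography.populations]
        if include_start_events:
            self.pending = [e for e in demography.events if e.time >= start_time]
        else:
            self.pending = [e for e in demography.events if e.time > start_time]
        self._apply_past_epochs(start_time)

        cap = max(16, 2 * len(lineages))
        self.lineages: list[Lineage | None] = [None] * cap
        self.free: list[int] = list(range(len(lineages), cap))[::-1]
        self.fenwick = _Fenwick(cap)
        self.k = 0
        for i, lin in enumerate(lineages):
            self.lineages[i] = lin
            self.fenwick.set(i, lin.span)
            self.pops[lin.population].add(i)
            self.k += 1

    def _apply_past_epochs(self, start_time: float) -> None:
        """Replay demographic events older than the start time (hybrid)."""
        past = [e for e in self.demography.events if e.time < start_time]
        for ev in past:
            if ev.kind == "size_change":
                ps = self.pops[ev.population]
                ps.n_base, ps.t_ref = float(ev.new_size), ev.time
            elif ev.kind == "growth_change":
                ps = self.pops[ev.population]
                ps.n_base = ps.size_at(ev.time)
                ps.t_ref, ps.alpha = ev.time, float(ev.new_rate)
            # pulses in the past were handled by the WF phase

    # -- slot plumbing ---------------------------------------------------

    def _insert(self, lin: Lineage) -> int:
        if not self.free:
            old = len(self.lineages)
            self.lineages.extend([None] * old)
            self.free = list(range(old, 2 * old))[::-1]
            self.fenwick = self.fenwick.grow(2 * old)
        slot = self.free.pop()
        self.lineages[slot] = lin
        self.fenwick.set(slot, lin.span)
        self.pops[lin.population].add(slot)
        self.k += 1
        return slot

    def _remove(self, slot: int) -> Lineage:
        lin = self.lineages[slot]
        self.lineages[slot] = None
        self.fenwick.set(slot, 0.0)
        self.pops[lin.population].remove(slot)
        self.free.append(slot)
        self.k -= 1
        return lin

    # -- event sampling --------------------------------------------------

    def _draw_coal_time(self, pop: _PopState, k: int) -> float:
        if k < 2:
            return math.inf
        pairs = 0.5 * k * (k - 1)
        e = self.rng.exponential()
        rate0 = pairs / (2.0 * pop.size_at(self.time))
        if pop.alpha == 0.0:
            return self.time + e / rate0
        arg = 1.0 + pop.alpha * e / rate0
        if arg <= 0.0:
            return math.inf
        return self.time + math.log(arg) / pop.alpha

    def sample_next_event(self):
        """Draw the next (kind, time, info) among recombination, common
        ancestor and migration; returns (None, inf, None) when nothing can
        happen."""
        best = (None, math.inf, None)
        mass = self.fenwick._prefix(self.fenwick.n)
        if mass > 0:
            t = self.time + self.rng.exponential() / mass
            if t < best[1]:
                best = ("recombination", t, None)
        for i, ps in enumerate(self.pops):
            t = self._draw_coal_time(ps, len(ps.slots))
            if t < best[1]:
                best = ("common_ancestor", t, i)
        for i, ps in enumerate(self.pops):
            ki = len(ps.slots)
            if ki == 0:
                continue
            out = sum(self.demography.migration[i][j]
                      for j in range(len(self.pops)) if j != i)
            if out > 0:
                t = self.time + self.rng.exponential() / (ki * out)
                if t < best[1]:
                    best = ("migration", t, i)
        return best

    # -- event execution -------------------------------------------------

    def _do_recombination(self) -> None:
        mass = self.fenwick._prefix(self.fenwick.n)
        while True:
            slot = self.fenwick.find(self.rng.uniform(0.0, mass))
            lin = self.lineages[slot]
            if lin is None:  # numerical edge of the weighted search
                continue
            x = lin.left + self.rng.uniform(0.0, lin.span)
            if lin.left < x < lin.right:
                break
        a, b = apply_recombination(lin, x)
        if not a.segs or not b.segs:
            return  # breakpoint coincided with a segment boundary; no-op
        self.lineages[slot] = a
        self.fenwick.set(slot, a.span)
        self._insert(b)

    def _do_common_ancestor(self, pop_index: int) -> None:
        ps = self.pops[pop_index]
        k = len(ps.slots)
        i = int(self.rng.integers(k))
        j = int(self.rng.integers(k - 1))
        if j >= i:
            j += 1
        sa, sb = ps.slots[i], ps.slots[j]
        a = self._remove(sa)
        b = self._remove(sb)
        merged = merge_lineages(a, b, self.time, self.tables, self.overlap)
        if merged is not None and merged.segs:
            self._insert(merged)

    def _do_migration(self, source_pop: int) -> None:
        ps = self.pops[source_pop]
        rates = [self.demography.migration[source_pop][j] if j != source_pop else 0.0
                 for j in range(len(self.pops))]
        tot = sum(rates)
        u = self.rng.uniform(0.0, tot)
        acc = 0.0
        dest = source_pop
        for j, r in enumerate(rates):
            acc += r
            if u < acc:
                dest = j
                break
        slot = ps.slots[int(self.rng.integers(len(ps.slots)))]
        lin = self.lineages[slot]
        ps.remove(slot)
        lin.population = dest
        self.pops[dest].add(slot)

    def _apply_demographic_event(self, ev) -> None:
        if ev.kind == "size_change":
            ps = self.pops[ev.population]
            ps.n_base, ps.t_ref = float(ev.new_size), ev.time
        elif ev.kind == "growth_change":
            ps = self.pops[ev.population]
            ps.n_base = ps.size_at(ev.time)
            ps.t_ref, ps.alpha = ev.time, float(ev.new_rate)
        elif ev.kind == "pulse":
            self._apply_pulse(ev)
        else:
            raise ConfigurationError(f"unknown event kind {ev.kind}")

    def _apply_pulse(self, ev: Pulse) -> None:
        moved: list[int] = []
        for slot in list(self.pops[ev.dest].slots):
            if self.rng.uniform() < ev.fraction:
                moved.append(slot)
        for slot in moved:
            lin = self.lineages[slot]
            self.pops[ev.dest].remove(slot)
            lin.population = ev.source
            self.pops[ev.source].add(slot)
        if ev.record_census:
            self._record_census(ev.time)

    def _record_census(self, time: float) -> None:
        for slot, lin in enumerate(self.lineages):
            if lin is None or not lin.segs:
                continue
            cnode = self.tables.add_node(time, lin.population, NODE_IS_CENSUS)
            for l, r, node in lin.segs:
                self.tables.add_edge(l, r, cnode, node)
            lin.segs = [(l, r, cnode) for l, r, _ in lin.segs]

    # -- main loop ---------------------------------------------------------

    def run(self, end_time: float | None = None) -> None:
        next_trace = math.inf
        if self.record_trace:
            self.trace.append((math.floor(self.time), self.k))
            next_trace = math.floor(self.time) + 1.0
        ev_idx = 0
        while self.k > 1:
            kind, t_event, info = self.sample_next_event()
            boundary = math.inf
            action = None
            if ev_idx < len(self.pending):
                boundary = self.pending[ev_idx].time
                action = "demo"
            if next_trace < boundary:
                boundary, action = next_trace, "trace"
            if end_time is not None and end_time < boundary:
                boundary, action = end_time, "end"
            if t_event >= boundary:
                self.time = max(self.time, boundary)
                if action == "demo":
                    self._apply_demographic_event(self.pending[ev_idx])
                    ev_idx += 1
                elif action == "trace":
                    self.trace.append((boundary, self.k))
                    next_trace = boundary + 1.0
                elif action == "end":
                    break
                continue
            if kind is None:
                break
            self.time = t_event
            if kind == "recombination":
                self._do_recombination()
            elif kind == "common_ancestor":
                self._do_common_ancestor(info)
            else:
                self._do_migration(info)

    def extant_lineages(self) -> list[Lineage]:
        return [lin for lin in self.lineages if lin is not None and lin.segs]


def run_hudson(config: SimConfig) -> Genealogy:
    """Simulate a complete genealogy under Hudson's coalescent."""
    rng = np.random.default_rng(config.seed)
    spacer = config.map.hudson_spacer
    lineages, tables, overlap = new_sample_lineages(
        dict(config.samples), config.map, spacer=spacer)
    eng = HudsonEngine(config.map, config.demography, rng, lineages, tables,
                       overlap, start_time=0.0, spacer=spacer,
                       record_trace=config.record_lineage_counts)
    eng.run(end_time=config.end_time)
    return finalize_tables(tables, config.map, spacer, eng.trace,
                           model="hudson", seed=config.seed)
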