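"""Ancestral segments, lineages, overlap bookkeeping and genealogy recording.

Both engines trace lineages backwards in time. A lineage carries a sorted
list of disjoint half-open segments ``(left, right, node)``; ``node`` is
the genealogy node whose ancestry the segment represents. A global
:class:`OverlapMap` tracks, for every genomic point, how many extant
lineages still carry material ancestral to the sample there. When a merge
reduces that number to one, the point has found its grand MRCA and the
material is pruned from the simulation ("memory-light" contract): the MRCA
node itself stays in the node table.

Merging is k-way: the coalescent merges pairs, the Wright-Fisher engine
merges whole (parent, haplotype) buckets at once, creating polytomies.
One ancestor node is created per merge event, shared by every interval
that coalesces in that event, which keeps marginal trees consistent
across intervals.
"""

from __future__ import annotations

import heapq
from bisect import bisect_left, bisect_right, insort

import numpy as np

from .genome import ConfigurationError, GeneticMap

__all__ = [
    "Lineage",
    "OverlapMap",
    "TableBuilder",
    "new_sample_lineages",
    "merge_lineages",
    "merge_many",
    "is_fully_coalesced",
]

NODE_IS_SAMPLE = 1
NODE_IS_CENSUS = 2


class Lineage:
    """A lineage: sorted disjoint ancestral segments plus a population.

    ``individual`` identifies the diploid parent this lineage currently
    occupies (Wright-Fisher engine only); admixture pulses use it so that
    both haplotypes of one individual migrate together.
    """

    __slots__ = ("segs", "population", "individual")

    def __init__(self, segs, population, individual=None):
        self.segs = segs  # list of (left, right, node)
        self.population = population
        self.individual = individual

    @property
    def left(self) -> float:
        return self.segs[0][0]

    @property
    def right(self) -> float:
        return self.segs[-1][1]

    @property
    def span(self) -> float:
        """Extent from leftmost to rightmost endpoint, trapped gaps included."""
        if not self.segs:
            return 0.0
        return self.segs[-1][1] - self.segs[0][0]

    @property
    def ancestral_length(self) -> float:
        return sum(r - l for l, r, _ in self.segs)

    def check(self, axis_length: float) -> None:
        prev = 0.0
        last_r = None
        for l, r, _ in self.segs:
            if not (0.0 <= l < r <= axis_length):
                raise AssertionError("segment outside axis")
            if last_r is not None and l < last_r:
                raise AssertionError("segments overlap or unsorted")
            last_r = r
            prev = r


class OverlapMap:
    """Piecewise-constant count of extant lineages ancestral to each point.

    Stored as parallel sorted lists ``pos`` / ``cnt``: the count is
    ``cnt[i]`` on ``[pos[i], pos[i+1])`` and ``pos[0] == 0``. A count of
    zero marks fully coalesced (or never-sampled) material.
    """

    __slots__ = ("pos", "cnt", "axis_length")

    def __init__(self, axis_length: float, initial_count: int):
        self.axis_length = axis_length
        self.pos = [0.0]
        self.cnt = [initial_count]

    def count_at(self, x: float) -> int:
        i = bisect_right(self.pos, x) - 1
        return self.cnt[i]

    def _split_at(self, x: float) -> int:
        """Ensure x is a breakpoint; return its index."""
        i = bisect_left(self.pos, x)
        if i < len(self.pos) and self.pos[i] == x:
            return i
        self.pos.insert(i, x)
        self.cnt.insert(i, self.cnt[i - 1])
        return i

    def decrement(self, left: float, right: float, by: int):
        """Reduce the count by ``by`` on ``[left, right)``.

        Returns a list of pieces ``(a, b, survived)``: ``survived`` is
        False where the count dropped to one (grand MRCA found there; the
        stored count becomes zero and the caller must prune the material).
        """
        if right <= left or by <= 0:
            return [(left, right, True)] if right > left else []
        i = self._split_at(left)
        j = self._split_at(right) if right < self.axis_length else len(self.pos)
        out = []
        for k in range(i, j):
            a = self.pos[k]
            b = self.pos[k + 1] if k + 1 < len(self.pos) else self.axis_length
            c = self.cnt[k]
            if c - by == 1:
                self.cnt[k] = 0
                out.append((a, b, False))
            else:
                if c - by < 1:
                    raise AssertionError("overlap count underflow")
                self.cnt[k] = c - by
                out.append((a, b, True))
        self._compact(max(i - 1, 0), min(j + 1, len(self.pos)))
        return out

    def _compact(self, lo: int, hi: int) -> None:
        """Merge equal adjacent pieces in the index range [lo, hi)."""
        k = max(lo, 1)
        while k < len(self.pos) and k <= hi:
            if self.cnt[k] == self.cnt[k - 1]:
                del self.pos[k]
                del self.cnt[k]
                hi -= 1
            else:
                k += 1

    def total_uncoalesced(self) -> float:
        tot = 0.0
        for k, c in enumerate(self.cnt):
            if c > 0:
                b = self.pos[k + 1] if k + 1 < len(self.pos) else self.axis_length
                tot += b - self.pos[k]
        return tot


class TableBuilder:
    """Accumulates node and edge rows during a simulation."""

    def __init__(self):
        self.node_time: list[float] = []
        self.node_population: list[int] = []
        self.node_flags: list[int] = []
        self.node_individual: list[int] = []
        self.edge_left: list[float] = []
        self.edge_right: list[float] = []
        self.edge_parent: list[int] = []
        self.edge_child: list[int] = []

    @property
    def num_nodes(self) -> int:
        return len(self.node_time)

    def add_node(self, time: float, population: int, flags: int = 0,
                 individual: int = -1) -> int:
        self.node_time.append(float(time))
        self.node_population.append(int(population))
        self.node_flags.append(int(flags))
        self.node_individual.append(int(individual))
        return len(self.node_time) - 1

    def add_edge(self, left: float, right: float, parent: int, child: int) -> None:
        self.edge_left.append(float(left))
        self.edge_right.append(float(right))
        self.edge_parent.append(int(parent))
        self.edge_child.append(int(child))


def new_sample_lineages(counts, genetic_map: GeneticMap, spacer: float = 0.0):
    """Create one whole-axis lineage and one sample node per haploid sample.

    ``counts`` maps population index to haploid sample count. Returns
    ``(lineages, tables, overlap)`` where ``overlap`` is primed with the
    total sample count across the whole axis.
    """
    items = sorted(counts.items()) if isinstance(counts, dict) else sorted(counts)
    total = sum(k for _, k in items)
    if total < 1:
        raise ConfigurationError("total sample count must be >= 1")
    axis = genetic_map.axis_length(spacer)
    tables = TableBuilder()
    lineages = []
    for pop, k in items:
        for _ in range(k):
            node = tables.add_node(0.0, pop, NODE_IS_SAMPLE)
            lineages.append(Lineage([(0.0, axis, node)], pop))
    overlap = OverlapMap(axis, total)
    return lineages, tables, overlap


def merge_many(children, time, population, tables: TableBuilder,
               overlap: OverlapMap, individual: int = -1):
    """Merge the segment lists of ``children`` into a single lineage.

    Where h >= 2 children overlap, one ancestor node (created lazily, once
    per call) receives edges from all h carriers, the overlap count drops
    by h-1, and material whose count reaches one is pruned. Material
    carried by a single child passes through unchanged. Returns the merged
    :class:`Lineage`, or ``None`` if nothing ancestral remains.
    """
    for c in children:
        if c.population != population:
            raise AssertionError("merge across populations; migrate first")
    segs = sorted((s for c in children for s in c.segs), key=lambda s: (s[0], s[1]))
    if not segs:
        return None

    out: list[tuple[float, float, int]] = []
    new_node = -1
    active: list[tuple[float, int]] = []  # heap of (right, node)
    points = sorted({p for s in segs for p in (s[0], s[1])})
    si = 0
    for pi in range(len(points) - 1):
        a, b = points[pi], points[pi + 1]
        while si < len(segs) and segs[si][0] <= a:
            heapq.heappush(active, (segs[si][1], segs[si][2]))
            si += 1
        while active and active[0][0] <= a:
            heapq.heappop(active)
        h = len(active)
        if h == 0:
            continue
        if h == 1:
            _append_seg(out, a, b, active[0][1])
            continue
        if new_node == -1:
            new_node = tables.add_node(time, population, 0, individual)
        for _, child_node in sorted(active, key=lambda t: t[1]):
            tables.add_edge(a, b, new_node, child_node)
        for pa, pb, survived in overlap.decrement(a, b, h - 1):
            if survived:
                _append_seg(out, pa, pb, new_node)
    if not out:
        return None
    return Lineage(out, population)


def _append_seg(out, a, b, node):
    if out and out[-1][2] == node and out[-1][1] == a:
        out[-1] = (out[-1][0], b, node)
    else:
        out.append((a, b, node))


def merge_lineages(a: Lineage, b: Lineage, time, tables, overlap,
                   individual: int = -1):
    """Pairwise common-ancestor event (the coalescent's merge)."""
    return merge_many([a, b], time, a.population, tables, overlap, individual)


def is_fully_coalesced(lineages) -> bool:
    """True iff no extant lineage carries ancestral material."""
    return all(not lin.segs for lin in lineages) if lineages else True
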