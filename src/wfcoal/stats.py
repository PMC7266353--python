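"""Multi-locus statistics computed from recorded genealogies.

IBD is defined genealogically: a maximal genomic interval on which a pair
of samples has a constant MRCA node with time at most ``max_gen``
generations in the past. Segment lengths are reported in centimorgans and
exclude any inert inter-chromosome spacer the simulation axis carried.
Ancestry fractions are attributed through census nodes recorded at an
admixture pulse. Mutations are dropped on edges under the infinite-sites
model to produce site tables for SFS and LD summaries.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .genome import ConfigurationError
from .tables import Genealogy

__all__ = [
    "lineage_counts",
    "extract_ibd",
    "ancestry_fractions",
    "drop_mutations",
    "sfs",
    "pairwise_r2",
]


def lineage_counts(g: Genealogy) -> pd.DataFrame:
    """Table of (generation, extant lineage count) recorded during the run."""
    if g.trace.empty:
        raise ConfigurationError("run was executed without lineage-count recording")
    return g.trace.copy()


# ---------------------------------------------------------------------------
# descent machinery shared by IBD, ancestry and mutation carriers

def _descent_sets(g: Genealogy, time_cap: float | None = None,
                  pair_visitor=None):
    """Bottom-up descendant intervals for every node with time <= cap.

    Returns ``{node: [(left, right, sample), ...]}`` sorted by left. If
    ``pair_visitor`` is given it is called as
    ``pair_visitor(node, time, sample_i, sample_j, left, right)`` for every
    interval on which two samples meet for the first time (i.e. their
    marginal MRCA at that interval is ``node``).
    """
    times = g.nodes.time.to_numpy()
    edges = g.edges
    if time_cap is not None:
        keep = times[edges.parent.to_numpy()] <= time_cap + 1e-9
        edges = edges[keep]
    by_parent: dict[int, list[tuple[float, float, int]]] = defaultdict(list)
    for l, r, p, c in zip(edges.left.to_numpy(), edges.right.to_numpy(),
                          edges.parent.to_numpy(), edges.child.to_numpy()):
        by_parent[int(p)].append((float(l), float(r), int(c)))

    descent: dict[int, list[tuple[float, float, int]]] = {}
    for s in g.sample_ids:
        descent[int(s)] = [(0.0, g.axis_length, int(s))]

    internal = sorted(by_parent, key=lambda u: (times[u], u))
    for u in internal:
        contribs: list[tuple[float, float, int, int]] = []  # (l, r, sample, child_slot)
        for slot, (el, er, c) in enumerate(by_parent[u]):
            for dl, dr, s in descent.get(c, ()):
                a, b = max(dl, el), min(dr, er)
                if a < b:
                    contribs.append((a, b, s, slot))
        contribs.sort()
        if pair_visitor is not None and len(by_parent[u]) > 1:
            _visit_pairs(u, float(times[u]), contribs, pair_visitor)
        merged: list[tuple[float, float, int]] = []
        for a, b, s, _ in contribs:
            merged.append((a, b, s))
        merged.sort()
        descent[u] = _union_per_sample(merged)
    return descent


def _visit_pairs(u, t, contribs, visitor):
    # contribs sorted by left; brute sweep with active window
    active: list[tuple[float, float, int, int]] = []
    for a, b, s, slot in contribs:
        active = [iv for iv in active if iv[1] > a]
        for a2, b2, s2, slot2 in active:
            if slot2 != slot and s2 != s:
                lo, hi = max(a, a2), min(b, b2)
                if lo < hi:
                    visitor(u, t, min(s, s2), max(s, s2), lo, hi)
        active.append((a, b, s, slot))


def _union_per_sample(intervals):
    """Union overlapping/adjacent intervals belonging to the same sample."""
    by_sample: dict[int, list[tuple[float, float]]] = defaultdict(list)
    for a, b, s in intervals:
        by_sample[s].append((a, b))
    out = []
    for s, ivs in by_sample.items():
        ivs.sort()
        cl, cr = ivs[0]
        for a, b in ivs[1:]:
            if a <= cr:
                cr = max(cr, b)
            else:
                out.append((cl, cr, s))
                cl, cr = a, b
        out.append((cl, cr, s))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# IBD

def _split_at(a: float, b: float, boundaries) -> list[tuple[float, float]]:
    """Split [a, b) at the given sorted positions."""
    out = []
    lo = a
    for x in boundaries:
        if lo < x < b:
            out.append((lo, float(x)))
            lo = float(x)
        elif x >= b:
            break
    out.append((lo, b))
    return out


def extract_ibd(g: Genealogy, max_gen: float, min_cm: float = 0.0):
    """IBD records and per-pair summaries from a recorded genealogy.

    Returns ``(records, summaries)``: ``records`` has one row per maximal
    constant-MRCA interval with TMRCA <= ``max_gen`` and genetic length
    >= ``min_cm`` centimorgans; ``summaries`` aggregates per sample pair.
    """
    if max_gen <= 0:
        raise ConfigurationError("max_gen must be > 0")
    raw: dict[tuple[int, int], list[tuple[float, float, int, float]]] = defaultdict(list)

    def visitor(u, t, si, sj, lo, hi):
        raw[(si, sj)].append((lo, hi, u, t))

    _descent_sets(g, time_cap=max_gen, pair_visitor=visitor)

    bounds = g.map.boundaries(g.spacer)
    rows = []
    for (si, sj), ivs in raw.items():
        ivs.sort()
        cl, cr, cm, ct = ivs[0]
        pieces = []
        for a, b, u, t in ivs[1:]:
            if u == cm and a <= cr:
                cr = max(cr, b)
            else:
                pieces.append((cl, cr, cm, ct))
                cl, cr, cm, ct = a, b, u, t
        pieces.append((cl, cr, cm, ct))
        for a, b, u, t in pieces:
            # IBD segments never span chromosomes
            for pa, pb in _split_at(a, b, bounds):
                length_cm = 100.0 * g.map.genetic_length(pa, pb, g.spacer)
                if length_cm >= min_cm and length_cm > 0:
                    rows.append((si, sj, pa, pb, u, t, length_cm))
    records = pd.DataFrame(rows, columns=["sample_a", "sample_b", "left", "right",
                                          "mrca", "tmrca", "length_cm"])
    records = records.sort_values(["sample_a", "sample_b", "left"]).reset_index(drop=True)
    if len(records):
        summaries = (records.groupby(["sample_a", "sample_b"])
                     .agg(n_segments=("length_cm", "size"),
                          total_cm=("length_cm", "sum"),
                          min_tmrca=("tmrca", "min"))
                     .reset_index())
    else:
        summaries = pd.DataFrame(columns=["sample_a", "sample_b", "n_segments",
                                          "total_cm", "min_tmrca"])
    return records, summaries


def ibd_grid_scan(g: Genealogy, max_gen: float):
    """Independent brute-force IBD oracle: per-pair MRCA between every pair
    of adjacent table breakpoints, evaluated at interval midpoints.

    Because MRCAs are piecewise constant between recorded breakpoints this
    scan is exact; it is deliberately slow and used to validate
    :func:`extract_ibd`.
    """
    times = g.nodes.time.to_numpy()
    edges = g.edges
    samples = [int(s) for s in g.sample_ids]
    pts = g.breakpoints()
    out: dict[tuple[int, int], list[tuple[float, float, int, float]]] = defaultdict(list)
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        x = 0.5 * (a + b)
        cover = edges[(edges.left.to_numpy() <= x) & (edges.right.to_numpy() > x)]
        par = dict(zip(cover.child.to_numpy(), cover.parent.to_numpy()))
        anc: dict[int, list[int]] = {}
        for s in samples:
            path = [s]
            u = s
            while u in par:
                u = int(par[u])
                path.append(u)
            anc[s] = path
        for ii, si in enumerate(samples):
            seti = {u: d for d, u in enumerate(anc[si])}
            for sj in samples[ii + 1:]:
                mrca = None
                for u in anc[sj]:
                    if u in seti:
                        mrca = u
                        break
                if mrca is not None and times[mrca] <= max_gen and times[mrca] > 0:
                    out[(si, sj)].append((a, b, mrca, float(times[mrca])))
    bounds = g.map.boundaries(g.spacer)
    rows = []
    for (si, sj), ivs in out.items():
        ivs.sort()
        merged = []
        cl, cr, cm, ct = ivs[0]
        for a, b, u, t in ivs[1:]:
            if u == cm and a <= cr + 1e-12:
                cr = max(cr, b)
            else:
                merged.append((cl, cr, cm, ct))
                cl, cr, cm, ct = a, b, u, t
        merged.append((cl, cr, cm, ct))
        for a, b, u, t in merged:
            for pa, pb in _split_at(a, b, bounds):
                rows.append((si, sj, pa, pb, u, t))
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "left", "right",
                                     "mrca", "tmrca"])
    return df.sort_values(["sample_a", "sample_b", "left"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ancestry fractions

def ancestry_fractions(g: Genealogy, census_time: float, migrant_population: int):
    """Per-sample migrant-ancestry fraction and its across-sample variance.

    The fraction of sample s is the genetic length (spacer gaps excluded)
    of the genome whose ancestral lineage at ``census_time`` sits in a
    census node of ``migrant_population``, divided by the total map length.
    """
    census = g.census_nodes(census_time)
    if len(census) == 0:
        raise ConfigurationError(
            "no census nodes at that time; enable pulse census recording")
    descent = _descent_sets(g, time_cap=census_time)
    pops = g.nodes.population.to_numpy()
    L = g.map.total_length
    fractions = pd.Series(0.0, index=[int(s) for s in g.sample_ids])
    for cn in census:
        if pops[cn] != migrant_population:
            continue
        for a, b, s in descent.get(int(cn), ()):
            fractions[s] += g.map.genetic_length(a, b, g.spacer)
    fractions /= L
    fractions = fractions.clip(0.0, 1.0)  # guard float round-off at the ends
    var = float(fractions.var(ddof=1)) if len(fractions) > 1 else 0.0
    return fractions, var


# ---------------------------------------------------------------------------
# mutations, SFS, LD

def drop_mutations(g: Genealogy, mu: float, rng) -> pd.DataFrame:
    """Infinite-sites mutations on edges.

    Each edge receives Poisson(mu * genetic span * branch length)
    mutations at uniform positions; a site lists the derived-allele
    carriers (the samples below the edge's child at that position).
    Returns a site table (position, chromosome, node, count, carriers).
    """
    if mu < 0:
        raise ConfigurationError("mutation rate must be >= 0")
    rows = []
    if mu > 0 and len(g.edges):
        times = g.nodes.time.to_numpy()
        descent = _descent_sets(g)
        seen = set()
        for l, r, p, c in zip(g.edges.left.to_numpy(), g.edges.right.to_numpy(),
                              g.edges.parent.to_numpy(), g.edges.child.to_numpy()):
            span = g.map.genetic_length(l, r, g.spacer)
            branch = times[int(p)] - times[int(c)]
            lam = mu * span * branch
            if lam <= 0:
                continue
            n = rng.poisson(lam)
            for _ in range(n):
                while True:
                    x = rng.uniform(l, r)
                    if x not in seen and _not_in_gap(g, x):
                        seen.add(x)
                        break
                carriers = tuple(sorted(
                    s for a, b, s in descent.get(int(c), ()) if a <= x < b))
                if carriers:
                    rows.append((x, g.map.chromosome_of(x, g.spacer), int(c),
                                 len(carriers), carriers))
    sites = pd.DataFrame(rows, columns=["position", "chromosome", "node",
                                        "count", "carriers"])
    return sites.sort_values("position").reset_index(drop=True)


def _not_in_gap(g: Genealogy, x: float) -> bool:
    if g.spacer == 0:
        return True
    ends = g.map.ends(g.spacer)
    starts = g.map.starts(g.spacer)
    chrom = g.map.chromosome_of(x, g.spacer)
    return starts[chrom] <= x < ends[chrom]


def branch_sfs(g: Genealogy, mu: float) -> pd.Series:
    """Expected allele-count spectrum given the genealogy (branch mode).

    Index i holds mu times the total (genetic span x branch length) over
    which an edge subtends exactly i samples — the infinite-sites
    expectation of :func:`sfs` under mutation rate ``mu``, free of
    mutational sampling noise.
    """
    n = g.num_samples
    out = np.zeros(n + 1)
    if len(g.edges) == 0:
        return pd.Series(out[1:n], index=range(1, n))
    times = g.nodes.time.to_numpy()
    descent = _descent_sets(g)
    for l, r, p, c in zip(g.edges.left.to_numpy(), g.edges.right.to_numpy(),
                          g.edges.parent.to_numpy(), g.edges.child.to_numpy()):
        branch = times[int(p)] - times[int(c)]
        if branch <= 0:
            continue
        ivs = [(max(a, l), min(b, r)) for a, b, _ in descent.get(int(c), ())]
        ivs = [(a, b) for a, b in ivs if a < b]
        if not ivs:
            continue
        pts = sorted({x for ab in ivs for x in ab})
        for i in range(len(pts) - 1):
            a, b = pts[i], pts[i + 1]
            cnt = sum(1 for aa, bb in ivs if aa <= a and bb >= b)
            if 0 < cnt <= n:
                out[cnt] += mu * g.map.genetic_length(a, b, g.spacer) * branch
    return pd.Series(out[1:n], index=range(1, n))


def sfs(sites: pd.DataFrame, n: int) -> pd.Series:
    """Allele-count histogram: index i counts sites with i derived carriers."""
    counts = pd.Series(0, index=range(1, n), dtype=int)
    if len(sites):
        vc = sites["count"].value_counts()
        for i, v in vc.items():
            if 1 <= i <= n - 1:
                counts[i] = int(v)
    return counts


def pairwise_r2(sites: pd.DataFrame, g: Genealogy, bin_edges,
                rng=None, max_pairs_per_bin: int = 20000,
                min_minor_count: int = 1) -> pd.DataFrame:
    """Mean r-squared between site pairs, binned by genetic distance.

    ``bin_edges`` are distances in Morgans; pairs on different chromosomes
    go to an extra "unlinked" bin. r2 is the squared sample correlation of
    the 0/1 haplotype indicators over all samples.
    """
    samples = [int(s) for s in g.sample_ids]
    n = len(samples)
    idx = {s: i for i, s in enumerate(samples)}
    poly = sites[(sites["count"] >= min_minor_count)
                 & (sites["count"] <= n - min_minor_count)].reset_index(drop=True)
    m = len(poly)
    if m < 2:
        return pd.DataFrame(columns=["bin_left", "bin_right", "mean_r2", "n_pairs"])
    geno = np.zeros((m, n))
    for i, carriers in enumerate(poly.carriers):
        for s in carriers:
            geno[i, idx[s]] = 1.0
    pos = poly.position.to_numpy()
    chrom = poly.chromosome.to_numpy()
    edges_arr = np.asarray(list(bin_edges), dtype=float)
    nbins = len(edges_arr) - 1
    labels: list[list[tuple[int, int]]] = [[] for _ in range(nbins + 1)]
    for i in range(m):
        for j in range(i + 1, m):
            if chrom[i] != chrom[j]:
                labels[nbins].append((i, j))
            else:
                d = g.map.genetic_length(min(pos[i], pos[j]),
                                         max(pos[i], pos[j]), g.spacer)
                b = np.searchsorted(edges_arr, d, side="right") - 1
                if 0 <= b < nbins:
                    labels[b].append((i, j))
    rows = []
    for b in range(nbins + 1):
        pairs = labels[b]
        if not pairs:
            continue
        if rng is not None and len(pairs) > max_pairs_per_bin:
            sel = rng.choice(len(pairs), size=max_pairs_per_bin, replace=False)
            pairs = [pairs[int(i)] for i in sel]
        vals = []
        for i, j in pairs:
            x, y = geno[i], geno[j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
            vals.append(r * r)
        if vals:
            if b < nbins:
                rows.append((edges_arr[b], edges_arr[b + 1],
                             float(np.mean(vals)), len(vals)))
            else:
                rows.append((np.inf, np.inf, float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "mean_r2", "n_pairs"])
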