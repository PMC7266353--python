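"""Closed-form expectations and forward-simulation oracles.

These are the independent surfaces against which the backward engines are
checked: expected IBD segment counts/lengths between relatives, the
probability of carrying a p-th cousin in a sample, and the expected
variance of migrant-ancestry proportions after a single admixture pulse.
The forward gene-dropping oracle is an entirely separate code path from
the backward engines (it shares only the meiosis draw, deliberately, so
that comparisons are about genealogy rather than recombination
modelling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import Population
from .dtwf import draw_meiosis
from .genome import ConfigurationError, GeneticMap

__all__ = [
    "RelativePair",
    "expected_ibd",
    "cousin_containment",
    "expected_ancestry_variance",
    "forward_pedigree_oracle",
    "gene_drop_pair",
]


@dataclass(frozen=True)
class RelativePair:
    """A relationship class between two haploid genomes (gametes).

    ``a`` is the number of shared ancestor individuals (1 for half-type
    relationships, 2 for full/couple-sharing ones) and ``m`` the total
    number of meioses separating the two genomes through the shared
    ancestor(s). Same-parent gametes are (a=1, m=2); gametes of two
    diploid half-sibs are (a=1, m=4); gametes of full first cousins
    through a shared grandparent couple are (a=2, m=6).
    """

    a: int
    m: int
    label: str = ""

    def __post_init__(self):
        if self.a not in (1, 2):
            raise ConfigurationError("a must be 1 or 2")
        if self.m < 2:
            raise ConfigurationError("m must be >= 2")

    @property
    def p_ibd(self) -> float:
        """Pointwise probability that the pair is IBD at a locus."""
        return self.a * 2.0 ** (1 - self.m)


def expected_ibd(pair: RelativePair, genetic_map: GeneticMap,
                 min_len: float = 0.0):
    """Expected number and total length of IBD segments >= ``min_len``.

    Model: along each chromosome, the IBD indicator for gametes separated
    by m meioses is an alternating renewal process: crossovers in any of
    the m meioses (rate m per Morgan) end an IBD segment, so segment
    lengths are Exp(m) truncated at chromosome ends; segments begin at
    stationary rate m*p per Morgan with p = a*2^(1-m). Lengths are in
    Morgans. The forward gene-dropping oracle validates this closed form.
    """
    m = pair.m
    p = pair.p_ibd
    t = float(min_len)
    if t < 0:
        raise ConfigurationError("min_len must be >= 0")
    e_count = 0.0
    e_length = 0.0
    emt = math.exp(-m * t)
    for l in genetic_map.chromosome_lengths:
        if l < t:
            continue
        e_count += p * emt * (1.0 + m * (l - t))
        # start-at-0 run plus interior starts, each truncated at the
        # chromosome end (integrals of the Exp(m) tail)
        start0 = p * ((t + 1.0 / m) * emt - (1.0 / m) * math.exp(-m * l))
        interior = m * p * ((l - t) * (t + 1.0 / m) * emt
                            - (math.exp(-m * t) - math.exp(-m * l)) / m ** 2)
        e_length += start0 + interior
    return e_count, e_length


# ---------------------------------------------------------------------------
# cousins in a sample (monogamous Wright-Fisher population)

def cousin_containment(K: int, N: int, p: int, rng=None, replicates: int = 20,
                       method: str = "simulation"):
    """Probability that a sampled individual has >= 1 p-th cousin in the
    sample, in a monogamous Wright-Fisher population of N breeding couples
    (2N individuals per generation), with K sampled individuals.

    Two individuals are p-th cousins when they share an ancestor couple
    exactly p+1 generations back (and none more recently). Returns
    ``(probability, metadata)``; ``method`` is either ``"simulation"``
    (``replicates`` independent pedigrees) or ``"closed_form"`` (Poisson
    collision approximation ``1 - (1 - q)^(K-1)`` with
    ``q = 1 - (1 - 1/N)^(4^p)``).
    """
    if K < 1 or N < 1 or K > N:
        raise ConfigurationError("need 1 <= K <= N")
    if p < 1:
        raise ConfigurationError("cousin degree p must be >= 1")
    if K == 1:
        return 0.0, {"method": method, "replicates": 0}
    if method == "closed_form":
        q = 1.0 - (1.0 - 1.0 / N) ** (4 ** p)
        return 1.0 - (1.0 - q) ** (K - 1), {"method": "closed_form", "replicates": 0}
    if rng is None:
        rng = np.random.default_rng()
    vals = [_cousin_sim_once(K, N, p, rng) for _ in range(replicates)]
    return float(np.mean(vals)), {
        "method": "simulation", "replicates": replicates,
        "sd": float(np.std(vals, ddof=1)) if replicates > 1 else float("nan"),
    }


def _cousin_sim_once(K, N, p, rng):
    # parent_couple[t][i]: couple index (in [0, N)) of individual i of
    # generation t; individuals 2c and 2c+1 form couple c of their
    # generation. Sampled individuals are one child from each of K
    # distinct couples: a sibling-free cohort, which is what both the
    # Poisson closed form and sibling-filtered real cohorts describe.
    levels = p + 1
    parent_couple = [None] + [rng.integers(0, N, size=2 * N) for _ in range(1, levels)]
    sample_couples = rng.choice(N, size=K, replace=False)
    # ancestor couple sets per sample per level (level 0 = parent couple)
    anc: list[list[np.ndarray]] = []
    for c in sample_couples:
        sets = [np.asarray([c])]
        for t in range(1, levels):
            members = np.concatenate([(2 * sets[-1]), (2 * sets[-1] + 1)])
            sets.append(np.unique(parent_couple[t][members]))
        anc.append(sets)
    # invert top level: couple -> sample indices
    top: dict[int, list[int]] = {}
    for i, sets in enumerate(anc):
        for c in sets[-1]:
            top.setdefault(int(c), []).append(i)
    has = np.zeros(K, dtype=bool)
    for c, members in top.items():
        if len(members) < 2:
            continue
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                i, j = members[ii], members[jj]
                if has[i] and has[j]:
                    continue
                closer = any(
                    np.intersect1d(anc[i][t], anc[j][t], assume_unique=True).size
                    for t in range(levels - 1))
                if not closer:
                    has[i] = has[j] = True
    return has.mean()


# ---------------------------------------------------------------------------
# ancestry variance after a single pulse

def expected_ancestry_variance(f: float, g: int, genetic_map: GeneticMap,
                               N: float, cohort: bool = True,
                               quad_points: int = 400):
    """Expected across-sample variance of migrant-ancestry proportions,
    ``g`` generations after a pulse of fraction ``f``, for haploid sample
    genomes in a diploid population of size N.

    Two genome positions share migrant status iff they trace to the same
    *individual* at the admixed generation. The probability u_t that two
    positions at genetic distance d sit on the same haplotype t
    generations back follows ``u_{t+1} = u_t s(d) + (1 - u_t)/(2N)`` with
    Haldane cosegregation ``s(d) = (1 + exp(-2d))/2`` (1/2 across
    chromosomes); the same-individual probability after the final step is
    ``q_g = u_{g-1} + (1 - u_{g-1})/N``. The variance is
    ``f(1-f) * E_{x,y}[q_g]``; with ``cohort=True`` the expected
    between-sample covariance (same recursion started from different
    haplotypes) is subtracted, which is what the sample variance across a
    cohort estimates. The genealogical part of the curve is approximately
    ``f(1-f)/2^(g-1)``; the recursion adds the recombination and
    finite-population terms that dominate at larger g.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError("f must be in [0, 1]")
    if g < 1:
        raise ConfigurationError("g must be >= 1")
    if f == 0.0 or f == 1.0:
        return 0.0

    L = genetic_map.total_length
    lengths = np.asarray(genetic_map.chromosome_lengths)

    # distance grid within chromosomes, plus the unlinked (cross-chromosome)
    # point; weights from the geometry of uniform (x, y) pairs
    ds, ws = [], []
    for l in lengths:
        grid = np.linspace(0.0, l, quad_points)
        dens = 2.0 * (l - grid) / L ** 2  # density of |x-y|=d within this chrom
        wts = np.zeros_like(grid)  # per-point trapezoid weights
        dg = np.diff(grid)
        wts[:-1] += 0.5 * dg * dens[:-1]
        wts[1:] += 0.5 * dg * dens[1:]
        ds.append(grid)
        ws.append(wts)
    ds = np.concatenate(ds + [[0.0]])
    s = 0.5 * (1.0 + np.exp(-2.0 * ds))
    w_same = np.concatenate(ws + [[0.0]])
    s[-1] = 0.5  # the unlinked point
    w_same[-1] = 1.0 - w_same[:-1].sum()

    u = np.ones_like(s)   # same haplotype, same genome
    v = np.zeros_like(s)  # different sample haplotypes
    for _ in range(g - 1):
        u = u * s + (1.0 - u) / (2.0 * N)
        v = v * s + (1.0 - v) / (2.0 * N)
    qu = u + (1.0 - u) / N
    qv = v + (1.0 - v) / N
    mean_qu = float((qu * w_same).sum())
    mean_qv = float((qv * w_same).sum())
    var = f * (1.0 - f) * (mean_qu - (mean_qv if cohort else 0.0))
    return var


# ---------------------------------------------------------------------------
# forward gene-dropping oracles

def _meiosis_product(hap0, hap1, genetic_map: GeneticMap, rng):
    """One gamete from a diploid (hap0, hap1); haps are label mosaics
    [(left, right, label), ...] covering [0, L)."""
    L = genetic_map.total_length
    draw = draw_meiosis((0.0, L), genetic_map, rng)
    cuts = [(float(x), 0, 0) for x in draw.breakpoints]
    cuts += [(float(x), 1, int(c)) for x, c in zip(draw.boundaries, draw.boundary_coins)]
    cuts.sort()
    hap = draw.phase
    out = []
    pos = 0.0
    ci = 0
    sources = (hap0, hap1)
    while pos < L:
        while ci < len(cuts) and cuts[ci][0] <= pos:
            _, kind, coin = cuts[ci]
            hap = (1 - hap) if kind == 0 else coin
            ci += 1
        nxt = cuts[ci][0] if ci < len(cuts) else L
        for a, b, lab in sources[hap]:
            lo, hi = max(a, pos), min(b, nxt)
            if lo < hi:
                if out and out[-1][1] == lo and out[-1][2] == lab:
                    out[-1] = (out[-1][0], hi, lab)
                else:
                    out.append((lo, hi, lab))
        pos = nxt
    return out


def gene_drop_pair(pair: RelativePair, genetic_map: GeneticMap, rng,
                   min_len: float = 0.0):
    """Drop genes through the pedigree of one relative pair; return the
    (count, total length) of IBD segments >= ``min_len`` Morgans.

    The two gametes descend from a shared ancestor individual (a=1) or
    ancestor couple (a=2) through m/2 meioses on each side (m even) or
    (m+1)/2 and (m-1)/2 (m odd). IBD = same ancestor-haplotype label.
    """
    L = genetic_map.total_length
    m_i = pair.m // 2
    m_j = pair.m - m_i

    def fresh(label):
        return [(0.0, L, label)]

    def descend(start_hap_pair, n_meioses):
        gam = _meiosis_product(start_hap_pair[0], start_hap_pair[1], genetic_map, rng)
        for _ in range(n_meioses - 1):
            gam = _meiosis_product(gam, fresh(-1), genetic_map, rng)
        return gam

    if pair.a == 1:
        start = (fresh(0), fresh(1))          # the shared ancestor's haplotypes
        gi = descend(start, m_i)
        gj = descend(start, m_j)
    else:
        # shared couple: each side's first individual has one gamete from
        # each member of the couple
        anc_a = (fresh(0), fresh(1))
        anc_b = (fresh(2), fresh(3))
        def child_gametes(n_meioses):
            h_from_a = _meiosis_product(anc_a[0], anc_a[1], genetic_map, rng)
            h_from_b = _meiosis_product(anc_b[0], anc_b[1], genetic_map, rng)
            gam = _meiosis_product(h_from_a, h_from_b, genetic_map, rng)
            for _ in range(n_meioses - 2):
                gam = _meiosis_product(gam, fresh(-1), genetic_map, rng)
            return gam
        gi = child_gametes(m_i)
        gj = child_gametes(m_j)

    # intersect the two label mosaics; IBD where labels match and >= 0.
    # adjacent runs with different labels stay separate segments (their
    # MRCA haplotype differs), matching the genealogical definition
    segs = []
    for a1, b1, l1 in gi:
        if l1 < 0:
            continue
        for a2, b2, l2 in gj:
            if l2 == l1:
                lo, hi = max(a1, a2), min(b1, b2)
                if lo < hi:
                    segs.append((lo, hi, l1))
    segs.sort()
    merged = []
    for a, b, lab in segs:
        if merged and merged[-1][2] == lab and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b), lab)
        else:
            merged.append((a, b, lab))
    # segments never span chromosomes
    bounds = genetic_map.boundaries(0.0)
    pieces = []
    for a, b, _ in merged:
        lo = a
        for x in bounds:
            if lo < x < b:
                pieces.append((lo, float(x)))
                lo = float(x)
        pieces.append((lo, b))
    kept = [(a, b) for a, b in pieces if b - a >= min_len]
    return len(kept), float(sum(b - a for a, b in kept))


def forward_pedigree_oracle(N: int, G: int, genetic_map: GeneticMap, rng,
                            monogamous: bool = False,
                            migrant_fraction: float = 0.0):
    """Forward-time random-mating population with gene dropping.

    N diploid individuals per generation; each child draws two parents
    (one fixed couple if ``monogamous``, two independent uniform parents
    otherwise — matching the engines' non-monogamous convention) and one
    gamete from each. Founder haplotypes carry unique labels; when
    ``migrant_fraction`` > 0, founder *individuals* are labelled migrant
    with that probability. Returns ``(haplotypes, migrant_labels)``:
    the 2N final-generation haplotype mosaics and the set of founder
    labels that are migrant.
    """
    if N < 1 or G < 1:
        raise ConfigurationError("need N >= 1 and G >= 1")
    L = genetic_map.total_length
    pop = [[[(0.0, L, 2 * i)], [(0.0, L, 2 * i + 1)]] for i in range(N)]
    migrant = set()
    if migrant_fraction > 0:
        for i in range(N):
            if rng.uniform() < migrant_fraction:
                migrant.update((2 * i, 2 * i + 1))
    for _ in range(G):
        if monogamous:
            perm = rng.permutation(N)
            couples = [(int(perm[2 * c]), int(perm[2 * c + 1]))
                       for c in range(N // 2)]
            choice = rng.integers(0, len(couples), size=N)
            parents = [couples[int(c)] for c in choice]
        else:
            pa = rng.integers(0, N, size=N)
            pb = rng.integers(0, N, size=N)
            parents = list(zip(pa.tolist(), pb.tolist()))
        pop = [[_meiosis_product(*pop[p1], genetic_map, rng),
                _meiosis_product(*pop[p2], genetic_map, rng)]
               for p1, p2 in parents]
    haps = [h for ind in pop for h in ind]
    return haps, migrant


def migrant_fraction_of(hap, migrant_labels, genetic_map: GeneticMap) -> float:
    """Fraction of a gene-dropped haplotype inherited from migrant founders."""
    L = genetic_map.total_length
    tot = sum(b - a for a, b, lab in hap if lab in migrant_labels)
    return tot / L
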