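# Methods

`wfcoal` simulates the genealogy of a sample of haploid genomes backwards
in time under three models — Hudson's coalescent with recombination, a
discrete-time Wright-Fisher (WF) model, and a hybrid of the two — and
computes the multi-locus statistics on which the models disagree:
identity-by-descent (IBD) sharing, lineage counts through time, the
variance of admixture-ancestry proportions, the site frequency spectrum
(SFS), and long-range linkage disequilibrium (LD).

## Coordinates and maps

All simulation coordinates are genetic (Morgans) on one concatenated
half-open axis. A `GeneticMap` is a list of per-chromosome genetic
lengths with a uniform rate within each chromosome; the bundled
`human22` fixture has 22 autosome-like lengths totalling ≈35.5 M.
Physical positions (for VCF output) come from a uniform `bp_per_morgan`
scale, 1 cM/Mb by default.

The two engines treat chromosome boundaries differently, which is the
heart of the matter:

* the WF engine models meiosis directly — crossover breakpoints are a
  Poisson process at rate equal to the genetic span, material alternates
  between the two parental haplotypes from a fair starting phase, and an
  independent fair coin at each chromosome boundary implements
  independent assortment;
* Hudson's linear-rate model cannot represent assortment, so chromosomes
  are concatenated with an inert spacer (`hudson_spacer`, default 0.5 M)
  whose only effect is map distance between chromosomes. The spacer is
  configurable precisely because it is an approximation; reported
  genetic lengths (IBD, mutation targets) always exclude spacer gaps.
  The hybrid model runs on the spacer-free axis throughout so the WF to
  coalescent hand-over is seamless.

## Genealogy recording

Both engines share one bookkeeping core: lineages carry sorted disjoint
ancestral segments tagged with genealogy nodes; a global piecewise-
constant overlap counter tracks how many extant lineages are ancestral
to each point; merges create one ancestor node per event (so WF
generations may produce polytomies), record edges for every coalescing
interval, and prune material whose counter reaches one — the grand MRCA
stays in the node table, and pruning is what lets simulations terminate.
Node times are real-valued under Hudson and integers under the WF model.
Edges are stored grouped by parent in nondecreasing time order with
adjacent same-(parent, child) intervals squashed; tables round-trip
through versioned TSVs byte-identically.

## Event generation

Hudson engine: competing exponentials — recombination at rate equal to
the summed lineage spans (trapped gaps included), common-ancestor events
in population i at rate k(k−1)/(4N_i(t)), migration per lineage.
Exponential size change N(t) = N0·e^(−αt) is handled by closed-form
inversion of the integrated coalescent rate, so waiting times are exact.
Scheduled demographic events truncate draws (memorylessness makes
redrawing valid). Breakpoints are drawn by choosing a lineage with
probability proportional to its span and a uniform position within the
span; a draw landing exactly on a segment boundary (probability zero in
exact arithmetic) is redrawn. Interval arithmetic is exact — no epsilon
comparisons.

WF engine: per generation — scheduled events, then migration, then each
lineage draws one uniform diploid parent and one meiosis, then all
material landing on the same (parent, haplotype) coalesces. Parent
choice is non-monogamous with no selfing prevention, which (by design,
matching the underlying model) overstates half-sibs relative to real
cohorts. Diploid sizes are rounded per generation with a floor of one.
Lineage counts can therefore never exceed 2N(t), while under Hudson they
routinely blow past it for large samples — the central pathology these
simulations expose.

Admixture pulses: looking backwards, each lineage in the destination
population draws its parent from the source with probability f, and a
census node is recorded on every extant lineage at the pulse time so
migrant ancestry can be attributed afterwards. In the WF engine the
migration coin is shared by the two haplotypes of one diploid parent —
migrants are individuals, so one generation after the pulse a haploid
genome's ancestry variance is f(1−f), not f(1−f)/2. Hudson has no
individuals; its pulses move lineages independently, which is exactly
why it underestimates early ancestry variance by an order of magnitude.

## Statistics

IBD is genealogical: maximal intervals on which a sample pair's marginal
MRCA is constant with time ≤ `max_gen`, merged across adjacent pieces
with the same MRCA, split at chromosome boundaries (segments never span
chromosomes), lengths in cM excluding spacers, thresholded at `min_cm`.
The extraction is validated, exactly, against a brute-force scan that
recomputes every pair's MRCA between every two adjacent table
breakpoints — breakpoint-midpoint evaluation makes the oracle exact, not
approximate.

Ancestry fractions descend each census node to its sample intervals;
the cohort variance is the across-sample sample variance (ddof 1).
Mutations are infinite-sites Poisson on edges (rate μ per Morgan per
generation times genetic span times branch length); the SFS and r²
summaries operate on the resulting site table. r² is the squared sample
correlation of 0/1 haplotype indicators, binned by genetic distance with
a separate unlinked (cross-chromosome) bin; no frequency filter by
default.

## Closed forms and oracles

Expected IBD between gametes separated by m meioses through a shared
ancestors uses an alternating-renewal model: pointwise IBD probability
p = a·2^(1−m), segment death rate m per Morgan (any crossover in the m
meioses ends a segment; exact at m=2, a ≲1.5% approximation for larger
m), stationary start rate m·p, with chromosome-end truncation integrated
explicitly. The arbiter is a forward gene-dropping oracle that shares
only the meiosis draw with the engines and nothing else.

Cousin containment uses a monogamous WF pedigree of N breeding couples
(2N adults); sampled individuals are one child per couple — a
sibling-free cohort, which is what both the Poisson closed form
1−(1−q)^(K−1), q = 1−(1−1/N)^(4^p), and sibling-filtered real cohorts
describe. Sampling siblings too would cluster cousin events within
sibships and lower the containment probability by several points; the
simulation, not the closed form, is the reference output.

Expected ancestry variance tracks, for two genome positions at genetic
distance d, the probability u_t of sharing a haplotype t generations
back: u_{t+1} = u_t·s(d) + (1−u_t)/(2N), with Haldane cosegregation
s(d) = (1+e^(−2d))/2 and s = 1/2 across chromosomes; the probability of
sharing the census *individual* after g generations is
u_{g−1} + (1−u_{g−1})/N. The cohort variance is f(1−f) times the
genome-averaged difference between that quantity and its between-sample
analogue (the recursion started from distinct haplotypes) — subtracting
the between-sample covariance is what the sample variance of a cohort
estimates. The genealogical part behaves like f(1−f)/2^(g−1); the 1/2N
re-meeting terms supply the recombination-variance floor that dominates
after ~10 generations at N=80. Averaging over d uses per-chromosome
trapezoid quadrature (400 points per chromosome; the result changes in
the fourth digit if doubled).

## Scale of the shipped experiments

The full-scale experiments of the large-cohort comparisons (10,000
whole genomes, 22 chromosomes; 100,000-generation horizons) are provided
in `scripts/longrun.py` and take CPU-hours. The test suite runs the same
contrasts at reduced scale, chosen to preserve the regime that drives
each effect rather than raw size: lineage explosion with 1,000 samples
on four chromosomes (peak still >2× the haploid size), persistence with
2,000 samples to generation 10,000, the SFS contrast with the sample
size equal to the haploid population size (2,000 of 2N=2,000) on a 1 Mb
region, IBD with 500 samples, and ancestry variance at its original
published scale (N=80, 80 samples), which was always desk-sized.
Lineage-count-only experiments run through a numba kernel implementing
the identical Hudson process without genealogy recording (validated
against the recording engine distributionally); everything else uses the
recording engines.

## What the synthetic data does and does not capture

The generator *is* the model: uniform per-chromosome recombination, no
crossover interference, no sex differences, random mating without
monogamy, panmictic populations with exponential size change, pulse
admixture. Passing tests therefore demonstrate internal consistency
between engines, closed forms and independent oracles — and reproduce
the qualitative model contrasts — but say nothing about features real
cohorts add: monogamous families (full sibs instead of the half-sib
excess), assortative mating, sex-specific maps, genotyping error in IBD
detection. The half-sib cluster the WF model produces is a property of
the idealized model, expected to sit in a slightly different place than
family clusters in real biobank data.

## Numerical and degenerate-input conventions

Positions are IEEE doubles compared exactly; breakpoint ties have
probability zero and are redrawn if they occur. A single-sample
simulation returns one sample node and no edges. Empty site tables give
all-zero spectra; monomorphic input gives an empty r² table. Ancestry
fractions are clipped to [0,1] against end-of-sum round-off (≤1 ulp).
Census times compare with a 1e-9 tolerance to absorb float time
arithmetic. The fast count kernel preallocates capacity for ~4M
segments and raises rather than reallocating if exceeded.
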