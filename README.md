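# wfcoal

Whole-genome genealogy simulation for large cohorts, under three
backwards-in-time models:

* **Hudson's coalescent with recombination** — lineages split at a rate
  equal to the genetic span of their ancestral material and pairs merge
  at rate C(k,2)/2N(t);
* **a discrete-time Wright-Fisher (WF) model** — explicit generations in
  which every lineage draws one diploid parent and a meiosis (Poisson
  crossovers at the map rate, alternating haplotypes, independent
  chromosome assortment);
* **a hybrid** — WF dynamics for the recent `T` generations, coalescent
  dynamics beyond.

## Why

The coalescent assumes short regions and small samples. Simulated over
whole genomes with thousands of samples, each long-range recombination
spawns an *independent* ancestral lineage, so simulated individuals
acquire far more ancestors than the 2^t a diploid pedigree allows — the
lineage count can exceed the haploid population size 2N many-fold and
stay above it for tens of thousands of generations. That distorts every
statistic tied to recent pedigree structure: close relatives share far
too few identity-by-descent (IBD) segments, the variance of admixture
ancestry after a pulse is underestimated ~20-fold, long-range (between-
chromosome) linkage disequilibrium vanishes, and the site frequency
spectrum misses the singleton excess of simultaneous WF mergers. The WF
engine restores diploid inheritance — each gamete has exactly one parent
— at equal or better speed for long regions; the hybrid keeps the
coalescent's advantage for short ones.

The package is aimed at population-genetics method developers who need
realistic relatedness structure in simulated cohorts (IBD detection,
relative finding, admixture inference, rare-variant studies).

## Worked example

Simulate the recent pedigree of 100 haploid genomes (22 human-length
chromosomes) in a diploid population of 500, stop five generations back,
and extract IBD segments of at least 5 cM:

```sh
$ wfcoal simulate --model dtwf --samples 100 --Ne 500 --map human22 \
      --seed 7 --end-time 5 --out cohort
INFO wfcoal: wrote cohort (724 nodes, 9107 edges)
$ wfcoal stats ibd --tables cohort --max-gen 5 --min-cm 5 --out .
INFO wfcoal: 4093 IBD records, 1356 pairs
$ head -4 ibd.tsv
sample_a  sample_b  left       right      mrca  tmrca  length_cm
0         2         10.652595  10.873838  177   3.0    22.124321
0         2         11.319112  11.454545  177   3.0    13.543365
0         2         19.374503  19.584944  177   3.0    21.044130
```

Samples 0 and 2 meet a common ancestor 3 generations back (node 177) and
share many ~10-25 cM segments scattered across the genome — the pattern
real relatives show, and the one the coalescent fails to produce. The
matching closed form (`a` shared ancestors, `m` meioses apart):

```sh
$ wfcoal theory ibd-expect -a 1 -m 2 --min-cm 5
a  m  min_cm  expected_segments  expected_total_cm
1  2  5.0     41.04252044469308  1759.6780445383426
```

i.e. two gametes of one parent should share ≈41 segments ≥5 cM totalling
≈17.6 Morgans — the isolated half-sib cluster in WF simulations of small
populations. And the Shchur-style cousin count for a biobank-scale
sample (K/N = 0.2):

```sh
$ wfcoal theory cousins -k 2000 -n 10000 -p 1 --replicates 5 --seed 1
K     N      p  probability  method      replicates
2000  10000  1  0.5495       simulation  5
```

about 55% of sampled individuals have a first cousin in the sample.

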