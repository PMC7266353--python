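"""Full-scale lineage-count replications (hours of CPU; not run in CI).

These reproduce the large-cohort experiments at their original scale:

* explosion: 10,000 haploid whole genomes (22 chromosomes) in a
  population of 10,000 diploids with growth rate 0.001 — the coalescent's
  lineage count climbs to ~10x the haploid population size, while the
  Wright-Fisher engine stays below 2N.
* persistence: constant N, the coalescent's count remains above the
  haploid size for over 100,000 generations.

Usage: python scripts/longrun.py explosion|persistence [--seed S]
"""

import argparse

import numpy as np

from wfcoal.demography import SimConfig, DemographicModel
from wfcoal.dtwf import run_dtwf
from wfcoal.fastcount import hudson_lineage_counts
from wfcoal.genome import build_human22_map


def explosion(seed: int):
    gmap = build_human22_map()
    trace = hudson_lineage_counts(
        seed=seed, num_samples=10000, axis_length=gmap.axis_length(0.5),
        n0=10000, growth_rate=0.001, end_time=500,
        seg_capacity=1 << 24, lineage_capacity=1 << 19,
        counter_capacity=1 << 23)
    print("hudson peak lineage count:", trace.max(),
          "(=%.1fx the haploid size 2N=20000)" % (trace.max() / 20000))
    cfg = SimConfig(samples={0: 10000}, map=gmap,
                    demography=DemographicModel.single(10000, 0.001),
                    seed=seed, end_time=500)
    g = run_dtwf(cfg)
    print("dtwf peak lineage count:", g.trace.lineages.max(), "(cap 2N=20000)")


def persistence(seed: int):
    gmap = build_human22_map()
    trace = hudson_lineage_counts(
        seed=seed, num_samples=10000, axis_length=gmap.axis_length(0.5),
        n0=10000, growth_rate=0.0, end_time=120_000,
        seg_capacity=1 << 24, lineage_capacity=1 << 19,
        counter_capacity=1 << 23)
    above = np.nonzero(trace <= 20000)[0]
    first = above[above > 0][0] if (above > 0).any() else None
    print("count at 100,000 generations:", trace[100_000])
    print("first generation at or below 2N:", first)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("experiment", choices=["explosion", "persistence"])
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    if args.experiment == "explosion":
        explosion(args.seed)
    else:
        persistence(args.seed)
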