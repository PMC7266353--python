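"""Demographic models: populations, migration, and scheduled events.

Sizes are diploid individuals. Time is measured in generations, backwards
from the present (t=0 is sampling time). A population's size at time t is
``N(t) = N0 * exp(-alpha * t)`` with backward growth rate ``alpha``; the
discrete-generation engine rounds this to the nearest integer with a floor
of one individual.

Migration is parameterised backwards: ``m[i][j]`` is the per-generation
probability (rate, for the continuous-time engine) that a lineage currently
in population i draws its parent from population j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import ConfigurationError, GeneticMap

__all__ = [
    "Population",
    "SizeChange",
    "GrowthChange",
    "Pulse",
    "DemographicModel",
    "SimConfig",
    "population_size_at",
]


@dataclass(frozen=True)
class Population:
    initial_size: float
    growth_rate: float = 0.0

    def __post_init__(self):
        if self.initial_size < 1:
            raise ConfigurationError("population initial_size must be >= 1")

    def size_at(self, t: float) -> float:
        """Continuous diploid size ``N0 * exp(-alpha * t)`` at time t >= 0."""
        return self.initial_size * math.exp(-self.growth_rate * t)


def population_size_at(pop: Population, t: float, discrete: bool = False) -> float:
    """Diploid size of ``pop`` at time ``t`` generations in the past.

    With ``discrete=True`` the size is rounded to the nearest integer and
    floored at 1, which is the convention used by the Wright-Fisher engine.
    """
    if t < 0:
        raise ConfigurationError("t must be >= 0")
    n = pop.size_at(t)
    if discrete:
        return max(1, int(round(n)))
    return n


@dataclass(frozen=True)
class SizeChange:
    """At ``time``, set population ``population``'s size to ``new_size``
    (and restart its growth clock there)."""

    time: float
    population: int
    new_size: float

    kind = "size_change"


@dataclass(frozen=True)
class GrowthChange:
    """At ``time``, fix the population's size at its current value and set
    a new backward growth rate."""

    time: float
    population: int
    new_rate: float

    kind = "growth_change"


@dataclass(frozen=True)
class Pulse:
    """One-generation admixture pulse.

    Looking backwards from the present, every lineage in ``dest`` at
    ``time`` draws its parent from ``source`` with probability
    ``fraction``. When ``record_census`` is set (the default) a census node
    is recorded on every extant lineage at the pulse time, so that migrant
    ancestry can be attributed afterwards.
    """

    time: float
    dest: int
    source: int
    fraction: float
    record_census: bool = True

    kind = "pulse"

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError("pulse fraction must be in [0, 1]")


@dataclass(frozen=True)
class DemographicModel:
    populations: tuple[Population, ...]
    migration: tuple[tuple[float, ...], ...] = ()
    events: tuple = ()

    def __post_init__(self):
        pops = tuple(self.populations)
        if not pops:
            raise ConfigurationError("need at least one population")
        npop = len(pops)
        if self.migration:
            m = np.asarray(self.migration, dtype=float)
            if m.shape != (npop, npop):
                raise ConfigurationError("migration matrix must be square, one row per population")
            off = m - np.diag(np.diag(m))
            if np.any(off < 0) or np.any(off > 1):
                raise ConfigurationError("off-diagonal migration entries must be in [0, 1]")
            if np.any(off.sum(axis=1) > 1 + 1e-12):
                raise ConfigurationError("row sums of off-diagonal migration must be <= 1")
            mig = tuple(tuple(float(x) for x in row) for row in m)
        else:
            mig = tuple(tuple(0.0 for _ in range(npop)) for _ in range(npop))
        events = tuple(sorted(self.events, key=lambda e: e.time))
        for ev in events:
            if ev.time < 0:
                raise ConfigurationError("event times must be >= 0")
            for attr in ("population", "dest", "source"):
                p = getattr(ev, attr, None)
                if p is not None and not (0 <= p < npop):
                    raise ConfigurationError(f"event refers to unknown population {p}")
        object.__setattr__(self, "populations", pops)
        object.__setattr__(self, "migration", mig)
        object.__setattr__(self, "events", events)

    @property
    def num_populations(self) -> int:
        return len(self.populations)

    def migration_rates_from(self, i: int) -> np.ndarray:
        return np.asarray(self.migration[i], dtype=float)

    @classmethod
    def single(cls, initial_size: float, growth_rate: float = 0.0, events=()) -> "DemographicModel":
        return cls(populations=(Population(initial_size, growth_rate),), events=tuple(events))


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulation run.

    ``samples`` maps population index to haploid sample count. ``model``
    is one of ``hudson``, ``dtwf`` or ``hybrid``; ``switch_time`` is the
    number of Wright-Fisher generations simulated before a hybrid run
    hands over to the coalescent. ``end_time`` optionally stops the
    simulation early (lineages may then remain uncoalesced), which is how
    census-based ancestry experiments and recent-IBD experiments avoid
    simulating the deep past.
    """

    samples: tuple[tuple[int, int], ...]
    map: GeneticMap
    demography: DemographicModel
    model: str = "hudson"
    switch_time: float = 0.0
    seed: int = 1
    mutation_rate: float = 0.0
    record_lineage_counts: bool = True
    end_time: float | None = None

    def __post_init__(self):
        if self.model not in ("hudson", "dtwf", "hybrid"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.switch_time < 0:
            raise ConfigurationError("switch_time must be >= 0")
        samples = tuple(
            (int(p), int(k)) for p, k in
            (self.samples.items() if isinstance(self.samples, dict) else self.samples)
        )
        total = sum(k for _, k in samples)
        if total < 1:
            raise ConfigurationError("total sample count must be >= 1")
        for p, k in samples:
            if k < 0 or not (0 <= p < self.demography.num_populations):
                raise ConfigurationError("invalid sample specification")
        object.__setattr__(self, "samples", samples)

    @property
    def num_samples(self) -> int:
        return sum(k for _, k in self.samples)

    def sample_populations(self) -> list[int]:
        out: list[int] = []
        for p, k in self.samples:
            out.extend([p] * k)
        return out
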