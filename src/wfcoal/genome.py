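"""Genetic maps on a single concatenated coordinate axis.

All simulation coordinates are genetic (Morgans).  The chromosomes of a map
are laid out end to end on one half-open axis ``[0, axis_length)``.  Two
axis conventions are used by the engines:

* the Wright-Fisher engine uses the *compact* axis (``spacer=0``), where
  chromosome boundaries carry independent-assortment coin flips instead of
  map distance;
* the Hudson engine inserts ``hudson_spacer`` Morgans of inert map distance
  between consecutive chromosomes, because a linear crossover-rate model
  has no other way to approximate independent assortment.

Genetic lengths reported to users (IBD segment lengths, mutation target
sizes) always exclude the spacer gaps.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "build_human22_map", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class GeneticMap:
    """A multi-chromosome genetic map with uniform rate per chromosome.

    Parameters
    ----------
    chromosome_lengths:
        Genetic length of each chromosome in Morgans; all > 0.
    hudson_spacer:
        Inter-chromosome gap in Morgans, used only when an engine asks for
        the spacered axis. Non-negative.
    bp_per_morgan:
        Linear scale used when physical (bp) coordinates are required,
        e.g. for VCF output. Defaults to 1e8 (1 cM/Mb).
    """

    chromosome_lengths: tuple[float, ...]
    hudson_spacer: float = 0.5
    bp_per_morgan: float = 1e8

    _lengths: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        lengths = np.asarray(self.chromosome_lengths, dtype=float)
        if lengths.ndim != 1 or lengths.size == 0:
            raise ConfigurationError("need at least one chromosome length")
        if not np.all(lengths > 0):
            raise ConfigurationError("chromosome lengths must be positive")
        if self.hudson_spacer < 0:
            raise ConfigurationError("hudson_spacer must be >= 0")
        if self.bp_per_morgan <= 0:
            raise ConfigurationError("bp_per_morgan must be > 0")
        object.__setattr__(self, "chromosome_lengths", tuple(float(x) for x in lengths))
        object.__setattr__(self, "_lengths", lengths)
        object.__setattr__(self, "_axis_cache", {})

    # -- basic quantities ------------------------------------------------

    @property
    def num_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    @property
    def total_length(self) -> float:
        """Total genetic length L in Morgans (spacers excluded)."""
        return float(self._lengths.sum())

    def axis_length(self, spacer: float = 0.0) -> float:
        """Length of the concatenated axis for a given inter-chromosome gap."""
        return self.total_length + spacer * (self.num_chromosomes - 1)

    def starts(self, spacer: float = 0.0) -> np.ndarray:
        """Axis start position of each chromosome (strictly increasing)."""
        cached = self._axis_cache.get(spacer)
        if cached is None:
            steps = self._lengths + spacer
            starts = np.concatenate([[0.0], np.cumsum(steps[:-1])])
            cached = (starts, starts + self._lengths)
            self._axis_cache[spacer] = cached
        return cached[0]

    def ends(self, spacer: float = 0.0) -> np.ndarray:
        """Axis end position of each chromosome (start of its spacer gap)."""
        self.starts(spacer)
        return self._axis_cache[spacer][1]

    def boundaries(self, spacer: float = 0.0) -> np.ndarray:
        """Interior chromosome boundaries: the end of chromosomes 1..C-1.

        On the compact axis these are the points at which independent
        assortment applies; on a spacered axis they mark where each gap
        begins.
        """
        return self.ends(spacer)[:-1]

    def chromosome_of(self, position: float, spacer: float = 0.0) -> int:
        """Index of the chromosome containing ``position`` (gaps map to the
        preceding chromosome)."""
        starts = self.starts(spacer)
        idx = int(np.searchsorted(starts, position, side="right") - 1)
        return max(idx, 0)

    def genetic_length(self, left: float, right: float, spacer: float = 0.0) -> float:
        """Genetic length of ``[left, right)`` excluding spacer gaps."""
        if right <= left:
            return 0.0
        if spacer == 0.0:
            return right - left
        starts = self.starts(spacer)
        ends = self.ends(spacer)
        overlap = np.minimum(right, ends) - np.maximum(left, starts)
        return float(np.clip(overlap, 0.0, None).sum())

    def to_physical(self, position: float, spacer: float = 0.0) -> tuple[int, int]:
        """Map an axis position to (chromosome index, bp position >= 1)."""
        chrom = self.chromosome_of(position, spacer)
        start = self.starts(spacer)[chrom]
        offset = min(max(position - start, 0.0), self.chromosome_lengths[chrom])
        return chrom, int(round(offset * self.bp_per_morgan)) + 1


def build_human22_map(
    spacer: float = 0.5, bp_per_morgan: float = 1e8
) -> GeneticMap:
    """A 22-chromosome map with realistic human autosome lengths.

    The per-chromosome genetic lengths are read from the versioned fixture
    shipped with the package (``data/human22.tsv``); they total roughly 35
    Morgans. ``spacer`` becomes the map's ``hudson_spacer``.
    """
    if spacer < 0:
        raise ConfigurationError("spacer must be >= 0")
    ref = importlib.resources.files("wfcoal.data").joinpath("human22.tsv")
    lengths = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chromosome"):
            continue
        _, val = line.split("\t")
        lengths.append(float(val))
    if len(lengths) != 22:
        raise ConfigurationError("human22 fixture is corrupt")
    return GeneticMap(
        chromosome_lengths=tuple(lengths),
        hudson_spacer=spacer,
        bp_per_morgan=bp_per_morgan,
    )
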