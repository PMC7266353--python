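import numpy as np
import pytest

from wfcoal.demography import DemographicModel, Population, Pulse, SimConfig
from wfcoal.genome import GeneticMap, build_human22_map


@pytest.fixture(scope="session")
def human22():
    return build_human22_map()


@pytest.fixture
def two_chrom_map():
    return GeneticMap((0.8, 0.6), hudson_spacer=0.4)


@pytest.fixture
def point_map():
    """Effectively a single point locus (negligible recombination)."""
    return GeneticMap((1e-6,), hudson_spacer=0.0)


@pytest.fixture
def small_demography():
    return DemographicModel.single(50)


def make_config(samples, gmap, n=100, growth=0.0, seed=1, model="hudson",
                events=(), n_pops=1, **kw):
    if n_pops == 1:
        demog = DemographicModel.single(n, growth, events=events)
    else:
        demog = DemographicModel(
            populations=tuple(Population(n) for _ in range(n_pops)),
            events=tuple(events))
    if isinstance(samples, int):
        samples = {0: samples}
    return SimConfig(samples=samples, map=gmap, demography=demog, seed=seed,
                     model=model, **kw)
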