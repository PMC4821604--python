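import numpy as np
import pytest
from hypothesis import settings

from nucshift import density as dens
from nucshift import simulate as sim
from nucshift.genome import ChromSizes, SignalTrack

settings.register_profile("suite", max_examples=25, derandomize=True,
                          deadline=None)
settings.load_profile("suite")

GENE_SEED = 1
SITE_SEED = 3


@pytest.fixture(scope="session")
def active_bundle():
    """200 active genes, paired WT (+1=132, NRL=175) / mutant (123, 170)."""
    return sim.generate(sim.single_gene_config("active", n=200, seed=GENE_SEED))


@pytest.fixture(scope="session")
def active_densities(active_bundle):
    return {cond: dens.density_from_fragments(active_bundle.fragments[cond],
                                              active_bundle.chrom_sizes)
            for cond in ("wt", "mut")}


@pytest.fixture(scope="session")
def sites_bundle():
    """100 sites per flanking-organization class, all six classes."""
    return sim.generate(sim.sites_only_config(n_per_class=100, seed=SITE_SEED))


@pytest.fixture(scope="session")
def site_densities(sites_bundle):
    return {cond: dens.density_from_fragments(sites_bundle.fragments[cond],
                                              sites_bundle.chrom_sizes)
            for cond in ("wt", "mut")}


@pytest.fixture
def small_sizes():
    return ChromSizes({"chr1": 10_000})


@pytest.fixture
def flat_track(small_sizes):
    return SignalTrack(small_sizes, "flat",
                       {"chr1": np.full(10_000, 2.5)})
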