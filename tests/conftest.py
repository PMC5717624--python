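import pytest
from hypothesis import settings

from phyloniche import envspace as es
from phyloniche import synthetic as syn
from phyloniche.trees import Phylogeny

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    return syn.SyntheticConfig(seed=11, n_pixels=500, n_env_vars=12,
                               noise_sd=0.3, n_species=8, n_taxa=8, n_trees=3)


@pytest.fixture(scope="session")
def small_raster(small_cfg):
    return syn.generate_raster(small_cfg)


@pytest.fixture(scope="session")
def small_space(small_raster):
    return es.fit_env_space(small_raster)


@pytest.fixture(scope="session")
def balanced4():
    return Phylogeny.from_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")


@pytest.fixture(scope="session")
def tree10():
    cfg = syn.SyntheticConfig(seed=23, n_taxa=10, n_trees=1)
    return syn.generate_tree(cfg)


@pytest.fixture(scope="session")
def dataset18():
    """Mid-sized study-shaped dataset shared by the slower pipeline tests."""
    cfg = syn.SyntheticConfig(seed=5, n_pixels=1000, n_species=18, n_taxa=18,
                              n_trees=4)
    return syn.generate_dataset(cfg)
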