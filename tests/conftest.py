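import numpy as np
import pytest

from berrymorph.synthetic import (PlantedQTL, TraitModel, make_linkage_map,
                                  simulate_cross)


@pytest.fixture(scope="session")
def two_lg_map():
    """Small 2-LG map (31 markers per LG, 60 cM each)."""
    return make_linkage_map(62, 2, 60.0)


@pytest.fixture(scope="session")
def cross351(two_lg_map):
    """Study-sized cross (n=351) with a planted locus on LG1 at 30 cM."""
    return simulate_cross(two_lg_map, 351, seed=11, extra_loci=[(1, 30.0)])


@pytest.fixture(scope="session")
def qtl_trait_model():
    return TraitModel("t", [PlantedQTL(1, 30.0, var_frac=0.2)])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
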