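import numpy as np
import pytest

from twilightfix import (
    AlgorithmInputs,
    BoundaryBox,
    Scenario,
    make_truth_bundle,
)
from twilightfix.weighting import PolygonLandMask


@pytest.fixture(scope="session")
def solstice_bundle():
    """14-day December deployment at 54 S (seed 1): the solstice study scenario."""
    return make_truth_bundle(Scenario.solstice(rng_seed=1))


@pytest.fixture(scope="session")
def equinox_bundle():
    """10-day late-March deployment at 54 S (seed 2): the equinox study scenario."""
    return make_truth_bundle(Scenario.equinox(rng_seed=2))


@pytest.fixture()
def region_box():
    return BoundaryBox(-60.0, -15.0, -65.0, -40.0)


def inputs_for(bundle, with_land=True):
    mask = None
    if with_land and bundle.scenario.land is not None:
        mask = PolygonLandMask(bundle.scenario.land)
    return AlgorithmInputs(
        release=bundle.release,
        release_time=bundle.release_time,
        land_mask=mask,
        sst_field=bundle.sst_field,
        immersion=bundle.immersion,
        temps=bundle.temps,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
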