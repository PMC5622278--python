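import warnings

import pytest

from landsim.params import Params
from landsim.soil_water import SoilLayer, hypres_retention


@pytest.fixture(autouse=True)
def _quiet_pedotransfer_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="pedotransfer inputs outside calibration")
        warnings.filterwarnings("ignore", message="grid has no ditch edge")
        yield


@pytest.fixture
def params() -> Params:
    return Params()


def make_layer(thickness=230.0, clay=25.0, silt=55.0, sand=20.0, ph=7.0,
               bd=1.30, om=1.5, topsoil=True, water=None, **pools
               ) -> SoilLayer:
    """A silty-clay-loam layer with HYPRES anchors; water defaults to FC."""
    anchors = hypres_retention(clay, silt, om, bd, topsoil)
    layer = SoilLayer(thickness=thickness, clay=clay, silt=silt, sand=sand,
                      ph=ph, bulk_density=bd, anchors=anchors)
    layer.water = layer.fc_mm if water is None else water
    for key, value in pools.items():
        setattr(layer, key, value)
    return layer


@pytest.fixture
def layer() -> SoilLayer:
    return make_layer()


@pytest.fixture
def profile() -> list:
    return [make_layer(topsoil=True),
            make_layer(bd=1.40, om=0.5, topsoil=False),
            make_layer(bd=1.45, om=0.5, topsoil=False)]
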