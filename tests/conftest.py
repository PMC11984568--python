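import numpy as np
import pytest

from cbctplan import (
    InfluenceEngine,
    PhantomConfig,
    design_spots,
    generate_phantom,
    hu_to_rsp,
    scenario_set,
)
from cbctplan.optimize import _ring_mask


@pytest.fixture(scope="session")
def default_phantom():
    """Default-geometry phantom (the one the worked examples use)."""
    return generate_phantom(7)


@pytest.fixture(scope="session")
def compact_phantom():
    return generate_phantom(3, PhantomConfig.compact())


def make_setup(seed=3, angles=(50.0, 160.0, 260.0), srs=1.0, rrs=0.03):
    """Compact phantom plus beams/engine/ROI for quick optimization tests."""
    img, structs = generate_phantom(seed, PhantomConfig.compact())
    rsp = hu_to_rsp(img)
    beams = design_spots(
        rsp, structs, angles, range_expansion=rrs, shift_margin=srs
    )
    engine = InfluenceEngine(rsp, beams)
    roi = structs.ctv_low | structs.ctv_high | _ring_mask(structs, img.spacing, 10.0)
    for oar in structs.oars.values():
        roi |= oar
    vox = np.flatnonzero(roi.ravel())
    scen = scenario_set(srs, rrs, 2)
    return {
        "image": img,
        "structs": structs,
        "rsp": rsp,
        "beams": beams,
        "engine": engine,
        "vox": vox,
        "scenarios": scen,
    }


@pytest.fixture(scope="session")
def compact_setup():
    return make_setup()
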