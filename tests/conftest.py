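import numpy as np
import pytest

from tdcsfield import AnatomySpec, CohortVariability, ElectrodeMontage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_spec():
    """Small 4-shell sphere (proportionally scaled pads) that solves fast."""
    return AnatomySpec(
        layers=(
            ("skin", 50.0),
            ("compact_bone", 44.0),
            ("csf", 38.0),
            ("grey_matter", 33.0),
        ),
        montage=ElectrodeMontage(pad_size_mm=20.0),
    )


@pytest.fixture
def gentle_variability():
    return CohortVariability(
        scalp_thickness_sd=0.3,
        skull_thickness_sd=0.5,
        csf_thickness_sd=0.3,
        gyral_amplitude_sd=0.3,
    )


def point_sources_for(model, anode_mm, cathode_mm, current_ma=1.0):
    """Snap two point sources to the nearest grid nodes; returns node world coords."""
    h = model.voxel_size_mm

    def nearest(p):
        return tuple(
            int(round((p[a] - model.node_coords(a)[0]) / h)) for a in range(3)
        )

    def world(n):
        return np.array([model.node_coords(a)[n[a]] for a in range(3)])

    na, nc = nearest(anode_mm), nearest(cathode_mm)
    model.point_sources = [(na, current_ma), (nc, -current_ma)]
    return world(na), world(nc)
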