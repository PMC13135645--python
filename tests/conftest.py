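"""Shared fixtures: analytic tubes, a default synthetic AVF, waveforms."""

import numpy as np
import pytest

from avflow import (
    AVFDesignParams,
    Centreline,
    FlowWaveform,
    build_end_to_side_avf,
    build_tube,
)


@pytest.fixture(scope="session")
def straight_centreline():
    x = np.linspace(0.0, 100.0, 101)
    return Centreline(
        np.column_stack([x, np.zeros_like(x), np.zeros_like(x)]),
        "vessel",
        np.zeros_like(x),
    )


@pytest.fixture(scope="session")
def cylinder(straight_centreline):
    """Straight tube, D = 5 mm, L = 100 mm."""
    return build_tube(straight_centreline, 5.0)


@pytest.fixture(scope="session")
def arc_centreline():
    """Planar arc of radius 33.333 mm (kappa = 0.03 mm^-1), ~87 mm long."""
    R = 100.0 / 3.0
    phi = np.linspace(0.0, 1.5 * np.pi / 2, 200)
    pts = np.column_stack([R * np.sin(phi), R * (1 - np.cos(phi)), np.zeros_like(phi)])
    return Centreline(pts, "vessel")


@pytest.fixture(scope="session")
def arc_tube(arc_centreline):
    return build_tube(arc_centreline, 5.0)


@pytest.fixture(scope="session")
def default_avf():
    """One default synthetic end-to-side AVF, shared across tests."""
    return build_end_to_side_avf(AVFDesignParams())


@pytest.fixture(scope="session")
def recovered_centrelines(default_avf):
    from avflow import extract_limb_centrelines

    seeds = {
        label: cl.point_at(cl.length - 2.0)
        for label, cl in default_avf.centrelines.items()
    }
    return extract_limb_centrelines(
        default_avf.mesh, default_avf.anastomosis_faces, seeds, default_avf.junction
    )


@pytest.fixture()
def pulsatile_waveform():
    return FlowWaveform.physiologic(mean_flow=600.0, period=1.0)
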