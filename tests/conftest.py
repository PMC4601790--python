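import numpy as np
import pytest

from minflat.detsim import run
from minflat.geometry import CellGeometry, build_pill
from minflat.params import HUANG_RATES, InitialCondition


def make_box_geometry(shape, dx, membrane="all"):
    """Hand-built rectangular geometry for oracle tests.

    membrane: "all" puts area on every outer face of boundary voxels,
    "slab" only on the two z faces (an ideal slab), "none" for a closed box
    with no membrane reactions.
    """
    mask = np.ones(shape, bool)
    area = np.zeros(shape)
    if membrane == "all":
        for ax in range(3):
            sl = [slice(None)] * 3
            sl[ax] = 0
            area[tuple(sl)] += dx**2
            sl[ax] = shape[ax] - 1
            area[tuple(sl)] += dx**2
    elif membrane == "slab":
        area[:, :, 0] += dx**2
        area[:, :, -1] += dx**2
    return CellGeometry(
        dx=dx,
        origin=np.zeros(3),
        mask=mask,
        volume=np.full(shape, dx**3),
        area=area,
        wall_distance=np.where(mask, dx, 0.0),
    )


@pytest.fixture(scope="session")
def single_voxel():
    """One-voxel 'cell': volume dx^3, all six faces membrane."""
    return make_box_geometry((1, 1, 1), 0.05)


@pytest.fixture(scope="session")
def pill_coarse():
    return build_pill(4.0, 0.5, 0.1)


@pytest.fixture(scope="session")
def pill_trajectory(pill_coarse):
    """Long deterministic wild-type run (shared by several tests): 1100 s at
    dx = 0.1 um, enough settled record to measure 10 periods of correlation
    lags after discarding the 200 s transient."""
    return run(
        pill_coarse,
        HUANG_RATES,
        InitialCondition(seed=1),
        t_end=1100.0,
        output_stride=1.0,
    )


@pytest.fixture(scope="session")
def disc3():
    from minflat.synthetic import make_disc

    return make_disc(3.0, 0.1)


@pytest.fixture(scope="session")
def disc3_trajectory(disc3):
    """Flattened 3-um disc (above the stability limit): develops sustained
    oscillation from a polar-gradient seed."""
    return run(
        disc3,
        HUANG_RATES,
        InitialCondition(seed=3, mode="polar-gradient", amplitude=0.05),
        t_end=700.0,
        output_stride=1.0,
    )


def settled_polar_series(trajectory, geometry, transient):
    from minflat.oscillometry import polar_counts

    return polar_counts(trajectory, geometry).after(transient)
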