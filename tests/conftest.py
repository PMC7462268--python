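"""Shared fixtures: carriers, hand-built micro-networks, and the
(session-scoped, expensive) standard tumor bed with its solved states."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import oxynet as ox
from oxynet.netgen import TissueGrid, VascularNetwork


@pytest.fixture(scope="session")
def mouse_rbc():
    return ox.get_carrier("mouse_rbc")


@pytest.fixture(scope="session")
def human_rbc():
    return ox.get_carrier("human_rbc")


@pytest.fixture(scope="session")
def mouse_blood(mouse_rbc):
    return ox.BloodComposition(hct=0.45, rbc_carrier=mouse_rbc)


def build_network(nodes, segments, domain=(400.0, 400.0, 400.0)):
    """Construct a VascularNetwork from plain tuples.

    ``nodes``: (id, x, y, z, kind); ``segments``: (id, a, b, radius).
    """
    ndf = pd.DataFrame(
        [(n[1], n[2], n[3], n[4]) for n in nodes],
        columns=["x", "y", "z", "kind"],
        index=pd.Index([n[0] for n in nodes], name="id"),
    )
    rows = []
    for sid, a, b, radius in segments:
        pa = ndf.loc[a, ["x", "y", "z"]].to_numpy(float)
        pb = ndf.loc[b, ["x", "y", "z"]].to_numpy(float)
        rows.append((a, b, radius, float(np.linalg.norm(pa - pb)),
                     "capillary", "host"))
    sdf = pd.DataFrame(
        rows, columns=["a", "b", "radius", "length", "wall_type", "region"],
        index=pd.Index([s[0] for s in segments], name="id"),
    )
    return VascularNetwork(ndf, sdf, domain)


@pytest.fixture
def single_tube():
    """One vessel from an arterial to a venous root."""
    return build_network(
        nodes=[(0, 0, 200, 200, "arterial_root"), (1, 400, 200, 200, "venous_root")],
        segments=[(0, 0, 1, 10.0)],
    )


@pytest.fixture
def y_bifurcation():
    """Symmetric diverging Y rejoining at a single venous root."""
    return build_network(
        nodes=[
            (0, 0, 200, 200, "arterial_root"),
            (1, 200, 200, 200, "interior"),
            (2, 300, 100, 200, "interior"),
            (3, 300, 300, 200, "interior"),
            (4, 400, 200, 200, "venous_root"),
        ],
        segments=[(0, 0, 1, 12.0), (1, 1, 2, 6.0), (2, 1, 3, 6.0),
                  (3, 2, 4, 6.0), (4, 3, 4, 6.0)],
    )


def uniform_grid(shape=(10, 10, 10), spacing=40.0, v_m=45.0, k_m=5.0):
    """All-host tissue grid."""
    ones = np.ones(shape)
    return TissueGrid(
        spacing=spacing, phi_normal=ones, phi_tumor=np.zeros(shape),
        phi_necrotic=np.zeros(shape), v_m=v_m * ones, k_m=k_m * ones,
    )


# --------------------------------------------------------------------------
# expensive shared states (computed once per session)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_bed():
    """A smaller seeded tumor bed for moderately expensive solver tests."""
    net = ox.generate_av_network(domain_size=(640.0,) * 3, lattice_pitch=80.0,
                                 n_roots=2, target_mvd=150.0, seed=11)
    net, grid = ox.apply_tumor_phantom(
        net, center=(320.0,) * 3, radius=220.0, necrotic_radius=90.0,
        dilation_factor=1.3, prune_fraction=0.5, seed=11, grid_spacing=40.0,
        host="mouse",
    )
    return net, grid


@pytest.fixture(scope="session")
def standard_bed():
    return ox.standard_tumor_fixture(seed=3, host="mouse")


@pytest.fixture(scope="session")
def standard_baseline(standard_bed):
    """Baseline scenario solved on the standard bed."""
    net, grid = standard_bed
    return ox.run_scenario(net, grid, ox.get_scenario("baseline"), host="mouse")
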