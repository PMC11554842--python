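import numpy as np
import pytest

import biofilmsim as bs


@pytest.fixture
def unit_element():
    """Single unit brick with 3-2-1 rigid-body pins."""
    mesh = bs.build_box_mesh((1.0, 1.0, 1.0), 1.0)
    spec = bs.BVPSpec(
        "cube_directional", (1, 1, 1), mesh.spacing, ("corner_000", 1.0),
        phi_init_set="corner_000",
        mech_constraints=[
            ("corner_000", (0, 1, 2)),
            ("corner_100", (1, 2)),
            ("corner_010", (2,)),
        ],
    )
    return mesh, spec


@pytest.fixture
def small_box():
    """4x2x2 um box at 1 um spacing (45 nodes, 16 elements)."""
    return bs.build_box_mesh((4.0, 2.0, 2.0), 1.0)


@pytest.fixture
def rod():
    """Thin rod mesh for quasi-1D field tests."""
    return bs.build_box_mesh((8.0, 1.0, 1.0), 1.0)


def make_state(mesh, phi=0.0, c=0.0):
    state = bs.FieldState(
        0.0,
        np.full(mesh.n_nodes, float(phi)),
        np.full(mesh.n_nodes, float(c)),
        np.zeros((mesh.n_nodes, 3)),
        np.zeros(mesh.n_elements),
        np.zeros((mesh.n_elements, 8)),
    )
    return state


@pytest.fixture
def make_state_factory():
    return make_state
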