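import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microperm import (
    RheologyParams,
    Subnetwork,
    SyntheticSpec,
    VesselNetwork,
    make_cubic_lattice,
    make_random_capillary,
    make_single_tube,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_net(box, nodes, segs, face_tol=1.0):
    """Small-network builder: nodes {id: (x,y,z)}, segs [(sid, a, b, r[, l])]."""
    node_ids = sorted(nodes)
    positions = [nodes[i] for i in node_ids]
    seg_ids = [s[0] for s in segs]
    na = [s[1] for s in segs]
    nb = [s[2] for s in segs]
    radii = [s[3] for s in segs]
    lengths = [s[4] if len(s) > 4 else None for s in segs]
    return VesselNetwork.from_arrays(node_ids, positions, seg_ids, na, nb, radii,
                                     lengths, box=box, face_tol=face_tol)


def tube_k11(radius, length, mu_mpas=1.0):
    """Closed-form tensor element of a box-spanning axial tube, mm³·s/kg."""
    return math.pi * radius**4 / (8.0 * mu_mpas * 1e-3 * length**2) * 1e-3


def lattice_k(radius, spacing, mu_mpas=1.0):
    """Closed-form diagonal of the periodic cubic lattice, mm³·s/kg."""
    return math.pi * radius**4 / (8.0 * mu_mpas * 1e-3 * spacing**2) * 1e-3


@pytest.fixture
def fixed_mu():
    return RheologyParams(fixed_viscosity=1.0)


@pytest.fixture
def tube():
    return make_single_tube((100.0, 100.0, 100.0), 4.0)


@pytest.fixture
def tube_sub(tube):
    return Subnetwork.from_network(tube)


@pytest.fixture
def lattice():
    return make_cubic_lattice((200.0, 200.0, 200.0), 50.0, 4.0)


@pytest.fixture
def capillary():
    """Small seeded capillary bed (one major + one corner component)."""
    return make_random_capillary(
        SyntheticSpec(box=(200.0, 200.0, 100.0), spacing=50.0, seed=7)
    )


@pytest.fixture
def y_network():
    """Trunk splitting into two unequal daughters, all ends on x faces."""
    return build_net(
        (100.0, 100.0, 100.0),
        {0: (0, 50, 50), 1: (50, 50, 50), 2: (100, 30, 50), 3: (100, 70, 50)},
        [(0, 0, 1, 4.0), (1, 1, 2, 3.0), (2, 1, 3, 2.0)],
    )


def rel_diff(a, b):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-300)
    return float(np.max(np.abs(a - b)) / scale)
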