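import math

import numpy as np
import pytest

from microperm import (
    RheologyParams,
    SolverConfig,
    Subnetwork,
    SyntheticSpec,
    assemble_and_solve,
    make_cubic_lattice,
    make_random_capillary,
    make_single_tube,
    mirror_network,
    surface_flux,
)
from microperm.flow import AXES, conductance

from conftest import build_net, rel_diff


def dense_pressure_oracle(mir, direction, grad=1.0, mu=1.0):
    """Brute-force dense solve of the mirrored boundary-value problem.

    Independent formulation: one pressure variable per node; identity rows
    for Dirichlet nodes, equality rows for each periodic pair, and one
    Kirchhoff row per remaining equivalence class, assembled densely and
    solved with numpy.
    """
    net = mir.network
    d = AXES[direction]
    tol = net.face_tol
    box = net.box
    ids = sorted(net.nodes)
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)

    def on_face(nid, ax, hi):
        target = box[ax] if hi else 0.0
        return abs(net.nodes[nid].position[ax] - target) <= tol

    dirichlet = {}
    for nid in ids:
        if on_face(nid, d, False):
            dirichlet[nid] = box[d] * grad
        elif on_face(nid, d, True):
            dirichlet[nid] = 0.0

    # periodic pairs on the lateral faces, by brute-force coordinate match
    pairs = []
    for ax in range(3):
        if ax == d:
            continue
        lo = [nid for nid in ids if on_face(nid, ax, False)]
        hi = [nid for nid in ids if on_face(nid, ax, True)]
        for a in lo:
            pa = net.nodes[a].position
            for b in hi:
                pb = net.nodes[b].position
                if all(abs(pa[o] - pb[o]) < 1e-6 for o in range(3) if o != ax):
                    pairs.append((a, b))
                    break

    # union classes for the Kirchhoff rows
    cls = {nid: nid for nid in ids}

    def find(x):
        while cls[x] != x:
            x = cls[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            cls[max(ra, rb)] = min(ra, rb)
    members = {}
    for nid in ids:
        members.setdefault(find(nid), []).append(nid)

    rows, rhs = [], []
    for nid, val in dirichlet.items():
        r = np.zeros(n)
        r[idx[nid]] = 1.0
        rows.append(r)
        rhs.append(val)
    for a, b in pairs:
        if a in dirichlet or b in dirichlet:
            continue
        r = np.zeros(n)
        r[idx[a]], r[idx[b]] = 1.0, -1.0
        rows.append(r)
        rhs.append(0.0)
    for rep, group in members.items():
        if any(m in dirichlet for m in group):
            continue
        r = np.zeros(n)
        wrote = False
        for m in group:
            for sid, seg in net.segments.items():
                if m not in (seg.node_a, seg.node_b):
                    continue
                other = seg.node_b if m == seg.node_a else seg.node_a
                g = conductance(seg.radius, seg.length, mu)
                r[idx[m]] += g
                r[idx[other]] -= g
                wrote = True
        if not wrote:
            r[idx[rep]] = 1.0
        rows.append(r)
        rhs.append(0.0)
    # pairs may close cycles at corners, so the consistent system can be
    # overdetermined; least squares recovers the exact solution. Rows are
    # normalized so conductance rows do not dwarf the constraint rows.
    a_mat = np.vstack(rows)
    rhs = np.array(rhs)
    norms = np.abs(a_mat).max(axis=1)
    a_mat /= norms[:, None]
    rhs /= norms
    p, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    return {nid: p[idx[nid]] for nid in ids}


class TestMirroring:
    def test_tube_mirrors_to_four_parallel_tubes(self, tube_sub):
        mir = mirror_network(tube_sub)
        assert len(mir.network.segments) == 8   # 4 tubes × 2 half-segments
        assert len(mir.network.nodes) == 12     # x-plane nodes merged
        assert np.allclose(mir.box, [200.0, 200.0, 200.0])
        ys = {round(mir.network.nodes[s.node_a].position[1]) for s in mir.network.segments.values()}
        assert ys == {50, 150}

    def test_interior_network_octuples_node_count(self):
        # no nodes on any face: 8 images, no merges
        net = build_net((100, 100, 100),
                        {0: (30, 40, 50), 1: (60, 55, 45), 2: (70, 30, 60)},
                        [(0, 0, 1, 2.0), (1, 1, 2, 2.0)])
        mir = mirror_network(Subnetwork.from_network(net))
        assert len(mir.network.nodes) == 8 * 3
        assert len(mir.network.segments) == 8 * 2

    def test_every_lateral_node_has_periodic_partner(self, capillary):
        from microperm.preprocess import preprocess
        sub = preprocess(capillary)[0][0]
        mir = mirror_network(sub)
        net, box, tol = mir.network, mir.box, mir.network.face_tol
        for ax in range(3):
            lo = [n for n in net.nodes.values() if abs(n.position[ax]) <= tol]
            hi = [n for n in net.nodes.values() if abs(n.position[ax] - box[ax]) <= tol]
            assert len(lo) == len(hi) > 0
            for n in lo:
                matches = [m for m in hi if all(
                    abs(n.position[o] - m.position[o]) < 1e-6 for o in range(3) if o != ax)]
                assert len(matches) == 1


class TestPoiseuilleSolve:
    def test_single_tube_closed_form_flow(self, tube_sub, fixed_mu):
        mir = mirror_network(tube_sub)
        state = assemble_and_solve(mir, "x", fixed_mu)
        # every image tube carries πr⁴Δp_total/(8μL_total)
        expected = math.pi * 4.0**4 * 200.0 / (8 * 1e-3 * 200.0)
        for q in state.flow.values():
            assert abs(q) == pytest.approx(expected, rel=1e-12)

    def test_two_segments_in_series_halve_conductance(self, fixed_mu):
        whole = build_net((100, 100, 100), {0: (0, 50, 50), 1: (100, 50, 50)},
                          [(0, 0, 1, 4.0)])
        split = build_net((100, 100, 100),
                          {0: (0, 50, 50), 1: (50, 50, 50), 2: (100, 50, 50)},
                          [(0, 0, 1, 4.0), (1, 1, 2, 4.0)])
        m_whole = mirror_network(Subnetwork.from_network(whole))
        m_split = mirror_network(Subnetwork.from_network(split))
        q_whole = surface_flux(m_whole, assemble_and_solve(m_whole, "x", fixed_mu))
        q_split = surface_flux(m_split, assemble_and_solve(m_split, "x", fixed_mu))
        # same end-to-end length: identical flux; each half has 2× conductance
        assert q_split == pytest.approx(q_whole, rel=1e-12)
        g_half = conductance(4.0, 50.0, 1.0)
        assert conductance(4.0, 100.0, 1.0) == pytest.approx(g_half / 2, rel=1e-15)

    def test_lattice_pressures_match_dense_oracle(self, fixed_mu):
        lat = make_cubic_lattice((100.0, 100.0, 50.0), 25.0, 3.0)
        mir = mirror_network(Subnetwork.from_network(lat))
        state = assemble_and_solve(mir, "x", fixed_mu)
        oracle = dense_pressure_oracle(mir, "x")
        worst = max(abs(state.pressure[nid] - oracle[nid]) for nid in oracle)
        assert worst <= 1e-10 * max(abs(v) for v in oracle.values())

    def test_jittered_network_pressures_match_dense_oracle(self, fixed_mu):
        cap = make_random_capillary(SyntheticSpec(box=(100.0, 100.0, 50.0),
                                                  spacing=25.0, seed=11))
        from microperm.preprocess import preprocess
        sub = preprocess(cap, apply_rev_gate=False)[0][0]
        mir = mirror_network(sub)
        state = assemble_and_solve(mir, "y", fixed_mu)
        oracle = dense_pressure_oracle(mir, "y")
        scale = max(abs(v) for v in oracle.values())
        worst = max(abs(state.pressure[nid] - oracle[nid]) for nid in oracle)
        assert worst <= 1e-10 * scale

    def test_no_spanning_direction_gives_zero_state(self, tube_sub, fixed_mu):
        mir = mirror_network(tube_sub)
        state = assemble_and_solve(mir, "y", fixed_mu)  # tube does not span y
        assert all(q == 0.0 for q in state.flow.values())
        assert surface_flux(mir, state) == 0.0


class TestConservation:
    @staticmethod
    def interior_kirchhoff_residuals(mir, state):
        net, box, tol = mir.network, mir.box, mir.network.face_tol
        net_flow = {nid: 0.0 for nid in net.nodes}
        abs_flow = {nid: 0.0 for nid in net.nodes}
        for sid, seg in net.segments.items():
            q = state.flow[sid]
            net_flow[seg.node_a] -= q
            net_flow[seg.node_b] += q
            abs_flow[seg.node_a] += abs(q)
            abs_flow[seg.node_b] += abs(q)
        out = []
        for nid, node in net.nodes.items():
            if any(node.position[a] <= tol or node.position[a] >= box[a] - tol
                   for a in range(3)):
                continue  # Dirichlet or periodic-merged
            out.append((abs(net_flow[nid]), abs_flow[nid]))
        return out

    def test_kirchhoff_and_flux_balance_on_capillary(self, capillary, fixed_mu):
        from microperm.preprocess import preprocess
        sub = preprocess(capillary)[0][0]
        mir = mirror_network(sub)
        for direction in ("x", "y", "z"):
            state = assemble_and_solve(mir, direction, fixed_mu)
            residuals = self.interior_kirchhoff_residuals(mir, state)
            mean_abs = np.mean([a for _, a in residuals])
            assert max(r for r, _ in residuals) <= 1e-10 * mean_abs
            out = surface_flux(mir, state, direction, hi=True)
            inn = surface_flux(mir, state, direction, hi=False)  # influx, positive
            assert out == pytest.approx(inn, rel=1e-10)


class TestScalingLaws:
    def test_gradient_linearity(self, capillary, fixed_mu):
        from microperm.preprocess import preprocess
        sub = preprocess(capillary)[0][0]
        mir = mirror_network(sub)
        s1 = assemble_and_solve(mir, "x", fixed_mu, SolverConfig(gradient_pa_per_um=1.0))
        s10 = assemble_and_solve(mir, "x", fixed_mu, SolverConfig(gradient_pa_per_um=10.0))
        qmax = max(abs(q) for q in s1.flow.values())
        for sid in s1.flow:
            assert s10.flow[sid] == pytest.approx(10 * s1.flow[sid],
                                                  rel=1e-12, abs=1e-12 * qmax)

    def test_radius_scaling_fourth_power(self, fixed_mu):
        alpha = 1.3
        base = make_cubic_lattice((100.0, 100.0, 50.0), 25.0, 2.0)
        scaled = base.copy()
        for s in scaled.segments.values():
            s.radius *= alpha
        m1 = mirror_network(Subnetwork.from_network(base))
        m2 = mirror_network(Subnetwork.from_network(scaled))
        q1 = surface_flux(m1, assemble_and_solve(m1, "x", fixed_mu))
        q2 = surface_flux(m2, assemble_and_solve(m2, "x", fixed_mu))
        assert q2 == pytest.approx(alpha**4 * q1, rel=1e-12)

    def test_min_radius_guard(self, fixed_mu):
        assert conductance(0.01, 10.0, 1.0) == conductance(0.1, 10.0, 1.0)
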