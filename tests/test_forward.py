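"""FEM forward solver, adjoint Jacobian and linearized transfer series."""

import numpy as np
import pytest
from scipy import stats

from seegeit.forward import (
    assemble_stiffness,
    compute_jacobian,
    simulate_transfer_series,
    solve_forward,
)
from seegeit.geometry import HeadModel, build_brain_mesh, default_layout, place_electrodes
from seegeit.protocol import InjectionProtocol, make_injection_protocol
from seegeit.scenario import make_seizure_scenario


def hand_stiffness(vertices, tets, sigma):
    """Independent P1 assembly: gradients from a direct linear solve."""
    n = vertices.shape[0]
    K = np.zeros((n, n))
    for e, tet in enumerate(tets):
        p = vertices[tet]
        # gradient of barycentric i solves: grad . (p_j - p_i0) relations;
        # build via the affine map row by row
        A = np.column_stack([p[:, 0], p[:, 1], p[:, 2], np.ones(4)])
        grads = np.linalg.solve(A, np.eye(4)[:, :])[:3].T  # (4, 3)
        vol = abs(np.linalg.det(p[1:] - p[0])) / 6.0
        local = sigma[e] * vol * grads @ grads.T
        for i in range(4):
            for j in range(4):
                K[tet[i], tet[j]] += local[i, j]
    return K


class TestStiffness:
    def test_matches_hand_assembly_on_two_tet_mesh(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float
        )
        tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        sigma = np.array([0.22, 0.5])
        model = HeadModel(vertices=verts, tetrahedra=tets, element_conductivity=sigma)
        K = assemble_stiffness(model).toarray()
        K_hand = hand_stiffness(verts, tets, sigma)
        assert np.allclose(K, K_hand, atol=1e-12)

    def test_constant_null_space(self, model4):
        K = assemble_stiffness(model4)
        assert np.abs(K @ np.ones(model4.n_vertices)).max() < 1e-9

    def test_linear_in_conductivity(self, model4):
        K1 = assemble_stiffness(model4)
        K2 = assemble_stiffness(model4.with_conductivity(2 * model4.element_conductivity))
        assert np.allclose((2 * K1 - K2).data, 0, atol=1e-12)

    def test_nonpositive_conductivity_rejected(self, model4):
        sigma = model4.element_conductivity.copy()
        sigma[3] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            assemble_stiffness(model4.with_conductivity(sigma))


def bar_model(length=40.0, side=8.0, h=2.0):
    """Thin homogeneous bar meshed by Delaunay over a lattice."""
    from scipy.spatial import Delaunay

    from seegeit.geometry import Electrode, tet_volumes

    xs = np.arange(0, length + h / 2, h)
    ys = np.arange(0, side + h / 2, h)
    zs = np.arange(0, side + h / 2, h)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rng = np.random.default_rng(1)
    jit = rng.uniform(-0.05 * h, 0.05 * h, pts.shape)
    interior = (
        (pts[:, 0] > 0) & (pts[:, 0] < length)
        & (pts[:, 1] > 0) & (pts[:, 1] < side)
        & (pts[:, 2] > 0) & (pts[:, 2] < side)
    )
    pts[interior] += jit[interior]
    tri = Delaunay(pts)
    tets = tri.simplices.copy()
    vols = tet_volumes(pts, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    tets = tets[np.abs(vols) > 1e-9]

    def nearest(p):
        return int(np.argmin(np.linalg.norm(pts - p, axis=1)))

    mid = side / 2
    contacts = [
        Electrode("A", "seeg", "p1", np.array([0.0, mid, mid]), vertex=nearest([0, mid, mid])),
        Electrode("B", "seeg", "p2", np.array([length, mid, mid]),
                  vertex=nearest([length, mid, mid])),
        Electrode("M1", "seeg", "p1", np.array([length / 3, mid, mid]),
                  vertex=nearest([length / 3, mid, mid])),
        Electrode("M2", "seeg", "p2", np.array([2 * length / 3, mid, mid]),
                  vertex=nearest([2 * length / 3, mid, mid])),
        Electrode("R", "ecog", "grid", np.array([length / 2, 0.0, mid]),
                  vertex=nearest([length / 2, 0, mid])),
    ]
    sigma = 0.3
    model = HeadModel(
        vertices=pts,
        tetrahedra=tets,
        element_conductivity=np.full(len(tets), sigma),
        electrodes=contacts,
        edge_length=h,
    )
    return model, sigma, length, side


class TestForwardSolve:
    def test_bar_resistance_matches_analytic(self):
        """Four-terminal section resistance of a homogeneous bar = L/(sigma A)."""
        model, sigma, length, side = bar_model()
        proto = InjectionProtocol(pairs=(("A", "B", 8500.0),), reference_contact="R")
        fwd = solve_forward(model, proto)
        idx = {c: i for i, c in enumerate(fwd.contact_ids)}
        v = fwd.electrode_voltages
        dv = v[idx["M1"], 0] - v[idx["M2"], 0]
        r_measured = abs(dv) / proto.current_amplitude
        # section length between the actual attached vertices (the nominal
        # L/3 markers snap to lattice nodes)
        x1 = model.vertices[model.contact("M1").vertex][0]
        x2 = model.vertices[model.contact("M2").vertex][0]
        area = (side * 1e-3) ** 2
        r_analytic = abs(x2 - x1) * 1e-3 / (sigma * area)
        assert abs(r_measured - r_analytic) / r_analytic < 0.05

    def test_reciprocity(self, model4, protocol28, forward_sol):
        vert = {e.id: e.vertex for e in model4.electrodes}
        a, b, _ = protocol28.pairs[0]
        c, d, _ = protocol28.pairs[1]
        u0 = forward_sol.drive_potentials[:, 0]
        u1 = forward_sol.drive_potentials[:, 1]
        v_ab_cd = u0[vert[c]] - u0[vert[d]]
        v_cd_ab = u1[vert[a]] - u1[vert[b]]
        assert abs(v_ab_cd - v_cd_ab) / abs(v_ab_cd) < 1e-6

    def test_ohmic_scaling(self, model4, protocol28, forward_sol):
        doubled = solve_forward(
            model4.with_conductivity(2 * model4.element_conductivity), protocol28
        )
        assert np.allclose(
            doubled.electrode_voltages, 0.5 * forward_sol.electrode_voltages, rtol=1e-9
        )

    def test_channel_count_excludes_injectors_and_reference(
        self, model4, protocol28, forward_sol
    ):
        n_contacts = len(model4.electrodes)
        assert forward_sol.n_channels == protocol28.n_injections * (n_contacts - 3)
        for d, m in forward_sol.channels:
            a, b, _f = protocol28.pairs[d]
            assert m not in (a, b, protocol28.reference_contact)


class TestJacobian:
    def test_finite_difference_oracle(self, model4, protocol28, forward_sol, jacobian):
        """Adjoint sensitivities against re-solved perturbations (<5% rel)."""
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(12):
            e = int(rng.integers(model4.n_elements))
            dsig = 1e-3 * 0.22
            sigma = model4.element_conductivity.copy()
            sigma[e] += dsig
            fwd2 = solve_forward(model4.with_conductivity(sigma), protocol28)
            dv = fwd2.channel_baseline() - jacobian.baseline
            pred = jacobian.entries[:, e] * dsig
            big = np.abs(dv) > 1e-15
            sel = rng.choice(np.flatnonzero(big), size=min(6, big.sum()), replace=False)
            rel = np.abs(pred[sel] - dv[sel]) / np.abs(dv[sel])
            assert np.all(rel < 0.05)
            n_checked += sel.size
        assert n_checked >= 50

    def test_uniform_perturbation_identity(self, model4, jacobian):
        """Euler homogeneity: J sigma = -V_baseline (within 2%)."""
        lhs = jacobian.entries @ model4.element_conductivity
        rel = np.abs(lhs + jacobian.baseline) / np.abs(jacobian.baseline)
        assert rel.max() < 0.02


class TestTransferSeries:
    def test_null_scenario_constant(self, model4, protocol28, jacobian):
        sc = make_seizure_scenario(model4, seed=0, kind="null")
        ts = simulate_transfer_series(model4, protocol28, jacobian, sc)
        assert np.all(ts.deviations == 0)

    def test_deviation_decays_with_distance_to_focus(self, model4, protocol28, jacobian):
        sc = make_seizure_scenario(model4, seed=1, kind="focal")
        ts = simulate_transfer_series(model4, protocol28, jacobian, sc)
        rel = np.abs(ts.deviations).max(axis=1) / np.abs(ts.baseline)
        pos = {e.id: e.position for e in model4.electrodes}
        pair_pos = {d: 0.5 * (pos[a] + pos[b]) for d, (a, b, _f) in enumerate(protocol28.pairs)}
        d_focus = np.array(
            [
                0.5 * np.linalg.norm(pair_pos[d] - sc.focus_center)
                + 0.5 * np.linalg.norm(pos[m] - sc.focus_center)
                for d, m in ts.channels
            ]
        )
        rho = stats.spearmanr(d_focus, rel).statistic
        assert rho < -0.3  # sensitivity falls off with distance

    def test_peak_relative_change_tunable_into_observed_range(
        self, model4, protocol28, jacobian
    ):
        """delta_sigma_fraction = -0.2 lands the peak-channel change in 2-10%."""
        sc = make_seizure_scenario(model4, seed=1, kind="focal", delta_sigma_fraction=-0.2)
        ts = simulate_transfer_series(model4, protocol28, jacobian, sc)
        dev = np.abs(ts.deviations)
        ch = int(np.unravel_index(np.argmax(dev), dev.shape)[0])
        pct = 100.0 * dev[ch].max() / abs(ts.baseline[ch])
        assert 2.0 < pct < 10.0

    def test_linearization_warning_for_large_perturbation(
        self, model4, protocol28, jacobian
    ):
        sc = make_seizure_scenario(model4, seed=1, delta_sigma_fraction=-0.5)
        with pytest.warns(UserWarning, match="linearized"):
            simulate_transfer_series(model4, protocol28, jacobian, sc)
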