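"""Quasi-static FEM forward problem, adjoint Jacobian, and transfer series.

Linear (P1) tetrahedral finite elements solve nabla.(sigma nabla u) = 0 with
point current sources at the attached electrode vertices (Neumann problem;
the constant null space is removed with a zero-mean Lagrange constraint).
All injections share one sparse factorization.  Sensitivities use the
adjoint construction: for drive field u_d and measurement field w_m,

    dV(d,m)/dsigma_e = -integral_e grad(u_d) . grad(w_m) dV,

so a channel-by-element Jacobian follows from per-element P1 gradients.
Boundary transfer-voltage time series for a seizure scenario are produced by
first-order superposition V(t) = V0 + J @ dsigma(t) (time-difference regime;
no re-solve per frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import HeadModel, tet_volumes
from .protocol import InjectionProtocol
from .scenario import BLOCK_END, BLOCK_START, SeizureScenario, element_delta_sigma

__all__ = [
    "ForwardSolution",
    "JacobianMatrix",
    "TransferSeries",
    "assemble_stiffness",
    "element_gradients",
    "solve_forward",
    "compute_jacobian",
    "simulate_transfer_series",
]


def element_gradients(model: HeadModel) -> tuple[np.ndarray, np.ndarray]:
    """P1 shape-function gradients (n_elem, 4, 3) and element volumes."""
    v = model.vertices[model.tetrahedra]  # (n, 4, 3)
    T = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=1)
    Tinv = np.linalg.inv(T)  # rows of inv(T)^T are grads of lambda_1..3
    g123 = np.transpose(Tinv, (0, 2, 1))  # (n, 3, 3): grad lambda_i in rows
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (n, 4, 3)
    vols = np.abs(tet_volumes(model.vertices, model.tetrahedra))
    return grads, vols


def assemble_stiffness(model: HeadModel) -> sp.csr_matrix:
    """Assemble the conductivity-weighted stiffness matrix K (symmetric PSD).

    K has a one-dimensional null space (constants).  Units: vertices in mm,
    conductivity in S/m -> K in S*mm; currents in A against this K give
    potentials in kV, so solutions are rescaled by the caller (see
    :func:`solve_forward`).
    """
    sigma = np.asarray(model.element_conductivity, dtype=float)
    bad = np.flatnonzero(sigma <= 0)
    if bad.size:
        raise ValueError(f"non-positive conductivity in elements {bad[:10].tolist()}...")
    grads, vols = element_gradients(model)
    # local K_e[i, j] = sigma_e * vol_e * grad_i . grad_j
    local = np.einsum("eid,ejd->eij", grads, grads) * (sigma * vols)[:, None, None]
    tets = model.tetrahedra
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((local.ravel(), (rows, cols)), shape=(model.n_vertices,) * 2)
    return K.tocsr()


@dataclass
class ForwardSolution:
    """Drive and adjoint (measurement-driven) nodal fields for a protocol.

    Potentials are zero-mean; electrode voltages are reported against the
    protocol's reference contact.  ``channels`` lists (injection index,
    measurement contact id) in Jacobian row order: injection-major, all
    contacts except the two injectors and the reference.
    """

    drive_potentials: np.ndarray  # (n_verts, n_inj), V per unit protocol current
    adjoint_potentials: np.ndarray  # (n_verts, n_contacts), unit-dipole fields
    electrode_voltages: np.ndarray  # (n_contacts, n_inj), V vs reference
    channels: list[tuple[int, str]]
    contact_ids: list[str]
    reference_contact: str

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_baseline(self) -> np.ndarray:
        """Baseline transfer voltage V0 per channel (V)."""
        idx = {c: i for i, c in enumerate(self.contact_ids)}
        return np.array(
            [self.electrode_voltages[idx[m], d] for d, m in self.channels]
        )


def _factorize_zero_mean(K: sp.csr_matrix):
    """LU of the zero-mean-augmented system [[K, 1], [1^T, 0]]."""
    n = K.shape[0]
    one = np.ones((n, 1))
    A = sp.bmat([[K, one], [one.T, None]], format="csc")
    return splu(A)


def solve_forward(model: HeadModel, protocol: InjectionProtocol) -> ForwardSolution:
    """Solve all drive and adjoint fields for one model/protocol.

    Drive RHS: +I/-I at the injection pair's attached vertices.  Adjoint
    RHS: unit dipole between a measurement contact and the reference.
    Reciprocity of the symmetric operator makes drive-A-measure-B equal
    drive-B-measure-A to solver tolerance.
    """
    K = assemble_stiffness(model)
    lu = _factorize_zero_mean(K)
    n = model.n_vertices
    vert = {e.id: e.vertex for e in model.electrodes}
    ref = protocol.reference_contact
    if ref not in vert:
        raise ValueError(f"reference contact {ref!r} is not placed on the model")

    # mm-scaled assembly: K in S*mm, so u = K^{-1} I comes out in V*1e3.
    scale = 1e3

    n_inj = protocol.n_injections
    rhs = np.zeros((n + 1, n_inj))
    for d, (a, b, _f) in enumerate(protocol.pairs):
        va, vb = vert[a], vert[b]
        if va == vb:
            raise ValueError(f"injection pair ({a}, {b}) maps to one vertex")
        rhs[va, d] += protocol.current_amplitude
        rhs[vb, d] -= protocol.current_amplitude
    sol = lu.solve(rhs)
    drive = sol[:n] * scale

    contact_ids = [e.id for e in model.electrodes]
    n_c = len(contact_ids)
    rhs_adj = np.zeros((n + 1, n_c))
    vref = vert[ref]
    for m, cid in enumerate(contact_ids):
        rhs_adj[vert[cid], m] += 1.0
        rhs_adj[vref, m] -= 1.0
    adj = lu.solve(rhs_adj)[:n] * scale

    volts = np.empty((n_c, n_inj))
    for m, cid in enumerate(contact_ids):
        volts[m] = drive[vert[cid]] - drive[vref]

    channels = []
    for d, (a, b, _f) in enumerate(protocol.pairs):
        for cid in contact_ids:
            if cid in (a, b, ref):
                continue
            channels.append((d, cid))

    return ForwardSolution(
        drive_potentials=drive,
        adjoint_potentials=adj,
        electrode_voltages=volts,
        channels=channels,
        contact_ids=contact_ids,
        reference_contact=ref,
    )


@dataclass
class JacobianMatrix:
    """Channel x element transfer-voltage sensitivity, V per (S/m).

    Rows follow ``channels`` (injection-major, measurement contacts excluding
    the injectors and the reference); columns are mesh tetrahedra.  For a
    homogeneous model, Euler homogeneity gives J @ sigma = -V_baseline.
    """

    entries: np.ndarray  # (n_channels, n_elements)
    channels: list[tuple[int, str]]
    baseline: np.ndarray  # (n_channels,) V

    @property
    def n_channels(self) -> int:
        return self.entries.shape[0]

    @property
    def n_elements(self) -> int:
        return self.entries.shape[1]


def compute_jacobian(
    model: HeadModel,
    protocol: InjectionProtocol,
    forward: ForwardSolution,
) -> JacobianMatrix:
    """Adjoint-field Jacobian: J[(d,m), e] = -vol_e * grad(u_d).grad(w_m).

    Gradients are constant per P1 element, so the element integral is exact.
    Volume units are mm^3 against S*mm stiffness scaling, consistent with
    the mm-assembled forward solve (entries in V per S/m).
    """
    if forward.adjoint_potentials is None:
        raise ValueError("forward solution lacks adjoint fields")
    grads, vols = element_gradients(model)
    tets = model.tetrahedra
    contact_idx = {c: i for i, c in enumerate(forward.contact_ids)}

    # Per-element gradient of each nodal field: sum_i grads[:, i] * u[tet[:, i]]
    def field_grads(u_cols: np.ndarray) -> np.ndarray:
        # u_cols: (n_verts, k) -> (k, n_elem, 3)
        uv = u_cols[tets]  # (n_elem, 4, k)
        return np.einsum("eiv,eid->ved", uv, grads)

    gd = field_grads(forward.drive_potentials)  # (n_inj, n_elem, 3)
    ga = field_grads(forward.adjoint_potentials)  # (n_contacts, n_elem, 3)

    # Unit bookkeeping: fields are in volts but gradients are per mm and
    # volumes in mm^3, so the SI integral -int grad(u).grad(w) dV carries a
    # net 1e-3 factor (1e-9 m^3/mm^3 x 1e6 from the two 1/mm gradients).
    rows = np.empty((len(forward.channels), model.n_elements))
    r = 0
    for d, (a, b, _f) in enumerate(protocol.pairs):
        for cid in forward.contact_ids:
            if cid in (a, b, forward.reference_contact):
                continue
            m = contact_idx[cid]
            rows[r] = -vols * np.einsum("ed,ed->e", gd[d], ga[m])
            r += 1
    rows *= 1e-3
    return JacobianMatrix(
        entries=rows, channels=list(forward.channels), baseline=forward.channel_baseline()
    )


@dataclass
class TransferSeries:
    """Per-channel transfer voltages on a 1 s grid, plus the ground truth."""

    times: np.ndarray  # (n_frames,) s, block-relative
    voltages: np.ndarray  # (n_channels, n_frames) V
    baseline: np.ndarray  # (n_channels,) V
    channels: list[tuple[int, str]]
    truth_g: np.ndarray  # (n_elements,) element-space delta-sigma pattern (S/m)
    truth_f: np.ndarray  # (n_frames,) normalized time course

    @property
    def deviations(self) -> np.ndarray:
        return self.voltages - self.baseline[:, None]


def simulate_transfer_series(
    model: HeadModel,
    protocol: InjectionProtocol,
    jacobian: JacobianMatrix,
    scenario: SeizureScenario,
    t_start: float = BLOCK_START,
    t_end: float = BLOCK_END,
) -> TransferSeries:
    """Linearized transfer voltages V(t) = V0 + J @ dsigma(t) on a 1 s grid.

    The scenario's perturbation is separable (spatial pattern x time course),
    so only one matrix-vector product with J is needed.  Ground-truth factors
    are returned for scoring.  Warns when |dsigma|/sigma > 0.5 (outside the
    linearization's trust region).
    """
    times = np.arange(t_start, t_end + 0.5, 1.0)
    g, f = element_delta_sigma(scenario, model, times)
    rel = np.abs(g) / model.element_conductivity
    if max(rel.max(), abs(scenario.delta_sigma_fraction)) >= 0.5:
        warnings.warn("`|delta sigma|/sigma > 0.5`: linearized series unreliable", stacklevel=2)
    s = jacobian.entries @ g  # (n_channels,) static deviation pattern
    volts = jacobian.baseline[:, None] + s[:, None] * f[None, :]
    return TransferSeries(
        times=times,
        voltages=volts,
        baseline=jacobian.baseline.copy(),
        channels=list(jacobian.channels),
        truth_g=g,
        truth_f=f,
    )
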