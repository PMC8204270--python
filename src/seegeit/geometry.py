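"""Synthetic head model: half-ellipsoid brain mesh and intracranial electrodes.

The study geometry is a porcine-scale brain approximated by a half-ellipsoid
(flat base at z = 0, curved dorsal surface above), meshed with linear
tetrahedra and carrying a uniform isotropic conductivity of 0.22 S/m.
Electrodes are an epicortical 4x8 grid (ECoG, 10 mm spacing) on the dorsal
surface plus 3-4 ten-contact depth probes (SEEG, 5 mm spacing) inserted
obliquely towards the midline.  Contacts keep their nominal millimetre
coordinates and are *attached* to the nearest mesh vertex (point-electrode
model); the attachment must lie within one edge length of the contact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

BRAIN_CONDUCTIVITY = 0.22  # S/m, uniform isotropic brain tissue

__all__ = [
    "Electrode",
    "HeadModel",
    "GridLayout",
    "ProbeLayout",
    "ElectrodeLayout",
    "build_brain_mesh",
    "place_electrodes",
    "default_layout",
    "tet_volumes",
    "element_centroids",
]


@dataclass(frozen=True)
class Electrode:
    """A single recording/injecting contact.

    ``position`` is the nominal coordinate in mm; ``vertex`` is the mesh
    vertex the contact is electrically attached to.  Within a probe,
    contact numbering increases from deep to superficial (contact 1 is the
    deepest, at the probe tip).
    """

    id: str
    kind: str  # "ecog" | "seeg"
    probe_id: str
    position: np.ndarray  # (3,) mm
    contact_length: float = 2.0  # mm
    diameter: float = 0.86  # mm
    vertex: int = -1


@dataclass
class HeadModel:
    """Tetrahedral brain mesh with conductivity and electrode geometry."""

    vertices: np.ndarray  # (n_verts, 3) mm
    tetrahedra: np.ndarray  # (n_tets, 4) int
    element_conductivity: np.ndarray  # (n_tets,) S/m
    electrodes: list[Electrode] = field(default_factory=list)
    cannula_tip: np.ndarray | None = None  # mm, BPN injection reference point
    boundary_vertices: np.ndarray | None = None  # indices on the outer surface
    edge_length: float = 4.0  # nominal mesh edge length, mm
    semi_axes: tuple[float, float, float] = (45.0, 30.0, 25.0)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tetrahedra.shape[0]

    @property
    def contact_ids(self) -> list[str]:
        return [e.id for e in self.electrodes]

    @property
    def contact_positions(self) -> np.ndarray:
        return np.array([e.position for e in self.electrodes])

    def contact(self, contact_id: str) -> Electrode:
        for e in self.electrodes:
            if e.id == contact_id:
                return e
        raise KeyError(f"no contact with id {contact_id!r}")

    def probes(self) -> dict[str, list[Electrode]]:
        out: dict[str, list[Electrode]] = {}
        for e in self.electrodes:
            out.setdefault(e.probe_id, []).append(e)
        return out

    def seeg_probe_ids(self) -> list[str]:
        return sorted({e.probe_id for e in self.electrodes if e.kind == "seeg"})

    def total_volume(self) -> float:
        return float(tet_volumes(self.vertices, self.tetrahedra).sum())

    def with_conductivity(self, sigma: np.ndarray) -> "HeadModel":
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (self.n_elements,):
            raise ValueError("conductivity must have one value per element")
        return replace(self, element_conductivity=sigma)


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for conforming orientation)."""
    p = vertices[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def element_centroids(model: HeadModel) -> np.ndarray:
    return model.vertices[model.tetrahedra].mean(axis=1)


def _params_seed(*parts) -> int:
    """Deterministic seed derived from geometry parameters (< 2**31)."""
    h = hashlib.sha256(repr(parts).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def build_brain_mesh(
    semi_axes: tuple[float, float, float] = (45.0, 30.0, 25.0),
    edge_length: float = 4.0,
) -> HeadModel:
    """Mesh a half-ellipsoid brain domain with ~``edge_length`` tetrahedra.

    The domain is {x²/a² + y²/b² + z²/c² ≤ 1, z ≥ 0}: a convex half-ellipsoid
    with a flat base.  Nodes are a body lattice (slightly jittered away from
    the surface to avoid slivers) plus projected surface/base samples;
    convexity lets a Delaunay triangulation of the nodes tile the domain.

    Raises ``ValueError`` for degenerate geometry (any semi-axis ≤ 2× edge
    length or non-positive inputs).
    """
    a, b, c = (float(s) for s in semi_axes)
    h = float(edge_length)
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    if h < 1.0:
        raise ValueError("target edge length must be >= 1 mm (desk scale)")
    if min(a, b, c) <= 2.0 * h:
        raise ValueError(
            f"degenerate geometry: semi-axes {semi_axes} must all exceed "
            f"2x edge length ({2*h:.1f} mm)"
        )

    ax = np.arange(-a, a + 0.5 * h, h)
    ay = np.arange(-b, b + 0.5 * h, h)
    az = np.arange(0.0, c + 0.5 * h, h)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rho = np.sqrt((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2)

    # Interior lattice nodes, kept clear of the curved surface by ~0.35 h
    # (approximate radial distance |p|(1/rho - 1)).
    r = np.linalg.norm(pts, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist_surf = np.where(rho > 0, r * (1.0 / np.maximum(rho, 1e-12) - 1.0), np.inf)
    interior = (rho < 1.0) & (dist_surf >= 0.35 * h)
    interior_pts = pts[interior]

    # Curved-surface nodes: project lattice directions onto the ellipsoid.
    shell = (rho >= 0.5) & (rho <= 1.6) & (pts[:, 2] > 1e-9)
    surf = pts[shell] / rho[shell, None]
    # Base-plane ring at z = 0 comes from shell points with z == 0.
    base_shell = (rho >= 0.5) & (rho <= 1.6) & (np.abs(pts[:, 2]) <= 1e-9)
    base = pts[base_shell] / rho[base_shell, None]
    surf = np.vstack([surf, base])
    # Dedupe surface samples on a 0.6 h grid to avoid near-coincident nodes.
    key = np.round(surf / (0.6 * h)).astype(np.int64)
    _, keep = np.unique(key, axis=0, return_index=True)
    surf = surf[np.sort(keep)]

    # Jitter interior nodes (deterministic in the parameters) so the lattice
    # Delaunay has no degenerate cospherical configurations.  Base-plane
    # interior nodes are jittered only in-plane to keep the base flat.
    rng = np.random.default_rng(_params_seed("brain-mesh", semi_axes, h))
    jit = rng.uniform(-0.08 * h, 0.08 * h, size=interior_pts.shape)
    on_base = np.abs(interior_pts[:, 2]) <= 1e-9
    jit[on_base, 2] = 0.0
    interior_pts = interior_pts + jit

    nodes = np.vstack([interior_pts, surf])
    tri = Delaunay(nodes)
    tets = tri.simplices.copy()
    vols = tet_volumes(nodes, tets)
    # Fix orientation, drop exact slivers.
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    keep = vols > 1e-9 * h**3
    tets = tets[keep]

    # Drop any nodes left unreferenced.
    used = np.unique(tets)
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = nodes[used]
    tets = remap[tets]

    # Boundary vertices: faces appearing exactly once.
    faces = np.vstack(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    faces_sorted = np.sort(faces, axis=1)
    _, idx, counts = np.unique(faces_sorted, axis=0, return_index=True, return_counts=True)
    bverts = np.unique(faces_sorted[idx[counts == 1]])

    return HeadModel(
        vertices=nodes,
        tetrahedra=tets,
        element_conductivity=np.full(tets.shape[0], BRAIN_CONDUCTIVITY),
        boundary_vertices=bverts,
        edge_length=h,
        semi_axes=(a, b, c),
    )


@dataclass(frozen=True)
class GridLayout:
    """Epicortical grid: ``rows`` x ``cols`` contacts at ``spacing`` mm."""

    rows: int = 4
    cols: int = 8
    spacing: float = 10.0
    center_xy: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class ProbeLayout:
    """Depth probe: ``n_contacts`` from the tip towards the surface."""

    probe_id: str
    tip: tuple[float, float, float]
    direction: tuple[float, float, float]  # from tip towards entry (superficial)
    n_contacts: int = 10
    spacing: float = 5.0


@dataclass(frozen=True)
class ElectrodeLayout:
    grid: GridLayout | None
    probes: tuple[ProbeLayout, ...]
    cannula_tip: tuple[float, float, float] = (14.0, 0.0, 9.0)


def default_layout(n_probes: int = 3) -> ElectrodeLayout:
    """Standard study layout: 4x8 ECoG grid + ``n_probes`` 10-contact probes.

    Probe trajectories run obliquely along the long axis towards the midline
    so that the 45 mm contact span fits inside the half-ellipsoid; tips
    cluster around the cannula (the epileptogenic focus reference).
    """
    probes = [
        ProbeLayout("seeg1", tip=(18.0, -8.0, 8.0), direction=(-1.0, 0.12, 0.06)),
        ProbeLayout("seeg2", tip=(18.0, 8.0, 8.0), direction=(-1.0, -0.12, 0.06)),
        ProbeLayout("seeg3", tip=(21.0, 0.0, 14.0), direction=(-1.0, 0.0, 0.10)),
        ProbeLayout("seeg4", tip=(10.0, 0.0, 5.0), direction=(-1.0, 0.0, 0.12)),
    ]
    if not 1 <= n_probes <= 4:
        raise ValueError("n_probes must be in 1..4")
    return ElectrodeLayout(grid=GridLayout(), probes=tuple(probes[:n_probes]))


def _surface_z(a: float, b: float, c: float, x: float, y: float) -> float:
    s = 1.0 - (x / a) ** 2 - (y / b) ** 2
    if s <= 0:
        raise ValueError(f"grid point ({x:.1f}, {y:.1f}) lies outside the dome footprint")
    return c * np.sqrt(s)


def place_electrodes(model: HeadModel, layout: ElectrodeLayout) -> HeadModel:
    """Position contacts and attach each to its nearest mesh vertex.

    ECoG contacts sit on the curved surface and snap to boundary vertices;
    SEEG contacts lie on straight probe trajectories in the interior.  A
    probe whose contacts leave the domain raises ``ValueError`` naming the
    probe; two contacts attached to the same vertex raise a collision error.
    """
    a, b, c = model.semi_axes
    electrodes: list[Electrode] = []

    if layout.grid is not None:
        g = layout.grid
        if g.rows * g.cols > 32:
            raise ValueError("at most 32 ECoG contacts supported")
        x0, y0 = g.center_xy
        xs = x0 + (np.arange(g.cols) - (g.cols - 1) / 2.0) * g.spacing
        ys = y0 + (np.arange(g.rows) - (g.rows - 1) / 2.0) * g.spacing
        k = 0
        for yi in ys:
            for xi in xs:
                k += 1
                z = _surface_z(a, b, c, xi, yi)
                electrodes.append(
                    Electrode(
                        id=f"E{k:02d}",
                        kind="ecog",
                        probe_id="grid",
                        position=np.array([xi, yi, z]),
                        contact_length=0.0,
                        diameter=4.0,
                    )
                )

    if len(layout.probes) > 4:
        raise ValueError("at most 4 SEEG probes supported")
    for probe in layout.probes:
        if probe.n_contacts > 10:
            raise ValueError("at most 10 contacts per SEEG probe")
        tip = np.asarray(probe.tip, dtype=float)
        u = np.asarray(probe.direction, dtype=float)
        u = u / np.linalg.norm(u)
        for i in range(probe.n_contacts):
            pos = tip + i * probe.spacing * u
            rho = np.sqrt((pos[0] / a) ** 2 + (pos[1] / b) ** 2 + (pos[2] / c) ** 2)
            if rho > 0.995 or pos[2] < 0:
                raise ValueError(
                    f"probe {probe.probe_id!r} exits the domain at contact {i + 1} "
                    f"({pos.round(1).tolist()} mm)"
                )
            electrodes.append(
                Electrode(
                    id=f"{probe.probe_id.upper()}-{i + 1:02d}",
                    kind="seeg",
                    probe_id=probe.probe_id,
                    position=pos,
                )
            )

    # Attach to nearest mesh vertex (ECoG restricted to boundary vertices).
    bset = model.boundary_vertices
    if bset is None:
        raise ValueError("model has no boundary vertex table; build the mesh first")
    taken: dict[int, str] = {}
    attached: list[Electrode] = []
    for e in electrodes:
        cand_idx = bset if e.kind == "ecog" else np.arange(model.n_vertices)
        d = np.linalg.norm(model.vertices[cand_idx] - e.position, axis=1)
        j = int(cand_idx[int(np.argmin(d))])
        dmin = float(d.min())
        if j in taken:
            raise ValueError(
                f"contact collision: {e.id} and {taken[j]} both attach to mesh vertex {j}"
            )
        if dmin > model.edge_length:
            raise ValueError(
                f"contact {e.id} is {dmin:.1f} mm from the nearest mesh vertex "
                f"(> edge length {model.edge_length:.1f} mm)"
            )
        taken[j] = e.id
        attached.append(replace(e, vertex=j))

    return replace(
        model,
        electrodes=attached,
        cannula_tip=np.asarray(layout.cannula_tip, dtype=float),
    )
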