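"""Structured hexahedral meshes and built-in boundary-value problems.

All geometry lives in the reference (material) configuration, with
coordinates in micrometres.  Meshes are regular grids of 8-node bricks;
semi-2D cases (maze, grate) are one-element-thick layers of the same
element.  Rigid walls and obstacles are represented by deactivating
elements (``active_mask``); deactivated elements are excluded from every
assembly loop and their surfaces receive sliding constraints in the
mechanics module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Mesh",
    "BVPSpec",
    "build_box_mesh",
    "make_bvp",
    "node_set_from_predicate",
    "CASE_IDS",
]

CASE_IDS = ("cube_directional", "agar", "obstacles", "maze", "grate")


@dataclass
class Mesh:
    """Regular hexahedral grid.

    Attributes
    ----------
    node_coords : (N, 3) float array, micrometres.
    element_conn : (E, 8) int array, VTK hexahedron node ordering.
    spacing : (hx, hy, hz) element edge lengths in micrometres.
    shape : (nx, ny, nz) number of elements per direction.
    node_sets : named node-index sets (faces, corners, BVP regions).
    active_mask : per-element flag; ``False`` marks wall/obstacle
        elements that are excluded from all assembly.
    dim_hint : ``"3d"`` or ``"semi-2d"`` (one-element-thick layer).
    """

    node_coords: np.ndarray
    element_conn: np.ndarray
    spacing: Tuple[float, float, float]
    shape: Tuple[int, int, int]
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    dim_hint: str = "3d"

    def __post_init__(self) -> None:
        if self.active_mask is None:
            self.active_mask = np.ones(len(self.element_conn), dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.element_conn)

    @property
    def active_elements(self) -> np.ndarray:
        """Indices of active elements, ascending."""
        return np.nonzero(self.active_mask)[0]

    @property
    def active_nodes(self) -> np.ndarray:
        """Nodes attached to at least one active element, ascending."""
        return np.unique(self.element_conn[self.active_mask])

    def element_centers(self) -> np.ndarray:
        return self.node_coords[self.element_conn].mean(axis=1)

    def validate(self) -> None:
        """Check the structural invariants (connectivity, node sets)."""
        if self.element_conn.min() < 0 or self.element_conn.max() >= self.n_nodes:
            raise ValueError("connectivity refers to non-existent nodes")
        for name, idx in self.node_sets.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise ValueError(f"node set {name!r} out of range")


@dataclass
class BVPSpec:
    """Boundary-value-problem description attached to a mesh.

    ``c_dirichlet`` is ``(node_set_name, value)`` with value in [0, 1]
    (always 1 for the built-in cases).  ``phi_init_set`` names the nodes
    where the biofilm field starts at 1; by default those nodes evolve
    freely afterwards (``phi_held_fixed=False``).  ``mech_constraints``
    is a list of ``(node_set_name, components)`` pairs; components are
    axis indices whose displacement is fixed to zero.
    """

    case_id: str
    domain_size: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    c_dirichlet: Tuple[str, float]
    phi_init_set: str = "phi_init"
    phi_held_fixed: bool = False
    mech_constraints: List[Tuple[str, Tuple[int, ...]]] = field(default_factory=list)

    def validate(self, mesh: Mesh) -> None:
        name, value = self.c_dirichlet
        if not 0.0 <= value <= 1.0:
            raise ValueError("Dirichlet value for c must lie in [0, 1]")
        for req in (name, self.phi_init_set):
            if req not in mesh.node_sets:
                raise ValueError(f"node set {req!r} missing from mesh")
        # no initial biofilm inside an obstacle: every phi-init node must
        # belong to at least one active element
        active = set(mesh.active_nodes.tolist())
        bad = [n for n in mesh.node_sets[self.phi_init_set] if n not in active]
        if bad:
            raise ValueError(f"phi initial nodes inside obstacles: {bad[:5]}")


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _as_triple(value) -> Tuple[float, float, float]:
    if np.isscalar(value):
        return (float(value),) * 3
    value = tuple(float(v) for v in value)
    if len(value) != 3:
        raise ValueError("expected a scalar or a length-3 sequence")
    return value


def build_box_mesh(extents, spacing) -> Mesh:
    """Build a regular hexahedral grid over ``[0, Lx] x [0, Ly] x [0, Lz]``.

    ``spacing`` may be a scalar or a per-axis triple and must divide each
    extent exactly.  Node ordering is lexicographic with x fastest; the
    corner node sits at the origin.  Canonical node sets are created for
    the six faces (``xmin`` ... ``zmax``) and the eight corners
    (``corner_000`` ... ``corner_111``).
    """
    ext = _as_triple(extents)
    spc = _as_triple(spacing)
    if any(e <= 0 for e in ext) or any(h <= 0 for h in spc):
        raise ValueError("extents and spacing must be positive")
    counts = []
    for e, h in zip(ext, spc):
        n = e / h
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(
                f"spacing {h} does not divide extent {e}; choose a spacing "
                "that tiles the box exactly"
            )
        counts.append(int(round(n)))
    nx, ny, nz = counts
    hx, hy, hz = spc

    xs = np.arange(nx + 1) * hx
    ys = np.arange(ny + 1) * hy
    zs = np.arange(nz + 1) * hz
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.transpose(2, 1, 0).ravel(), J.transpose(2, 1, 0).ravel(), K.transpose(2, 1, 0).ravel()
    conn = np.column_stack([
        nid(I, J, K), nid(I + 1, J, K), nid(I + 1, J + 1, K), nid(I, J + 1, K),
        nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I + 1, J + 1, K + 1), nid(I, J + 1, K + 1),
    ]).astype(np.int64)

    mesh = Mesh(coords, conn, (hx, hy, hz), (nx, ny, nz))
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    tol = 1e-9 * max(ext)
    mesh.node_sets.update({
        "xmin": np.nonzero(x < tol)[0],
        "xmax": np.nonzero(x > ext[0] - tol)[0],
        "ymin": np.nonzero(y < tol)[0],
        "ymax": np.nonzero(y > ext[1] - tol)[0],
        "zmin": np.nonzero(z < tol)[0],
        "zmax": np.nonzero(z > ext[2] - tol)[0],
    })
    for ci in (0, 1):
        for cj in (0, 1):
            for ck in (0, 1):
                mesh.node_sets[f"corner_{ci}{cj}{ck}"] = np.array(
                    [nid(ci * nx, cj * ny, ck * nz)], dtype=np.int64
                )
    mesh.validate()
    return mesh


def node_set_from_predicate(mesh: Mesh, predicate: Callable) -> np.ndarray:
    """Nodes whose coordinates satisfy ``predicate``, ascending.

    The predicate receives an ``(N, 3)`` coordinate array and may return a
    boolean array; a per-point callable ``(x, y, z) -> bool`` also works.
    """
    coords = mesh.node_coords
    try:
        flags = np.asarray(predicate(coords))
        if flags.shape != (len(coords),):
            raise TypeError
    except TypeError:
        flags = np.array([bool(predicate(*xyz)) for xyz in coords])
    return np.nonzero(flags)[0].astype(np.int64)


# ---------------------------------------------------------------------------
# built-in boundary value problems
# ---------------------------------------------------------------------------

def _pin_sets(mesh: Mesh, ext) -> List[Tuple[str, Tuple[int, ...]]]:
    """Minimal 3-2-1 rigid-body pins for a free box."""
    coords = mesh.node_coords

    def nearest(pt):
        return int(np.argmin(np.linalg.norm(coords - np.asarray(pt), axis=1)))

    mesh.node_sets["pin_a"] = np.array([nearest((0, 0, 0))], dtype=np.int64)
    mesh.node_sets["pin_b"] = np.array([nearest((ext[0], 0, 0))], dtype=np.int64)
    mesh.node_sets["pin_c"] = np.array([nearest((0, ext[1], 0))], dtype=np.int64)
    return [("pin_a", (0, 1, 2)), ("pin_b", (1, 2)), ("pin_c", (2,))]


def _active_only(mesh: Mesh, nodes: np.ndarray) -> np.ndarray:
    keep = np.isin(nodes, mesh.active_nodes)
    return nodes[keep]


def _cube_directional(ov: dict):
    ext = _as_triple(ov.get("domain_size", 20.0))
    h = ov.get("spacing", 1.0)
    mesh = build_box_mesh(ext, h)
    center = np.asarray(ext) / 2.0
    radius = float(ov.get("phi_radius", 5.0))
    sphere = node_set_from_predicate(
        mesh, lambda X: np.linalg.norm(X - center, axis=1) <= radius + 1e-9
    )
    mesh.node_sets["phi_init"] = sphere
    # nutrient source: a patch around one corner of the cube.  The patch
    # radius matches the colony radius (the case's characteristic feature
    # size); a radius of 0 reduces it to a single corner node, but a point
    # source cannot feed the colony's consumption and the run stays inert.
    corner = np.asarray(ext)
    cr = float(ov.get("corner_radius", radius))
    source = node_set_from_predicate(
        mesh, lambda X: np.linalg.norm(X - corner, axis=1) <= cr + 1e-9
    )
    mesh.node_sets["c_source"] = source
    spec = BVPSpec(
        "cube_directional", ext, mesh.spacing, ("c_source", 1.0),
        mech_constraints=_pin_sets(mesh, ext),
    )
    return mesh, spec


def _agar(ov: dict):
    ext = _as_triple(ov.get("domain_size", 20.0))
    h = ov.get("spacing", 1.0)
    mesh = build_box_mesh(ext, h)
    hz = mesh.spacing[2]
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    radius = float(ov.get("phi_diameter", 5.0)) / 2.0
    # initial colony: a centred circle in the node plane directly above the
    # nutrient-covered bottom face
    disc = node_set_from_predicate(
        mesh,
        lambda X: (np.abs(X[:, 2] - hz) < 1e-9)
        & (np.hypot(X[:, 0] - cx, X[:, 1] - cy) <= radius + 1e-9),
    )
    mesh.node_sets["phi_init"] = disc
    mesh.node_sets["c_source"] = mesh.node_sets["zmin"]
    spec = BVPSpec(
        "agar", ext, mesh.spacing, ("c_source", 1.0),
        mech_constraints=_pin_sets(mesh, ext),
    )
    return mesh, spec


def _obstacles(ov: dict):
    ext = _as_triple(ov.get("domain_size", 30.0))
    h = ov.get("spacing", 1.0)
    mesh = build_box_mesh(ext, h)
    center = np.asarray(ext) / 2.0
    radius = float(ov.get("phi_radius", 5.0))
    col_r = float(ov.get("column_diameter", 6.0)) / 2.0
    # four symmetric rigid columns along z at the quarter points
    qx, qy = ext[0] / 4.0, ext[1] / 4.0
    axes = ov.get("column_axes", [(qx, qy), (qx, 3 * qy), (3 * qx, qy), (3 * qx, 3 * qy)])
    centers = mesh.element_centers()
    inactive = np.zeros(mesh.n_elements, dtype=bool)
    for ax, ay in axes:
        inactive |= np.hypot(centers[:, 0] - ax, centers[:, 1] - ay) <= col_r
    mesh.active_mask = ~inactive
    sphere = node_set_from_predicate(
        mesh, lambda X: np.linalg.norm(X - center, axis=1) <= radius + 1e-9
    )
    mesh.node_sets["phi_init"] = _active_only(mesh, sphere)
    mesh.node_sets["c_source"] = _active_only(mesh, mesh.node_sets["zmin"])
    spec = BVPSpec(
        "obstacles", ext, mesh.spacing, ("c_source", 1.0),
        mech_constraints=_pin_sets(mesh, ext),
    )
    return mesh, spec


def _maze(ov: dict):
    diameter = float(ov.get("diameter", 560.0))
    wall = float(ov.get("wall_width", 10.0))
    corridor = float(ov.get("corridor_width", wall))
    s = float(ov.get("spacing", 5.0))
    tz = float(ov.get("thickness", 4.0))
    mesh = build_box_mesh((diameter, diameter, tz), (s, s, tz))
    mesh.dim_hint = "semi-2d"
    cx = cy = diameter / 2.0
    r_chamber = float(ov.get("chamber_radius", 2.5 * wall))
    pitch = wall + corridor
    centers = mesh.element_centers()
    r = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
    theta = np.arctan2(centers[:, 1] - cy, centers[:, 0] - cx)

    outer = diameter / 2.0
    active = r <= r_chamber  # central chamber
    golden = 2.399963229728653  # radians; deterministic opening placement
    k = 0
    r_in = r_chamber
    while r_in + wall + corridor <= outer:
        wall_band = (r > r_in) & (r <= r_in + wall)
        corr_band = (r > r_in + wall) & (r <= r_in + wall + corridor)
        active |= corr_band
        # one opening through each wall ring
        ang = ((theta - k * golden + np.pi) % (2 * np.pi)) - np.pi
        r_mid = r_in + wall / 2.0
        half = max(corridor, 1.5 * s) / max(r_mid, 1e-9)
        active |= wall_band & (np.abs(ang) <= half)
        # a blocker opposite the opening turns each ring into two dead-ends
        ang_b = ((theta - k * golden) % (2 * np.pi)) - np.pi
        r_cmid = r_in + wall + corridor / 2.0
        half_b = max(wall, 1.5 * s) / max(r_cmid, 1e-9) / 2.0
        active &= ~(corr_band & (np.abs(ang_b) <= half_b))
        r_in += pitch
        k += 1
    active &= r <= outer
    mesh.active_mask = active

    source = node_set_from_predicate(
        mesh,
        lambda X: np.hypot(X[:, 0] - cx, X[:, 1] - cy) <= r_chamber - wall / 2.0,
    )
    mesh.node_sets["c_source"] = _active_only(mesh, source)
    # entrance: the outermost corridor band at angle of the last opening
    r_outer_corr = r_in - corridor
    ang_e = (k - 1) * golden
    ex, ey = cx + (r_outer_corr + corridor / 2.0) * np.cos(ang_e), cy + (
        r_outer_corr + corridor / 2.0
    ) * np.sin(ang_e)
    entrance = node_set_from_predicate(
        mesh, lambda X: np.hypot(X[:, 0] - ex, X[:, 1] - ey) <= 1.5 * corridor
    )
    mesh.node_sets["phi_init"] = _active_only(mesh, entrance)
    spec = BVPSpec(
        "maze", (diameter, diameter, tz), mesh.spacing, ("c_source", 1.0),
        mech_constraints=[("all_nodes", (2,))],
    )
    mesh.node_sets["all_nodes"] = np.arange(mesh.n_nodes, dtype=np.int64)
    return mesh, spec


def _grate(ov: dict):
    n = int(ov.get("n_channels", 5))
    w = float(ov.get("channel_width", 10.0))
    b = float(ov.get("wall_width", 10.0))
    s = float(ov.get("spacing", 2.5))
    tz = float(ov.get("thickness", 1.0))
    L = n * (w + b) + w
    mesh = build_box_mesh((L, L, tz), (s, s, tz))
    mesh.dim_hint = "semi-2d"
    centers = mesh.element_centers()
    pitch = w + b
    in_x = (centers[:, 0] % pitch) < w
    in_y = (centers[:, 1] % pitch) < w
    mesh.active_mask = in_x | in_y
    tol = 1e-9 * L
    mesh.node_sets["phi_init"] = _active_only(
        mesh, node_set_from_predicate(mesh, lambda X: X[:, 1] < tol)
    )
    mesh.node_sets["c_source"] = _active_only(
        mesh, node_set_from_predicate(mesh, lambda X: X[:, 1] > L - tol)
    )
    mesh.node_sets["all_nodes"] = np.arange(mesh.n_nodes, dtype=np.int64)
    spec = BVPSpec(
        "grate", (L, L, tz), mesh.spacing, ("c_source", 1.0),
        mech_constraints=[("all_nodes", (2,))],
    )
    return mesh, spec


_BUILDERS = {
    "cube_directional": _cube_directional,
    "agar": _agar,
    "obstacles": _obstacles,
    "maze": _maze,
    "grate": _grate,
}


def make_bvp(case_id: str, overrides: dict | None = None) -> Tuple[Mesh, BVPSpec]:
    """Build one of the five built-in boundary value problems.

    ``overrides`` tunes geometric knobs (domain size, spacing, colony
    radius, column layout, ...) without changing the case topology.
    """
    if case_id not in _BUILDERS:
        raise ValueError(
            f"unknown case {case_id!r}; available cases: {', '.join(CASE_IDS)}"
        )
    mesh, spec = _BUILDERS[case_id](dict(overrides or {}))
    spec.validate(mesh)
    return mesh, spec
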