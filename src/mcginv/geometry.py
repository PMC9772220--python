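"""Triangulated heart surfaces, sensor arrays and cross-mesh correspondence.

The inverse algorithms in this package are geometry-agnostic: they only need
source positions ``r'_q`` with orientations ``a_q`` and detector positions
``r_m``.  This module provides parametric closed ellipsoidal surfaces as
stand-ins for a ventricular epicardium, a planar magnetometer grid, and the
nearest-node correspondence used to compare potentials across two
independently meshed surfaces.

All coordinates are in centimetres and all indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, distance_matrix

__all__ = [
    "TriMesh",
    "SensorArray",
    "NodeMap",
    "make_ellipsoid_mesh",
    "remesh_perturb",
    "make_sensor_grid",
    "nearest_node_map",
    "read_ply",
    "write_ply",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Closed triangulated surface with per-node outward unit normals.

    Attributes
    ----------
    node_positions : (N, 3) float array, cm
        Source positions ``r'_q``.
    triangles : (F, 3) int array
        Vertex index triples.
    node_normals : (N, 3) float array
        Outward unit vectors ``a_q`` (dipole orientations).
    label : str
        Free-text identifier, e.g. ``"model1"``.
    """

    node_positions: np.ndarray
    triangles: np.ndarray
    node_normals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.node_normals = np.asarray(self.node_normals, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def euler_characteristic(self) -> int:
        """V - E + F; equals 2 for a closed genus-0 surface."""
        edges = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_nodes - n_edges + self.n_triangles

    def surface_area(self) -> float:
        p = self.node_positions[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def validate(self) -> None:
        """Raise ``ValueError`` on violated structural invariants."""
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_nodes
        ):
            raise ValueError("triangle index out of range")
        p = self.node_positions[self.triangles]
        areas = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        if np.any(areas <= 0):
            raise ValueError("degenerate (zero-area) triangle")
        norms = np.linalg.norm(self.node_normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("node normals must be unit length")


@dataclass
class SensorArray:
    """Planar grid of magnetometer positions ``r_m`` (cm)."""

    positions: np.ndarray
    grid_rows: int
    grid_cols: int
    spacing: float
    plane_normal: np.ndarray
    label: str = "grid"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class NodeMap:
    """Per-node nearest-neighbour correspondence between two meshes."""

    source_label: str
    target_label: str
    indices: np.ndarray  # one target index per source node
    distances: np.ndarray  # cm, >= 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors on S^2 (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _triangulate_directions(directions: np.ndarray) -> np.ndarray:
    """Spherical triangulation of unit vectors via their convex hull.

    Every unit vector is extreme, so all points appear as hull vertices;
    faces are re-oriented to point away from the origin.
    """
    hull = ConvexHull(directions)
    tris = hull.simplices.copy()
    p = directions[tris]
    face_n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    centroid = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", face_n, centroid) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _angle_weighted_normals(positions: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Per-vertex normals as angle-weighted averages of incident face normals."""
    normals = np.zeros_like(positions)
    p = positions[triangles]
    face_n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    face_n /= np.maximum(np.linalg.norm(face_n, axis=1, keepdims=True), 1e-300)
    for corner in range(3):
        a = p[:, (corner + 1) % 3] - p[:, corner]
        b = p[:, (corner + 2) % 3] - p[:, corner]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(normals, triangles[:, corner], ang[:, None] * face_n)
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)
    return normals


def make_ellipsoid_mesh(
    semi_axes: tuple[float, float, float],
    target_nodes: int,
    seed: int = 0,
    label: str = "",
) -> TriMesh:
    """Closed triangulated ellipsoid surface with exactly ``target_nodes`` nodes.

    Nodes are a Fibonacci lattice on the unit sphere, rotated by a seeded
    random rotation (so two meshes at different seeds are not index-aligned),
    scaled onto the ellipsoid, and triangulated through the convex hull of
    the unit directions.  Normals are the analytic outward ellipsoid normals.

    Parameters
    ----------
    semi_axes : three positive lengths (cm)
    target_nodes : int >= 12
    seed : controls the lattice rotation; identical seeds give bit-identical
        meshes.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if semi_axes.shape != (3,) or np.any(semi_axes <= 0):
        raise ValueError("semi_axes must be three positive lengths")
    if target_nodes < 12:
        raise ValueError("target_nodes must be >= 12")
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    directions = _fibonacci_directions(target_nodes) @ rot.T
    positions = directions * semi_axes
    triangles = _triangulate_directions(directions)
    # outward normal of x^2/a^2 + y^2/b^2 + z^2/c^2 = 1 is grad/|grad|
    grad = positions / semi_axes**2
    normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    mesh = TriMesh(positions, triangles, normals, label=label or "ellipsoid")
    mesh.validate()
    return mesh


def _fit_quadric(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of x'Qx + g'x = 1 to points; returns (Q, g).

    Exact for points sampled on a (possibly rotated/offset) ellipsoid.
    """
    x, y, z = points.T
    design = np.column_stack(
        [x * x, y * y, z * z, x * y, x * z, y * z, x, y, z]
    )
    coef, *_ = np.linalg.lstsq(design, np.ones(len(points)), rcond=None)
    A, B, C, D, E, F, G, H, I = coef
    Q = np.array([[A, D / 2, E / 2], [D / 2, B, F / 2], [E / 2, F / 2, C]])
    g = np.array([G, H, I])
    return Q, g


def _principal_form(Q: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center, principal axes R (columns) and semi-axes of x'Qx + g'x = 1."""
    center = np.linalg.solve(Q, -0.5 * g)
    kappa = 1.0 + 0.25 * g @ np.linalg.solve(Q, g)
    eigvals, R = np.linalg.eigh(Q / kappa)
    if np.any(eigvals <= 0) or kappa <= 0:
        raise ValueError("input mesh is not ellipsoid-like (indefinite quadric)")
    return center, R, 1.0 / np.sqrt(eigvals)


def _smooth_sphere_field(directions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field on the sphere, max |f| = 1 (low-order harmonics)."""
    x, y, z = directions.T
    basis = np.column_stack(
        [x, y, z, x * y, x * z, y * z, x * x - y * y, 3 * z * z - 1.0]
    )
    f = basis @ rng.standard_normal(basis.shape[1])
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def remesh_perturb(
    mesh: TriMesh,
    target_nodes: int,
    perturb_scale: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> TriMesh:
    """Independent re-triangulation of a surface at a new resolution.

    Fits the smooth ellipsoid underlying ``mesh`` by least squares, samples a
    fresh Fibonacci lattice (seeded rotation, so the new node set is not
    index-aligned with the input), and optionally bends the radius by a
    smooth random field bounded by ``perturb_scale`` x mean semi-axis.  This
    realises the two-model protocol that avoids the inverse crime: the
    forward data and the inversion then never share a discretisation.
    """
    if not 0.0 <= perturb_scale <= 0.2:
        raise ValueError("perturb_scale must be in [0, 0.2]")
    if target_nodes < 12:
        raise ValueError("target_nodes must be >= 12")
    Qm, g = _fit_quadric(mesh.node_positions)
    center, R, semi = _principal_form(Qm, g)
    mean_semi_axis = float(np.mean(semi))
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    directions = _fibonacci_directions(target_nodes) @ rot.T
    # anisotropic scaling in the fitted principal frame: for an unrotated
    # ellipsoid and identical seed this reproduces make_ellipsoid_mesh exactly
    positions = center + (semi * (directions @ R)) @ R.T
    if perturb_scale > 0:
        bump = perturb_scale * mean_semi_axis * _smooth_sphere_field(directions, rng)
        radial = positions - center
        rad_len = np.linalg.norm(radial, axis=1)
        positions = center + radial * (1.0 + bump / rad_len)[:, None]
    triangles = _triangulate_directions(directions)
    if perturb_scale == 0:
        grad = (positions - center) @ Qm  # outward quadric gradient
        normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    else:
        normals = _angle_weighted_normals(positions, triangles)
    out = TriMesh(positions, triangles, normals, label=label or f"{mesh.label}-remesh")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def make_sensor_grid(
    rows: int,
    cols: int,
    spacing: float,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    plane_normal: tuple[float, float, float] = (0.0, 0.0, 1.0),
    label: str = "grid",
) -> SensorArray:
    """rows x cols planar lattice of detector positions.

    The default protocol uses a 9 x 9 grid with 3 cm spacing (M = 81).
    A non-unit ``plane_normal`` is accepted and normalized with a warning.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    normal = np.asarray(plane_normal, dtype=float)
    nrm = np.linalg.norm(normal)
    if nrm == 0:
        raise ValueError("plane_normal must be nonzero")
    if abs(nrm - 1.0) > 1e-9:
        warnings.warn("plane_normal was not unit length; normalizing")
    normal = normal / nrm
    u, v = _plane_basis(normal)
    r = (np.arange(rows) - (rows - 1) / 2.0) * spacing
    c = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    rr, cc = np.meshgrid(r, c, indexing="ij")
    positions = (
        np.asarray(center, dtype=float)
        + rr.reshape(-1, 1) * u
        + cc.reshape(-1, 1) * v
    )
    return SensorArray(positions, rows, cols, float(spacing), normal, label=label)


# ---------------------------------------------------------------------------
# correspondence and I/O
# ---------------------------------------------------------------------------


def nearest_node_map(source: TriMesh, target: TriMesh) -> NodeMap:
    """Euclidean-nearest target node per source node; ties -> lowest index."""
    if source.n_nodes == 0 or target.n_nodes == 0:
        raise ValueError("meshes must be non-empty")
    d = distance_matrix(source.node_positions, target.node_positions)
    idx = np.argmin(d, axis=1)  # argmin returns the first (lowest) index on ties
    return NodeMap(source.label, target.label, idx, d[np.arange(len(idx)), idx])


def write_ply(mesh: TriMesh, path) -> None:
    """Write an ASCII PLY with vertex positions, normals and triangle faces."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {mesh.label}\n")
        fh.write(f"element vertex {mesh.n_nodes}\n")
        for prop in ("x", "y", "z", "nx", "ny", "nz"):
            fh.write(f"property float {prop}\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, n in zip(mesh.node_positions, mesh.node_normals):
            fh.write(
                f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g} "
                f"{n[0]:.10g} {n[1]:.10g} {n[2]:.10g}\n"
            )
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


class PlyParseError(ValueError):
    """Malformed PLY input; message names the offending line."""


def read_ply(path) -> TriMesh:
    """Read an ASCII PLY triangle mesh.

    Vertex properties must include ``x y z``; ``nx ny nz`` are used when
    present, otherwise normals are recomputed from the triangulation.
    Non-triangular faces are rejected.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PlyParseError("line 1: expected 'ply' magic")
    n_vertex = n_face = None
    vertex_props: list[str] = []
    label = ""
    elements: list[str] = []
    i = 1
    while i < len(lines):
        tokens = lines[i].split()
        i += 1
        if not tokens:
            continue
        if tokens[0] == "format":
            if tokens[1] != "ascii":
                raise PlyParseError(f"line {i}: only ascii PLY supported")
        elif tokens[0] == "comment":
            label = label or " ".join(tokens[1:])
        elif tokens[0] == "element":
            elements.append(tokens[1])
            if tokens[1] == "vertex":
                n_vertex = int(tokens[2])
            elif tokens[1] == "face":
                n_face = int(tokens[2])
            else:
                raise PlyParseError(f"line {i}: unsupported element '{tokens[1]}'")
        elif tokens[0] == "property":
            if elements and elements[-1] == "vertex":
                vertex_props.append(tokens[-1])
        elif tokens[0] == "end_header":
            break
        elif tokens[0] == "ply":
            raise PlyParseError(f"line {i}: duplicate 'ply' magic")
    else:
        raise PlyParseError("missing end_header")
    if n_vertex is None or n_face is None:
        raise PlyParseError("header must declare vertex and face elements")
    for req in ("x", "y", "z"):
        if req not in vertex_props:
            raise PlyParseError(f"vertex element lacks property '{req}'")
    body_start = i
    if len(lines) < body_start + n_vertex + n_face:
        raise PlyParseError(
            f"line {len(lines)}: file truncated "
            f"(expected {n_vertex} vertices + {n_face} faces)"
        )
    cols = {name: k for k, name in enumerate(vertex_props)}
    verts = np.empty((n_vertex, 3))
    has_normals = all(p in cols for p in ("nx", "ny", "nz"))
    normals = np.empty((n_vertex, 3)) if has_normals else None
    for j in range(n_vertex):
        tokens = lines[body_start + j].split()
        if len(tokens) < len(vertex_props):
            raise PlyParseError(f"line {body_start + j + 1}: short vertex row")
        vals = [float(t) for t in tokens]
        verts[j] = [vals[cols["x"]], vals[cols["y"]], vals[cols["z"]]]
        if has_normals:
            normals[j] = [vals[cols["nx"]], vals[cols["ny"]], vals[cols["nz"]]]
    faces = np.empty((n_face, 3), dtype=int)
    for j in range(n_face):
        lineno = body_start + n_vertex + j + 1
        tokens = lines[body_start + n_vertex + j].split()
        if not tokens:
            raise PlyParseError(f"line {lineno}: empty face row")
        if int(tokens[0]) != 3:
            raise PlyParseError(
                f"line {lineno}: face with {tokens[0]} vertices; only triangles supported"
            )
        faces[j] = [int(t) for t in tokens[1:4]]
    if normals is None:
        normals = _angle_weighted_normals(verts, faces)
    else:
        nrm = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = normals / np.maximum(nrm, 1e-300)
    mesh = TriMesh(verts, faces, normals, label=label or "ply")
    mesh.validate()
    return mesh
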