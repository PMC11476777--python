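"""Triangulated cell-surface data structures and geometry.

The cell surface is a closed, oriented 2-manifold triangle mesh.  A patch of
faces is designated as the *bud*; the closed loop of edges separating bud from
mother faces is the *septin ring*.  Every elastic element carries its own rest
state (edge rest length ``L0``, interior-edge rest dihedral ``theta0``, face
rest area ``A0``) so that growth and remodeling can reassign rest quantities
locally.

Conventions
-----------
* The bud axis is +z; the "bottom of the mother cell" is the minimum-z vertex.
* Face winding is counter-clockwise seen from outside (outward normals).
* Edges are identified by their sorted vertex pair ``(i, j)`` with ``i < j``
  and enumerated in lexicographic order, which makes every random choice over
  edges reproducible.
* The dihedral angle of an interior edge is the signed angle between the unit
  normals of its two incident faces, measured about the shared edge; it is
  positive where the surface is convex (as on the initial sphere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MOTHER = 0
BUD = 1


def cross3(a: "np.ndarray", b: "np.ndarray") -> "np.ndarray":
    """Row-wise cross product for (N, 3) arrays (faster than np.cross)."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out

__all__ = [
    "SurfaceMesh",
    "GeometryCache",
    "ValidationReport",
    "build_icosphere",
    "init_bud_patch",
    "compute_geometry",
    "validate",
    "save_ply",
    "load_ply",
    "load_mesh_file",
]


class MeshError(ValueError):
    """Raised when a mesh operation violates a structural precondition."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class _Topology:
    """Combinatorial structure derived from the face array (cached)."""

    edges: np.ndarray  # (E, 2) int64, i < j, lexicographically ordered
    edge_index: dict  # (i, j) -> row in `edges`
    edge_faces: np.ndarray  # (E, 2): [face with directed i->j, face with j->i]
    interior_mask: np.ndarray  # (E,) bool: both incident faces present
    hinges: np.ndarray  # (Ei, 4): [i, j, opp_a, opp_b] per interior edge
    hinge_edge_rows: np.ndarray  # (Ei,) row of each hinge's edge in `edges`
    valence: np.ndarray  # (V,) vertex valence
    hinge_row_of_edge: np.ndarray = None  # (E,) hinge row per edge (-1: none)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


class SurfaceMesh:
    """Closed oriented triangulated surface with per-element rest state.

    Parameters
    ----------
    vertices : (V, 3) float array
        Node positions in dimensionless length units.
    faces : (F, 3) int array
        Oriented vertex triples (outward CCW winding).
    """

    def __init__(self, vertices, faces):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")
        self.face_region = np.full(len(self.faces), MOTHER, dtype=np.int8)
        self.face_A0 = np.zeros(len(self.faces))
        self.edge_L0: dict = {}  # (i, j) -> rest length
        self.edge_theta0: dict = {}  # (i, j) -> rest dihedral (interior edges)
        self.septin_edges: set = set()  # edge keys forming the septin ring
        self.bud_axis = np.array([0.0, 0.0, 1.0])
        # journal of topological events since creation, used to transfer
        # vertex fields across remodeling: ("split", new_vertex, i, j) or
        # ("flip", i, j, oa, ob)
        self.journal: list = []
        self._topology: _Topology | None = None
        self._rest_cache: tuple | None = None

    # -- topology ----------------------------------------------------------

    def invalidate(self) -> None:
        """Drop cached structure after a topological or rest-state edit."""
        self._topology = None
        self._rest_cache = None

    def rest_arrays(self) -> tuple:
        """Rest state compiled to arrays in topology order.

        Returns ``(L0 per edge row, septin mask per edge row, theta0 per
        hinge row)``; cached until :meth:`invalidate`.
        """
        if self._rest_cache is None:
            top = self.topology
            L0 = np.array([self.edge_L0[tuple(e)] for e in top.edges])
            septin = np.fromiter(
                (tuple(e) in self.septin_edges for e in top.edges),
                dtype=bool, count=len(top.edges),
            )
            theta0 = np.array(
                [self.edge_theta0[tuple(top.edges[r])] for r in top.hinge_edge_rows]
            )
            self._rest_cache = (L0, septin, theta0)
        return self._rest_cache

    @property
    def topology(self) -> _Topology:
        if self._topology is None:
            self._topology = self._build_topology()
        return self._topology

    def _build_topology(self) -> _Topology:
        F = self.faces
        nv = len(self.vertices)
        edge_index: dict = {}
        rows: list = []
        ef: list = []
        for f_idx in range(len(F)):
            a, b, c = F[f_idx]
            for u, v in ((a, b), (b, c), (c, a)):
                key = (u, v) if u < v else (v, u)
                r = edge_index.get(key)
                if r is None:
                    r = len(rows)
                    edge_index[key] = r
                    rows.append(key)
                    ef.append([-1, -1])
                slot = 0 if u < v else 1  # forward (i->j) vs backward
                if ef[r][slot] != -1:
                    raise MeshError(
                        f"edge {key} has duplicate directed occurrence; "
                        "mesh is non-manifold or inconsistently oriented"
                    )
                ef[r][slot] = f_idx
        # lexicographic edge order for reproducible enumeration
        order = sorted(range(len(rows)), key=lambda r: rows[r])
        edges = np.array([rows[r] for r in order], dtype=np.int64)
        edge_faces = np.array([ef[r] for r in order], dtype=np.int64)
        edge_index = {tuple(e): k for k, e in enumerate(edges)}
        interior = (edge_faces >= 0).all(axis=1)

        hinge_rows = np.nonzero(interior)[0]
        hinges = np.empty((len(hinge_rows), 4), dtype=np.int64)
        for k, r in enumerate(hinge_rows):
            i, j = edges[r]
            fa, fb = edge_faces[r]
            hinges[k] = (i, j, _third_vertex(F[fa], i, j), _third_vertex(F[fb], j, i))

        valence = np.zeros(nv, dtype=np.int64)
        np.add.at(valence, edges.ravel(), 1)
        hinge_of = np.full(len(edges), -1, dtype=np.int64)
        hinge_of[hinge_rows] = np.arange(len(hinge_rows))
        return _Topology(edges, edge_index, edge_faces, interior, hinges,
                         hinge_rows, valence, hinge_of)

    # -- convenience -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return self.topology.n_edges

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def bud_faces(self) -> np.ndarray:
        return np.nonzero(self.face_region == BUD)[0]

    def bud_vertices(self) -> np.ndarray:
        """Vertices incident to at least one bud face."""
        bf = self.bud_faces()
        return np.unique(self.faces[bf].ravel()) if len(bf) else np.array([], dtype=np.int64)

    def septin_ring_vertices(self) -> np.ndarray:
        if not self.septin_edges:
            return np.array([], dtype=np.int64)
        return np.unique(np.array(sorted(self.septin_edges), dtype=np.int64).ravel())

    def edge_key(self, i: int, j: int) -> tuple:
        return (i, j) if i < j else (j, i)

    def copy(self) -> "SurfaceMesh":
        m = SurfaceMesh(self.vertices.copy(), self.faces.copy())
        m.face_region = self.face_region.copy()
        m.face_A0 = self.face_A0.copy()
        m.edge_L0 = dict(self.edge_L0)
        m.edge_theta0 = dict(self.edge_theta0)
        m.septin_edges = set(self.septin_edges)
        m.bud_axis = self.bud_axis.copy()
        m.journal = list(self.journal)
        return m

    def set_rest_state_from_geometry(self) -> None:
        """Initialize L0, theta0, A0 from the current configuration."""
        geom = compute_geometry(self)
        top = self.topology
        self._rest_cache = None
        self.edge_L0 = {tuple(e): geom.edge_length[k] for k, e in enumerate(top.edges)}
        self.edge_theta0 = {
            tuple(top.edges[r]): geom.dihedral_angle[k]
            for k, r in enumerate(top.hinge_edge_rows)
        }
        self.face_A0 = geom.face_area.copy()


def _third_vertex(face, u, v):
    for w in face:
        if w != u and w != v:
            return w
    raise MeshError(f"degenerate face {face}")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class GeometryCache:
    """Instantaneous geometric quantities (current L, theta, A, normals)."""

    face_area: np.ndarray  # (F,)
    face_normal: np.ndarray  # (F, 3) outward unit normals
    face_normal_raw: np.ndarray  # (F, 3) cross products (norm = 2 A)
    edge_length: np.ndarray  # (E,) in topology edge order
    dihedral_angle: np.ndarray  # (Ei,) per interior edge (hinge order)
    vertex_dual_area: np.ndarray  # (V,) barycentric lumped areas
    total_area: float = field(init=False)

    def __post_init__(self):
        self.total_area = float(self.face_area.sum())


def signed_dihedrals(vertices: np.ndarray, hinges: np.ndarray) -> np.ndarray:
    """Signed dihedral angles for hinge rows ``[i, j, opp_a, opp_b]``.

    The angle is measured between the unit normals of face a = (i, j, opp_a)
    and face b = (j, i, opp_b) about the directed edge i->j; positive where
    the surface bends convexly (outward).
    """
    xi = vertices[hinges[:, 0]]
    xj = vertices[hinges[:, 1]]
    xa = vertices[hinges[:, 2]]
    xb = vertices[hinges[:, 3]]
    e = xj - xi
    na = cross3(e, xa - xi)
    nb = cross3(xb - xj, e)  # = (xi - xj) x (xb - xj) for face (j, i, ob)
    na_u = na / np.linalg.norm(na, axis=1, keepdims=True)
    nb_u = nb / np.linalg.norm(nb, axis=1, keepdims=True)
    e_u = e / np.linalg.norm(e, axis=1, keepdims=True)
    sin_t = np.einsum("ij,ij->i", cross3(na_u, nb_u), e_u)
    cos_t = np.einsum("ij,ij->i", na_u, nb_u)
    return np.arctan2(sin_t, cos_t)


def compute_geometry(mesh: SurfaceMesh) -> GeometryCache:
    """Compute areas, normals, edge lengths, dihedrals and lumped vertex areas."""
    V, F = mesh.vertices, mesh.faces
    top = mesh.topology
    raw = cross3(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    two_area = np.linalg.norm(raw, axis=1)
    if np.any(two_area <= 0.0) or not np.all(np.isfinite(two_area)):
        bad = int(np.argmin(two_area))
        raise MeshError(f"degenerate face {bad} with zero area: {F[bad]}")
    area = 0.5 * two_area
    normal = raw / two_area[:, None]
    edge_vec = V[top.edges[:, 1]] - V[top.edges[:, 0]]
    edge_length = np.linalg.norm(edge_vec, axis=1)
    dihedral = signed_dihedrals(V, top.hinges) if len(top.hinges) else np.zeros(0)
    dual = np.zeros(len(V))
    np.add.at(dual, F.ravel(), np.repeat(area / 3.0, 3))
    return GeometryCache(area, normal, raw, edge_length, dihedral, dual)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=np.float64,
)

_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def build_icosphere(subdivisions: int, radius: float) -> SurfaceMesh:
    """Geodesic sphere fixture: subdivided icosahedron projected to a sphere.

    The rest state (L0, theta0, A0) is initialized to the constructed
    geometry, so the fresh sphere is elastically stress free.
    """
    if subdivisions < 0:
        raise MeshError("subdivisions must be >= 0")
    if radius <= 0:
        raise MeshError("radius must be > 0")
    verts = [v / np.linalg.norm(v) for v in _ICO_VERTS]
    faces = [tuple(f) for f in _ICO_FACES]
    for _ in range(subdivisions):
        midpoint: dict = {}
        new_faces = []

        def mid(u, v):
            key = (u, v) if u < v else (v, u)
            k = midpoint.get(key)
            if k is None:
                m = verts[u] + verts[v]
                m = m / np.linalg.norm(m)
                verts.append(m)
                k = len(verts) - 1
                midpoint[key] = k
            return k

        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    mesh = SurfaceMesh(np.array(verts) * radius, np.array(faces, dtype=np.int64))
    # icosahedron winding above is outward; assert via signed volume
    if _enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
        mesh.invalidate()
    mesh.set_rest_state_from_geometry()
    return mesh


def _enclosed_volume(mesh: SurfaceMesh) -> float:
    V, F = mesh.vertices, mesh.faces
    return float(np.einsum("ij,ij->i", V[F[:, 0]], np.cross(V[F[:, 1]], V[F[:, 2]])).sum() / 6.0)


# ---------------------------------------------------------------------------
# Bud patch designation
# ---------------------------------------------------------------------------


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping `axis` (unit) onto +z."""
    a = np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(a @ z)
    s = np.linalg.norm(v)
    if s < 1e-14:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def init_bud_patch(mesh: SurfaceMesh, axis, cap_angle: float) -> SurfaceMesh:
    """Designate a geodesic cap about `axis` as the bud, bounded by the ring.

    The mesh is rotated so that `axis` becomes +z.  Faces whose centroid
    direction (from the enclosed centroid) lies within `cap_angle` of the
    axis are labeled bud; the closed loop of edges between bud and mother
    faces becomes the septin ring.
    """
    if cap_angle <= 0:
        raise MeshError("cap_angle must be > 0 (empty bud region)")
    R = _rotation_to_z(np.asarray(axis, dtype=np.float64))
    mesh.vertices = mesh.vertices @ R.T
    mesh.bud_axis = np.array([0.0, 0.0, 1.0])
    center = mesh.vertices.mean(axis=0)
    cent = mesh.vertices[mesh.faces].mean(axis=1) - center
    cent = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    in_cap = cent[:, 2] >= np.cos(cap_angle)
    if not in_cap.any():
        raise MeshError("cap_angle selects no faces")
    if in_cap.all():
        raise MeshError("cap_angle selects every face")
    mesh.face_region = np.where(in_cap, BUD, MOTHER).astype(np.int8)
    mesh.septin_edges = _region_boundary_edges(mesh)
    _check_ring_is_simple_loop(mesh)
    if len(_region_components(mesh, BUD)) != 1:
        raise MeshError("bud patch is not a single connected component")
    return mesh


def _region_boundary_edges(mesh: SurfaceMesh) -> set:
    top = mesh.topology
    out = set()
    for r in np.nonzero(top.interior_mask)[0]:
        fa, fb = top.edge_faces[r]
        if mesh.face_region[fa] != mesh.face_region[fb]:
            out.add(tuple(top.edges[r]))
    return out


def _check_ring_is_simple_loop(mesh: SurfaceMesh) -> None:
    ring = mesh.septin_edges
    if not ring:
        raise MeshError("septin ring is empty")
    deg: dict = {}
    for i, j in ring:
        deg[i] = deg.get(i, 0) + 1
        deg[j] = deg.get(j, 0) + 1
    if any(d != 2 for d in deg.values()):
        raise MeshError("septin ring is not a simple closed loop (vertex degree != 2)")
    # connectivity: walk the loop
    adj: dict = {}
    for i, j in ring:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    start = next(iter(adj))
    seen = {start}
    prev, cur = None, start
    while True:
        nxt = [w for w in adj[cur] if w != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        seen.add(cur)
    if len(seen) != len(adj):
        raise MeshError("septin ring has more than one loop")


def _region_components(mesh: SurfaceMesh, region: int) -> list:
    """Connected components (via shared edges) of faces with the given label."""
    top = mesh.topology
    sel = np.nonzero(mesh.face_region == region)[0]
    sel_set = set(int(f) for f in sel)
    adj: dict = {f: [] for f in sel_set}
    for r in np.nonzero(top.interior_mask)[0]:
        fa, fb = (int(x) for x in top.edge_faces[r])
        if fa in sel_set and fb in sel_set:
            adj[fa].append(fb)
            adj[fb].append(fa)
    comps = []
    todo = set(sel_set)
    while todo:
        stack = [todo.pop()]
        comp = {stack[0]}
        while stack:
            f = stack.pop()
            for g in adj[f]:
                if g in todo:
                    todo.discard(g)
                    comp.add(g)
                    stack.append(g)
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    passed: bool
    euler_characteristic: int
    n_boundary_edges: int
    orientation_consistent: bool
    ring_ok: bool
    min_face_quality: float  # min inradius/circumradius ratio proxy (2r/R)
    messages: list


def validate(mesh: SurfaceMesh) -> ValidationReport:
    """Structural diagnostics: manifoldness, Euler characteristic, orientation,
    septin-ring integrity and worst face quality."""
    messages = []
    ok = True
    try:
        top = mesh.topology
        boundary = int((~top.interior_mask).sum())
        orient = True
    except MeshError as exc:
        return ValidationReport(False, 0, -1, False, False, 0.0, [str(exc)])
    if boundary:
        ok = False
        messages.append(f"{boundary} boundary edges (surface not closed)")
    chi = mesh.euler_characteristic()
    if chi != 2:
        ok = False
        messages.append(f"Euler characteristic {chi} != 2")
    ring_ok = True
    if mesh.septin_edges:
        try:
            _check_ring_is_simple_loop(mesh)
            if _region_boundary_edges(mesh) != mesh.septin_edges:
                raise MeshError("septin ring does not coincide with region boundary")
        except MeshError as exc:
            ring_ok = ok = False
            messages.append(str(exc))
    try:
        geom = compute_geometry(mesh)
        quality = _face_quality(mesh)
        # outward normals: area-weighted normal sum vanishes on a closed
        # surface; sign checked against the enclosed volume
        if _enclosed_volume(mesh) <= 0:
            ok = False
            orient = False
            messages.append("negative enclosed volume: normals point inward")
        resid = np.linalg.norm((geom.face_normal * geom.face_area[:, None]).sum(axis=0))
        if boundary == 0 and resid > 1e-9 * geom.total_area:
            ok = False
            messages.append(f"closed-surface normal residual {resid:.3e}")
    except MeshError as exc:
        ok = False
        quality = 0.0
        messages.append(str(exc))
    return ValidationReport(ok, chi, boundary, orient, ring_ok, quality, messages)


def _face_quality(mesh: SurfaceMesh) -> float:
    V, F = mesh.vertices, mesh.faces
    a = np.linalg.norm(V[F[:, 1]] - V[F[:, 0]], axis=1)
    b = np.linalg.norm(V[F[:, 2]] - V[F[:, 1]], axis=1)
    c = np.linalg.norm(V[F[:, 0]] - V[F[:, 2]], axis=1)
    s = (a + b + c) / 2
    area2 = np.maximum(s * (s - a) * (s - b) * (s - c), 0.0)
    area = np.sqrt(area2)
    # quality = 4*sqrt(3)*A / (a^2+b^2+c^2): 1 for equilateral
    return float(np.min(4 * np.sqrt(3) * area / (a**2 + b**2 + c**2)))


# ---------------------------------------------------------------------------
# Mesh file I/O (full-precision ASCII)
# ---------------------------------------------------------------------------


def save_ply(mesh: SurfaceMesh, path, vertex_fields: dict | None = None) -> None:
    """Write ASCII PLY with coordinates at full precision (round-trip exact)."""
    vertex_fields = vertex_fields or {}
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment budmorph surface snapshot\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for name in vertex_fields:
            fh.write(f"property double {name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property int region\n")
        fh.write("end_header\n")
        cols = [mesh.vertices] + [np.asarray(v).reshape(-1, 1) for v in vertex_fields.values()]
        data = np.hstack(cols)
        for row in data:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")
        for f, r in zip(mesh.faces, mesh.face_region):
            fh.write(f"3 {f[0]} {f[1]} {f[2]} {r}\n")


def load_ply(path):
    """Read the ASCII PLY written by :func:`save_ply`.

    Returns ``(mesh, vertex_fields)``; rest state is initialized from the
    loaded geometry.
    """
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise MeshError(f"{path}: not a PLY file")
        nv = nf = 0
        names: list = []
        props_section = None
        for line in fh:
            line = line.strip()
            if line.startswith("element vertex"):
                nv = int(line.split()[-1])
                props_section = "vertex"
            elif line.startswith("element face"):
                nf = int(line.split()[-1])
                props_section = "face"
            elif line.startswith("property double") and props_section == "vertex":
                names.append(line.split()[-1])
            elif line == "end_header":
                break
        rows = [fh.readline().split() for _ in range(nv)]
        data = np.array(rows, dtype=np.float64)
        faces = np.empty((nf, 3), dtype=np.int64)
        region = np.zeros(nf, dtype=np.int8)
        for k in range(nf):
            parts = fh.readline().split()
            if parts[0] != "3":
                raise MeshError("only triangle faces supported")
            faces[k] = [int(x) for x in parts[1:4]]
            if len(parts) > 4:
                region[k] = int(parts[4])
    mesh = SurfaceMesh(data[:, :3], faces)
    mesh.face_region = region
    if (region == BUD).any() and not (region == BUD).all():
        mesh.septin_edges = _region_boundary_edges(mesh)
    mesh.set_rest_state_from_geometry()
    fields = {name: data[:, 3 + k] for k, name in enumerate(names[3:], start=0)}
    return mesh, fields


def load_mesh_file(path) -> SurfaceMesh:
    """Load a custom initial cell surface from PLY or OFF (via trimesh)."""
    import trimesh

    tm = trimesh.load_mesh(path, process=False)
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if _enclosed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
        mesh.invalidate()
    rep = validate(mesh)
    if rep.n_boundary_edges:
        raise MeshError(f"{path}: surface is not closed ({rep.n_boundary_edges} boundary edges)")
    mesh.set_rest_state_from_geometry()
    return mesh
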