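"""Topological growth and stochastic edge-swap relaxation of the surface.

Growth inserts new surface material by *triangle-pair splitting*: the shared
edge of two adjacent triangles gains a midpoint vertex, turning the
two-triangles/four-nodes configuration into four triangles and five nodes
(V+1, E+3, F+2; Euler characteristic preserved).  New elements receive rest
quantities equal to their current geometry scaled by ``rest_growth_factor``
(> 1), so every insertion raises the equilibrium surface area and turgor
expands the bud.

The cell wall rearranges by Metropolis *edge swapping*: the central edge of
a triangle pair flips to connect the two previously unconnected opposite
vertices, accepted with probability ``min(1, exp(-dE_total/kT))``.  Swaps
conserve V, E, F; ring edges are never touched; flips that would duplicate
an edge or drop a vertex below valence 3 are rejected as illegal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import acos, atan2, cos, exp, pi, sqrt

import numpy as np

from . import mechanics as mech
from .mesh import BUD, MeshError, SurfaceMesh, signed_dihedrals
from .schedules import Schedule

__all__ = [
    "GrowthPolicy",
    "split_pair",
    "eligible_faces",
    "growth_event",
    "edge_swap_step",
    "run_swaps",
    "GrowthRecord",
    "SwapStats",
]


@dataclass(frozen=True)
class GrowthPolicy:
    """Growth and remodeling controls.

    threshold_fraction : insertion is gated to bud faces whose mean vertex
        concentration reaches this fraction of the bud maximum (default 0.8).
    insertions_per_event : triangle-pair splits per growth event.
    rest_growth_factor : multiplier > 1 applied to the rest quantities of
        newly created elements; sets the rest-area increment per event.
    es_schedule : frame -> number of edge-swap attempts following each
        material insertion of that frame (the per-insertion relaxation
        dose).
    kT : Metropolis temperature for swap acceptance.
    swap_domain : "all" (whole surface) or "bud".
    flip_rest_mode : "material" (rest state is a material property carried
        through flips; swapping relaxes toward the material-preferred shape)
        or "plastic" (flips reset the central rest angle to the current
        geometry, so each accepted flip locks deformation in).
    split_normal_offset : optional outward offset (fraction of local edge
        length) of the inserted midpoint, to break coplanarity.
    """

    threshold_fraction: float = 0.8
    insertions_per_event: int = 6
    rest_growth_factor: float = 1.15
    es_schedule: Schedule = field(default_factory=lambda: Schedule.constant(25))
    kT: float = 0.2
    swap_domain: str = "bud"
    flip_rest_mode: str = "material"
    split_normal_offset: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.insertions_per_event < 1:
            raise ValueError("insertions_per_event must be >= 1")
        if self.rest_growth_factor <= 1.0:
            raise ValueError("rest_growth_factor must be > 1")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")
        if self.swap_domain not in ("all", "bud"):
            raise ValueError("swap_domain must be 'all' or 'bud'")
        if self.flip_rest_mode not in ("material", "plastic"):
            raise ValueError("flip_rest_mode must be 'material' or 'plastic'")


# ---------------------------------------------------------------------------
# Triangle-pair splitting (material insertion)
# ---------------------------------------------------------------------------


def split_pair(mesh: SurfaceMesh, edge, rest_growth_factor: float = 1.4,
               normal_offset: float = 0.0) -> SurfaceMesh:
    """Split the two triangles sharing ``edge`` into four (in place).

    A new vertex is placed at the edge midpoint (optionally offset outward
    along the mean face normal by ``normal_offset`` times the edge length).
    New edges/faces take rest quantities from their current geometry times
    ``rest_growth_factor``; new hinge rest dihedrals equal their current
    angles; region and ring labels are inherited.
    """
    key = mesh.edge_key(*edge)
    if key in mesh.septin_edges:
        raise MeshError(f"cannot split septin-ring edge {key}")
    top = mesh.topology
    row = top.edge_index.get(key)
    if row is None:
        raise MeshError(f"no such edge {key}")
    fa, fb = top.edge_faces[row]
    if fa < 0 or fb < 0:
        raise MeshError(f"edge {key} is not interior")
    i, j = key
    oa = _third(mesh.faces[fa], i, j)
    ob = _third(mesh.faces[fb], i, j)
    if np.linalg.norm(mesh.vertices[j] - mesh.vertices[i]) < 1e-8:
        raise MeshError(f"edge {key} is degenerate (zero length)")

    xm = 0.5 * (mesh.vertices[i] + mesh.vertices[j])
    if normal_offset:
        raw_a = np.cross(mesh.vertices[j] - mesh.vertices[i],
                         mesh.vertices[oa] - mesh.vertices[i])
        raw_b = np.cross(mesh.vertices[i] - mesh.vertices[j],
                         mesh.vertices[ob] - mesh.vertices[j])
        # fb = (j, i, ob): its outward normal is (xi-xj) x (xob-xj)
        n = raw_a / np.linalg.norm(raw_a) + raw_b / np.linalg.norm(raw_b)
        n /= np.linalg.norm(n)
        xm = xm + normal_offset * np.linalg.norm(mesh.vertices[j] - mesh.vertices[i]) * n
    m = mesh.n_vertices
    mesh.vertices = np.vstack([mesh.vertices, xm[None, :]])

    region_a = mesh.face_region[fa]
    region_b = mesh.face_region[fb]
    # orientation-preserving replacement: fa=(..i,j..) -> (i,m,oa)+(m,j,oa),
    # fb -> (j,m,ob)+(m,i,ob)
    new_faces = np.array([[m, j, oa], [m, i, ob]], dtype=np.int64)
    mesh.faces[fa] = (i, m, oa)
    mesh.faces[fb] = (j, m, ob)
    mesh.faces = np.vstack([mesh.faces, new_faces])
    mesh.face_region = np.concatenate([mesh.face_region, [region_a, region_b]]).astype(np.int8)

    g = rest_growth_factor
    quad = np.array([mesh.faces[fa], mesh.faces[fb], new_faces[0], new_faces[1]])
    areas = _tri_areas(mesh.vertices, quad)
    if np.any(areas <= 0) or \
            min(_min_angle(mesh.vertices, f) for f in quad) < 0.02:
        # roll back the vertex/face insertion and refuse
        mesh.vertices = mesh.vertices[:-1]
        mesh.faces[fa] = (i, j, oa)
        mesh.faces[fb] = (j, i, ob)
        mesh.faces = mesh.faces[:-2]
        mesh.face_region = mesh.face_region[:-2]
        mesh.invalidate()
        raise MeshError(f"split of edge {key} would create a degenerate face")
    # material insertion must never shrink the local rest area: if the pair
    # is currently compressed (area below its rest), grow from the rest
    # value, otherwise from the current (strained) area
    rest_parent = mesh.face_A0[fa] + mesh.face_A0[fb]
    base = max(float(areas.sum()), rest_parent)
    assign = g * base * areas / areas.sum()
    mesh.face_A0 = np.concatenate([mesh.face_A0, np.zeros(2)])
    mesh.face_A0[[fa, fb, mesh.n_faces - 2, mesh.n_faces - 1]] = assign

    del mesh.edge_L0[key]
    had_theta = mesh.edge_theta0.pop(key, None)
    for u in (i, j, oa, ob):
        k2 = mesh.edge_key(u, m)
        mesh.edge_L0[k2] = float(np.linalg.norm(mesh.vertices[u] - mesh.vertices[m])) * g
    mesh.journal.append(("split", m, i, j))
    mesh.invalidate()
    # rest dihedrals of the four new hinges = current angles
    top = mesh.topology
    hinge_of = {tuple(top.edges[r]): k for k, r in enumerate(top.hinge_edge_rows)}
    theta = signed_dihedrals(mesh.vertices, top.hinges)
    for u in (i, j, oa, ob):
        k2 = mesh.edge_key(u, m)
        hr = hinge_of.get(k2)
        if hr is None:
            raise MeshError(f"split bookkeeping failed for edge {k2}")
        mesh.edge_theta0[k2] = float(theta[hr])
    if had_theta is None:
        raise MeshError(f"split edge {key} had no rest dihedral (boundary?)")
    mesh._rest_cache = None
    return mesh


def _third(face, i, j):
    for w in face:
        if w != i and w != j:
            return int(w)
    raise MeshError(f"degenerate face {face}")


def _tri_areas(V, F):
    raw = np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    return 0.5 * np.linalg.norm(raw, axis=1)


def _min_angle(V, face) -> float:
    x = V[np.asarray(face)]
    angles = []
    for k in range(3):
        e1 = x[(k + 1) % 3] - x[k]
        e2 = x[(k + 2) % 3] - x[k]
        c = float(np.dot(e1, e2) / (np.linalg.norm(e1) * np.linalg.norm(e2)))
        angles.append(np.arccos(np.clip(c, -1.0, 1.0)))
    return min(angles)


# ---------------------------------------------------------------------------
# Chemically gated growth
# ---------------------------------------------------------------------------


def eligible_faces(mesh: SurfaceMesh, a: np.ndarray,
                   threshold_fraction: float = 0.8) -> np.ndarray:
    """Bud faces whose mean vertex concentration reaches the threshold.

    The threshold is ``threshold_fraction * Conc_max`` with ``Conc_max`` the
    maximum vertex concentration on the bud.  Mother faces are never
    eligible; a non-positive field yields an empty set.
    """
    a = np.asarray(a, dtype=np.float64)
    bud = mesh.bud_faces()
    if len(bud) == 0:
        raise MeshError("mesh has no bud faces")
    bud_verts = mesh.bud_vertices()
    conc_max = float(a[bud_verts].max())
    if conc_max <= 0.0:
        return np.array([], dtype=np.int64)
    face_mean = a[mesh.faces[bud]].mean(axis=1)
    return bud[face_mean >= threshold_fraction * conc_max]


@dataclass
class GrowthRecord:
    requested: int
    performed: int
    new_vertices: list
    shortfall: int


def growth_event(mesh: SurfaceMesh, region_faces: np.ndarray, policy: GrowthPolicy,
                 rng: np.random.Generator) -> GrowthRecord:
    """Insert material: split ``insertions_per_event`` random interior edges
    of the region (both incident faces inside, ring excluded).  If the region
    offers fewer candidates, split as many as available."""
    region_faces = np.asarray(region_faces)
    if len(region_faces) == 0:
        raise MeshError("growth region is empty")
    performed = 0
    new_vertices: list = []
    for _ in range(policy.insertions_per_event):
        region_set = set(int(f) for f in region_faces)
        cands = _region_interior_edges(mesh, region_set)
        if not cands:
            # a region too small to own an interior edge (e.g. a single
            # face) still receives material: split on its boundary within
            # the same compartment
            cands = _region_incident_edges(mesh, region_set)
        ok = False
        while cands:
            key = cands.pop(int(rng.integers(len(cands))))
            try:
                split_pair(mesh, key, policy.rest_growth_factor,
                           policy.split_normal_offset)
            except MeshError:
                continue  # degenerate candidate; draw another
            ok = True
            break
        if not ok:
            break
        new_vertices.append(mesh.n_vertices - 1)
        performed += 1
        # newly created faces belong to the region (labels inherited); add them
        region_faces = np.concatenate([region_faces, [mesh.n_faces - 2, mesh.n_faces - 1]])
    return GrowthRecord(policy.insertions_per_event, performed, new_vertices,
                        policy.insertions_per_event - performed)


def _region_incident_edges(mesh: SurfaceMesh, region: set) -> list:
    """Non-ring edges with at least one incident face in the region, the
    other in the same compartment (mother/bud)."""
    top = mesh.topology
    reg = mesh.face_region
    out = []
    for r in range(top.n_edges):
        fa, fb = top.edge_faces[r]
        if fa < 0 or fb < 0 or reg[fa] != reg[fb]:
            continue
        if int(fa) in region or int(fb) in region:
            key = tuple(top.edges[r])
            if key not in mesh.septin_edges:
                out.append(key)
    return out


def _region_interior_edges(mesh: SurfaceMesh, region: set) -> list:
    top = mesh.topology
    out = []
    for r in range(top.n_edges):
        fa, fb = top.edge_faces[r]
        if fa < 0 or fb < 0:
            continue
        if int(fa) in region and int(fb) in region:
            key = tuple(top.edges[r])
            if key not in mesh.septin_edges:
                out.append(key)
    return out


# ---------------------------------------------------------------------------
# Metropolis edge swapping
# ---------------------------------------------------------------------------


@dataclass
class SwapStats:
    attempts: int = 0
    accepted: int = 0
    illegal: int = 0

    def merge(self, other: "SwapStats") -> None:
        self.attempts += other.attempts
        self.accepted += other.accepted
        self.illegal += other.illegal


def _flip_context(mesh: SurfaceMesh, key):
    """Collect the local stencil of a prospective flip, or None if illegal."""
    top = mesh.topology
    row = top.edge_index.get(key)
    if row is None:
        return None
    if key in mesh.septin_edges:
        return None
    fa, fb = top.edge_faces[row]
    if fa < 0 or fb < 0:
        return None
    i, j = key
    oa = _third(mesh.faces[fa], i, j)
    ob = _third(mesh.faces[fb], i, j)
    if oa == ob:
        return None
    new_key = mesh.edge_key(oa, ob)
    if new_key in mesh.edge_L0:
        return None  # flip would duplicate an existing edge
    if top.valence[i] <= 3 or top.valence[j] <= 3:
        return None  # endpoint would drop below valence 3
    return row, fa, fb, i, j, oa, ob, new_key


def _hinge_rows_for(mesh: SurfaceMesh, keys):
    top = mesh.topology
    rows = []
    for k in keys:
        r = top.edge_index[k]
        fa, fb = top.edge_faces[r]
        i, j = k
        rows.append([i, j, _third(mesh.faces[fa], i, j), _third(mesh.faces[fb], i, j)])
    return np.array(rows, dtype=np.int64)


def _flip_delta_energy(mesh: SurfaceMesh, ctx, params: mech.MechParams,
                       rest_mode: str = "material"):
    """Local change in E_total caused by the flip (positions unchanged).

    Affected terms: stretch of the central edge, area of the two faces,
    bending of the central and four boundary hinges, and the Morse pair
    energies of the (dis)connected vertex pairs.  Returns (dE, apply_data).

    ``rest_mode`` sets how the flipped elements' rest state is reassigned:

    * ``"material"`` (default): the new central edge inherits the mean rest
      length *and* mean rest dihedral of the four boundary edges, and the
      conserved rest area is split evenly between the two new faces.  Rest
      state stays a property of the material, so swapping relaxes the
      surface toward its material-preferred shape.
    * ``"plastic"``: the new central edge's rest dihedral is reset to its
      current angle and rest area follows the current face areas.  Each
      accepted flip then erases shape memory (plastic creep).
    """
    row, fa, fb, i, j, oa, ob, new_key = ctx
    V = mesh.vertices
    reg = mesh.face_region
    both_bud = reg[fa] == BUD and reg[fb] == BUD
    ks = params.ks_bud if both_bud else params.ks_mother
    kb_c = params.kb_bud if both_bud else params.kb_mother
    pi_, pj, pa, pb = (tuple(map(float, V[v])) for v in (i, j, oa, ob))

    # --- stretch of central edge, before and after
    L_ij = _dist(pi_, pj)
    L_ab = _dist(pa, pb)
    key_c = (i, j) if i < j else (j, i)
    L0_ij = mesh.edge_L0[key_c]
    bkeys = [mesh.edge_key(i, oa), mesh.edge_key(j, oa),
             mesh.edge_key(i, ob), mesh.edge_key(j, ob)]
    L0_new = 0.25 * (mesh.edge_L0[bkeys[0]] + mesh.edge_L0[bkeys[1]]
                     + mesh.edge_L0[bkeys[2]] + mesh.edge_L0[bkeys[3]])
    dE = 0.5 * ks * ((L_ab - L0_new) ** 2 - (L_ij - L0_ij) ** 2)

    # --- face areas; before (i,j,oa)+(j,i,ob), after (i,ob,oa)+(j,oa,ob)
    A1b = _tri_area3(pi_, pj, pa)
    A2b = _tri_area3(pj, pi_, pb)
    A1a = _tri_area3(pi_, pb, pa)
    A2a = _tri_area3(pj, pa, pb)
    if A1a <= 1e-14 or A2a <= 1e-14:
        return None, None
    if _min_angle3(pi_, pb, pa) < 0.1 or _min_angle3(pj, pa, pb) < 0.1:
        return None, None  # flip would create a needle/cap triangle
    A0_1, A0_2 = float(mesh.face_A0[fa]), float(mesh.face_A0[fb])
    S0 = A0_1 + A0_2
    if rest_mode == "material":
        A0a_1 = A0a_2 = 0.5 * S0
    else:
        A0a_1 = S0 * A1a / (A1a + A2a)
        A0a_2 = S0 - A0a_1
    ka = params.ka
    dE += ka / (2 * A0a_1) * (A1a - A0a_1) ** 2 \
        + ka / (2 * A0a_2) * (A2a - A0a_2) ** 2 \
        - ka / (2 * A0_1) * (A1b - A0_1) ** 2 \
        - ka / (2 * A0_2) * (A2b - A0_2) ** 2

    # --- bending: boundary hinges keep theta0 but their inner opposite
    # vertex moves; the central hinge is replaced
    hinges_before = _hinge_rows_for(mesh, [key_c] + bkeys)
    th0_b = [mesh.edge_theta0[k] for k in bkeys]
    kb_b = _boundary_kbs(mesh, bkeys, params)
    th_c = _dihedral4(V, hinges_before[0])
    e_bend_before = kb_c * (1 - cos(th_c - mesh.edge_theta0[key_c]))
    hinges_after = [list(h) for h in hinges_before]
    for r_idx, k in enumerate(bkeys, start=1):
        h = hinges_after[r_idx]
        for slot in (2, 3):
            if h[slot] == j and k in (bkeys[0], bkeys[2]):
                h[slot] = ob if k == bkeys[0] else oa
            elif h[slot] == i and k in (bkeys[1], bkeys[3]):
                h[slot] = ob if k == bkeys[1] else oa
    e_bend_after = 0.0
    for r_idx in range(4):
        hb = hinges_before[r_idx + 1]
        ha = hinges_after[r_idx + 1]
        thb = _dihedral4(V, hb)
        tha = _dihedral4(V, ha)
        e_bend_before += kb_b[r_idx] * (1 - cos(thb - th0_b[r_idx]))
        e_bend_after += kb_b[r_idx] * (1 - cos(tha - th0_b[r_idx]))
    # central hinge after: face (j, oa, ob) holds oa->ob, (i, ob, oa) ob->oa
    central_after = [oa, ob, j, i] if oa < ob else [ob, oa, i, j]
    th_c_after = _dihedral4(V, central_after)
    if rest_mode == "material":
        th0_c_new = 0.25 * (th0_b[0] + th0_b[1] + th0_b[2] + th0_b[3])
    else:
        th0_c_new = th_c_after  # reset: central hinge carries no energy
    e_bend_after += kb_c * (1 - cos(th_c_after - th0_c_new))
    dE += e_bend_after - e_bend_before

    # --- Morse pairs: (oa, ob) stops being a Morse pair, (i, j) becomes one
    if params.Dm > 0:
        dE += _morse_scalar(L_ij, params) - _morse_scalar(L_ab, params)

    new_fa = np.array([[i, ob, oa], [j, oa, ob]], dtype=np.int64)
    apply_data = (new_fa, (A0a_1, A0a_2), L0_new, th0_c_new, new_key, key_c,
                  fa, fb, bkeys,
                  np.array(hinges_after[1:], dtype=np.int64),
                  np.array(central_after, dtype=np.int64))
    return float(dE), apply_data


def _dist(p, q):
    return sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2)


def _tri_area3(p, q, r):
    ux, uy, uz = q[0] - p[0], q[1] - p[1], q[2] - p[2]
    vx, vy, vz = r[0] - p[0], r[1] - p[1], r[2] - p[2]
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    return 0.5 * sqrt(cx * cx + cy * cy + cz * cz)


def _min_angle3(p, q, r):
    a = _dist(q, r)
    b = _dist(p, r)
    c = _dist(p, q)
    out = pi
    for opp, e1, e2 in ((a, b, c), (b, a, c), (c, a, b)):
        x = (e1 * e1 + e2 * e2 - opp * opp) / (2 * e1 * e2)
        out = min(out, acos(max(-1.0, min(1.0, x))))
    return out


def _dihedral4(V, hinge):
    """Signed dihedral of hinge [i, j, opp_a, opp_b] (scalar math)."""
    hi, hj, ha, hb = hinge
    xi = (float(V[hi, 0]), float(V[hi, 1]), float(V[hi, 2]))
    xj = (float(V[hj, 0]), float(V[hj, 1]), float(V[hj, 2]))
    xa = (float(V[ha, 0]), float(V[ha, 1]), float(V[ha, 2]))
    xb = (float(V[hb, 0]), float(V[hb, 1]), float(V[hb, 2]))
    ex, ey, ez = xj[0] - xi[0], xj[1] - xi[1], xj[2] - xi[2]
    ax, ay, az = xa[0] - xi[0], xa[1] - xi[1], xa[2] - xi[2]
    bx, by, bz = xb[0] - xj[0], xb[1] - xj[1], xb[2] - xj[2]
    nax = ey * az - ez * ay
    nay = ez * ax - ex * az
    naz = ex * ay - ey * ax
    nbx = by * ez - bz * ey
    nby = bz * ex - bx * ez
    nbz = bx * ey - by * ex
    cxx = nay * nbz - naz * nby
    cxy = naz * nbx - nax * nbz
    cxz = nax * nby - nay * nbx
    elen = sqrt(ex * ex + ey * ey + ez * ez)
    sin_t = (cxx * ex + cxy * ey + cxz * ez) / elen
    cos_t = nax * nbx + nay * nby + naz * nbz
    return atan2(sin_t, cos_t)


def _morse_scalar(L, params):
    if L > params.Lm:
        return 0.0
    return params.Dm * (1.0 - exp(-params.am * (L - params.Lm))) ** 2


def _boundary_kbs(mesh, bkeys, params):
    top = mesh.topology
    reg = mesh.face_region
    out = []
    for k in bkeys:
        fa, fb = top.edge_faces[top.edge_index[k]]
        out.append(params.kb_bud if reg[fa] == BUD and reg[fb] == BUD
                   else params.kb_mother)
    return np.array(out)


def _apply_flip(mesh: SurfaceMesh, apply_data) -> None:
    (new_fa, A0_after, L0_new, th0_c_new, new_key, old_key, fa, fb,
     bkeys, bhinges_after, central_after) = apply_data
    mesh.faces[fa] = new_fa[0]
    mesh.faces[fb] = new_fa[1]
    mesh.face_A0[fa], mesh.face_A0[fb] = A0_after
    del mesh.edge_L0[old_key]
    del mesh.edge_theta0[old_key]
    mesh.edge_L0[new_key] = L0_new
    mesh.edge_theta0[new_key] = th0_c_new
    mesh.journal.append(("flip", *old_key, *new_key))
    top = mesh._topology
    if top is None:
        mesh._rest_cache = None
        return
    # surgical update: a flip replaces one interior edge and rewires the
    # five local hinges; face indices, edge count and boundary edge rows
    # are all unchanged
    row = top.edge_index.pop(old_key)
    top.edge_index[new_key] = row
    top.edges[row] = new_key
    a, b = new_key
    # face (j, oa, ob) holds oa->ob; face (i, ob, oa) holds ob->oa
    oa = int(new_fa[1][1])
    top.edge_faces[row] = (fb, fa) if a == oa else (fa, fb)
    hr = top.hinge_row_of_edge[row]
    top.hinges[hr] = central_after
    for k, hrow in zip(bkeys, bhinges_after):
        rk = top.edge_index[k]
        top.hinges[top.hinge_row_of_edge[rk]] = hrow
        # two of the boundary edges migrate between the two rewired faces
        inner = fa if set(k) <= set(int(v) for v in mesh.faces[fa]) else fb
        for slot in (0, 1):
            if top.edge_faces[rk, slot] in (fa, fb):
                top.edge_faces[rk, slot] = inner
    i, j = old_key
    top.valence[i] -= 1
    top.valence[j] -= 1
    top.valence[a] += 1
    top.valence[b] += 1
    if mesh._rest_cache is not None:
        L0_arr, septin, theta0_arr = mesh._rest_cache
        L0_arr[row] = L0_new
        theta0_arr[hr] = th0_c_new


def edge_swap_step(mesh: SurfaceMesh, params: mech.MechParams, kT: float,
                   rng: np.random.Generator, edge=None,
                   swap_domain: str = "all",
                   rest_mode: str = "material") -> SwapStats:
    """One Metropolis flip attempt (in place).

    If ``edge`` is None a candidate is drawn uniformly from the domain
    ("all" edges or bud-interior edges).  Illegal flips (ring edge, duplicate
    edge, valence < 3, degenerate result) are rejected and counted.
    """
    stats = SwapStats(attempts=1)
    if edge is None:
        if swap_domain == "bud":
            cands = _region_interior_edges(
                mesh, set(int(f) for f in mesh.bud_faces()))
            if not cands:
                stats.illegal = 1
                return stats
            key = cands[int(rng.integers(len(cands)))]
        else:
            top = mesh.topology
            key = tuple(top.edges[int(rng.integers(top.n_edges))])
    else:
        key = mesh.edge_key(*edge)
    ctx = _flip_context(mesh, key)
    if ctx is None:
        stats.illegal = 1
        return stats
    dE, apply_data = _flip_delta_energy(mesh, ctx, params, rest_mode)
    if dE is None:
        stats.illegal = 1
        return stats
    if metropolis_accept(dE, kT, rng):
        _apply_flip(mesh, apply_data)
        stats.accepted = 1
    return stats


def metropolis_accept(dE: float, kT: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/kT))."""
    return dE <= 0 or rng.random() < np.exp(-dE / kT)


def run_swaps(mesh: SurfaceMesh, n_steps: int, params: mech.MechParams, kT: float,
              rng: np.random.Generator, swap_domain: str = "all",
              rest_mode: str = "material") -> SwapStats:
    """``n_steps`` Metropolis flip attempts at uniformly random edges.

    The candidate pool is built once and maintained across accepted flips
    (a flip replaces exactly one same-compartment interior edge by another).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    stats = SwapStats()
    if n_steps == 0:
        return stats
    if swap_domain == "bud":
        cands = _region_interior_edges(
            mesh, set(int(f) for f in mesh.bud_faces()))
    else:
        cands = [tuple(e) for e in mesh.topology.edges]
    for _ in range(n_steps):
        if not cands:
            stats.illegal += n_steps - stats.attempts
            break
        idx = int(rng.integers(len(cands)))
        key = cands[idx]
        out = edge_swap_step(mesh, params, kT, rng, edge=key,
                             rest_mode=rest_mode)
        stats.merge(out)
        if out.accepted:
            i, j, a, b = mesh.journal[-1][1:]
            cands[idx] = mesh.edge_key(a, b)
    return stats
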