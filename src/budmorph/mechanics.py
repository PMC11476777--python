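"""Elastic energies, forces, and overdamped dynamics of the cell surface.

The cell wall is a spring network on the triangulated surface driven outward
by turgor pressure.  Each node obeys the overdamped law

    c dx_i/dt = -grad_i E_total + F_turgor,i

with total potential energy

    E_total = E_stretch + E_bend + E_area + E_excluded,

where

* ``E_stretch = sum_edges (k_s/2)(L - L0)^2`` for ordinary edges; septin-ring
  edges use the rescaled law ``(k_s/(2 L0^2))(L - L0)^2`` so the ring resists
  strain rather than absolute extension,
* ``E_bend = sum_hinges k_b (1 - cos(theta - theta0))`` over adjacent triangle
  pairs (theta = dihedral between face normals),
* ``E_area = sum_faces (k_a/(2 A0))(A - A0)^2``,
* ``E_excluded = sum_pairs D_m (1 - exp(-a_m (L - L_m)))^2`` over non-connected
  vertex pairs closer than the Morse range ``L_m`` (self-avoidance),

and the turgor force lumps each face's pressure load to its corners:
``F_turgor,i = P * sum_{faces f owning i} (A_f / 3) n_f``.

Stiffnesses may differ between mother and bud regions (an edge or hinge
counts as "bud" only when all its incident faces are bud faces).

Integration is explicit forward Euler on the overdamped equation; a step that
produces non-finite positions raises with a suggestion to reduce ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh import BUD, GeometryCache, SurfaceMesh, compute_geometry, cross3

__all__ = [
    "MechParams",
    "energy_stretch",
    "energy_bend",
    "energy_area",
    "energy_excluded_volume",
    "turgor_forces",
    "total_energy",
    "net_forces",
    "step_overdamped",
    "relax",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MechParams:
    """Mechanical coefficients (dimensionless simulation units).

    Attributes
    ----------
    c : friction coefficient of the surface (force*time/length).
    ks_mother, ks_bud : stretching spring coefficients per region.
    kb_mother, kb_bud : bending coefficients per region.
    ka : local area-resistance coefficient.
    Dm, am, Lm : Morse well depth, width, and interaction range; pairs of
        non-connected nodes closer than ``Lm`` repel (self-avoidance).
    P : turgor pressure (force/area); constant within one cell cycle.
    dt : mechanical time step for the forward-Euler update.
    max_step_frac : per-step displacement cap as a fraction of the shortest
        current edge (guards the explicit integrator on locally refined
        regions; 0 disables the cap).
    """

    c: float = 1.0
    ks_mother: float = 30.0
    ks_bud: float = 30.0
    kb_mother: float = 2.0
    kb_bud: float = 0.25
    ka: float = 20.0
    Dm: float = 0.5
    am: float = 20.0
    Lm: float = 0.12
    P: float = 4.0
    dt: float = 2.0e-3
    max_step_frac: float = 0.2

    def __post_init__(self):
        for name in ("c", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("ks_mother", "ks_bud", "kb_mother", "kb_bud", "ka", "Dm", "am", "Lm", "P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kw) -> "MechParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Per-element coefficient lookup
# ---------------------------------------------------------------------------


def _edge_is_bud(mesh: SurfaceMesh) -> np.ndarray:
    top = mesh.topology
    ef = top.edge_faces
    reg = mesh.face_region
    fa = np.where(ef[:, 0] >= 0, reg[ef[:, 0]], 0)
    fb = np.where(ef[:, 1] >= 0, reg[ef[:, 1]], 0)
    return (fa == BUD) & (fb == BUD)


def _stretch_coeffs(mesh: SurfaceMesh, params: MechParams):
    """Effective per-edge force constants k_eff so that E = (k_eff/2)(L-L0)^2.

    Ordinary edge: k_eff = ks; septin edge: k_eff = ks / L0^2 (the paper's
    "scaled by 2 L0^2 instead of 2" denominator).
    """
    L0, septin, _ = mesh.rest_arrays()
    ks = np.where(_edge_is_bud(mesh), params.ks_bud, params.ks_mother)
    k_eff = np.where(septin, ks / np.maximum(L0, 1e-300) ** 2, ks)
    return L0, k_eff


def _bend_coeffs(mesh: SurfaceMesh, params: MechParams):
    top = mesh.topology
    _, _, theta0 = mesh.rest_arrays()
    reg = mesh.face_region
    ef = top.edge_faces[top.hinge_edge_rows]
    bud = (reg[ef[:, 0]] == BUD) & (reg[ef[:, 1]] == BUD)
    kb = np.where(bud, params.kb_bud, params.kb_mother)
    return theta0, kb


def _scatter(F: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    n = len(F)
    for k in range(3):
        F[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------


def energy_stretch(mesh: SurfaceMesh, geom: GeometryCache, params: MechParams,
                   per_edge: bool = False):
    L0, k_eff = _stretch_coeffs(mesh, params)
    e = 0.5 * k_eff * (geom.edge_length - L0) ** 2
    return (float(e.sum()), e) if per_edge else float(e.sum())


def energy_bend(mesh: SurfaceMesh, geom: GeometryCache, params: MechParams,
                per_hinge: bool = False):
    theta0, kb = _bend_coeffs(mesh, params)
    e = kb * (1.0 - np.cos(geom.dihedral_angle - theta0))
    return (float(e.sum()), e) if per_hinge else float(e.sum())


def energy_area(mesh: SurfaceMesh, geom: GeometryCache, params: MechParams,
                per_face: bool = False):
    A0 = mesh.face_A0
    if np.any(A0 <= 0):
        raise ValueError(f"face {int(np.argmin(A0))} has non-positive rest area")
    e = params.ka / (2.0 * A0) * (geom.face_area - A0) ** 2
    return (float(e.sum()), e) if per_face else float(e.sum())


def _morse_pairs(mesh: SurfaceMesh, params: MechParams,
                 radius: float | None = None) -> np.ndarray:
    """Non-connected vertex pairs within the Morse range (sorted, unique)."""
    if params.Dm == 0.0 or params.Lm <= 0.0:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(mesh.vertices)
    pairs = tree.query_pairs(radius if radius is not None else params.Lm,
                             output_type="ndarray")
    if len(pairs) == 0:
        return pairs.astype(np.int64).reshape(0, 2)
    pairs = pairs.astype(np.int64)
    nv = mesh.n_vertices
    edges = mesh.topology.edges
    edge_codes = edges[:, 0] * nv + edges[:, 1]
    codes = pairs[:, 0] * nv + pairs[:, 1]
    return pairs[~np.isin(codes, edge_codes)]


def energy_excluded_volume(mesh: SurfaceMesh, params: MechParams) -> float:
    pairs = _morse_pairs(mesh, params)
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(mesh.vertices[pairs[:, 0]] - mesh.vertices[pairs[:, 1]], axis=1)
    return float(morse_energy(d, params).sum())


def morse_energy(L, params: MechParams):
    """D_m (1 - exp(-a_m (L - L_m)))^2, applied only for L <= L_m."""
    L = np.asarray(L, dtype=np.float64)
    e = params.Dm * (1.0 - np.exp(-params.am * (L - params.Lm))) ** 2
    return np.where(L <= params.Lm, e, 0.0)


def total_energy(mesh: SurfaceMesh, geom: GeometryCache | None = None,
                 params: MechParams | None = None) -> dict:
    """All energy terms plus their sum, as a dict with key ``total``."""
    if geom is None:
        geom = compute_geometry(mesh)
    terms = {
        "stretch": energy_stretch(mesh, geom, params),
        "bend": energy_bend(mesh, geom, params),
        "area": energy_area(mesh, geom, params),
        "excluded": energy_excluded_volume(mesh, params),
    }
    terms["total"] = sum(terms.values())
    return terms


# ---------------------------------------------------------------------------
# Forces (analytic gradients)
# ---------------------------------------------------------------------------


def _add_stretch_forces(mesh, geom, params, F):
    top = mesh.topology
    L0, k_eff = _stretch_coeffs(mesh, params)
    i, j = top.edges[:, 0], top.edges[:, 1]
    d = mesh.vertices[j] - mesh.vertices[i]
    L = geom.edge_length
    # dE/dL = k_eff (L - L0); force on j is -dE/dL * d/L
    f = (k_eff * (L - L0) / L)[:, None] * d
    _scatter(F, i, f)
    _scatter(F, j, -f)


def _add_area_forces(mesh, geom, params, F):
    V, Fc = mesh.vertices, mesh.faces
    A0 = mesh.face_A0
    dEdA = params.ka / A0 * (geom.face_area - A0)
    n = geom.face_normal
    # grad_{x0} A = 0.5 * n x (x2 - x1), cyclic
    for k in range(3):
        e = V[Fc[:, (k + 2) % 3]] - V[Fc[:, (k + 1) % 3]]
        gA = 0.5 * cross3(n, e)
        _scatter(F, Fc[:, k], -dEdA[:, None] * gA)


def dihedral_gradients(vertices: np.ndarray, hinges: np.ndarray):
    """Analytic gradients of the signed dihedral angle per hinge.

    Returns (gi, gj, ga, gb): gradients w.r.t. edge endpoints i, j and the
    opposite vertices of faces a = (i, j, oa), b = (j, i, ob), consistent with
    :func:`budmorph.mesh.signed_dihedrals`.
    """
    xi = vertices[hinges[:, 0]]
    xj = vertices[hinges[:, 1]]
    xa = vertices[hinges[:, 2]]
    xb = vertices[hinges[:, 3]]
    e = xj - xi
    elen = np.linalg.norm(e, axis=1)
    na = cross3(e, xa - xi)  # norm = 2 A_a
    nb = cross3(xb - xj, e)
    na2 = np.einsum("ij,ij->i", na, na)
    nb2 = np.einsum("ij,ij->i", nb, nb)
    ga = -(elen / na2)[:, None] * na
    gb = -(elen / nb2)[:, None] * nb
    # edge-endpoint gradients follow from translation/rotation invariance
    dot_a_j = np.einsum("ij,ij->i", xa - xj, e) / elen**2
    dot_b_j = np.einsum("ij,ij->i", xb - xj, e) / elen**2
    dot_a_i = np.einsum("ij,ij->i", xa - xi, e) / elen**2
    dot_b_i = np.einsum("ij,ij->i", xb - xi, e) / elen**2
    gi = -(dot_a_j * elen / na2)[:, None] * na - (dot_b_j * elen / nb2)[:, None] * nb
    gj = (dot_a_i * elen / na2)[:, None] * na + (dot_b_i * elen / nb2)[:, None] * nb
    return gi, gj, ga, gb


def _add_bend_forces(mesh, geom, params, F):
    top = mesh.topology
    if len(top.hinges) == 0:
        return
    theta0, kb = _bend_coeffs(mesh, params)
    dEdt = kb * np.sin(geom.dihedral_angle - theta0)
    gi, gj, ga, gb = dihedral_gradients(mesh.vertices, top.hinges)
    h = top.hinges
    _scatter(F, h[:, 0], -dEdt[:, None] * gi)
    _scatter(F, h[:, 1], -dEdt[:, None] * gj)
    _scatter(F, h[:, 2], -dEdt[:, None] * ga)
    _scatter(F, h[:, 3], -dEdt[:, None] * gb)


def _add_morse_forces(mesh, params, F, pairs=None):
    if pairs is None:
        pairs = _morse_pairs(mesh, params)
    if len(pairs) == 0:
        return
    d = mesh.vertices[pairs[:, 1]] - mesh.vertices[pairs[:, 0]]
    L = np.linalg.norm(d, axis=1)
    ex = np.exp(-params.am * (L - params.Lm))
    dEdL = 2.0 * params.Dm * (1.0 - ex) * params.am * ex
    dEdL = np.where(L <= params.Lm, dEdL, 0.0)
    f = (dEdL / np.maximum(L, 1e-12))[:, None] * d
    _scatter(F, pairs[:, 0], f)
    _scatter(F, pairs[:, 1], -f)


def turgor_forces(mesh: SurfaceMesh, geom: GeometryCache, params: MechParams) -> np.ndarray:
    """Pressure load lumped to face corners: F_i = P sum_f (A_f/3) n_f."""
    F = np.zeros_like(mesh.vertices)
    if params.P == 0.0:
        return F
    load = (params.P / 3.0) * geom.face_area[:, None] * geom.face_normal
    for k in range(3):
        _scatter(F, mesh.faces[:, k], load)
    return F


def elastic_forces(mesh: SurfaceMesh, geom: GeometryCache, params: MechParams) -> np.ndarray:
    """-grad E_total per vertex (analytic)."""
    F = np.zeros_like(mesh.vertices)
    _add_stretch_forces(mesh, geom, params, F)
    _add_bend_forces(mesh, geom, params, F)
    _add_area_forces(mesh, geom, params, F)
    _add_morse_forces(mesh, params, F)
    return F


def net_forces(mesh: SurfaceMesh, params: MechParams,
               geom: GeometryCache | None = None) -> np.ndarray:
    if geom is None:
        geom = compute_geometry(mesh)
    return elastic_forces(mesh, geom, params) + turgor_forces(mesh, geom, params)


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------


def step_overdamped(mesh: SurfaceMesh, params: MechParams,
                    geom: GeometryCache | None = None) -> SurfaceMesh:
    """One forward-Euler step of c dx/dt = -grad E + F_turgor (in place)."""
    if geom is None:
        geom = compute_geometry(mesh)
    F = net_forces(mesh, params, geom)
    new = mesh.vertices + _capped_displacement(F, params, geom, mesh)
    if not np.all(np.isfinite(new)):
        dmax = float(np.nanmax(np.abs(new - mesh.vertices)))
        raise IntegrationError(
            f"non-finite positions after step (max displacement {dmax:.3g}); "
            f"reduce dt below {params.dt:.3g}"
        )
    mesh.vertices = new
    return mesh


def _capped_displacement(F: np.ndarray, params: MechParams,
                         geom: GeometryCache, mesh: SurfaceMesh | None = None
                         ) -> np.ndarray:
    disp = (params.dt / params.c) * F
    if params.max_step_frac > 0:
        cap = params.max_step_frac * float(geom.edge_length.min())
        norms = np.linalg.norm(disp, axis=1)
        over = norms > cap
        if over.any():
            disp = disp.copy()
            disp[over] *= (cap / norms[over])[:, None]
    return disp


@dataclass
class RelaxResult:
    converged: bool
    steps: int
    max_force: float


# ---------------------------------------------------------------------------
# Compiled inner loop (optional numba acceleration with a numpy fallback)
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised indirectly
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _force_kernel(V, edges, L0, keff, hinges, theta0, kb,
                      faces, A0, ka, P, F, vmin):  # noqa: C901 - hot loop
        nv = V.shape[0]
        for i in range(nv):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
            vmin[i] = 1e300
        min_edge = 1e300
        # springs
        for e in range(edges.shape[0]):
            i, j = edges[e, 0], edges[e, 1]
            dx = V[j, 0] - V[i, 0]
            dy = V[j, 1] - V[i, 1]
            dz = V[j, 2] - V[i, 2]
            L = (dx * dx + dy * dy + dz * dz) ** 0.5
            if L < min_edge:
                min_edge = L
            if L < vmin[i]:
                vmin[i] = L
            if L < vmin[j]:
                vmin[j] = L
            c = keff[e] * (L - L0[e]) / L
            F[i, 0] += c * dx
            F[i, 1] += c * dy
            F[i, 2] += c * dz
            F[j, 0] -= c * dx
            F[j, 1] -= c * dy
            F[j, 2] -= c * dz
        # faces: area elasticity + turgor
        for f in range(faces.shape[0]):
            a, b, cc = faces[f, 0], faces[f, 1], faces[f, 2]
            e1x = V[b, 0] - V[a, 0]
            e1y = V[b, 1] - V[a, 1]
            e1z = V[b, 2] - V[a, 2]
            e2x = V[cc, 0] - V[a, 0]
            e2y = V[cc, 1] - V[a, 1]
            e2z = V[cc, 2] - V[a, 2]
            nx = e1y * e2z - e1z * e2y
            ny = e1z * e2x - e1x * e2z
            nz = e1x * e2y - e1y * e2x
            nn = (nx * nx + ny * ny + nz * nz) ** 0.5
            A = 0.5 * nn
            ux, uy, uz = nx / nn, ny / nn, nz / nn
            # turgor: P*A/3 along the normal at each corner
            tp = P * A / 3.0
            F[a, 0] += tp * ux
            F[a, 1] += tp * uy
            F[a, 2] += tp * uz
            F[b, 0] += tp * ux
            F[b, 1] += tp * uy
            F[b, 2] += tp * uz
            F[cc, 0] += tp * ux
            F[cc, 1] += tp * uy
            F[cc, 2] += tp * uz
            # area gradient: grad_{x_k} A = 0.5 * n x e_opp
            co = -ka / A0[f] * (A - A0[f])
            for k in range(3):
                if k == 0:
                    vk = a
                    ox = V[cc, 0] - V[b, 0]
                    oy = V[cc, 1] - V[b, 1]
                    oz = V[cc, 2] - V[b, 2]
                elif k == 1:
                    vk = b
                    ox = V[a, 0] - V[cc, 0]
                    oy = V[a, 1] - V[cc, 1]
                    oz = V[a, 2] - V[cc, 2]
                else:
                    vk = cc
                    ox = V[b, 0] - V[a, 0]
                    oy = V[b, 1] - V[a, 1]
                    oz = V[b, 2] - V[a, 2]
                gx = 0.5 * (uy * oz - uz * oy)
                gy = 0.5 * (uz * ox - ux * oz)
                gz = 0.5 * (ux * oy - uy * ox)
                F[vk, 0] += co * gx
                F[vk, 1] += co * gy
                F[vk, 2] += co * gz
        # hinge bending
        for h in range(hinges.shape[0]):
            i, j = hinges[h, 0], hinges[h, 1]
            oa, ob = hinges[h, 2], hinges[h, 3]
            ex = V[j, 0] - V[i, 0]
            ey = V[j, 1] - V[i, 1]
            ez = V[j, 2] - V[i, 2]
            elen = (ex * ex + ey * ey + ez * ez) ** 0.5
            ax = V[oa, 0] - V[i, 0]
            ay = V[oa, 1] - V[i, 1]
            az = V[oa, 2] - V[i, 2]
            nax = ey * az - ez * ay
            nay = ez * ax - ex * az
            naz = ex * ay - ey * ax
            bx = V[ob, 0] - V[j, 0]
            by = V[ob, 1] - V[j, 1]
            bz = V[ob, 2] - V[j, 2]
            nbx = by * ez - bz * ey
            nby = bz * ex - bx * ez
            nbz = bx * ey - by * ex
            na2 = nax * nax + nay * nay + naz * naz
            nb2 = nbx * nbx + nby * nby + nbz * nbz
            nan = na2 ** 0.5
            nbn = nb2 ** 0.5
            # signed dihedral
            cxx = (nay * nbz - naz * nby)
            cxy = (naz * nbx - nax * nbz)
            cxz = (nax * nby - nay * nbx)
            sin_t = (cxx * ex + cxy * ey + cxz * ez) / (nan * nbn * elen)
            cos_t = (nax * nbx + nay * nby + naz * nbz) / (nan * nbn)
            theta = np.arctan2(sin_t, cos_t)
            dEdt = kb[h] * np.sin(theta - theta0[h])
            # gradients (see dihedral_gradients)
            ga = -elen / na2
            gb = -elen / nb2
            da_j = ((V[oa, 0] - V[j, 0]) * ex + (V[oa, 1] - V[j, 1]) * ey
                    + (V[oa, 2] - V[j, 2]) * ez) / (elen * na2)
            db_j = ((V[ob, 0] - V[j, 0]) * ex + (V[ob, 1] - V[j, 1]) * ey
                    + (V[ob, 2] - V[j, 2]) * ez) / (elen * nb2)
            da_i = (ax * ex + ay * ey + az * ez) / (elen * na2)
            db_i = (bx * ex + by * ey + bz * ez
                    + (V[j, 0] - V[i, 0]) * ex + (V[j, 1] - V[i, 1]) * ey
                    + (V[j, 2] - V[i, 2]) * ez) / (elen * nb2)
            # F = -dEdt * grad(theta)
            F[oa, 0] -= dEdt * ga * nax
            F[oa, 1] -= dEdt * ga * nay
            F[oa, 2] -= dEdt * ga * naz
            F[ob, 0] -= dEdt * gb * nbx
            F[ob, 1] -= dEdt * gb * nby
            F[ob, 2] -= dEdt * gb * nbz
            F[i, 0] -= dEdt * (-da_j * nax - db_j * nbx)
            F[i, 1] -= dEdt * (-da_j * nay - db_j * nby)
            F[i, 2] -= dEdt * (-da_j * naz - db_j * nbz)
            F[j, 0] -= dEdt * (da_i * nax + db_i * nbx)
            F[j, 1] -= dEdt * (da_i * nay + db_i * nby)
            F[j, 2] -= dEdt * (da_i * naz + db_i * nbz)
        return min_edge

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba missing or broken
    _HAVE_NUMBA = False


def _compiled_force_arrays(mesh: SurfaceMesh, params: MechParams):
    top = mesh.topology
    L0, k_eff = _stretch_coeffs(mesh, params)
    theta0, kb = _bend_coeffs(mesh, params)
    return (top.edges, L0, k_eff, top.hinges, theta0, kb,
            mesh.faces, mesh.face_A0)


def _fast_forces(mesh, params, arrays, F_buf, vmin_buf, morse_pairs=None):
    """Elastic (minus Morse) + turgor forces via the compiled kernel."""
    edges, L0, k_eff, hinges, theta0, kb, faces, A0 = arrays
    min_edge = _force_kernel(mesh.vertices, edges, L0, k_eff, hinges, theta0,
                             kb, faces, A0, params.ka, params.P, F_buf,
                             vmin_buf)
    _add_morse_forces(mesh, params, F_buf, morse_pairs)
    return F_buf, min_edge


def relax(mesh: SurfaceMesh, params: MechParams, max_steps: int = 1000,
          force_tol: float = 1e-3, check_every: int = 10) -> RelaxResult:
    """Iterate overdamped steps until the largest nodal net force falls below
    ``force_tol`` or ``max_steps`` is exhausted.

    The inner loop runs through a numba-compiled kernel when numba is
    available and falls back to the vectorized numpy path otherwise; both
    evaluate the same analytic forces.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if _HAVE_NUMBA:
        return _relax_fast(mesh, params, max_steps, force_tol, check_every)
    return _relax_numpy(mesh, params, max_steps, force_tol, check_every)


def _relax_fast(mesh, params, max_steps, force_tol, check_every):
    arrays = _compiled_force_arrays(mesh, params)
    F = np.empty_like(mesh.vertices)
    vmin = np.empty(mesh.n_vertices)
    steps = 0
    dt_c = params.dt / params.c
    # Morse candidate pairs are refreshed only after the accumulated step
    # bound can have moved a pair by the search margin
    margin = 0.5 * params.Lm
    morse_pairs = None
    refresh_at = 0
    while True:
        if params.Dm > 0 and steps >= refresh_at:
            morse_pairs = _morse_pairs(mesh, params, params.Lm + margin)
            cap_now = params.max_step_frac * float(
                np.linalg.norm(mesh.vertices[arrays[0][:, 1]]
                               - mesh.vertices[arrays[0][:, 0]],
                               axis=1).min()) if params.max_step_frac > 0                 else params.dt * 1e3
            per_step = max(cap_now, 1e-12)
            refresh_at = steps + max(1, int(margin / (2 * per_step)))
        F, min_edge = _fast_forces(mesh, params, arrays, F, vmin, morse_pairs)
        norms2 = np.einsum("ij,ij->i", F, F)
        fmax = float(np.sqrt(norms2.max()))
        if fmax < force_tol:
            return RelaxResult(True, steps, fmax)
        if steps >= max_steps:
            return RelaxResult(False, steps, fmax)
        disp = dt_c * F
        if params.max_step_frac > 0:
            # conservative global cap: every step is bounded by the finest
            # edge scale on the surface
            cap = params.max_step_frac * min_edge
            if dt_c * fmax > cap:
                norms = dt_c * np.sqrt(norms2)
                over = norms > cap
                disp[over] *= (cap / norms[over])[:, None]
        new = mesh.vertices + disp
        if not np.all(np.isfinite(new)):
            raise IntegrationError("non-finite positions during relaxation; reduce dt")
        mesh.vertices = new
        steps += 1


def _relax_numpy(mesh, params, max_steps, force_tol, check_every):
    steps = 0
    fmax = np.inf
    while steps < max_steps:
        geom = compute_geometry(mesh)
        F = elastic_forces(mesh, geom, params) + turgor_forces(mesh, geom, params)
        fmax = float(np.linalg.norm(F, axis=1).max())
        if fmax < force_tol:
            return RelaxResult(True, steps, fmax)
        n = min(check_every, max_steps - steps)
        for _ in range(n):
            new = mesh.vertices + _capped_displacement(F, params, geom, mesh)
            if not np.all(np.isfinite(new)):
                raise IntegrationError(
                    "non-finite positions during relaxation; reduce dt"
                )
            mesh.vertices = new
            steps += 1
            if steps >= max_steps:
                break
            geom = compute_geometry(mesh)
            F = elastic_forces(mesh, geom, params) + turgor_forces(mesh, geom, params)
    fmax = float(np.linalg.norm(net_forces(mesh, params), axis=1).max())
    return RelaxResult(fmax < force_tol, steps, fmax)
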