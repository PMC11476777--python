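"""Cdc42 activator / global-inhibitor reaction-diffusion on the surface.

The active, membrane-bound Cdc42 concentration ``a`` lives on mesh vertices
and obeys, on the deforming surface Gamma,

    da/dt = Dc * Lap_Gamma a + k0 / (1 + (beta u)^-q)
            + k1 / (1 + (gamma p a)^-h) - k2 a - k3 b a,
    db/dt = k4 (abar - kss) b,            p = 1 / (1 + (beta u)^-q),

where ``b`` is a single global inhibitor (a well-mixed negative regulator
such as Cla4p), ``abar`` is the surface average of ``a`` and ``kss`` its
homeostatic set point: whenever ``b > 0`` at steady state, ``abar = kss``
exactly.  The spatial cue

    u = umin + (umax - umin) * ((H_T - H_min) / H_total)^n(t)

is evaluated at face centers from their height along the bud axis (H_T),
the bottom of the mother cell (H_min) and the tip-to-bottom distance
(H_total); the exponent schedule n(t) sets how sharply the cue decays away
from the bud tip.

Discretization: linear finite elements with cotangent stiffness and
barycentric lumped mass; IMEX stepping (implicit diffusion via a cached
sparse LU factorization, explicit reactions); the cue is mass-averaged from
faces to vertices for the reaction terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import expit

from .mesh import GeometryCache, MeshError, SurfaceMesh, compute_geometry
from .schedules import Schedule

__all__ = [
    "SignalingParams",
    "CueParams",
    "CueField",
    "ChemicalState",
    "cue_field",
    "assemble_laplacian",
    "surface_average",
    "rd_step",
    "solve_quasi_steady",
    "apply_remodel_events",
    "transfer_state_after_remodel",
]

_EPS_U = 1e-12  # cue clamp; umin > 0 is the supported configuration


@dataclass(frozen=True)
class SignalingParams:
    """Rate constants of the activator / global-inhibitor system.

    Defaults put the system in the single-polarized-cluster regime on a
    unit-radius cell: the diffusion length sqrt(Dc / k2) is a fraction of
    the bud size, self-enhancement (k1, gamma, h) amplifies the cue-selected
    site, and the inhibitor integral control (k4, kss) pins the surface
    average of ``a`` at kss.
    """

    Dc: float = 0.05
    k0: float = 6.0
    k1: float = 4.5
    k2: float = 1.0
    k3: float = 1.0
    k4: float = 2.0
    kss: float = 0.03
    beta: float = 2.0
    gamma: float = 2.0
    q: float = 4.0
    h: float = 2.0

    def __post_init__(self):
        for name in ("Dc", "k0", "k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.q <= 0 or self.h <= 0:
            raise ValueError("Hill exponents q, h must be > 0")
        if self.kss <= 0:
            raise ValueError("kss must be > 0")

    def with_(self, **kw) -> "SignalingParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CueParams:
    umin: float = 0.05
    umax: float = 1.0
    n_schedule: Schedule = field(default_factory=lambda: Schedule.constant(8.0))

    def __post_init__(self):
        if not 0 <= self.umin <= self.umax:
            raise ValueError("need 0 <= umin <= umax")


@dataclass
class CueField:
    """Per-face spatial cue and the heights it was built from."""

    u: np.ndarray  # (F,)
    n: float  # exponent used
    H_min: float
    H_total: float

    def vertex_values(self, mesh: SurfaceMesh, geom: GeometryCache) -> np.ndarray:
        """Mass-average the face cue onto vertices (A_f/3 weights)."""
        w = geom.face_area / 3.0
        num = np.zeros(mesh.n_vertices)
        den = np.zeros(mesh.n_vertices)
        for k in range(3):
            idx = mesh.faces[:, k]
            num += np.bincount(idx, weights=w * self.u, minlength=mesh.n_vertices)
            den += np.bincount(idx, weights=w, minlength=mesh.n_vertices)
        return num / den


@dataclass
class ChemicalState:
    """Active-Cdc42 vertex field and the global inhibitor scalar."""

    a: np.ndarray
    b: float
    converged: bool = True
    iterations: int = 0
    clip_count: int = 0

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.b <= 0:
            raise ValueError(
                "inhibitor b must start positive (b = 0 is an absorbing state)"
            )

    @classmethod
    def uniform(cls, mesh: SurfaceMesh, params: SignalingParams) -> "ChemicalState":
        return cls(np.full(mesh.n_vertices, params.kss), params.kss)


# ---------------------------------------------------------------------------
# Spatial cue
# ---------------------------------------------------------------------------


def cue_field(mesh: SurfaceMesh, cue_params: CueParams, frame: int) -> CueField:
    """Evaluate u at face centers with exponent n = n_schedule(frame)."""
    n = float(cue_params.n_schedule(frame))
    H_T = mesh.vertices[mesh.faces, 2].mean(axis=1)
    # normalize by the face-center range so the tip face carries exactly
    # umax and the bottom face exactly umin
    H_min = float(H_T.min())
    H_total = float(H_T.max()) - H_min
    if H_total <= 0:
        raise MeshError("degenerate geometry: tip and bottom coincide (H_total = 0)")
    s = np.clip((H_T - H_min) / H_total, 0.0, 1.0)
    u = cue_params.umin + (cue_params.umax - cue_params.umin) * s**n
    return CueField(u, n, H_min, H_total)


# ---------------------------------------------------------------------------
# Discrete Laplace-Beltrami
# ---------------------------------------------------------------------------


def assemble_laplacian(mesh: SurfaceMesh, geom: GeometryCache | None = None,
                       angle_tol: float = 5e-3):
    """Cotangent stiffness matrix and lumped vertex-area mass vector.

    Returns ``(W, masses)`` where ``W`` is the symmetric weak-form Laplacian
    with zero row sums (``W = -K``, K positive semidefinite) and ``masses``
    are barycentric dual areas summing to the total surface area.  The weak
    identity is ``integral(f * Lap g) ~ f^T W g``; the pointwise operator is
    ``Lap g ~ W g / masses``.  Cotangents of angles within ``angle_tol`` of
    0 or pi are clamped (with a warning) to keep near-degenerate triangles
    from poisoning the operator.
    """
    if geom is None:
        geom = compute_geometry(mesh)
    V, F = mesh.vertices, mesh.faces
    n = len(V)
    rows, cols, vals = [], [], []
    cot_max = 1.0 / np.tan(angle_tol)
    clamped = 0
    for k in range(3):
        vk = F[:, k]
        vi = F[:, (k + 1) % 3]
        vj = F[:, (k + 2) % 3]
        e1 = V[vi] - V[vk]
        e2 = V[vj] - V[vk]
        from .mesh import cross3
        cross = np.linalg.norm(cross3(e1, e2), axis=1)
        dot = np.einsum("ij,ij->i", e1, e2)
        cot = dot / np.maximum(cross, 1e-300)
        bad = np.abs(cot) > cot_max
        if bad.any():
            clamped += int(bad.sum())
            cot = np.clip(cot, -cot_max, cot_max)
        w = 0.5 * cot
        rows += [vi, vj, vi, vj]
        cols += [vj, vi, vi, vj]
        vals += [w, w, -w, -w]
    if clamped:
        warnings.warn(
            f"{clamped} near-degenerate triangle corners; cotangent weights clamped"
        )
    W = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return W, geom.vertex_dual_area.copy()


def surface_average(mesh: SurfaceMesh, a: np.ndarray,
                    geom: GeometryCache | None = None) -> float:
    """Lumped-mass surface average: sum(m_i a_i) / sum(m_i)."""
    if geom is None:
        geom = compute_geometry(mesh)
    m = geom.vertex_dual_area
    return float(m @ np.asarray(a) / m.sum())


# ---------------------------------------------------------------------------
# Reaction-diffusion stepping
# ---------------------------------------------------------------------------


class DiffusionOperator:
    """Cached implicit-diffusion solve ``(M + dt Dc K) x = rhs`` for one mesh."""

    def __init__(self, mesh: SurfaceMesh, Dc: float, dt: float,
                 geom: GeometryCache | None = None):
        if dt <= 0:
            raise ValueError("dt_chem must be > 0")
        self.geom = geom if geom is not None else compute_geometry(mesh)
        W, self.masses = assemble_laplacian(mesh, self.geom)
        M = sp.diags(self.masses)
        A = (M - dt * Dc * W).tocsc()  # W = -K
        try:
            self._lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular operator
            raise RuntimeError(f"implicit diffusion solve failed: {exc}") from exc
        self.dt = dt
        self.Dc = Dc

    def step(self, a: np.ndarray, reaction: np.ndarray) -> np.ndarray:
        return self._lu.solve(self.masses * (a + self.dt * reaction))

    def diffuse(self, a: np.ndarray) -> np.ndarray:
        return self._lu.solve(self.masses * a)


def _hill(x: np.ndarray, exponent: float) -> np.ndarray:
    """1 / (1 + x^-e) for x >= 0, computed stably; 0 at x <= 0."""
    x = np.maximum(np.asarray(x, dtype=np.float64), _EPS_U)
    return expit(exponent * np.log(x))


def reaction_terms(a: np.ndarray, b: float, u_vertex: np.ndarray,
                   params: SignalingParams) -> np.ndarray:
    p = _hill(params.beta * u_vertex, params.q)
    auto = _hill(params.gamma * p * a, params.h)
    return params.k0 * p + params.k1 * auto - params.k2 * a - params.k3 * b * a


def _reaction_substep(a: np.ndarray, b: float, u_vertex: np.ndarray,
                      params: SignalingParams, dt: float) -> np.ndarray:
    """Positivity-preserving semi-implicit reaction update.

    Production (cue term and self-enhancement, evaluated at the current a)
    is explicit; the linear inactivation k2 + k3 b is implicit, so the
    update stays stable and non-negative for arbitrarily large inhibitor
    levels.  The fixed point coincides with the reaction balance.
    """
    p = _hill(params.beta * u_vertex, params.q)
    auto = _hill(params.gamma * p * a, params.h)
    production = params.k0 * p + params.k1 * auto
    return (a + dt * production) / (1.0 + dt * (params.k2 + params.k3 * b))


def rd_step(mesh: SurfaceMesh, state: ChemicalState, cue: CueField,
            params: SignalingParams, dt_chem: float,
            op: DiffusionOperator | None = None) -> ChemicalState:
    """One IMEX step: explicit reactions and inhibitor ODE, implicit diffusion."""
    if op is None:
        op = DiffusionOperator(mesh, params.Dc, dt_chem)
    u_v = cue.vertex_values(mesh, op.geom)
    a_star = _reaction_substep(state.a, state.b, u_v, params, dt_chem)
    a_new = op.diffuse(a_star)
    clip = int((a_new < 0).sum())
    if clip:
        a_new = np.maximum(a_new, 0.0)
    abar = float(op.masses @ a_new / op.masses.sum())
    # exact update of the multiplicative ODE db/dt = k4 (abar - kss) b over
    # the step (abar held constant), rate-limited per step
    b_new = state.b * float(np.exp(np.clip(
        dt_chem * params.k4 * (abar - params.kss), -0.2, 0.2)))
    out = ChemicalState(a_new, b_new, state.converged, state.iterations + 1,
                        state.clip_count + clip)
    return out


def solve_quasi_steady(mesh: SurfaceMesh, state: ChemicalState, cue: CueField,
                       params: SignalingParams, tol: float = 1e-6,
                       max_iters: int = 20000, dt_chem: float = 0.05) -> ChemicalState:
    """Iterate IMEX steps to the quasi-steady state on the current geometry.

    Convergence requires both the field residual ``max|da|/dt < tol`` and the
    homeostatic balance ``|abar - kss| < tol`` (forced by db/dt = 0 at b > 0).
    On hitting ``max_iters`` the best state is returned flagged unconverged,
    with a warning.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    op = DiffusionOperator(mesh, params.Dc, dt_chem)
    u_v = cue.vertex_values(mesh, op.geom)
    a, b = state.a.copy(), state.b
    clip_total = 0
    mass_sum = op.masses.sum()
    for it in range(1, max_iters + 1):
        a_star = _reaction_substep(a, b, u_v, params, dt_chem)
        a_new = op.diffuse(a_star)
        clip = int((a_new < 0).sum())
        if clip:
            a_new = np.maximum(a_new, 0.0)
            clip_total += clip
        abar = float(op.masses @ a_new / mass_sum)
        b_new = b * float(np.exp(np.clip(
            dt_chem * params.k4 * (abar - params.kss), -0.2, 0.2)))
        resid = float(np.abs(a_new - a).max()) / dt_chem
        a, b = a_new, b_new
        if resid < tol and abs(abar - params.kss) < tol:
            return ChemicalState(a, b, True, it, clip_total)
    warnings.warn(
        f"quasi-steady solve did not converge in {max_iters} iterations "
        f"(residual {resid:.3g}, |abar-kss| {abs(abar - params.kss):.3g})"
    )
    return ChemicalState(a, b, False, max_iters, clip_total)


# ---------------------------------------------------------------------------
# Field transfer across remodeling
# ---------------------------------------------------------------------------


def apply_remodel_events(state: ChemicalState, events) -> ChemicalState:
    """Replay journal events onto the vertex field.

    Swaps ("flip") leave vertex fields untouched; each split vertex receives
    the mean of its parent edge's endpoint values; ``b`` is global and
    unchanged.
    """
    a = list(state.a)
    for ev in events:
        if ev[0] == "split":
            _, m, i, j = ev
            if m != len(a):
                raise MeshError(f"journal out of order: split vertex {m} != {len(a)}")
            a.append(0.5 * (a[i] + a[j]))
        elif ev[0] != "flip":
            raise MeshError(f"unknown journal event {ev[0]!r}")
    return ChemicalState(np.array(a), state.b, state.converged,
                         state.iterations, state.clip_count)


def transfer_state_after_remodel(old_mesh: SurfaceMesh, state: ChemicalState,
                                 new_mesh: SurfaceMesh) -> ChemicalState:
    """Carry the vertex field from ``old_mesh`` to its remodeled descendant.

    ``new_mesh`` must have been produced from ``old_mesh`` by splits and/or
    swaps with recorded provenance (the mesh journal); a journal mismatch or
    an unaccounted vertex raises.
    """
    if old_mesh.n_vertices != len(state.a):
        raise MeshError("state does not match the old mesh")
    if new_mesh.journal[: len(old_mesh.journal)] != old_mesh.journal:
        raise MeshError("meshes do not share provenance (journal mismatch)")
    out = apply_remodel_events(state, new_mesh.journal[len(old_mesh.journal):])
    if len(out.a) != new_mesh.n_vertices:
        raise MeshError(
            "provenance incomplete: journal does not account for all new vertices"
        )
    return out
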