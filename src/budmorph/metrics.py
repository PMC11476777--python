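"""Shape and growth quantification of the bud.

Metrics mirror the measurements used on microscopy images: bud surface
area, aspect ratio (long axis over short axis), polarization height (how
far down from the bud tip the high-concentration region extends), and the
linear fit of area-vs-time used to read off the growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mesh import GeometryCache, MeshError, SurfaceMesh, compute_geometry

__all__ = [
    "ShapeRecord",
    "bud_area",
    "aspect_ratio",
    "polarization_height",
    "fit_linear_growth",
]


@dataclass
class ShapeRecord:
    """Per-frame shape metrics appended to the scenario time series."""

    frame: int
    bud_area: float
    ar_pca: float
    ar_heightwidth: float
    ph: float
    relative_ph: float
    conc_max: float
    abar: float
    b: float
    e_total: float
    n_exponent: float
    es_steps: int
    swap_accepted: int = 0
    relax_steps: int = 0


def bud_area(mesh: SurfaceMesh, geom: GeometryCache | None = None) -> float:
    """Total area of faces labeled bud (0 for an empty bud)."""
    bf = mesh.bud_faces()
    if len(bf) == 0:
        return 0.0
    if geom is None:
        geom = compute_geometry(mesh)
    return float(geom.face_area[bf].sum())


def aspect_ratio(mesh: SurfaceMesh, estimator: str = "pca") -> float:
    """Long-to-short axis ratio of the bud vertex cloud.

    ``pca``: extents along the principal directions of the centered cloud;
    AR = largest extent / smallest extent (>= 1 by construction, rotation
    and scale invariant).  ``heightwidth``: bud height above the neck plane
    (tip z minus mean septin-ring z) over the maximal diameter perpendicular
    to the bud axis.
    """
    pts = mesh.vertices[mesh.bud_vertices()]
    if len(pts) < 4:
        raise MeshError("need >= 4 bud vertices for an aspect ratio")
    if estimator == "pca":
        X = pts - pts.mean(axis=0)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        if s[-1] <= 1e-12 * s[0]:
            raise MeshError("degenerate (coplanar) bud vertex cloud")
        proj = X @ Vt.T
        extents = proj.max(axis=0) - proj.min(axis=0)
        return float(extents.max() / extents.min())
    if estimator == "heightwidth":
        ring = mesh.septin_ring_vertices()
        if len(ring) == 0:
            raise MeshError("height/width estimator needs a septin ring")
        neck = mesh.vertices[ring]
        axis_origin = neck.mean(axis=0)
        height = float(pts[:, 2].max() - axis_origin[2])
        radial = np.linalg.norm(pts[:, :2] - axis_origin[None, :2], axis=1)
        width = 2.0 * float(radial.max())
        if width <= 0:
            raise MeshError("degenerate bud width")
        return height / width
    raise ValueError(f"unknown estimator {estimator!r}")


def polarization_height(mesh: SurfaceMesh, a: np.ndarray,
                        fraction: float = 0.8) -> tuple:
    """(PH, relative PH) of the high-concentration region.

    PH is the z-distance from the bud tip down to the lowest bud vertex
    whose concentration reaches ``fraction`` of the bud maximum Conc_max;
    PH_total is the tip-to-neck height (mean septin-ring z).  The relative
    value PH / PH_total is clipped to [0, 1].
    """
    a = np.asarray(a, dtype=np.float64)
    bv = mesh.bud_vertices()
    if len(bv) == 0:
        raise MeshError("mesh has no bud vertices")
    ring = mesh.septin_ring_vertices()
    if len(ring) == 0:
        raise MeshError("polarization height needs a septin ring")
    z = mesh.vertices[:, 2]
    z_tip = float(z[bv].max())
    conc_max = float(a[bv].max())
    if conc_max <= 0.0:
        raise MeshError("no positive concentration on the bud")
    sel = bv[a[bv] >= fraction * conc_max]
    if len(sel) == 0:
        raise MeshError("no bud vertex reaches the concentration threshold")
    ph = z_tip - float(z[sel].min())
    ph_total = z_tip - float(z[ring].mean())
    rel = min(max(ph / ph_total, 0.0), 1.0) if ph_total > 0 else 1.0
    return ph, rel


def fit_linear_growth(times, areas) -> tuple:
    """Ordinary least squares of area against time: (slope, intercept, R^2)."""
    t = np.asarray(times, dtype=np.float64)
    y = np.asarray(areas, dtype=np.float64)
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("constant time values")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
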