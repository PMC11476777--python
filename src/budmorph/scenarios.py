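"""Scenario configuration, the coupled simulation loop, presets, and output.

One *frame* of the coupled model is: evaluate the spatial cue, re-converge
the signaling field on the current geometry (quasi-steady coupling), gate
the growth region by concentration, insert material (triangle-pair splits),
transfer the field to the grown mesh, run the scheduled Metropolis edge
swaps, mechanically relax, and record shape metrics.

Presets reproduce the in-silico experiments: spherical vs tubular budding
under a shallow (n = 2) vs sharp (n = 8) cue; fixed-tip growth with 25 / 75
/ 125 edge-swap steps per growth event; edge-swap schedules switching from
25 to 50 mid-run; and time-varying cue exponents n(t) that rise and then
decay to stabilize the aspect ratio.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import mechanics as mech
from . import metrics as met
from . import remodeling as rem
from . import signaling as sig
from .mesh import (BUD, MeshError, SurfaceMesh, build_icosphere, compute_geometry,
                   init_bud_patch, load_mesh_file, load_ply, save_ply, validate)
from .schedules import Schedule

__all__ = [
    "MeshSpec",
    "ChemSolverSpec",
    "OutputSpec",
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "write_snapshot",
    "read_snapshot",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class MeshSpec:
    subdivisions: int = 2
    radius: float = 1.0
    cap_angle: float = 0.5  # radians
    mesh_file: str | None = None  # optional PLY/OFF initial cell


@dataclass(frozen=True)
class ChemSolverSpec:
    tol: float = 1e-5
    max_iters: int = 20000
    dt_chem: float = 0.05


@dataclass(frozen=True)
class OutputSpec:
    out_dir: str | None = None
    snapshot_every: int = 0  # 0: no snapshots
    snapshot_format: str = "vtk"  # "vtk" or "ply"
    length_um: float = 1.8  # plot-only unit scale: 1 length unit in um
    frame_min: float = 0.75  # plot-only unit scale: 1 frame in minutes


@dataclass
class ScenarioConfig:
    """Full declarative description of one simulation run."""

    mesh: MeshSpec = field(default_factory=MeshSpec)
    mech: mech.MechParams = field(default_factory=mech.MechParams)
    signaling: sig.SignalingParams = field(default_factory=sig.SignalingParams)
    cue: sig.CueParams = field(default_factory=sig.CueParams)
    growth: rem.GrowthPolicy = field(default_factory=rem.GrowthPolicy)
    chem: ChemSolverSpec = field(default_factory=ChemSolverSpec)
    output: OutputSpec = field(default_factory=OutputSpec)
    frames: int = 160
    relax_max_steps: int = 400
    relax_force_tol: float = 0.05
    fixed_tip: bool = False  # ablation: pin growth to a tip cap, skip signaling
    fixed_tip_fraction: float = 0.25  # tip cap height as fraction of bud height
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        if self.frames < 1:
            raise ValueError("frames must be >= 1")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cue"] = dict(d["cue"])
        d["cue"]["n_schedule"] = self.cue.n_schedule.to_spec()
        d["growth"] = dict(d["growth"])
        d["growth"]["es_schedule"] = self.growth.es_schedule.to_spec()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        kw: dict = {}
        if "mesh" in d:
            kw["mesh"] = MeshSpec(**d.pop("mesh"))
        if "mech" in d:
            kw["mech"] = mech.MechParams(**d.pop("mech"))
        if "signaling" in d:
            kw["signaling"] = sig.SignalingParams(**d.pop("signaling"))
        if "cue" in d:
            c = dict(d.pop("cue"))
            if "n_schedule" in c:
                c["n_schedule"] = Schedule.from_spec(c["n_schedule"])
            kw["cue"] = sig.CueParams(**c)
        if "growth" in d:
            g = dict(d.pop("growth"))
            if "es_schedule" in g:
                g["es_schedule"] = Schedule.from_spec(g["es_schedule"])
            kw["growth"] = rem.GrowthPolicy(**g)
        if "chem" in d:
            kw["chem"] = ChemSolverSpec(**d.pop("chem"))
        if "output" in d:
            kw["output"] = OutputSpec(**d.pop("output"))
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Presets (the in-silico experiments)
# ---------------------------------------------------------------------------


def _base(name: str, **kw) -> ScenarioConfig:
    cfg = ScenarioConfig(name=name, **kw)
    return cfg


def _fig3(n: float, name: str) -> ScenarioConfig:
    return _base(
        name,
        cue=sig.CueParams(n_schedule=Schedule.constant(n)),
        growth=rem.GrowthPolicy(es_schedule=Schedule.constant(25)),
    )


def _fig4_es(es: int, name: str) -> ScenarioConfig:
    # the fixed-tip experiments probe growth vs wall-rearrangement
    # competition, so the per-frame mechanical budget is kept small and the
    # scheduled edge swaps are the dominant relaxation channel
    return _base(
        name,
        fixed_tip=True,
        fixed_tip_fraction=0.1,
        relax_max_steps=150,
        growth=rem.GrowthPolicy(es_schedule=Schedule.constant(es)),
    )


def _fig4_schedule(switch_frame: int, name: str) -> ScenarioConfig:
    sched = Schedule((0, switch_frame), (25.0, 50.0), "step")
    return _base(name, fixed_tip=True, fixed_tip_fraction=0.1,
                 relax_max_steps=150,
                 growth=rem.GrowthPolicy(es_schedule=sched))


def _fig5(case: int, name: str) -> ScenarioConfig:
    # n(t) rises 5 -> 12, then decays to 7; case 2's decay takes twice as
    # long as case 1's (the slower loss of polarization).
    if case == 1:
        sched = Schedule((0, 50, 100), (5.0, 12.0, 7.0), "linear")
    else:
        sched = Schedule((0, 50, 150), (5.0, 12.0, 7.0), "linear")
    return _base(
        name,
        cue=sig.CueParams(n_schedule=sched),
        growth=rem.GrowthPolicy(es_schedule=Schedule.constant(25)),
    )


PRESETS = {
    "fig3_n2": lambda: _fig3(2.0, "fig3_n2"),
    "fig3_n8": lambda: _fig3(8.0, "fig3_n8"),
    "fig4_es25": lambda: _fig4_es(25, "fig4_es25"),
    "fig4_es75": lambda: _fig4_es(75, "fig4_es75"),
    "fig4_es125": lambda: _fig4_es(125, "fig4_es125"),
    "fig4_schedule150": lambda: _fig4_schedule(150, "fig4_schedule150"),
    "fig4_schedule100": lambda: _fig4_schedule(100, "fig4_schedule100"),
    "fig5_case1": lambda: _fig5(1, "fig5_case1"),
    "fig5_case2": lambda: _fig5(2, "fig5_case2"),
}


def preset(name: str) -> ScenarioConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


# ---------------------------------------------------------------------------
# The coupled loop
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    records: list
    mesh: SurfaceMesh
    state: sig.ChemicalState | None
    flags: list
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        df.insert(1, "sim_time", df["frame"] * self.config.output.frame_min)
        return df

    @property
    def final_aspect_ratio(self) -> float:
        return self.records[-1].ar_pca

    def write_outputs(self, out_dir=None) -> dict:
        out_dir = Path(out_dir or self.config.output.out_dir or ".")
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        csv = out_dir / f"{self.config.name}_timeseries.csv"
        self.to_dataframe().to_csv(csv, index=False)
        paths["csv"] = str(csv)
        prov = out_dir / f"{self.config.name}_provenance.json"
        with open(prov, "w") as fh:
            json.dump(self.provenance, fh, indent=2)
        paths["provenance"] = str(prov)
        return paths


def _build_initial_mesh(cfg: ScenarioConfig) -> SurfaceMesh:
    if cfg.mesh.mesh_file:
        m = load_mesh_file(cfg.mesh.mesh_file)
    else:
        m = build_icosphere(cfg.mesh.subdivisions, cfg.mesh.radius)
    init_bud_patch(m, [0.0, 0.0, 1.0], cfg.mesh.cap_angle)
    m.set_rest_state_from_geometry()
    return m


def _tip_region(mesh: SurfaceMesh, fraction: float) -> np.ndarray:
    """Bud faces whose centroid lies in the top `fraction` of the bud height."""
    bf = mesh.bud_faces()
    z = mesh.vertices[:, 2]
    z_tip = float(z[mesh.bud_vertices()].max())
    ring = mesh.septin_ring_vertices()
    z_neck = float(z[ring].mean())
    cutoff = z_tip - fraction * (z_tip - z_neck)
    cz = mesh.vertices[mesh.faces[bf], 2].mean(axis=1)
    sel = bf[cz >= cutoff]
    if len(sel) < 4:  # guarantee a workable patch on coarse buds
        sel = bf[np.argsort(cz)[-min(4, len(bf)):]]
    return sel


def _tip_indicator(mesh: SurfaceMesh, region: np.ndarray) -> np.ndarray:
    a = np.zeros(mesh.n_vertices)
    a[np.unique(mesh.faces[region].ravel())] = 1.0
    return a


def run_scenario(cfg: ScenarioConfig, progress=None) -> ScenarioResult:
    """Run the coupled mechano-chemical budding simulation.

    Fully deterministic under a fixed ``cfg.seed`` (a single RNG stream is
    consumed in stage order).  Any stage failure is re-raised with the frame
    index and stage name attached.
    """
    rng = np.random.default_rng(cfg.seed)
    mesh = _build_initial_mesh(cfg)
    state = sig.ChemicalState.uniform(mesh, cfg.signaling)
    records: list = []
    flags: list = []
    stage = "equilibrate"
    try:
        # equilibrate the pressurized initial cell before any growth
        mech.relax(mesh, cfg.mech, cfg.relax_max_steps, cfg.relax_force_tol)
        for frame in range(1, cfg.frames + 1):
            stage = "cue"
            cue = sig.cue_field(mesh, cfg.cue, frame)
            if cfg.fixed_tip:
                stage = "region"
                region = _tip_region(mesh, cfg.fixed_tip_fraction)
                a_field = _tip_indicator(mesh, region)
                state = sig.ChemicalState(a_field, state.b)
            else:
                stage = "signaling"
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    state = sig.solve_quasi_steady(
                        mesh, state, cue, cfg.signaling,
                        tol=cfg.chem.tol, max_iters=cfg.chem.max_iters,
                        dt_chem=cfg.chem.dt_chem)
                for w in wlist:
                    flags.append(f"frame {frame}: {w.message}")
                # homeostasis holds on the geometry the field was solved on
                abar_solved = sig.surface_average(mesh, state.a)
                if state.converged and \
                        abs(abar_solved - cfg.signaling.kss) > 50 * cfg.chem.tol:
                    flags.append(
                        f"frame {frame}: homeostasis violated "
                        f"(|abar-kss| = {abs(abar_solved - cfg.signaling.kss):.3g})")
                stage = "region"
                region = rem.eligible_faces(mesh, state.a,
                                            cfg.growth.threshold_fraction)
                if len(region) == 0:
                    # a single-vertex peak can leave every face mean below
                    # threshold; fall back to the faces touching the peak
                    bv = mesh.bud_vertices()
                    peak = bv[int(np.argmax(state.a[bv]))]
                    bf = mesh.bud_faces()
                    region = bf[(mesh.faces[bf] == peak).any(axis=1)]
            stage = "growth"
            j0 = len(mesh.journal)
            es = int(round(cfg.growth.es_schedule(frame)))
            one = replace(cfg.growth, insertions_per_event=1)
            stats = rem.SwapStats()
            # each insertion is followed by its edge-swap relaxation dose
            for _ in range(cfg.growth.insertions_per_event):
                grec = rem.growth_event(mesh, region, one, rng)
                if grec.performed == 0:
                    break
                stats.merge(rem.run_swaps(mesh, es, cfg.mech, cfg.growth.kT,
                                          rng, cfg.growth.swap_domain,
                                          cfg.growth.flip_rest_mode))
                if cfg.fixed_tip:
                    region = _tip_region(mesh, cfg.fixed_tip_fraction)
                else:
                    region = np.concatenate(
                        [region, [mesh.n_faces - 2, mesh.n_faces - 1]])
            stage = "transfer"
            state = sig.apply_remodel_events(state, mesh.journal[j0:])
            stage = "relax"
            relax_res = mech.relax(mesh, cfg.mech, cfg.relax_max_steps,
                                   cfg.relax_force_tol)
            stage = "metrics"
            geom = compute_geometry(mesh)
            e_total = mech.total_energy(mesh, geom, cfg.mech)["total"]
            abar = abar_solved if not cfg.fixed_tip else \
                sig.surface_average(mesh, state.a, geom)
            bv = mesh.bud_vertices()
            conc_max = float(state.a[bv].max())
            ph, rel_ph = met.polarization_height(mesh, state.a,
                                                 cfg.growth.threshold_fraction)
            rec = met.ShapeRecord(
                frame=frame,
                bud_area=met.bud_area(mesh, geom),
                ar_pca=met.aspect_ratio(mesh, "pca"),
                ar_heightwidth=met.aspect_ratio(mesh, "heightwidth"),
                ph=ph,
                relative_ph=rel_ph,
                conc_max=conc_max,
                abar=abar,
                b=state.b,
                e_total=e_total,
                n_exponent=float(cue.n),
                es_steps=es,
                swap_accepted=stats.accepted,
                relax_steps=relax_res.steps,
            )
            records.append(rec)
            stage = "checks"
            rep = validate(mesh)
            if not rep.passed:
                flags.append(f"frame {frame}: topology invalid: {rep.messages}")
            if cfg.output.snapshot_every and cfg.output.out_dir and \
                    frame % cfg.output.snapshot_every == 0:
                stage = "snapshot"
                out = Path(cfg.output.out_dir)
                out.mkdir(parents=True, exist_ok=True)
                ext = "vtk" if cfg.output.snapshot_format == "vtk" else "ply"
                write_snapshot(
                    mesh,
                    {"a": state.a},
                    {"u": sig.cue_field(mesh, cfg.cue, frame).u,
                     "eligible": np.isin(np.arange(mesh.n_faces), region)
                     .astype(float)},
                    out / f"{cfg.name}_frame{frame:04d}.{ext}",
                    cfg.output.snapshot_format,
                )
            if progress is not None:
                progress(frame, rec)
    except Exception as exc:
        raise RuntimeError(
            f"scenario {cfg.name!r} failed at frame {len(records) + 1}, "
            f"stage {stage!r}: {exc}"
        ) from exc
    provenance = {
        "name": cfg.name,
        "seed": cfg.seed,
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "frames_completed": len(records),
        "flags": flags,
    }
    return ScenarioResult(cfg, records, mesh, state, flags, provenance)


# ---------------------------------------------------------------------------
# Snapshot I/O
# ---------------------------------------------------------------------------


def write_snapshot(mesh: SurfaceMesh, vertex_fields: dict, face_fields: dict,
                   path, fmt: str = "vtk") -> None:
    """Write geometry plus per-vertex and per-face scalar fields.

    ``vtk``: legacy ASCII VTK PolyData (viewable in ParaView); coordinates
    and fields written at full precision.  ``ply``: ASCII PLY via
    :func:`budmorph.mesh.save_ply` (vertex fields only; the face region
    label is always stored).
    """
    path = Path(path)
    vertex_fields = dict(vertex_fields or {})
    face_fields = dict(face_fields or {})
    if fmt == "ply":
        save_ply(mesh, path, vertex_fields)
        return
    if fmt != "vtk":
        raise ValueError(f"unknown snapshot format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbudmorph surface snapshot\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        vertex_fields.setdefault(
            "region",
            _vertex_region(mesh),
        )
        fh.write(f"POINT_DATA {mesh.n_vertices}\n")
        for name, vals in vertex_fields.items():
            vals = np.asarray(vals)
            if len(vals) != mesh.n_vertices:
                raise ValueError(f"vertex field {name!r} has length "
                                 f"{len(vals)} != {mesh.n_vertices}")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(repr(float(v)) for v in vals) + "\n")
        face_fields.setdefault("region", mesh.face_region.astype(float))
        fh.write(f"CELL_DATA {mesh.n_faces}\n")
        for name, vals in face_fields.items():
            vals = np.asarray(vals)
            if len(vals) != mesh.n_faces:
                raise ValueError(f"face field {name!r} has length "
                                 f"{len(vals)} != {mesh.n_faces}")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(repr(float(v)) for v in vals) + "\n")


def _vertex_region(mesh: SurfaceMesh) -> np.ndarray:
    reg = np.zeros(mesh.n_vertices)
    reg[mesh.bud_vertices()] = float(BUD)
    return reg


def read_snapshot(path):
    """Read a snapshot written by :func:`write_snapshot`.

    Returns ``(mesh, vertex_fields, face_fields)``; for PLY, face fields are
    empty.  Coordinates round-trip bit-identically.
    """
    path = Path(path)
    if path.suffix == ".ply":
        mesh, vfields = load_ply(path)
        return mesh, vfields, {}
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if line.startswith("POINTS"):
            nv = int(line.split()[1])
            break
    else:
        raise MeshError(f"{path}: no POINTS section")
    verts = np.array([next(lines).split() for _ in range(nv)], dtype=np.float64)
    for line in lines:
        if line.startswith("POLYGONS"):
            nf = int(line.split()[1])
            break
    else:
        raise MeshError(f"{path}: no POLYGONS section")
    faces = np.array([next(lines).split()[1:4] for _ in range(nf)], dtype=np.int64)
    vfields: dict = {}
    ffields: dict = {}
    target, count = None, 0
    for line in lines:
        if line.startswith("POINT_DATA"):
            target, count = vfields, nv
        elif line.startswith("CELL_DATA"):
            target, count = ffields, nf
        elif line.startswith("SCALARS") and target is not None:
            name = line.split()[1]
            next(lines)  # LOOKUP_TABLE
            target[name] = np.array([next(lines) for _ in range(count)],
                                    dtype=np.float64)
    mesh = SurfaceMesh(verts, faces)
    if "region" in ffields:
        mesh.face_region = ffields["region"].astype(np.int8)
        if (mesh.face_region == BUD).any() and not (mesh.face_region == BUD).all():
            from .mesh import _region_boundary_edges
            mesh.septin_edges = _region_boundary_edges(mesh)
    mesh.set_rest_state_from_geometry()
    return mesh, vfields, ffields
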