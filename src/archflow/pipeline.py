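"""End-to-end orchestration: phantom -> mesh -> flow -> analysis.

A run is described by a nested configuration (YAML or dict); only the
stages present in the config are executed, in dependency order.  Every
artifact is written under the output directory and listed in
``manifest.json`` with its SHA-256 checksum, so a re-run with the same
config and seed can be verified byte-for-byte (all randomness is fanned
out deterministically from the single global seed with fixed per-stage
offsets).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("archflow.pipeline")

_STAGE_SEED_OFFSET = {"phantom": 11, "mesh": 23, "simulate": 37,
                      "streamlines": 53, "landmarks": 71}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    stages: dict
    seed: int = 0
    out_dir: str = "archflow_run"
    units: str = "mm"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        return cls(stages=raw.get("stages", {}), seed=int(raw.get("seed", 0)),
                   out_dir=raw.get("out_dir", "archflow_run"),
                   units=raw.get("units", "mm"))

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + _STAGE_SEED_OFFSET.get(stage, 97)) % (2 ** 31)


@dataclass
class RunReport:
    out_dir: Path
    artifacts: dict               # name -> relative path
    summary: dict
    manifest_path: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def demo_config(seed: int = 0, out_dir: str = "archflow_demo") -> RunConfig:
    """Coarse end-to-end configuration exercising every stage."""
    return RunConfig(seed=seed, out_dir=out_dir, stages={
        "phantom": {"pitch": 0.03},
        "mesh": {"h": 0.055},
        "simulate": {"dt": 0.01, "n_cycles": 1, "period": 0.4,
                     "inlet_mean": 12.0, "inlet_amplitude": 8.0},
        "wss": {},
        "streamlines": {"n_seeds": 60, "step": 0.02},
        "geometry": {},
        "landmarks": {"n_specimens": 8, "n_outliers": 2,
                      "mode_sds": [0.02, 0.01], "noise_sd": 0.002},
        "morphometrics": {"with_scaling": False},
    })


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages; halts on the first failing stage,
    preserving completed artifacts."""
    from . import hemo_post, io, morphometrics, phantoms, solver
    from . import streamlines as sl
    from . import vessel_geometry as vg
    from .mesh import tetrahedralize

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict = {"seed": config.seed}
    st = config.stages

    def record(name, path):
        artifacts[name] = str(Path(path).relative_to(out))

    surface = mesh = sol = None
    try:
        if "phantom" in st:
            c = st["phantom"]
            sten = (phantoms.StenosisSpec(**c["oft_stenosis"])
                    if c.get("oft_stenosis") else None)
            spec = phantoms.ArchPhantomSpec(
                pitch=c.get("pitch", 0.02),
                oft_stenosis=sten,
                cranial_outlets=c.get("cranial_outlets", False),
                seed=config.stage_seed("phantom"))
            surface = phantoms.make_arch_phantom(spec)
            io.write_stl(surface, out / "phantom.stl")
            io.write_vtp(surface, out / "phantom.vtp")
            (out / "phantom_regions.json").write_text(json.dumps(
                {str(k): v for k, v in surface.region_names.items()},
                sort_keys=True))
            record("phantom_stl", out / "phantom.stl")
            record("phantom_vtp", out / "phantom.vtp")
            record("phantom_regions", out / "phantom_regions.json")
            logger.info("stage phantom: %d faces", len(surface.faces))

        if "mesh" in st:
            if surface is None:
                raise PipelineError("mesh stage requires the phantom stage")
            c = st["mesh"]
            mesh = tetrahedralize(surface, c.get("h", 0.05),
                                  seed=config.stage_seed("mesh"))
            io.write_vtu(mesh, out / "mesh.vtu")
            record("mesh", out / "mesh.vtu")
            q = mesh.quality_report()
            summary["mesh"] = {"n_cells": q.n_cells,
                               "n_vertices": q.n_vertices,
                               "total_volume_mm3": q.total_volume}
            logger.info("stage mesh: %s", q)

        if "simulate" in st:
            if mesh is None:
                raise PipelineError("simulate stage requires the mesh stage")
            c = st["simulate"]
            fluid = solver.FluidProperties(
                density=c.get("density", 1060.0),
                viscosity=c.get("viscosity", 3.71e-3))
            period = c.get("period", 0.4)
            waves = {"inlet": solver.PressureWaveform.sinusoid(
                c.get("inlet_mean", 12.0), c.get("inlet_amplitude", 8.0),
                period)}
            for name in mesh.facet_names.values():
                if name.startswith("outlet"):
                    waves[name] = solver.PressureWaveform.constant(
                        c.get("outlet_pressure", 0.0), period)
            bcs = solver.BoundarySpec(pressures=waves)
            ts = solver.TimeSteppingSpec(dt=c.get("dt", 0.01),
                                         n_cycles=c.get("n_cycles", 4))
            sol = solver.simulate(mesh, fluid, bcs, ts)
            np.savez(out / "solution.npz", times=sol.times, u=sol.u, p=sol.p)
            record("solution", out / "solution.npz")
            diag = solver.diagnostics(sol)
            summary["simulate"] = {
                "n_steps": len(sol.times) - 1,
                "max_mass_imbalance": float(diag.mass_imbalance.max()),
                "peak_velocity_m_s": float(diag.peak_velocity.max()),
                "max_reynolds": float(diag.reynolds.max()),
            }
            summary["phases"] = hemo_post.flow_phases(sol, period)
            logger.info("stage simulate: %s", summary["simulate"])

        if "wss" in st and sol is not None:
            wss = hemo_post.compute_wss(sol)
            rs = hemo_post.regional_summary(
                wss, surface.region_names if surface else None)
            rs.table.to_csv(out / "wss_regional.csv", index=False)
            rs.peaks.to_csv(out / "wss_peaks.csv", index=False)
            record("wss_regional", out / "wss_regional.csv")
            record("wss_peaks", out / "wss_peaks.csv")
            ip = summary.get("phases", {}).get("peak", len(sol.times) - 1)
            summary["wss"] = {
                "peak_phase_index": int(ip),
                "regional_mean_Pa": {
                    r.region_name: float(r.mean_Pa)
                    for r in rs.table[np.isclose(rs.table.time_s,
                                                 sol.times[ip])].itertuples()},
            }
            logger.info("stage wss done")

        if "streamlines" in st and sol is not None:
            c = st["streamlines"]
            up = surface.metadata["upstream_plane"]
            dn = surface.metadata["downstream_plane"]
            sp = surface.metadata.get("seed_plane", up)
            ip = summary.get("phases", {}).get("peak", len(sol.times) - 1)
            seeds = sl.seed_cross_section(
                mesh, sp["point"], sp["normal"], c.get("n_seeds", 60),
                seed=config.stage_seed("streamlines"))
            bundle = sl.trace_streamlines(
                sl.FrozenField(sol, ip), seeds, step=c.get("step", 0.02),
                max_length=c.get("max_length", 4.0), mesh=mesh)
            arch_tags = [t for t, n in surface.region_names.items()
                         if n.startswith("AA")]
            sl.classify_by_branch(bundle, surface.classify_points, arch_tags)
            io.write_vtp(bundle.polylines, out / "streamlines.vtp")
            record("streamlines", out / "streamlines.vtp")
            rep = sl.ordering_analysis(bundle, (up["point"], up["normal"]),
                                       (dn["point"], dn["normal"]))
            rep.branch_table.to_csv(out / "ordering.csv", index=False)
            record("ordering", out / "ordering.csv")
            summary["streamlines"] = {
                "kendall_tau": rep.kendall_tau,
                "adjacency_preserved": rep.adjacency_preserved,
                "split_branches": [
                    [surface.region_names.get(a, a),
                     surface.region_names.get(b, b)]
                    for a, b in rep.split_branches],
            }
            logger.info("stage streamlines: %s", summary["streamlines"])

        if "geometry" in st and mesh is not None:
            cl = vg.extract_centerline(mesh, "inlet", "outlet", branch="OFT-DA")
            io.write_vtp([cl.points], out / "centerline.vtp",
                         point_data={"mis_radius_mm": cl.radii})
            record("centerline", out / "centerline.vtp")
            bm = vg.branch_metrics(cl, mesh)
            import pandas as pd
            pd.DataFrame([bm.as_row()]).to_csv(out / "branch_metrics.csv",
                                               index=False)
            record("branch_metrics", out / "branch_metrics.csv")
            summary["geometry"] = {k: (None if v is None else float(v))
                                   for k, v in bm.as_row().items()
                                   if k != "branch"}
            logger.info("stage geometry: %s", summary["geometry"])

        if "landmarks" in st:
            c = st["landmarks"]
            lspec = phantoms.LandmarkPopulationSpec(
                n_specimens=c.get("n_specimens", 8),
                n_outliers=c.get("n_outliers", 2),
                isotropic_noise_sd=c.get("noise_sd", 0.002),
                seed=config.stage_seed("landmarks"))
            if c.get("mode_sds"):
                tmpl, labels = phantoms.default_landmark_template()
                modes = phantoms.default_mode_vectors(tmpl, labels)
                k = min(len(modes), len(c["mode_sds"]))
                lspec = phantoms.LandmarkPopulationSpec(
                    n_specimens=lspec.n_specimens,
                    n_outliers=lspec.n_outliers,
                    isotropic_noise_sd=lspec.isotropic_noise_sd,
                    mode_vectors=tuple(modes[:k]),
                    mode_sds=tuple(c["mode_sds"][:k]), seed=lspec.seed)
            cohort = phantoms.make_landmark_population(lspec)
            io.write_cohort(cohort, out / "landmarks")
            record("landmark_csv", out / "landmarks" / "cohort.csv")
        else:
            cohort = None
            if "morphometrics" in st and st["morphometrics"].get("cohort_dir"):
                from .io import read_cohort
                cohort = read_cohort(st["morphometrics"]["cohort_dir"])

        if "morphometrics" in st and cohort is not None:
            c = st["morphometrics"]
            g = morphometrics.gpa(cohort,
                                  with_scaling=c.get("with_scaling", False))
            p = morphometrics.pca_shapes(g)
            flags = morphometrics.detect_outliers(p, k=2)
            import pandas as pd
            pd.DataFrame(g.aligned.reshape(len(g.aligned), -1)).to_csv(
                out / "aligned.csv", index=False)
            pd.DataFrame(p.scores).to_csv(out / "pc_scores.csv", index=False)
            io.write_fcsv(g.mean_shape, out / "mean_shape.fcsv")
            (out / "outliers.json").write_text(json.dumps(
                {"flagged": [cohort.ids[i] for i in np.nonzero(flags)[0]],
                 "coordinates": g.coordinates_name}, sort_keys=True))
            _, radii, axes = morphometrics.landmark_variance(g)
            ell = pd.DataFrame(
                np.hstack([radii, axes.transpose(0, 2, 1).reshape(
                    len(radii), 9)]),
                columns=[f"radius_{i}" for i in range(3)]
                + [f"axis{i}_{c}" for i in range(3) for c in "xyz"])
            ell.insert(0, "landmark", np.arange(len(radii)))
            ell.to_csv(out / "variance_ellipsoids.csv", index=False)
            for name in ("aligned.csv", "pc_scores.csv", "mean_shape.fcsv",
                         "outliers.json", "variance_ellipsoids.csv"):
                record(name.split(".")[0], out / name)
            summary["morphometrics"] = {
                "coordinates": g.coordinates_name,
                "variance_ratio": p.variance_ratio[:3].tolist(),
                "n_outliers_flagged": int(flags.sum()),
            }
            logger.info("stage morphometrics: %s", summary["morphometrics"])
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage failed: {e}") from e

    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, default=float))
    artifacts["summary"] = "summary.json"
    manifest = {
        "seed": config.seed,
        "stages": config.stages,
        "units": config.units,
        "artifacts": {
            name: {"path": rel, "sha256": _sha256(out / rel),
                   "bytes": (out / rel).stat().st_size}
            for name, rel in sorted(artifacts.items())},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return RunReport(out_dir=out, artifacts=artifacts, summary=summary,
                     manifest_path=mpath)


def verify_manifest(out_dir) -> bool:
    """Re-hash every artifact listed in the manifest."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    for name, meta in manifest["artifacts"].items():
        if _sha256(out / meta["path"]) != meta["sha256"]:
            return False
    return True
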