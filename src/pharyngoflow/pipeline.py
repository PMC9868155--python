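"""End-to-end report: synth → slice → solve → postproc → classify.

Chains the library stages into the Table-style morphometry report, the
per-plane pressure table and the per-subsegment resistance/loss table,
plus the three-level flow segmentation.  Each stage is timed and logged to
standard error; a failure raises :class:`StageError` naming the stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import geometry, io, postproc, synthetic
from .reduced_flow import FluidProperties, SolverConfig, solve_quasi1d

__all__ = ["StageError", "ReportResult", "run_report"]

log = logging.getLogger("pharyngoflow")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, exc: BaseException):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage
        self.__cause__ = exc


@dataclass
class ReportResult:
    sections: list
    morphometry: geometry.MorphometryReport
    planes: pd.DataFrame
    subsegments: pd.DataFrame
    levels: _classify.LevelSegmentation
    paths: dict


def _stage(name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs", name, dt)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_report(cfg: io.RunConfig) -> ReportResult:
    """Run the full pipeline described by a :class:`~pharyngoflow.io.RunConfig`.

    Deterministic under a fixed seed: the same configuration writes
    byte-identical CSV/JSON outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)

    with _stage("synth"):
        if cfg.template is not None:
            spec = synthetic.SyntheticSpec.from_template(
                cfg.template, seed=cfg.seed, spacing_mm=cfg.spacing_mm
            )
            profile = synthetic.make_area_profile(spec)
            mesh = synthetic.make_surface_mesh(profile, spec)
            top_z, bottom_z = float(profile.z_mm[0]), float(profile.z_mm[-1])
            dividing = spec.dividing_plane
        elif cfg.mesh_path is not None:
            mesh = io.read_surface_mesh(cfg.mesh_path)
            top_z = float(mesh.bounds[1][2])
            bottom_z = float(mesh.bounds[0][2])
            dividing = cfg.dividing_plane
        else:
            raise ValueError("config must set either 'template' or 'mesh_path'")
        if dividing is None:
            raise ValueError(
                "missing required field 'dividing_plane': the soft-palate-tip "
                "landmark cannot be detected from a bare mesh"
            )

    with _stage("slice"):
        sections = geometry.slice_airway(mesh, top_z, bottom_z, cfg.spacing_mm)
        geometry.assign_regions(sections, dividing)
        geometry.area_ratio_series(sections)
        morpho = geometry.morphometry_report(sections, cfg.spacing_mm)
        amin_plane = geometry.find_plane_amin(sections)
        sliced_profile = synthetic.AreaProfile(
            z_mm=np.array([s.z_mm for s in sections]),
            area_mm2=np.array([s.area_mm2 for s in sections]),
            landmarks={"top": 1, "dividing": dividing, "bottom": len(sections)},
        )

    with _stage("solve"):
        fluid = FluidProperties(rho=cfg.fluid.rho, mu=cfg.fluid.mu)
        solver_cfg = SolverConfig(
            Q_lpm=cfg.solver.Q_lpm,
            inlet_total_pressure_pa=cfg.solver.inlet_total_pressure_pa,
            friction_model=cfg.solver.friction_model,
            expansion_loss=cfg.solver.expansion_loss,
            contraction_loss_coeff=cfg.solver.contraction_loss_coeff,
        )
        solve_quasi1d(sliced_profile, fluid, solver_cfg)  # validates the profile

    with _stage("flow"):
        n = len(sections)
        beta = np.ones(n)
        if amin_plane < n:
            frac = np.arange(n - amin_plane + 1) / max(n - amin_plane, 1)
            beta[amin_plane - 1 :] = 1.0 - (1.0 - cfg.flow.beta_downstream) * frac
        samples = synthetic.make_flow_field(
            sliced_profile,
            Q_lpm=cfg.solver.Q_lpm,
            beta=beta,
            recirc_strength=cfg.flow.recirc_strength,
            tke_model=cfg.flow.tke_model,
            seed=cfg.seed,
            fluid=fluid,
            solver_config=solver_cfg,
        )

    with _stage("postproc"):
        planes = postproc.plane_table(samples, sections=sections)
        subsegs = geometry.build_subsegments(sections, mesh)
        wall_areas = [s.wall_area_mm2 for s in subsegs]
        sub_table = postproc.subsegment_table(
            planes, samples.wall, Q_lpm=cfg.solver.Q_lpm, rho=fluid.rho,
            wall_areas_mm2=wall_areas,
        )

    with _stage("classify"):
        rev = []
        for _, grp in samples.planes.groupby("plane_index", sort=True):
            rev.append(
                _classify.reverse_flow_fraction(
                    grp[["ux_ms", "uy_ms", "uz_ms"]].to_numpy(),
                    grp["area_weight_mm2"].to_numpy(),
                    samples.flow_direction,
                )
            )
        seg = _classify.classify_levels(
            [s.area_mm2 for s in sections],
            amin_plane,
            rev,
            theta_exp=cfg.classifier.theta_exp,
            theta_rec=cfg.classifier.theta_rec,
        )
        # a subsegment inherits the level of its upper plane
        sub_table["level"] = seg.labels[:-1]

    with _stage("write"):
        plane_out = planes.copy()
        plane_out["region"] = [s.region for s in sections]
        plane_out["reverse_flow_fraction"] = rev
        paths = {
            "morphometry": outdir / "morphometry.json",
            "planes": outdir / "planes.csv",
            "subsegments": outdir / "subsegments.csv",
            "levels": outdir / "levels.json",
        }
        io.write_json(morpho.to_dict(), paths["morphometry"])
        io.write_table(plane_out, paths["planes"])
        io.write_table(sub_table, paths["subsegments"])
        io.write_json(seg.to_dict(), paths["levels"])

    return ReportResult(
        sections=sections,
        morphometry=morpho,
        planes=plane_out,
        subsegments=sub_table,
        levels=seg,
        paths={k: str(v) for k, v in paths.items()},
    )
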