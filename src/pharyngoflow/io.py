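"""File formats and run configuration.

STL (binary and ascii) for surface meshes; CSV for plane/wall samples and
per-plane / per-subsegment tables; JSON for morphometry and level
segmentations; YAML for the run configuration that drives the end-to-end
report pipeline.  All floats are written with a fixed "%.10g" format so a
given configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from pydantic import BaseModel, Field

from .classify import DEFAULT_THETA_EXP, DEFAULT_THETA_REC
from .synthetic import FlowFieldSamples

__all__ = [
    "RunConfig",
    "read_surface_mesh",
    "write_surface_mesh",
    "write_plane_samples",
    "read_plane_samples",
    "write_wall_samples",
    "read_wall_samples",
    "write_table",
    "write_json",
]

FLOAT_FMT = "%.10g"

PLANE_SAMPLE_COLUMNS = [
    "plane_index", "z_mm", "x_mm", "y_mm", "area_weight_mm2",
    "ux_ms", "uy_ms", "uz_ms", "ps_pa", "tke_m2s2",
]
WALL_SAMPLE_COLUMNS = ["subseg_index", "patch_area_mm2", "wss_pa"]


class FluidConfig(BaseModel):
    rho: float = 1.204
    mu: float = 1.81e-5


class SolverSection(BaseModel):
    Q_lpm: float = 18.0
    inlet_total_pressure_pa: float = 0.0
    friction_model: str = "blended"
    expansion_loss: str = "borda_carnot"
    contraction_loss_coeff: float = 0.0


class FlowSection(BaseModel):
    recirc_strength: float = 0.2
    beta_downstream: float = 0.6
    tke_model: str = "shear"


class ClassifierSection(BaseModel):
    theta_exp: float = DEFAULT_THETA_EXP
    theta_rec: float = DEFAULT_THETA_REC


class RunConfig(BaseModel):
    """End-to-end report configuration.

    Either ``template`` (one of the eight built-in airway templates) or
    ``mesh_path`` + ``dividing_plane`` must be given; the dividing plane
    (soft-palate tip) is an anatomical landmark that cannot be detected
    from a bare mesh.
    """

    template: str | None = None
    mesh_path: str | None = None
    dividing_plane: int | None = None
    spacing_mm: float = Field(default=0.5, gt=0)
    output_dir: str = "results/report"
    seed: int = 0
    fluid: FluidConfig = FluidConfig()
    solver: SolverSection = SolverSection()
    flow: FlowSection = FlowSection()
    classifier: ClassifierSection = ClassifierSection()
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def read_surface_mesh(path) -> trimesh.Trimesh:
    """Load a binary or ascii STL surface mesh (units mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty mesh file: {path}")
    mesh = trimesh.load(str(path), file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) < 4:
        raise ValueError(f"malformed or degenerate mesh in {path}")
    return mesh


def write_surface_mesh(mesh: trimesh.Trimesh, path, ascii: bool = False) -> None:
    """Write STL; binary by default, ascii on request."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = mesh.export(file_type="stl_ascii" if ascii else "stl")
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


def write_plane_samples(samples: FlowFieldSamples, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    samples.planes[PLANE_SAMPLE_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_plane_samples(path, flow_direction=(0.0, 0.0, -1.0), rho: float = 1.204) -> FlowFieldSamples:
    df = pd.read_csv(path)
    missing = set(PLANE_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plane sample CSV missing columns: {sorted(missing)}")
    return FlowFieldSamples(
        planes=df,
        wall=pd.DataFrame(columns=WALL_SAMPLE_COLUMNS),
        flow_direction=np.asarray(flow_direction, dtype=float),
        rho=rho,
    )


def write_wall_samples(samples: FlowFieldSamples, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    samples.wall[WALL_SAMPLE_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_wall_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WALL_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"wall sample CSV missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
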