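"""Parametric synthetic upper-airway geometries and flow fields.

The velopharyngeal + oropharyngeal segment (hard palate to epiglottis tip)
is, to first order, an hourglass: a tapering lumen down to a minimum-area
cross-section (plane_Amin), optionally a near-constant constricted segment
("plateau"), then a progressive expansion.  This module generates

* axial area profiles A(z) on a uniform 0.5 mm grid,
* watertight open-ended triangulated surface meshes realising a profile,
* discrete flow-field samples with the jet / recirculation structure that
  inspiratory flow develops downstream of the constriction: a forward
  high-velocity core of area fraction beta and an annular reversed-flow
  region at a fraction gamma of the core speed, normalised so the net
  volumetric flux on every plane equals the prescribed flow rate exactly.

Geometries are parameterised either freely or from eight templates that
emulate the morphometry of four subjects (Friedman tongue position grades
I-IV) each CT-scanned mouth-closed (MC) and mouth-open (MO) in a published
clinical CFD study of mouth opening in obstructive sleep apnoea.  Axial
convention: planes are perpendicular to the z axis, z DECREASES downstream,
and 1-based plane numbers increase downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

__all__ = [
    "AreaProfile",
    "SyntheticSpec",
    "FlowFieldSamples",
    "FluxNormalizationError",
    "TEMPLATES",
    "make_area_profile",
    "make_surface_mesh",
    "make_flow_field",
    "perturb_mesh",
]

#: default axial grid spacing, mm
DEFAULT_SPACING_MM = 0.5

LPM_TO_M3S = 1.0 / 60_000.0


class FluxNormalizationError(ValueError):
    """Raised when (beta, gamma) admit no positive net flux on a plane."""


@dataclass(frozen=True)
class AreaProfile:
    """Axial cross-sectional area function of an airway segment.

    Attributes
    ----------
    z_mm:
        Axial plane coordinates in mm, strictly decreasing downstream.
    area_mm2:
        Cross-sectional areas in mm², strictly positive.
    landmarks:
        1-based plane numbers of the named anatomical landmarks:
        ``top`` (plane I, hard-palate level), ``dividing`` (plane III,
        soft-palate tip) and ``bottom`` (plane IV, epiglottis tip).
    """

    z_mm: np.ndarray
    area_mm2: np.ndarray
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        z = np.asarray(self.z_mm, dtype=float)
        a = np.asarray(self.area_mm2, dtype=float)
        object.__setattr__(self, "z_mm", z)
        object.__setattr__(self, "area_mm2", a)
        if z.ndim != 1 or z.size < 2 or z.shape != a.shape:
            raise ValueError("z_mm and area_mm2 must be 1-D arrays of equal length >= 2")
        dz = np.diff(z)
        if not np.all(dz < 0):
            raise ValueError("z_mm must be strictly decreasing downstream")
        if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-9):
            raise ValueError("z spacing must be constant")
        if np.any(a <= 0):
            raise ValueError("all areas must be positive")
        lm = dict(self.landmarks)
        if lm:
            t, d, b = lm.get("top", 1), lm.get("dividing"), lm.get("bottom", self.n_planes)
            if d is not None and not (t < d < b):
                raise ValueError("landmarks must satisfy top < dividing < bottom")
            for k, v in lm.items():
                if v is not None and not (1 <= v <= self.n_planes):
                    raise ValueError(f"landmark {k!r}={v} outside 1..{self.n_planes}")
        object.__setattr__(self, "landmarks", lm)

    @property
    def n_planes(self) -> int:
        return int(self.z_mm.size)

    @property
    def spacing_mm(self) -> float:
        return float(self.z_mm[0] - self.z_mm[1])

    @property
    def amin_plane(self) -> int:
        """1-based plane number of the global area minimum (first on ties)."""
        return int(np.argmin(self.area_mm2)) + 1


# Template morphometry: four subjects (FTP grades I-IV), mouth-closed (MC)
# and mouth-open (MO).  Lengths (cm), total plane counts at 0.5 mm spacing,
# dividing-plane numbers and per-region minimum-area planes are the measured
# values of the clinical study these synthetic airways emulate; the template
# constriction is placed at the overall (smaller) of the two regional minima.
# `reference_amin_resistance_pa` is the subsegmental resistance reported by
# that study's 3-D CFD at the constriction subsegment, where reported (the
# study prints the unit as Pa); it is reference metadata, not a model output.
TEMPLATES: dict[str, dict] = {
    "FTP1_MC": dict(length_cm=4.75, dividing_plane=58, velo_amin_plane=44,
                    velo_amin_cm2=0.8288, oro_amin_plane=59, oro_amin_cm2=2.037,
                    plateau_mm=0.0),
    "FTP1_MO": dict(length_cm=6.65, dividing_plane=70, velo_amin_plane=54,
                    velo_amin_cm2=2.226, oro_amin_plane=102, oro_amin_cm2=1.153,
                    plateau_mm=0.0),
    "FTP2_MC": dict(length_cm=4.72, dividing_plane=54, velo_amin_plane=14,
                    velo_amin_cm2=0.6883, oro_amin_plane=61, oro_amin_cm2=1.177,
                    plateau_mm=20.0),
    "FTP2_MO": dict(length_cm=5.65, dividing_plane=68, velo_amin_plane=54,
                    velo_amin_cm2=0.6862, oro_amin_plane=77, oro_amin_cm2=0.8473,
                    plateau_mm=12.5, reference_amin_resistance_pa=0.8271),
    "FTP3_MC": dict(length_cm=4.52, dividing_plane=68, velo_amin_plane=47,
                    velo_amin_cm2=0.6074, oro_amin_plane=69, oro_amin_cm2=1.649,
                    plateau_mm=0.0),
    "FTP3_MO": dict(length_cm=5.01, dividing_plane=68, velo_amin_plane=49,
                    velo_amin_cm2=0.6035, oro_amin_plane=69, oro_amin_cm2=1.533,
                    plateau_mm=0.0, reference_amin_resistance_pa=0.7624),
    "FTP4_MC": dict(length_cm=4.53, dividing_plane=51, velo_amin_plane=38,
                    velo_amin_cm2=1.4440, oro_amin_plane=52, oro_amin_cm2=2.085,
                    plateau_mm=0.0),
    "FTP4_MO": dict(length_cm=5.12, dividing_plane=53, velo_amin_plane=41,
                    velo_amin_cm2=0.5443, oro_amin_plane=54, oro_amin_cm2=0.6441,
                    plateau_mm=6.0, reference_amin_resistance_pa=1.27),
}


def _n_planes_for_length(length_mm: float, spacing_mm: float) -> int:
    return int(np.floor(length_mm / spacing_mm * (1 + 1e-9))) + 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic hourglass airway.

    ``amin_relative_position`` places the constriction along the segment
    (0 = top, 1 = bottom); ``constriction_plateau_mm`` is the length of the
    near-constant constricted segment that starts at plane_Amin (areas stay
    within 5% of the minimum over the plateau); the lumen then expands to
    ``expansion_area_mm2``.  ``inlet_area_mm2`` defaults to the expansion
    area.  Cross-section shape (circle or ellipse) is a modelling choice:
    area, not shape, is the controlled quantity.
    """

    template: str = "custom"
    length_mm: float = 50.0
    amin_area_mm2: float = 100.0
    amin_relative_position: float = 0.4
    constriction_plateau_mm: float = 0.0
    expansion_area_mm2: float = 250.0
    inlet_area_mm2: float | None = None
    cross_section_shape: str = "circle"
    ellipse_aspect: float = 1.0
    n_theta: int = 64
    noise_amplitude: float = 0.0
    seed: int = 0
    spacing_mm: float = DEFAULT_SPACING_MM
    dividing_plane: int | None = None

    def __post_init__(self):
        if self.amin_area_mm2 <= 0 or self.expansion_area_mm2 <= 0:
            raise ValueError("areas must be positive")
        if self.amin_area_mm2 >= self.expansion_area_mm2:
            raise ValueError("amin_area_mm2 must be smaller than expansion_area_mm2")
        if not (0.0 < self.amin_relative_position < 1.0):
            raise ValueError("amin_relative_position must lie strictly in (0, 1)")
        if self.constriction_plateau_mm < 0:
            raise ValueError("constriction_plateau_mm must be >= 0")
        if self.n_theta < 16:
            raise ValueError("n_theta must be >= 16")
        if self.cross_section_shape not in ("circle", "ellipse"):
            raise ValueError("cross_section_shape must be 'circle' or 'ellipse'")
        if self.ellipse_aspect <= 0:
            raise ValueError("ellipse_aspect must be positive")
        if self.spacing_mm <= 0 or self.length_mm <= self.spacing_mm:
            raise ValueError("invalid length/spacing")

    @property
    def n_planes(self) -> int:
        return _n_planes_for_length(self.length_mm, self.spacing_mm)

    @property
    def resolved_inlet_area_mm2(self) -> float:
        return self.expansion_area_mm2 if self.inlet_area_mm2 is None else self.inlet_area_mm2

    @classmethod
    def from_template(cls, name: str, **overrides) -> "SyntheticSpec":
        """Build the spec of one of the eight FTP/mouth-position templates."""
        if name not in TEMPLATES:
            raise KeyError(f"unknown template {name!r}; choose from {sorted(TEMPLATES)}")
        t = TEMPLATES[name]
        spacing = overrides.pop("spacing_mm", DEFAULT_SPACING_MM)
        length_mm = t["length_cm"] * 10.0
        n = _n_planes_for_length(length_mm, spacing)
        # place the single modelled constriction at the overall minimum
        if t["velo_amin_cm2"] <= t["oro_amin_cm2"]:
            amin_plane, amin_cm2 = t["velo_amin_plane"], t["velo_amin_cm2"]
        else:
            amin_plane, amin_cm2 = t["oro_amin_plane"], t["oro_amin_cm2"]
        params = dict(
            template=name,
            length_mm=length_mm,
            amin_area_mm2=amin_cm2 * 100.0,
            amin_relative_position=(amin_plane - 1) / (n - 1),
            constriction_plateau_mm=t["plateau_mm"],
            spacing_mm=spacing,
            dividing_plane=t["dividing_plane"],
        )
        params.update(overrides)
        return cls(**params)


def make_area_profile(spec: SyntheticSpec) -> AreaProfile:
    """Generate the smooth axial area profile A(z) for a spec.

    The profile has a unique global minimum equal to ``amin_area_mm2`` at
    the requested relative position, a monotone cosine taper upstream, a
    plateau (areas within 5% of the minimum) of the requested length
    immediately downstream, and a monotone cosine expansion to
    ``expansion_area_mm2`` below.
    """
    n = spec.n_planes
    h = spec.spacing_mm
    z = spec.length_mm - h * np.arange(n)

    i_min = int(round(spec.amin_relative_position * (n - 1)))
    i_min = min(max(i_min, 1), n - 2)
    p = int(round(spec.constriction_plateau_mm / h))
    i_pe = i_min + p  # plateau end index
    if i_pe > n - 2:
        raise ValueError(
            f"plateau of {spec.constriction_plateau_mm} mm does not fit between the "
            f"constriction (plane {i_min + 1}) and the segment end"
        )

    a = np.empty(n)
    amin = spec.amin_area_mm2
    inlet = spec.resolved_inlet_area_mm2
    # upstream taper (strictly decreasing)
    t_up = np.arange(i_min + 1) / i_min
    a[: i_min + 1] = amin + (inlet - amin) * (1.0 + np.cos(np.pi * t_up)) / 2.0
    # plateau: strictly increasing but within 5% of the minimum, so the
    # global minimum stays unique at i_min
    if p > 0:
        t_pl = np.arange(1, p + 1) / p
        a[i_min + 1 : i_pe + 1] = amin * (1.0 + 0.04 * t_pl**2)
    a_pe = a[i_pe]
    if spec.expansion_area_mm2 <= a_pe:
        raise ValueError("expansion_area_mm2 must exceed the plateau-end area")
    # downstream expansion (strictly increasing)
    t_dn = np.arange(1, n - i_pe) / (n - 1 - i_pe)
    a[i_pe + 1 :] = a_pe + (spec.expansion_area_mm2 - a_pe) * (1.0 - np.cos(np.pi * t_dn)) / 2.0

    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        raw = rng.standard_normal(n)
        kernel = np.hanning(9)
        smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
        bump = 1.0 + spec.noise_amplitude * smooth
        # never perturb the constriction itself off its configured area
        bump[i_min] = 1.0
        a = np.maximum(a * bump, 0.5 * amin)
        a[i_min] = amin

    landmarks = {"top": 1, "dividing": spec.dividing_plane, "bottom": n}
    return AreaProfile(z_mm=z, area_mm2=a, landmarks=landmarks)


def _ring_radii(area_mm2: float, shape: str, aspect: float) -> tuple[float, float]:
    """Semi-axes (a, b) of the cross-section with the given enclosed area."""
    if shape == "circle" or aspect == 1.0:
        r = np.sqrt(area_mm2 / np.pi)
        return r, r
    return np.sqrt(area_mm2 * aspect / np.pi), np.sqrt(area_mm2 / (np.pi * aspect))


def make_surface_mesh(
    profile: AreaProfile,
    spec: SyntheticSpec | None = None,
    *,
    n_theta: int | None = None,
    cross_section_shape: str | None = None,
    ellipse_aspect: float | None = None,
) -> trimesh.Trimesh:
    """Triangulate an open-ended tube realising the area profile.

    Each grid plane carries an inscribed ``n_theta``-gon of the circular or
    elliptical cross-section; consecutive rings are stitched with outward-
    facing triangles.  Vertices are snapped to single precision so STL
    export round-trips exactly in both binary and ascii form.  The inscribed
    polygon area is area * (n/2π)·sin(2π/n) — within 0.2% of the profile
    area at n_theta = 64 and converging as n_theta grows.
    """
    if np.any(profile.area_mm2 <= 0):
        raise ValueError("degenerate (zero-area) sections cannot be meshed")
    n_t = n_theta if n_theta is not None else (spec.n_theta if spec else 64)
    shape = cross_section_shape or (spec.cross_section_shape if spec else "circle")
    aspect = ellipse_aspect if ellipse_aspect is not None else (spec.ellipse_aspect if spec else 1.0)
    if n_t < 16:
        raise ValueError("n_theta must be >= 16")
    n_z = profile.n_planes
    theta = 2.0 * np.pi * np.arange(n_t) / n_t
    ct, st = np.cos(theta), np.sin(theta)

    verts = np.empty((n_z * n_t, 3))
    for i, (zi, ai) in enumerate(zip(profile.z_mm, profile.area_mm2)):
        sa, sb = _ring_radii(ai, shape, aspect)
        rows = slice(i * n_t, (i + 1) * n_t)
        verts[rows, 0] = sa * ct
        verts[rows, 1] = sb * st
        verts[rows, 2] = zi

    # two triangles per quad between ring i (upper) and ring i+1 (lower)
    i_idx = np.repeat(np.arange(n_z - 1), n_t)
    t_idx = np.tile(np.arange(n_t), n_z - 1)
    t_next = (t_idx + 1) % n_t
    v00 = i_idx * n_t + t_idx
    v01 = i_idx * n_t + t_next
    v10 = (i_idx + 1) * n_t + t_idx
    v11 = (i_idx + 1) * n_t + t_next
    faces = np.concatenate(
        [np.column_stack([v00, v10, v01]), np.column_stack([v01, v10, v11])]
    )
    verts = verts.astype(np.float32).astype(np.float64)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def perturb_mesh(mesh: trimesh.Trimesh, amplitude_mm: float, seed: int = 0) -> trimesh.Trimesh:
    """Return a copy with bounded random vertex displacements.

    Displacements are normal deviates truncated to ±``amplitude_mm`` per
    coordinate; amplitude 0 returns an identical copy.  Deterministic under
    a fixed seed.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    out = mesh.copy()
    if amplitude_mm == 0:
        return out
    rng = np.random.default_rng(seed)
    disp = np.clip(rng.standard_normal(out.vertices.shape) / 3.0, -1.0, 1.0) * amplitude_mm
    out.vertices = out.vertices + disp
    # crude self-intersection guard: warn when displacements rival the lumen radius
    r_min = np.sqrt(mesh.vertices[:, 0] ** 2 + mesh.vertices[:, 1] ** 2).min()
    if amplitude_mm > 0.25 * max(r_min, 1e-9):
        warnings.warn(
            f"perturbation amplitude {amplitude_mm} mm may self-intersect the lumen "
            f"(min ring radius {r_min:.3g} mm)",
            RuntimeWarning,
        )
    return out


@dataclass(frozen=True)
class FlowFieldSamples:
    """Discrete flow samples on cross-sectional planes and the lumen wall.

    ``planes`` has columns plane_index, z_mm, x_mm, y_mm, area_weight_mm2,
    ux_ms, uy_ms, uz_ms, ps_pa, tke_m2s2 (one row per sample point);
    ``wall`` has subseg_index, patch_area_mm2, wss_pa.  ``flow_direction``
    is the unit axial vector of bulk inspiratory flow (here (0, 0, −1):
    z decreases downstream); ``rho`` the gas density in kg/m³.
    """

    planes: "object"  # pandas.DataFrame
    wall: "object"  # pandas.DataFrame
    flow_direction: np.ndarray
    rho: float


def make_flow_field(
    profile: AreaProfile,
    Q_lpm: float = 18.0,
    beta=None,
    recirc_strength: float = 0.2,
    tke_model: str = "shear",
    seed: int = 0,
    fluid=None,
    solver_config=None,
    n_r: int = 8,
    n_theta: int = 16,
    n_wall_patches: int = 8,
) -> FlowFieldSamples:
    """Sample a jet/recirculation flow field consistent with the profile.

    On each plane a central jet core of area fraction beta carries forward
    flow at speed u_core while the surrounding annulus carries reversed flow
    at ``recirc_strength``·u_core, with u_core chosen so the net volumetric
    flux equals ``Q_lpm`` exactly.  Static pressures are taken from the
    quasi-1D reduced-order solve of the same profile; turbulence kinetic
    energy peaks at the core/recirculation interface; wall shear samples
    come from the solver's friction model with zero-mean patch jitter.

    ``beta`` may be None (default rule: 1 upstream of plane_Amin, ramping
    linearly to 0.6 at the outlet), a scalar, an array per plane, or a
    callable of the 0-based plane position fraction.
    """
    import pandas as pd

    from .reduced_flow import FluidProperties, SolverConfig, solve_quasi1d

    if not (0.0 <= recirc_strength < 1.0):
        raise ValueError("recirc_strength must lie in [0, 1)")
    n = profile.n_planes
    i_amin = profile.amin_plane - 1
    if beta is None:
        b = np.ones(n)
        if i_amin < n - 1:
            frac = np.arange(n - i_amin) / max(n - 1 - i_amin, 1)
            b[i_amin:] = 1.0 - 0.4 * frac
    elif callable(beta):
        b = np.array([float(beta(i / (n - 1))) for i in range(n)])
    else:
        b = np.broadcast_to(np.asarray(beta, dtype=float), (n,)).copy()
    if np.any(b <= 0) or np.any(b > 1):
        raise ValueError("beta must lie in (0, 1]")

    fluid = fluid or FluidProperties()
    cfg = solver_config or SolverConfig(Q_lpm=Q_lpm)
    if abs(cfg.Q_lpm - Q_lpm) > 1e-12:
        cfg = replace(cfg, Q_lpm=Q_lpm)
    sol = solve_quasi1d(profile, fluid, cfg)

    gamma = recirc_strength
    denom = b - gamma * (1.0 - b)
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise FluxNormalizationError(
            f"beta={b[bad[0]]:.3g}, gamma={gamma:.3g} give nonpositive net flux "
            f"on plane {bad[0] + 1}"
        )

    rng = np.random.default_rng(seed)
    Q_si = Q_lpm * LPM_TO_M3S
    theta = 2.0 * np.pi * (np.arange(n_theta) + 0.5) / n_theta
    rows = []
    for i in range(n):
        A_mm2 = profile.area_mm2[i]
        A_si = A_mm2 * 1e-6
        u_core = Q_si / (A_si * denom[i])
        R = np.sqrt(A_mm2 / np.pi)  # sampling uses circle-equivalent radius, mm
        r_core = R * np.sqrt(b[i])
        zones = [(0.0, r_core, -u_core)]  # forward: uz < 0 (downstream is -z)
        if b[i] < 1.0:
            zones.append((r_core, R, gamma * u_core))
        for r_lo, r_hi, uz in zones:
            frac_area = (r_hi**2 - r_lo**2) / R**2
            n_zone = max(1, int(round(n_r * frac_area)))
            # ring edges equally spaced in r^2 -> equal cell areas
            edges2 = np.linspace(r_lo**2, r_hi**2, n_zone + 1)
            cell_area = A_mm2 * frac_area / (n_zone * n_theta)
            for k in range(n_zone):
                r_c = np.sqrt(0.5 * (edges2[k] + edges2[k + 1]))
                if tke_model == "shear":
                    width = max(0.1 * R, 1e-6)
                    k_tke = 0.05 * u_core**2 * np.exp(-(((r_c - r_core) / width) ** 2))
                    k_tke *= 1.0 + 0.05 * rng.standard_normal()
                    k_tke = max(k_tke, 1e-8)
                else:
                    k_tke = 0.0
                for th in theta:
                    rows.append(
                        (
                            i + 1,
                            profile.z_mm[i],
                            r_c * np.cos(th),
                            r_c * np.sin(th),
                            cell_area,
                            0.0,
                            0.0,
                            uz,
                            sol.ps_pa[i],
                            k_tke,
                        )
                    )
    planes = pd.DataFrame(
        rows,
        columns=[
            "plane_index", "z_mm", "x_mm", "y_mm", "area_weight_mm2",
            "ux_ms", "uy_ms", "uz_ms", "ps_pa", "tke_m2s2",
        ],
    )
    planes["plane_index"] = planes["plane_index"].astype(int)

    # wall-shear patches per subsegment, circle-equivalent perimeter
    wall_rows = []
    h = profile.spacing_mm
    for j in range(n - 1):
        A_mean = 0.5 * (profile.area_mm2[j] + profile.area_mm2[j + 1])
        band_area = 2.0 * np.sqrt(np.pi * A_mean) * h  # mm²
        patch = band_area / n_wall_patches
        jitter = 0.02 * rng.standard_normal(n_wall_patches)
        jitter -= jitter.mean()  # zero-mean: preserves the area-weighted mean
        tau = sol.tau_wall_pa[j] * (1.0 + jitter)
        for p_ in range(n_wall_patches):
            wall_rows.append((j + 1, patch, tau[p_]))
    wall = pd.DataFrame(wall_rows, columns=["subseg_index", "patch_area_mm2", "wss_pa"])
    wall["subseg_index"] = wall["subseg_index"].astype(int)

    return FlowFieldSamples(
        planes=planes,
        wall=wall,
        flow_direction=np.array([0.0, 0.0, -1.0]),
        rho=fluid.rho,
    )
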