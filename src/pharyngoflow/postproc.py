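"""Post-processing of sampled flow fields on the plane stack.

Implements the standard CFD post-processing conventions for duct flow:
mass-flow-weighted plane averages of static pressure, velocity magnitude
and turbulence kinetic energy; dynamic pressure Pv = ½ρv² and total
pressure Pt = Ps + Pv; the relative total pressure Pt' referenced to
plane I (which removes upstream nasal losses from the datum); per-
subsegment wall-shear aggregation; the square-law subsegmental resistance

    ΔPt = K·Pv = R·V²  with  V = v_N·(A_N + A_{N+1})/2,

so R = (Pt_N − Pt_{N+1}) / (v_N·(A_N + A_{N+1})/2)² in Pa·s²·m⁻⁶; and the
decomposition of each subsegment's total-pressure drop into a frictional
part (wall-shear dissipation power per unit flow, exact in the Poiseuille
limit) and an interior part (separation/recirculation/turbulence), which
sum to ΔPt by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubsegmentRecord",
    "mass_flow_average",
    "dynamic_pressure",
    "total_pressure",
    "relative_total_pressure",
    "subsegment_wss",
    "subsegment_resistance",
    "loss_decomposition",
    "plane_table",
    "subsegment_table",
]


@dataclass(frozen=True)
class SubsegmentRecord:
    """Aerodynamic summary of one inter-plane lumen slab."""

    index: int
    dpt_pa: float  # Pt_N − Pt_{N+1}
    K: float  # dimensionless loss coefficient, ΔPt = K·Pv_N
    R_pa_s2_m6: float  # square-law resistance
    wss_mean_pa: float
    wall_area_mm2: float
    frictional_loss_pa: float
    interior_loss_pa: float
    level: int | None = None


def mass_flow_average(phi, u, area_weight, rho, flow_direction):
    """Mass-flow-weighted surface average of a field on one plane.

    Σ φ_i·ρ·|u_i·n|·a_i / Σ ρ·|u_i·n|·a_i with n the bulk flow direction;
    the magnitude of the axial mass flux weights each sample, so reversed
    (recirculating) flow still contributes.  Raises on zero total mass flux
    (all samples perpendicular to n), where the average is undefined.
    """
    phi = np.asarray(phi, dtype=float)
    u = np.atleast_2d(np.asarray(u, dtype=float))
    a = np.asarray(area_weight, dtype=float)
    n = np.asarray(flow_direction, dtype=float)
    n = n / np.linalg.norm(n)
    w = rho * np.abs(u @ n) * a
    denom = w.sum()
    if denom <= 0:
        raise ValueError("zero total mass flux on plane: mass-flow average undefined")
    return float((phi * w).sum() / denom)


def dynamic_pressure(v, rho):
    """Pv = ½ρv²; non-negative for any velocity."""
    return 0.5 * rho * np.asarray(v, dtype=float) ** 2


def total_pressure(ps, pv):
    """Pt = Ps + Pv (equivalently the gap Ps − (−Pv))."""
    return np.asarray(ps, dtype=float) + np.asarray(pv, dtype=float)


def relative_total_pressure(pt_series):
    """Pt'_N = Pt_N − Pt_1: total pressure referenced to plane I."""
    pt = np.asarray(pt_series, dtype=float)
    if pt.size == 0:
        raise ValueError("empty total-pressure series")
    return pt - pt[0]


def subsegment_wss(wss_pa, patch_area):
    """Area-weighted mean wall-shear magnitude over one wall band."""
    tau = np.asarray(wss_pa, dtype=float)
    a = np.asarray(patch_area, dtype=float)
    if a.size == 0 or a.sum() <= 0:
        raise ValueError("zero wall area: mean wall shear undefined")
    return float((tau * a).sum() / a.sum())


def subsegment_resistance(pt_N, pt_N1, v_N, A_N_m2, A_N1_m2, rho=1.204):
    """Square-law resistance and loss coefficient of subsegment N.

    R = (Pt_N − Pt_{N+1}) / (v_N·(A_N + A_{N+1})/2)²  [Pa·s²·m⁻⁶],
    K = (Pt_N − Pt_{N+1}) / Pv_N                      [dimensionless].

    Areas in m², v in m/s.  A negative ΔPt yields negative R/K — reported,
    not clamped, as a diagnostic of local total-pressure gain.
    """
    if v_N <= 0:
        raise ValueError("v_N must be positive")
    if A_N_m2 <= 0 or A_N1_m2 <= 0:
        raise ValueError("areas must be positive")
    dpt = pt_N - pt_N1
    V = v_N * 0.5 * (A_N_m2 + A_N1_m2)
    R = dpt / V**2
    K = dpt / (0.5 * rho * v_N**2)
    return R, K


def loss_decomposition(dpt_pa, wss_mean_pa, wall_area_m2, v_mean_ms, Q_m3s):
    """Split a subsegment's ΔPt into frictional and interior components.

    frictional = τ̄_w·A_wall·v̄_N / Q  — the wall dissipation power per unit
    volumetric flow, which equals ΔPt exactly for fully developed laminar
    pipe flow; interior = ΔPt − frictional (may be negative; flagged by the
    caller, never clamped).
    """
    if Q_m3s <= 0:
        raise ValueError("Q must be positive")
    frictional = wss_mean_pa * wall_area_m2 * v_mean_ms / Q_m3s
    return frictional, dpt_pa - frictional


def plane_table(samples, sections=None, areas_mm2=None, z_mm=None) -> pd.DataFrame:
    """Mass-flow-average a :class:`~pharyngoflow.synthetic.FlowFieldSamples`
    plane set into a per-plane table.

    Returns columns plane_index, z_mm, area_mm2, ps_pa, v_ms, tke_m2s2,
    pv_pa, pt_pa, pt_prime_pa.  Plane areas come from ``sections`` (slicer
    output) when given, else from the sample area weights.
    """
    df = samples.planes
    n_dir = samples.flow_direction
    rho = samples.rho
    rows = []
    for idx, grp in df.groupby("plane_index", sort=True):
        u = grp[["ux_ms", "uy_ms", "uz_ms"]].to_numpy()
        a = grp["area_weight_mm2"].to_numpy()
        vmag = np.linalg.norm(u, axis=1)
        ps = mass_flow_average(grp["ps_pa"].to_numpy(), u, a, rho, n_dir)
        v = mass_flow_average(vmag, u, a, rho, n_dir)
        tke = mass_flow_average(grp["tke_m2s2"].to_numpy(), u, a, rho, n_dir)
        rows.append((int(idx), float(grp["z_mm"].iloc[0]), float(a.sum()), ps, v, tke))
    out = pd.DataFrame(rows, columns=["plane_index", "z_mm", "area_mm2", "ps_pa", "v_ms", "tke_m2s2"])
    if sections is not None:
        area_map = {s.index: s.area_mm2 for s in sections}
        out["area_mm2"] = out["plane_index"].map(area_map)
        z_map = {s.index: s.z_mm for s in sections}
        out["z_mm"] = out["plane_index"].map(z_map)
    elif areas_mm2 is not None:
        out["area_mm2"] = np.asarray(areas_mm2, dtype=float)
        if z_mm is not None:
            out["z_mm"] = np.asarray(z_mm, dtype=float)
    out["pv_pa"] = dynamic_pressure(out["v_ms"].to_numpy(), rho)
    out["pt_pa"] = total_pressure(out["ps_pa"].to_numpy(), out["pv_pa"].to_numpy())
    out["pt_prime_pa"] = relative_total_pressure(out["pt_pa"].to_numpy())
    if sections is not None:
        for s, (_, r) in zip(sections, out.iterrows()):
            s.ps_pa, s.v_ms, s.tke_m2s2 = r["ps_pa"], r["v_ms"], r["tke_m2s2"]
            s.pv_pa, s.pt_pa, s.pt_prime_pa = r["pv_pa"], r["pt_pa"], r["pt_prime_pa"]
    return out


def subsegment_table(
    planes: pd.DataFrame,
    wall: pd.DataFrame,
    Q_lpm: float,
    rho: float = 1.204,
    wall_areas_mm2=None,
) -> pd.DataFrame:
    """Per-subsegment records from a plane table plus wall-shear samples.

    Returns columns index, dpt_pa, K, R_pa_s2_m6, wss_mean_pa,
    wall_area_mm2, frictional_pa, interior_pa.  Wall band areas default to
    the summed patch areas of the wall samples; pass ``wall_areas_mm2``
    (e.g. mesh-derived band areas) to override.
    """
    from .synthetic import LPM_TO_M3S

    p = planes.sort_values("plane_index").reset_index(drop=True)
    n = len(p)
    Q = Q_lpm * LPM_TO_M3S
    recs = []
    wall_groups = dict(tuple(wall.groupby("subseg_index", sort=True)))
    for j in range(n - 1):
        idx = int(p["plane_index"].iloc[j])
        pt_N, pt_N1 = p["pt_pa"].iloc[j], p["pt_pa"].iloc[j + 1]
        v_N = p["v_ms"].iloc[j]
        A_N, A_N1 = p["area_mm2"].iloc[j] * 1e-6, p["area_mm2"].iloc[j + 1] * 1e-6
        R, K = subsegment_resistance(pt_N, pt_N1, v_N, A_N, A_N1, rho=rho)
        g = wall_groups.get(idx)
        if g is None or len(g) == 0:
            raise ValueError(f"no wall samples for subsegment {idx}")
        wss = subsegment_wss(g["wss_pa"].to_numpy(), g["patch_area_mm2"].to_numpy())
        if wall_areas_mm2 is not None:
            wall_area = float(np.asarray(wall_areas_mm2)[j])
        else:
            wall_area = float(g["patch_area_mm2"].sum())
        fric, inter = loss_decomposition(pt_N - pt_N1, wss, wall_area * 1e-6, v_N, Q)
        recs.append((idx, pt_N - pt_N1, K, R, wss, wall_area, fric, inter))
    return pd.DataFrame(
        recs,
        columns=[
            "index", "dpt_pa", "K", "R_pa_s2_m6", "wss_mean_pa",
            "wall_area_mm2", "frictional_pa", "interior_pa",
        ],
    )
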