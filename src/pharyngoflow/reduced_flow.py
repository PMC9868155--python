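"""Quasi-1D extended-Bernoulli flow over an axial area profile.

A reduced-order stand-in for a full 3-D RANS solve of inspiratory pharyngeal
airflow: the bulk velocity on each plane is v = Q/A, total pressure marches
downstream losing head to Darcy-Weisbach wall friction and to Borda-Carnot
sudden-expansion (separation) losses, and static pressure follows from
Pt = Ps + Pv.  The constriction Reynolds number in this regime is
transitional (~2-6 × 10³), hence the default friction model blends the
laminar 64/Re law below Re = 2000 into the Blasius smooth-pipe correlation
above Re = 4000.

All plane quantities use SI internally; the area profile comes in mm/mm²
(the CT convention) and is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LPM_TO_M3S, AreaProfile

__all__ = [
    "FluidProperties",
    "SolverConfig",
    "PressureProfile",
    "darcy_friction",
    "borda_carnot_loss",
    "reynolds_number",
    "solve_quasi1d",
]

RE_LAMINAR_MAX = 2000.0
RE_TURBULENT_MIN = 4000.0


@dataclass(frozen=True)
class FluidProperties:
    """Gas properties; defaults are air at ~20 °C.

    ``mu = 0`` is accepted and means exactly inviscid flow (zero friction
    and wall shear), the Bernoulli limit.
    """

    rho: float = 1.204  # kg/m³
    mu: float = 1.81e-5  # Pa·s

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass(frozen=True)
class SolverConfig:
    """Boundary conditions and loss-model switches.

    The inlet total pressure defaults to 0 at plane I: this makes the
    relative total pressure Pt' (referenced to plane I) the solver's native
    datum, removing upstream nasal losses from the picture.
    """

    Q_lpm: float = 18.0
    inlet_total_pressure_pa: float = 0.0
    friction_model: str = "blended"  # blended | laminar_64_over_Re | blasius
    expansion_loss: str = "borda_carnot"  # borda_carnot | none
    contraction_loss_coeff: float = 0.0

    def __post_init__(self):
        if self.Q_lpm <= 0:
            raise ValueError("Q must be positive")
        if self.friction_model not in ("blended", "laminar_64_over_Re", "blasius"):
            raise ValueError(f"unknown friction model {self.friction_model!r}")
        if self.expansion_loss not in ("borda_carnot", "none"):
            raise ValueError(f"unknown expansion loss model {self.expansion_loss!r}")
        if self.contraction_loss_coeff < 0:
            raise ValueError("contraction_loss_coeff must be >= 0")


@dataclass(frozen=True)
class PressureProfile:
    """Solver output: per-plane pressures and per-subsegment loss terms."""

    z_mm: np.ndarray
    area_mm2: np.ndarray
    v_ms: np.ndarray
    ps_pa: np.ndarray
    pv_pa: np.ndarray
    pt_pa: np.ndarray
    pt_prime_pa: np.ndarray
    # per subsegment (between plane N and N+1), length n-1
    dpt_friction_pa: np.ndarray
    dpt_expansion_pa: np.ndarray
    tau_wall_pa: np.ndarray
    f_darcy: np.ndarray
    re: np.ndarray

    @property
    def n_planes(self) -> int:
        return int(self.z_mm.size)


def darcy_friction(re, model: str = "blended"):
    """Darcy friction factor f(Re).

    blended (default): laminar f = 64/Re for Re <= 2000, Blasius
    f = 0.316·Re^-0.25 for Re >= 4000, linear interpolation in Re between —
    continuous at both junctions.  Scalar or array input; Re must be
    positive (np.inf is allowed and yields f = 0).
    """
    re_arr = np.asarray(re, dtype=float)
    if np.any(re_arr <= 0):
        raise ValueError("Re must be positive")
    lam = 64.0 / re_arr
    with np.errstate(over="ignore"):
        bla = 0.316 * re_arr**-0.25
    if model == "laminar_64_over_Re":
        f = lam
    elif model == "blasius":
        f = bla
    else:
        f_lo = 64.0 / RE_LAMINAR_MAX
        f_hi = 0.316 * RE_TURBULENT_MIN**-0.25
        w = (re_arr - RE_LAMINAR_MAX) / (RE_TURBULENT_MIN - RE_LAMINAR_MAX)
        blend = f_lo + (f_hi - f_lo) * w
        f = np.where(re_arr <= RE_LAMINAR_MAX, lam, np.where(re_arr >= RE_TURBULENT_MIN, bla, blend))
    f = np.where(np.isinf(re_arr), 0.0, f)
    return float(f) if np.isscalar(re) or np.ndim(re) == 0 else f


def borda_carnot_loss(A_up: float, A_down: float, v_up: float, rho: float) -> float:
    """Total-pressure loss at a sudden expansion, ΔPt = ½ρv²(1 − A_up/A_down)².

    Zero when the areas are equal; contractions (A_down < A_up) return 0 —
    ideal acceleration carries no expansion loss.
    """
    if A_down < A_up:
        return 0.0
    return 0.5 * rho * v_up**2 * (1.0 - A_up / A_down) ** 2


def reynolds_number(Q_lpm: float, area_m2: float, fluid: FluidProperties | None = None) -> float:
    """Circular-equivalent Reynolds number of flow Q through area A.

    v = Q/A and D_h = 2·sqrt(A/π); Re = ρ·v·D_h/μ.  Q = 0 gives Re = 0.
    """
    fluid = fluid or FluidProperties()
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    if Q_lpm < 0:
        raise ValueError("Q must be >= 0")
    if Q_lpm == 0:
        return 0.0
    if fluid.mu == 0:
        return np.inf
    v = Q_lpm * LPM_TO_M3S / area_m2
    d_h = 2.0 * np.sqrt(area_m2 / np.pi)
    return fluid.rho * v * d_h / fluid.mu


def solve_quasi1d(
    profile: AreaProfile,
    fluid: FluidProperties | None = None,
    cfg: SolverConfig | None = None,
) -> PressureProfile:
    """March total pressure down the profile with friction and minor losses.

    Per plane N: v_N = Q/A_N, Pv_N = ½ρv_N², Ps_N = Pt_N − Pv_N.  Per
    subsegment N (planes N → N+1): Pt_{N+1} = Pt_N − ΔPt_fric − ΔPt_exp,
    with ΔPt_fric = f·(Δz/D_h)·½ρv² and τ_w = (f/8)·ρ·v² evaluated at the
    upstream plane, and ΔPt_exp the Borda-Carnot loss when the lumen
    expands.  All loss terms are ≥ 0 so Pt is non-increasing downstream.
    """
    fluid = fluid or FluidProperties()
    cfg = cfg or SolverConfig()
    n = profile.n_planes
    A = profile.area_mm2 * 1e-6  # m²
    dz = (profile.z_mm[:-1] - profile.z_mm[1:]) * 1e-3  # m, positive
    Q = cfg.Q_lpm * LPM_TO_M3S
    v = Q / A
    pv = 0.5 * fluid.rho * v**2
    d_h = 2.0 * np.sqrt(A / np.pi)

    if fluid.mu == 0:
        re = np.full(n - 1, np.inf)
        f = np.zeros(n - 1)
        tau = np.zeros(n - 1)
        dpt_f = np.zeros(n - 1)
    else:
        re = fluid.rho * v[:-1] * d_h[:-1] / fluid.mu
        f = np.asarray(darcy_friction(re, cfg.friction_model))
        tau = f / 8.0 * fluid.rho * v[:-1] ** 2
        dpt_f = f * dz / d_h[:-1] * pv[:-1]

    dpt_e = np.zeros(n - 1)
    if cfg.expansion_loss == "borda_carnot":
        for j in range(n - 1):
            dpt_e[j] = borda_carnot_loss(A[j], A[j + 1], v[j], fluid.rho)
    if cfg.contraction_loss_coeff > 0:
        contracting = A[1:] < A[:-1]
        dpt_e = dpt_e + np.where(contracting, cfg.contraction_loss_coeff * pv[1:], 0.0)

    pt = np.empty(n)
    pt[0] = cfg.inlet_total_pressure_pa
    pt[1:] = pt[0] - np.cumsum(dpt_f + dpt_e)
    ps = pt - pv
    return PressureProfile(
        z_mm=profile.z_mm.copy(),
        area_mm2=profile.area_mm2.copy(),
        v_ms=v,
        ps_pa=ps,
        pv_pa=pv,
        pt_pa=pt,
        pt_prime_pa=pt - pt[0],
        dpt_friction_pa=dpt_f,
        dpt_expansion_pa=dpt_e,
        tau_wall_pa=tau,
        f_darcy=f,
        re=re,
    )
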