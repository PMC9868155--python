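"""Cross-sectional morphometry of an airway surface mesh.

The analysis convention: starting from the hard-palate plane (plane I) a
stack of planes perpendicular to the z axis descends per 0.5 mm to the
epiglottis tip (plane IV); 1-based plane numbers increase downstream while
z decreases.  The plane at the soft-palate tip (plane III, the "dividing
plane") splits the stack into the velopharyngeal and oropharyngeal regions;
each region's plane of minimum area is its plane_Amin.  The lumen between
consecutive planes N and N+1, together with the wall band between them, is
subsegment N.

Areas are the summed enclosed areas of all intersection loops at a z (a
non-convex or bifid lumen may intersect a plane in several loops); an empty
intersection inside the stack signals a discontinuous lumen and is an
error, mirroring the model-exclusion practice for airway reconstructions
whose continuity is broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

__all__ = [
    "PlaneSection",
    "Subsegment",
    "MorphometryReport",
    "DiscontinuousLumenError",
    "NoConstrictionError",
    "slice_airway",
    "find_plane_amin",
    "assign_regions",
    "area_ratio_series",
    "area_ratio_to_amin",
    "build_subsegments",
    "morphometry_report",
]

VELOPHARYNX = "velopharynx"
OROPHARYNX = "oropharynx"


class DiscontinuousLumenError(RuntimeError):
    """The mesh does not intersect a plane inside the requested stack."""


class NoConstrictionError(ValueError):
    """All areas in a region are equal: a degenerate (cylindrical) lumen."""


@dataclass
class PlaneSection:
    """One cross-sectional plane of the stack.

    ``index`` is the 1-based plane number; ``region`` is assigned by
    :func:`assign_regions`.  The mass-flow-weighted flow quantities
    (ps/v/tke and the derived pv/pt/pt') are filled by the post-processor.
    """

    index: int
    z_mm: float
    area_mm2: float
    region: str | None = None
    area_ratio_next: float | None = None
    ps_pa: float | None = None
    v_ms: float | None = None
    tke_m2s2: float | None = None
    pv_pa: float | None = None
    pt_pa: float | None = None
    pt_prime_pa: float | None = None


@dataclass(frozen=True)
class Subsegment:
    """Lumen slab between plane N (upper) and plane N+1 (lower)."""

    index: int  # = N, 1-based; spans planes N and N+1
    z_upper_mm: float
    z_lower_mm: float
    wall_area_mm2: float


@dataclass(frozen=True)
class MorphometryReport:
    """Segment-level summary: lengths, counts and per-region constrictions."""

    segment_length_cm: float
    n_planes: int
    dividing_plane_index: int | None
    regions: dict = field(default_factory=dict)
    # regions maps region name -> {"amin_plane": int|None,
    #                              "amin_area_cm2": float|None,
    #                              "no_constriction": bool}

    def to_dict(self) -> dict:
        return {
            "segment_length_cm": self.segment_length_cm,
            "n_planes": self.n_planes,
            "dividing_plane_index": self.dividing_plane_index,
            "regions": self.regions,
        }


def _section_heights(top_z: float, bottom_z: float, spacing: float) -> np.ndarray:
    n = int(np.floor((top_z - bottom_z) / spacing * (1 + 1e-9))) + 1
    return top_z - spacing * np.arange(n)


def slice_airway(
    mesh: trimesh.Trimesh,
    top_z: float,
    bottom_z: float,
    spacing_mm: float = 0.5,
) -> list[PlaneSection]:
    """Slice the mesh into the descending plane stack and measure areas.

    One section per grid z from ``top_z`` down to ``bottom_z``; the area is
    the total enclosed area of the plane/mesh intersection polygons.
    Heights are nudged by 1e-4·spacing off exact mesh-vertex z to avoid
    degenerate coplanar intersections.
    """
    if top_z <= bottom_z:
        raise ValueError("top_z must exceed bottom_z")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    heights = _section_heights(top_z, bottom_z, spacing_mm)
    z_lo, z_hi = mesh.bounds[0][2], mesh.bounds[1][2]
    eps = 1e-4 * spacing_mm
    h_eff = heights + eps
    # nudge the extreme planes just inside the mesh; anything genuinely
    # outside is left alone and reported as a missing cross-section
    h_eff = np.where(np.abs(heights - z_hi) <= 2 * eps, z_hi - eps, h_eff)
    h_eff = np.where(np.abs(heights - z_lo) <= 2 * eps, z_lo + eps, h_eff)
    paths = mesh.section_multiplane(
        plane_origin=[0.0, 0.0, 0.0], plane_normal=[0.0, 0.0, 1.0], heights=h_eff
    )
    sections = []
    for k, (z, path) in enumerate(zip(heights, paths)):
        polys = [] if path is None else [p for p in path.polygons_closed if p is not None]
        if not polys:
            raise DiscontinuousLumenError(
                f"no lumen cross-section at z = {z:.4f} mm (plane {k + 1}): "
                "the reconstructed lumen appears discontinuous"
            )
        # multiple intersection loops (non-convex or bifid lumen) are summed
        area = float(sum(abs(p.area) for p in polys))
        sections.append(PlaneSection(index=k + 1, z_mm=float(z), area_mm2=area))
    return sections


def find_plane_amin(sections: list[PlaneSection], region: str | None = None) -> int:
    """1-based plane number of the minimum-area plane (within a region).

    Ties break to the first (most upstream) minimal plane.  The returned
    plane's area must not exceed either in-region neighbour's and must be
    strictly smaller than at least one of them; a region of all-equal areas
    raises :class:`NoConstrictionError`.
    """
    subset = [s for s in sections if region is None or s.region == region]
    if not subset:
        raise ValueError(f"no planes in region {region!r}")
    areas = np.array([s.area_mm2 for s in subset])
    if np.ptp(areas) <= 1e-12 * max(areas.max(), 1.0):
        raise NoConstrictionError(
            f"all {len(subset)} plane areas in {region or 'the stack'} are equal: "
            "no constriction"
        )
    k = int(np.argmin(areas))
    neighbours = [areas[j] for j in (k - 1, k + 1) if 0 <= j < len(areas)]
    if any(areas[k] > nb for nb in neighbours) or not any(areas[k] < nb for nb in neighbours):
        raise NoConstrictionError(
            "regional minimum is not a constriction (not smaller than a neighbouring plane)"
        )
    return subset[k].index


def assign_regions(sections: list[PlaneSection], dividing_index: int) -> list[PlaneSection]:
    """Label planes 1..dividing as velopharynx, the rest as oropharynx."""
    n = len(sections)
    if not (1 < dividing_index < n):
        raise ValueError(f"dividing plane {dividing_index} must lie strictly inside 1..{n}")
    for s in sections:
        s.region = VELOPHARYNX if s.index <= dividing_index else OROPHARYNX
    return sections


def area_ratio_series(sections: list[PlaneSection]) -> np.ndarray:
    """Consecutive-plane area ratios A_N / A_{N+1}, N = 1..n−1.

    Ratios > 1 mean the lumen narrows downstream.  Each section's
    ``area_ratio_next`` field is filled as a side effect.
    """
    if len(sections) < 2:
        raise ValueError("need at least two sections")
    a = np.array([s.area_mm2 for s in sections])
    ratios = a[:-1] / a[1:]
    for s, r in zip(sections[:-1], ratios):
        s.area_ratio_next = float(r)
    return ratios


def area_ratio_to_amin(sections: list[PlaneSection], amin_index: int) -> np.ndarray:
    """Variant ratio A_N / A_amin for every plane N (1 at plane_Amin)."""
    a = np.array([s.area_mm2 for s in sections])
    a_min = a[amin_index - 1]
    return a / a_min


def _band_wall_area(mesh: trimesh.Trimesh, z_lo: float, z_hi: float) -> float:
    """Lateral surface area of the mesh between z_lo and z_hi (mm²)."""
    tri_z = mesh.triangles[:, :, 2]
    mask = (tri_z.max(axis=1) > z_lo) & (tri_z.min(axis=1) < z_hi)
    if not mask.any():
        return 0.0
    sub = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces[mask], process=False
    )
    sub = slice_mesh_plane(sub, plane_normal=[0, 0, 1], plane_origin=[0, 0, z_lo])
    if sub is None or len(sub.faces) == 0:
        return 0.0
    sub = slice_mesh_plane(sub, plane_normal=[0, 0, -1], plane_origin=[0, 0, z_hi])
    if sub is None or len(sub.faces) == 0:
        return 0.0
    return float(sub.area)


def build_subsegments(
    sections: list[PlaneSection], mesh: trimesh.Trimesh | None = None
) -> list[Subsegment]:
    """Build the n−1 subsegments, each with its lateral wall band area.

    Subsegment N is bounded above by plane N and below by plane N+1, so the
    resistance of subsegment N is computed from planes N and N+1.  The wall
    area comes from clipping the mesh to the z band; without a mesh the
    circle-equivalent perimeter 2·sqrt(πA̅) times the band height is used.
    """
    if len(sections) < 2:
        raise ValueError("need at least two sections")
    out = []
    for up, lo in zip(sections[:-1], sections[1:]):
        if mesh is not None:
            wall = _band_wall_area(mesh, lo.z_mm, up.z_mm)
        else:
            a_mean = 0.5 * (up.area_mm2 + lo.area_mm2)
            wall = 2.0 * np.sqrt(np.pi * a_mean) * (up.z_mm - lo.z_mm)
        out.append(
            Subsegment(index=up.index, z_upper_mm=up.z_mm, z_lower_mm=lo.z_mm, wall_area_mm2=wall)
        )
    return out


def morphometry_report(sections: list[PlaneSection], spacing_mm: float = 0.5) -> MorphometryReport:
    """Summarise the stack: length, plane counts and per-region plane_Amin.

    Length is (n_planes − 1)·spacing.  A region whose areas are all equal
    (or whose minimum is not a true constriction) is flagged
    ``no_constriction`` instead of reporting a minimum plane.
    """
    n = len(sections)
    region_names = []
    for s in sections:
        if s.region is not None and s.region not in region_names:
            region_names.append(s.region)
    dividing = None
    if len(region_names) > 1:
        dividing = max(s.index for s in sections if s.region == region_names[0])
    regions = {}
    for name in region_names or [None]:
        try:
            idx = find_plane_amin(sections, name)
            area_cm2 = sections[idx - 1].area_mm2 / 100.0
            regions[name or "all"] = {
                "amin_plane": idx,
                "amin_area_cm2": area_cm2,
                "no_constriction": False,
            }
        except NoConstrictionError:
            regions[name or "all"] = {
                "amin_plane": None,
                "amin_area_cm2": None,
                "no_constriction": True,
            }
    return MorphometryReport(
        segment_length_cm=(n - 1) * spacing_mm / 10.0,
        n_planes=n,
        dividing_plane_index=dividing,
        regions=regions,
    )
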