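"""Three-level decomposition of the pharyngeal flow along the plane stack.

The inspiratory jet through an hourglass lumen develops in three stages:

* level 1 — jet formation: the converging lumen from plane I down to (and
  including) plane_Amin, where static pressure is traded for kinetic energy
  and losses are dominated by wall friction;
* level 2 — pre full separation: the near-constant constricted segment with
  at most slight expansion downstream of plane_Amin, where the jet hugs the
  wall (high wall shear, still mostly frictional loss) and recirculation is
  small and transient;
* level 3 — full separation: the rapidly expanded lumen where the jet
  detaches and an anterior low-velocity recirculation region (near-wall
  flow reversed against the bulk direction) carries the interior loss.

The boundary between levels 2 and 3 is set by two declared thresholds:
the area expansion ratio A_N/A_amin (θ_exp) and the reversed-flow area
fraction (θ_rec).  Once either threshold is exceeded the flow is considered
fully separated for the remainder of the stack, keeping the levels
contiguous and ordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LevelSegmentation",
    "reverse_flow_fraction",
    "classify_levels",
    "DEFAULT_THETA_EXP",
    "DEFAULT_THETA_REC",
]

DEFAULT_THETA_EXP = 1.5
DEFAULT_THETA_REC = 0.10


@dataclass(frozen=True)
class LevelSegmentation:
    """Per-plane level labels and the two level boundaries.

    ``level2_start``/``level3_start`` are 1-based plane numbers (None when
    the level is empty); ``labels`` has one entry in {1, 2, 3} per plane;
    ``reverse_fractions`` echoes the per-plane reversed-flow area fraction
    used for the call.
    """

    level2_start: int | None
    level3_start: int | None
    labels: np.ndarray
    reverse_fractions: np.ndarray

    def to_dict(self) -> dict:
        return {
            "level2_start": self.level2_start,
            "level3_start": self.level3_start,
            "labels": [int(v) for v in self.labels],
        }


def reverse_flow_fraction(u, area_weight, flow_direction) -> float:
    """Area-weighted fraction of a plane carrying flow against the bulk.

    A sample is reversed when its axial velocity component opposes the bulk
    flow direction (u·n < 0).  Samples with zero axial component count as
    forward.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    a = np.asarray(area_weight, dtype=float)
    if a.size == 0 or a.sum() <= 0:
        raise ValueError("empty plane: reverse-flow fraction undefined")
    n = np.asarray(flow_direction, dtype=float)
    n = n / np.linalg.norm(n)
    reversed_mask = (u @ n) < 0
    return float(a[reversed_mask].sum() / a.sum())


def classify_levels(
    areas_mm2,
    amin_index: int,
    reverse_fractions,
    theta_exp: float = DEFAULT_THETA_EXP,
    theta_rec: float = DEFAULT_THETA_REC,
) -> LevelSegmentation:
    """Partition the plane stack into the three flow levels.

    Level 1 spans planes 1..``amin_index`` (inclusive — the jet is formed
    at plane_Amin).  Downstream planes stay level 2 while the expansion is
    slight (A_N/A_amin ≤ θ_exp) AND the reversed-flow fraction stays below
    θ_rec; the first violation starts level 3, which runs to the end.
    Larger θ_exp can only lengthen level 2.
    """
    a = np.asarray(areas_mm2, dtype=float)
    rev = np.asarray(reverse_fractions, dtype=float)
    n = a.size
    if rev.size != n:
        raise ValueError("reverse_fractions must match areas length")
    if not (1 <= amin_index <= n):
        raise ValueError(f"amin_index {amin_index} outside 1..{n}")
    if theta_exp < 1.0 or not (0.0 <= theta_rec <= 1.0):
        raise ValueError("thresholds out of range (theta_exp >= 1, 0 <= theta_rec <= 1)")
    labels = np.ones(n, dtype=int)
    a_min = a[amin_index - 1]
    level3_start = None
    for i in range(amin_index, n):  # 0-based positions downstream of amin
        if a[i] / a_min > theta_exp or rev[i] >= theta_rec:
            level3_start = i + 1
            break
        labels[i] = 2
    if level3_start is not None:
        labels[level3_start - 1 :] = 3
    level2_start = amin_index + 1 if amin_index < n and labels[amin_index] == 2 else None
    return LevelSegmentation(
        level2_start=level2_start,
        level3_start=level3_start,
        labels=labels,
        reverse_fractions=rev,
    )
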