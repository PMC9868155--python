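# Methods

Model, assumptions, parameters and numerical choices behind `pharyngoflow`.

## Conventions

- The airway segment runs from the hard-palate plane (plane I) to the
  epiglottis tip (plane IV). Planes are numbered 1-based, increasing
  downstream; the z coordinate (mm) **decreases** downstream; flow direction
  is (0, 0, −1).
- Plane spacing defaults to 0.5 mm; a segment of length L mm has
  `floor(L / 0.5) + 1` planes, and the reported segment length is
  `(n_planes − 1) × spacing`.
- The soft-palate-tip plane (plane III, `dividing_plane`) splits the stack
  into velopharynx (planes 1..III) and oropharynx (III+1..n). It is an
  anatomical landmark and must be supplied; it cannot be detected from a
  bare mesh.
- Units: mm and mm² at all I/O boundaries; SI internally.
  `Q` in L/min converts via 1/60000 m³/s per L/min.

## Governing relations

With volumetric flow `Q` and plane area `A`, the cross-sectional mean
velocity is `v = Q/A`. Per plane:

- dynamic pressure `Pv = ½ ρ v²`
- total pressure `Pt = Ps + Pv`
- relative total pressure `Pt′(N) = Pt(N) − Pt(I)` (zero at plane I)

Per subsegment N (between planes N and N+1):

- resistance `R = (Pt_N − Pt_{N+1}) / (v_N · Ā)²` with
  `Ā = (A_N + A_{N+1})/2` — units Pa·s²·m⁻⁶. (Reference template values
  carry the label "Pa" from the source tabulation; dimensionally they are
  resistances evaluated at the stated flow, and only their *ratios* are used.)
- loss coefficient `K = ΔPt / Pv_N`
- consecutive area ratio `A_N / A_{N+1}` (>1 means narrowing downstream);
  the variant `A_N / A_min` is available separately.

## Quasi-1D solver

`solve_quasi1d` marches `Pt` downstream:

- **Friction** (Darcy–Weisbach): `dPt = f · (Δz / D_h) · ½ρv²` with hydraulic
  diameter `D_h = 2√(A/π)` (circle-equivalent). Friction factor `f`:
  `64/Re` for Re ≤ 2000, Blasius `0.316·Re^−0.25` for Re ≥ 4000, linear
  blend between (continuous at both ends). Friction is evaluated at the
  upstream plane of each subsegment. Wall shear `τ_w = (f/8) ρ v²`.
- **Sudden expansion** (Borda–Carnot): `ΔPt = ½ρ v_up² (1 − A_up/A_down)²`
  applied where the area grows; contractions lose nothing by default
  (`contraction_loss_coeff = 0`).
- `μ = 0` is allowed and yields the inviscid (lossless, with
  `expansion_loss="none"`) Bernoulli limit — used as an exactness oracle.
- A straight laminar tube reproduces Hagen–Poiseuille `ΔP = 8μLQ/(πr⁴)` and
  `τ_w = 4μQ/(πr³)` exactly, because the circle-equivalent `D_h` is exact
  for a circle.

Reference conditions: air at ρ = 1.204 kg/m³, μ = 1.81×10⁻⁵ Pa·s;
Q = 18 L/min. At the narrowest template constriction (0.5443 cm²) this gives
Re ≈ 3052, inside the transitional band 2–6×10³ for which the blended
friction model is intended.

## Synthetic generator

`make_area_profile` builds an hourglass area profile: cosine taper from the
inlet area to the constriction, an optional near-flat plateau
(`A_min·(1 + 0.04 t²)`, guaranteeing a unique global minimum at the plateau
centre start), and a cosine expansion to the outlet. Eight templates
(`FTP1–4` × `MC`/`MO`) encode realistic lengths, dividing planes and
regional minimum areas; three carry reference constriction resistances used
for the mouth-open/mouth-closed fold-ratio comparison (1.27 / 0.8271 ≈ 1.54).

`make_surface_mesh` extrudes each plane's cross-section (circle or ellipse)
as an inscribed `n_theta`-gon ring. `perturb_mesh` adds seeded, truncated
radial noise (warning above 25% of the minimal radius).

`make_flow_field` samples a jet model on each plane: a forward core
occupying area fraction β (1 upstream of the constriction, ramping to 0.6 at
the outlet by default) and a reversed annulus at speed γ·u_core (γ = 0.2).
Cell areas and the core/annulus boundary are placed so the plane-integrated
flux equals Q **exactly** and the reversed-area fraction equals 1 − β
exactly. Static pressure comes from the quasi-1D solver; TKE peaks at the
core/annulus interface; wall patches carry the solver's τ_w with zero-mean
2% jitter that preserves the area-weighted mean.

Note on averaging: the **mass-flow-weighted** plane average
`⟨φ⟩ = Σ φ ρ|u·n|a / Σ ρ|u·n|a` weights the fast core heavily, so where
β < 1 the averaged velocity exceeds Q/A and the sampled-field `Pt` can rise
downstream (negative subsegment ΔPt, negative interior loss). These values
are reported as-is, never clamped; with β = 1 the post-processed tables
reproduce the solver to machine precision (the oracle-equivalence tests).

## Loss decomposition

For subsegment N: `frictional = τ̄_w · S_wall · v̄_N / Q` (for a
circle-equivalent duct this equals the solver's friction term
`4 τ Δz / D_h` exactly), `interior = ΔPt − frictional`. The identity
`frictional + interior = ΔPt` holds to machine precision by construction.

## Three-level classification

- Level 1: planes 1..`plane_Amin` (inclusive).
- Level 2: downstream planes while `A/A_min ≤ θ_exp` **and** reverse-flow
  fraction `< θ_rec`.
- Level 3: from the first violation to the outlet (levels are contiguous and
  never revert).

Defaults θ_exp = 1.5, θ_rec = 0.10. Level-2 extent is monotone
non-decreasing in θ_exp (property-tested).

## Numerical choices

- **Slicing**: `trimesh.section_multiplane`; plane heights are nudged by
  10⁻⁴·spacing off exact vertex z to avoid degenerate coplanar cuts, and the
  two boundary planes are pulled just inside the mesh. A plane with no
  intersection inside the stack raises `DiscontinuousLumenError` (mirroring
  the exclusion of broken airway reconstructions). Areas sum
  `|polygon.area|` over all closed intersection loops; disjoint lumens are
  summed, but *nested* loops (annular sections) are not supported because
  polygon containment trees are unavailable in this environment.
- **Mesh exactness**: vertices are snapped to float32 so ASCII and binary
  STL round-trips slice identically (< 10⁻⁹ area difference).
- **Inscribed-polygon bias**: an inscribed n-gon underestimates area by the
  factor `(n/2π)·sin(2π/n)` — 0.16% at n_theta = 64; the error decreases
  monotonically under refinement (grid-independence test at 16/32/64).
- **plane_Amin**: global (or in-region) argmin with first-minimum
  tie-breaking; the minimum must not exceed either in-region neighbour and
  must be strictly below at least one, otherwise `NoConstrictionError`
  (all-equal cylinders are flagged `no_constriction` in reports).
- **Wall band areas**: mesh faces are pre-filtered by z range and clipped
  twice with `slice_mesh_plane`; without a mesh, the circle-equivalent
  perimeter `2√(πĀ)` × band height is used.
- **Determinism**: all floats are written with `%.10g`; a fixed config and
  seed produce byte-identical outputs.

## Parameters (defaults)

| parameter | default | meaning |
| --- | --- | --- |
| `spacing_mm` | 0.5 | plane spacing |
| `rho` | 1.204 kg/m³ | air density |
| `mu` | 1.81×10⁻⁵ Pa·s | air viscosity (0 = inviscid) |
| `Q_lpm` | 18 | inspiratory flow rate |
| `friction_model` | blended | 64/Re ≤ 2000 ↔ Blasius ≥ 4000 |
| `expansion_loss` | borda_carnot | sudden-expansion total-pressure loss |
| `beta_downstream` | 0.6 | jet core area fraction at the outlet |
| `recirc_strength` γ | 0.2 | reversed-annulus speed ratio |
| `theta_exp` | 1.5 | level-2 area-ratio threshold |
| `theta_rec` | 0.10 | level-2 reverse-fraction threshold |
| `n_theta` | 64 | mesh circumferential resolution |

## Limitations

- Quasi-1D: no secondary flows, curvature or asymmetric jets; the interior
  loss is a residual, not a turbulence closure.
- The synthetic jet model is a sampling emulator with exact integral
  constraints, not a turbulence-resolving field; its mass-flow-averaged
  kinetic energy downstream of the constriction is exaggerated (see the
  averaging note above).
- Single constriction per region is assumed by the generator; the slicer and
  classifier themselves handle arbitrary profiles.
- Annular (nested-loop) cross-sections are rejected by the area summation.
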