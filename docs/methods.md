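# Methods

## Geometry model

The membrane mid-surface is either a plane or a circular cylinder with its
axis fixed to the laboratory Y axis; all curvature lives in the XZ plane.
The signed curvature is `c = s/R`, where `s ∈ {+1, −1}` records which side
of the surface the outer leaflet faces. `c > 0` means the outer monolayer
is convex. The sign is stored explicitly in the `SurfaceModel`; callers
never infer it from coordinates. The signed depth of a point is
`s·(‖p_XZ − center‖ − R)` (cylinder) or `s·(z − z₀)` (plane): zero on the
mid-surface, positive toward the outer leaflet. The outer normal is the
gradient of this depth field, and the inner-leaflet normal is its negation.
The plane is the exact `c → 0` limit; a property test verifies agreement
to 10⁻⁶ nm at `|c| = 10⁻⁸ nm⁻¹`.

Cylinder fitting uses an algebraic (Kåsa) circle fit in the XZ projection
as the initializer, refined by geometric least squares on the radial
residuals (`scipy.optimize.least_squares`, tolerances 10⁻¹⁴). A caller-
supplied hint vector (default +Z) declares which way the outer leaflet
faces and fixes the sign of the reported curvature. Points collinear in XZ
raise a degenerate-fit error. A sanity bound `|c| < 1 nm⁻¹` rejects radii
tighter than any membrane.

Analyses exclude the bicelle caps through a *sector*: an arc of half-angle
30° around the symmetry plane (cylinders) or a slab of half-width 30 % of
the X extent (flat), both configurable. These extents are package defaults,
chosen to keep a comfortable margin between the analysed region and the
caps; no physical result should depend on the exact value as long as the
caps are excluded.

## Walls

A wall is a rectangular bead grid with exact spacing d = 0.51 nm covering
the requested extent (default: the full box in the bending plane — the
conservative choice when it is unknown whether walls should cover the
caps). The two walls sit at signed depths ±D/2 (D = 5 nm). Each bead is an
anchor (fixed dummy, no nonbonded terms) plus a shell tied to it by a
zero-length harmonic bond, k = 10 kJ·mol⁻¹·nm⁻². Shells interact only with
the lipid tail carbons, σ = 0.85 nm and ε = 10⁻⁵ J/mol, which puts the LJ
minimum at 2^{1/6}σ ≈ 0.954 nm — beyond the 0.8 nm short-range cutoff, so
the potential is strictly repulsive wherever it acts. `WallSpec` enforces
`2^{1/6}σ ≥ r_c` as a hard validation error, and `scan_repulsive` provides
an independent numerical check (sign of dV/dr on a 10⁻⁴ nm grid).

**Units.** ε values are configured in J/mol. GROMACS topologies use
kJ/mol, so the ITP writer converts (10⁻⁵ J/mol → 10⁻⁸ kJ/mol) and appends
the configured J/mol value as a same-line comment for traceability.

**Bending.** A flat wall maps onto a curved one by arc-length-preserving
transfer: the in-plane x coordinate of each anchor becomes arc length on
that wall's own circle at radius `1/|c| ± D/2`. The bending plan
interpolates *curvature* linearly and regenerates the geometry at each
intermediate value — not linear Cartesian interpolation — because this
conserves bead counts, along-arc spacing (exactly) and wall separation at
every step. The per-step anchor displacement cap (default 0.05 nm) is
advisory: plans report their largest step and `n_steps_for_limit` finds
the smallest compliant step count, but a single-step plan remains legal.
How anchors are immobilised in the engine is left open in the original
technique; the writer emits stiff position restraints by default and
documents the freeze-group alternative.

## Bicelle assembly

Phospholipids of each monolayer occupy a 17 × 6 grid (in-plane spacing is
not a published quantity; default 0.8 nm, configurable), species shuffled
deterministically from the seed; cholesterol is intercalated at seeded
uniform positions. The default composition is the asymmetric
plasma-membrane content: outer SM 42 / PC 46 / PE 14 / PS 0, inner SM 12 /
PC 14 / PE 46 / PS 30, cholesterol 51 + 51. Phosphatidylinositol is
omitted (sub-molecule-per-system concentration). Lipids are internal
single-conformer pseudo-templates — head phosphorus plus explicit-H chain
carbons with configurable naming — because the artifact builds *starting*
structures whose downstream fate belongs to the simulation engine.

The selective inter-monolayer repulsion (σ = 0.8 nm, ε = 10⁻⁷ J/mol)
includes all heavy phospholipid atoms except distal tail carbons, i.e.
carbon indices ≥ 10, below the 9–10 double bond of the oleoyl chains; the
same index boundary is applied to SM's saturated chain by default
(configurable). Hydrogens and cholesterol are never included — cholesterol
must diffuse freely through the caps. The emitted override uses duplicated
per-leaflet atom types with a single modified pair interaction.

## Analyses

*Density profiles* histogram the signed depth of selected atoms
(mass-weighted by default, number-weighting available), divide by the
per-bin volume — constant for planes, ∝ |R + depth| for cylinders — and
normalise to unit integral. Default bin 0.01 nm.

*Order parameters*: `S_CD(i) = ⟨(3cos²θ − 1)/2⟩` over every C–H bond of
tail carbon i, with θ measured against the local outer normal of the
lipid's leaflet evaluated at the carbon. Explicit hydrogens are required;
their absence is an error, not a fallback.

*Area per lipid*: for each head group, neighbours within 1.5 nm are
projected onto the tangent plane defined by the fitted global surface
normal (the global shape is restrained by construction, so local PCA
planes are unnecessary), and the area of the target's Voronoi cell is
computed. Cells that are unbounded *or* have a vertex farther from the
target than the neighbour cutoff are flagged invalid and excluded from
means — the second condition catches edge cells that close numerically but
extend into unsampled territory. A brute-force nearest-site pixel
integration (10⁻³ nm grid) serves as the oracle in tests, agreeing within
1 %.

*Cholesterol*: the long axis runs from the tail-branching carbon to the
hydroxyl oxygen (the branching atom name is a config entry, default C17 —
sterol numbering of the ring–tail junction; the choice only shifts the
axis origin along the molecule). Inclination is the angle to the local
outer normal; depth is measured from the leaflet's head-group surface,
defined as the peak of that leaflet's head density (recomputed per
trajectory, or supplied explicitly). Molecules whose oxygen lies within
0.5 nm of the mid-surface form the minor pool; the minor fraction is their
percentage of all cholesterol. Peak positions use histogram modes after
Gaussian smoothing (bandwidth 2 bins); bins 2° (angles) and 0.025 nm
(depths).

## Synthetic fixtures

The generator emulates the *geometry* of flat and curved asymmetric
membranes, not their physics: heads on regular grids realising a target
APL (0.60 nm² default, a typical fluid-phase value), pseudo-tails whose
C–H vectors sit on a fixed cone around the local normal with
`cos θ = √((2S+1)/3)` and random azimuth — a distribution whose mean is
*exactly* the imposed S_CD — and cholesterol split into a tilted vertical
majority and a horizontal mid-membrane minority at an exact requested
count. Two curved placement modes exist: per-leaflet APL realised at each
head surface, or a shared angular grid ("mid"), which reproduces the
geometric (R+t)/(R−t) area ratio between convex and concave leaflets at
equal loading. Noise and trajectory jitter are per-molecule rigid
translations, uncorrelated across frames, so ground truth is unchanged in
expectation; no dynamics are simulated. Passing round-trip tests therefore
demonstrates the correctness of the measurement machinery, not the
realism of any conformational ensemble: real trajectories have correlated
frames, rough surfaces, and tails whose orientation distribution is not a
cone.

## Problem sizes and numerical choices

Tests run on patches of 30–120 lipids per leaflet and trajectories of
5–100 frames — ample for the deterministic constructions used (the
fixed-cone sampler makes S_CD recovery exact at any n; Voronoi areas on
noiseless grids are exact to machine precision). Statistical checks
(isotropic S_CD at 10⁵ samples, Gaussian APL at 10⁴) use seeded
generators. Degenerate inputs fail loudly: collinear fits, points on the
cylinder axis, empty selections, missing hydrogens or defining atoms,
composition/grid mismatches. File writers are byte-stable for fixed
input; GRO output is written by the package's own fixed-column formatter
and read back through MDAnalysis in tests as an independent oracle.

## Known limitations

* Only plane and Y-axis cylinder geometries; no spherical or saddle
  shapes, and no per-lipid instantaneous curvature fields.
* The package never runs the simulation engine; force-field content,
  solvation, minimisation and equilibration are out of scope, and the
  emitted ITP fragments are starting points for an engine workflow.
* Voronoi areas near the sector boundary rely on neighbours outside the
  sector; analyses are invariant to modifications outside the sector plus
  one neighbour-cutoff guard band.
* The anchor-moving schedule of the original bending procedure is not
  published in detail; the linear-in-curvature plan with a displacement
  cap is this package's own declared default.
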