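# memcurve

Tools for building membrane simulation systems restrained to a prescribed
global curvature, and for analysing flat and cylindrically curved bilayer
configurations.

## The problem

Membrane curvature in free molecular-dynamics simulations is transient: a
bilayer patch bends and flattens on its own schedule, so curvature-dependent
properties cannot be sampled at a *fixed*, known curvature. `memcurve`
implements a dummy-particle technique that holds a bicelle — a finite
bilayer strip closed by semicircular lipid caps, infinite along Y — at a
chosen signed curvature `c` (nm⁻¹, `c > 0` meaning the outer monolayer is
convex), plus the analyses needed to characterise the resulting curved
membranes.

The restraint is a pair of *walls*: rectangular grids of beads (default
spacing d = 0.51 nm) placed D = 5 nm apart around the hydrophobic core.
Each bead is an **anchor** — a dummy particle fixed in space with no
nonbonded interactions — bonded to a **shell** particle by a zero-length
harmonic bond (k = 10 kJ·mol⁻¹·nm⁻²). Shells interact only with the lipid
tail carbons via a Lennard-Jones potential (σ = 0.85 nm, ε = 10⁻⁵ J/mol)
whose minimum 2^{1/6}σ ≈ 0.954 nm lies beyond the short-range cutoff
r_c = 0.8 nm, so within the cutoff the potential is purely repulsive: the
walls shape the hydrophobic core without attracting anything. Bending is
performed by regenerating the anchor grid at gradually interpolated
curvatures, arc-length preserving, so grid spacing and wall separation are
conserved at every step.

The analyses are all curvature-aware, using the signed depth from the
fitted mid-surface and the *local outer normal* of each lipid's leaflet:

* normalised density profiles (cylindrical-shell volume correction),
* tail order parameters `S_CD(i) = ⟨(3cos²θᵢ − 1)/2⟩` per carbon,
* area per lipid from the Voronoi cell of each head group on its local
  tangent plane,
* cholesterol inclination (tail-branching carbon → OH axis vs. the local
  outer normal), depth from the head-group surface, and the *minor
  fraction* of horizontal mid-membrane cholesterol.

A synthetic-fixture generator builds flat and curved asymmetric membranes
with known ground truth (target APL, imposed S_CD profile, exact minor
cholesterol counts), so every analysis is testable end-to-end without any
simulation data.

## Worked example

```python
import memcurve as mc

# walls restraining a membrane to c = 0.2 nm^-1 (R = 5 nm)
spec = mc.WallSpec(curvature=0.2)
geom = mc.generate_walls(spec)
print(geom.n_beads)                       # {'outer': 288, 'inner': 288}
print(mc.check_repulsive(spec))           # 0.954092741062967  (>= 0.8 nm)

fit = mc.fit_surface(geom.anchors["outer"], "cylinder")
print(fit.radius)                         # 7.5  (= 1/0.2 + D/2)

# synthetic curved membrane, equal leaflet loading
frame, truth = mc.make_membrane_fixture(
    mc.FixtureSpec(curvature=0.2, seed=3, spacing_reference="mid",
                   composition=mc.Composition({"PC": (60, 60), "CHOL": (0, 0)})))
surf = mc.make_surface(0.2)
areas = mc.areas_per_lipid(frame, surf)
b = areas[areas.bounded]
print(b[b.leaflet == "outer"].area.mean() /
      b[b.leaflet == "inner"].area.mean())   # 2.333... = (R+t)/(R-t), t = 2 nm
```

The outer (convex) leaflet's area per lipid exceeds the inner (concave)
one by exactly the ratio of the head-surface radii — the geometric origin
of the curvature effect on lipid packing.

The same operations are available from the shell:

```sh
memcurve build-walls --curvature 0.2 --out walls     # walls.gro + walls.itp
memcurve bend-plan --target-curvature 0.2 --steps 40
memcurve build-bicelle --seed 1 --out bicelle.gro    # 17x6 grid per leaflet
memcurve fixtures --preset curved --seed 1
memcurve analyze apl --top fixture.gro --curvature 0.2
```

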