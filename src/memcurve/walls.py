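"""Dummy-particle repulsive walls restraining the membrane to a target curvature.

Each wall is a grid of independent beads.  A bead is an *anchor* — a dummy
particle fixed in absolute coordinates with no nonbonded interactions — plus
a *shell* particle tied to it by a zero-length harmonic bond.  The shells
interact only with the lipid tail carbons through a Lennard-Jones potential
chosen to be purely repulsive within the force-field short-range cutoff, so
the pair of walls confines the hydrophobic core to the prescribed shape
without touching head groups, cholesterol, water or ions.

Bending is performed by moving the anchors: a flat wall is mapped onto the
target cylinder arc by arc-length-preserving transfer of the in-plane x
coordinate, and intermediate steps interpolate the curvature linearly so
the bead grid spacing is conserved at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .frame import MembraneFrame, write_gro
from .geometry import SurfaceModel, make_surface

__all__ = [
    "WallSpec",
    "WallGeometry",
    "BendingPlan",
    "generate_walls",
    "check_repulsive",
    "scan_repulsive",
    "write_wall_files",
    "plan_bending",
    "n_steps_for_limit",
    "WallValidationError",
    "EmptyWallError",
]

J_PER_KJ = 1000.0


class WallValidationError(ValueError):
    """A WallSpec violates a hard invariant (e.g. the repulsivity guarantee)."""


class EmptyWallError(ValueError):
    """Grid spacing exceeds the requested wall extent."""


@dataclass(frozen=True)
class WallSpec:
    """Parameters of the restraining wall pair.

    Attributes
    ----------
    curvature : float
        Target signed mid-surface curvature c (nm^-1); 0 builds flat walls.
    separation : float
        Normal distance D between the two walls (nm).
    spacing : float
        Bead grid spacing d (nm), exact along the wall plane / arc.
    extent : (float, float)
        Wall size (length along the bending direction, length along Y), nm.
    sigma / epsilon_j_mol
        Shell-tail Lennard-Jones parameters; epsilon is stored in J/mol as
        configured and converted to kJ/mol when topology files are written.
    bond_k : float
        Anchor-shell harmonic bond force constant, kJ mol^-1 nm^-2 (length 0).
    cutoff : float
        Short-range cutoff r_c (nm) used by the force field; metadata for
        the repulsivity guarantee 2^(1/6) sigma >= r_c.
    tail_atom_types : tuple of str
        Atom types of the lipid tail carbons the shells repel.
    """

    curvature: float = 0.0
    separation: float = 5.0
    spacing: float = 0.51
    extent: tuple[float, float] = (12.0, 6.0)
    sigma: float = 0.85
    epsilon_j_mol: float = 1e-5
    bond_k: float = 10.0
    bond_length: float = 0.0
    cutoff: float = 0.8
    tail_atom_types: tuple[str, ...] = ("CT",)

    def __post_init__(self) -> None:
        if self.separation <= 0 or self.spacing <= 0:
            raise WallValidationError("separation and spacing must be positive")
        if self.sigma <= 0 or self.epsilon_j_mol <= 0:
            raise WallValidationError("LJ parameters must be positive")
        if 2.0 ** (1.0 / 6.0) * self.sigma < self.cutoff:
            raise WallValidationError(
                "repulsivity guarantee violated: 2^(1/6)*sigma = "
                f"{2.0 ** (1.0 / 6.0) * self.sigma:.4f} nm < cutoff "
                f"{self.cutoff} nm"
            )


@dataclass(frozen=True)
class WallGeometry:
    """Generated anchor/shell coordinates of the two walls.

    ``anchors[wall]`` and ``shells[wall]`` are (N, 3) arrays (nm) for
    ``wall`` in {"outer", "inner"}; anchors equal shells at generation time.
    ``mid_surface`` is the restrained membrane mid-surface; ``wall_surfaces``
    are its offsets at signed depth +D/2 (outer) and -D/2 (inner).
    """

    anchors: dict[str, np.ndarray]
    shells: dict[str, np.ndarray]
    mid_surface: SurfaceModel
    wall_surfaces: dict[str, SurfaceModel]
    spec: WallSpec

    @property
    def n_beads(self) -> dict[str, int]:
        return {w: len(a) for w, a in self.anchors.items()}

    def min_anchor_spacing(self, wall: str = "outer") -> float:
        """Minimum anchor-anchor Euclidean distance within one wall."""
        from scipy.spatial.distance import pdist

        return float(pdist(self.anchors[wall]).min())

    def arc_spacing(self, wall: str) -> np.ndarray:
        """Along-arc nearest-neighbor spacings of one wall's anchor grid."""
        a = self.anchors[wall]
        surf = self.wall_surfaces[wall]
        ys = np.unique(np.round(a[:, 1], 9))
        dists = []
        row = a[np.isclose(a[:, 1], ys[0])]
        if surf.kind == "plane":
            xs = np.sort(row[:, 0])
            dists.extend(np.diff(xs))
        else:
            cx, cz = surf.center
            ang = np.sort(np.arctan2(row[:, 0] - cx, (row[:, 2] - cz) * surf.outer_sign))
            dists.extend(np.diff(ang) * surf.radius)
        dists.extend(np.diff(np.sort(ys)))
        return np.asarray(dists)


def _flat_grid(spec: WallSpec) -> tuple[np.ndarray, np.ndarray]:
    lx, ly = spec.extent
    d = spec.spacing
    nx, ny = int(np.floor(lx / d)) + 1, int(np.floor(ly / d)) + 1
    if nx < 2 or ny < 2:
        raise EmptyWallError(
            f"spacing {d} nm leaves fewer than 2 beads over extent {spec.extent}"
        )
    x = (np.arange(nx) - (nx - 1) / 2.0) * d
    y = (np.arange(ny) - (ny - 1) / 2.0) * d
    return x, y


def _map_to_curvature(flat_xy_z: np.ndarray, c: float, depth: float) -> np.ndarray:
    """Arc-length-preserving map of flat wall points to curvature ``c``.

    The flat x coordinate becomes arc length on the wall's own circle at
    radius R + s*depth (R = 1/|c|, s = sign(c)), so along-arc spacing is
    conserved exactly.
    """
    if c == 0.0:
        out = flat_xy_z.copy()
        out[:, 2] = depth
        return out
    s = 1.0 if c > 0 else -1.0
    R = 1.0 / abs(c)
    r = R + s * depth
    if r <= 0:
        raise WallValidationError("wall radius non-positive at this curvature")
    alpha = flat_xy_z[:, 0] / r
    cz = -s * R  # axis position so the anchor point of the mid-surface is the origin
    out = np.empty_like(flat_xy_z)
    out[:, 0] = r * np.sin(alpha)
    out[:, 1] = flat_xy_z[:, 1]
    out[:, 2] = cz + s * r * np.cos(alpha)
    return out


def _offset(mid: SurfaceModel, depth: float) -> SurfaceModel:
    """Surface at constant signed depth from the mid-surface."""
    if mid.kind == "plane":
        return replace(mid, z0=mid.z0 + mid.outer_sign * depth)
    # signed depth d sits at radius R + s*d
    return replace(mid, radius=mid.radius + mid.outer_sign * depth)


def generate_walls(spec: WallSpec) -> WallGeometry:
    """Generate the anchor/shell bead grids of both walls.

    Flat case: two parallel planar grids at z = +-D/2 with exact spacing d.
    Curved case: coaxial cylindrical arcs at radii 1/|c| +- D/2, beads
    equally spaced along the arc and along Y (arc-length-preserving map of
    the flat grid, so bead counts match the flat walls).
    """
    x, y = _flat_grid(spec)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    flat = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    mid = make_surface(spec.curvature, (0.0, 0.0, 0.0))
    anchors, shells, wall_surfaces = {}, {}, {}
    for wall, depth in (("outer", +spec.separation / 2), ("inner", -spec.separation / 2)):
        pts = _map_to_curvature(flat, spec.curvature, depth)
        anchors[wall] = pts
        shells[wall] = pts.copy()
        wall_surfaces[wall] = _offset(mid, depth)
    return WallGeometry(anchors=anchors, shells=shells, mid_surface=mid,
                        wall_surfaces=wall_surfaces, spec=spec)


def check_repulsive(spec: WallSpec) -> float:
    """Largest r (nm) up to which the shell-tail LJ force is strictly repulsive.

    For V(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] the force is repulsive
    (dV/dr < 0) strictly below the potential minimum r_min = 2^(1/6) sigma.
    The "purely repulsive within the cutoff" guarantee holds iff
    r_min >= r_c.
    """
    return 2.0 ** (1.0 / 6.0) * spec.sigma


def lj_potential(r, sigma: float, epsilon: float):
    sr6 = (sigma / np.asarray(r, dtype=float)) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def scan_repulsive(sigma: float, epsilon: float, r_max: float, dr: float = 1e-4) -> float:
    """Numerical oracle: largest grid r with dV/dr < 0 on a ``dr`` grid.

    Scans the centred finite difference of the LJ potential from ``dr`` up
    to ``r_max`` and returns the largest radius before the first
    non-negative slope (or ``r_max`` if the slope stays negative).
    """
    r = np.arange(dr, r_max + dr, dr)
    v = lj_potential(r, sigma, epsilon)
    slope = np.gradient(v, r)
    bad = np.flatnonzero(slope >= 0)
    if len(bad) == 0:
        return float(r[-1])
    return float(r[bad[0] - 1]) if bad[0] > 0 else 0.0


def wall_frame(geom: WallGeometry) -> MembraneFrame:
    """Anchors-then-shells frame of the wall beads (resname WALO/WALI)."""
    names, resnames, resids, positions = [], [], [], []
    rid = 1
    for kind, store in (("ANC", geom.anchors), ("SHL", geom.shells)):
        for wall in ("outer", "inner"):
            pts = store[wall]
            resname = "WALO" if wall == "outer" else "WALI"
            for p in pts:
                names.append(kind)
                resnames.append(resname)
                resids.append(rid)
                positions.append(p)
                rid += 1
    positions = np.asarray(positions)
    span = positions.max(axis=0) - positions.min(axis=0) + 2.0
    n = len(names)
    return MembraneFrame(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        elements=np.full(n, "X", dtype=object),
        leaflet=np.full(n, "none", dtype=object),
        positions=positions,
        box=span,
    )


def wall_itp(geom: WallGeometry, spec: WallSpec, anchor_mode: str = "posres") -> str:
    """GROMACS ITP fragment for the wall beads.

    Declares the anchor type WANC with no nonbonded interactions, the shell
    type WSHL, zero-length harmonic anchor-shell bonds, and nonbond_params
    overrides pairing WSHL with each tail-carbon type at (sigma, epsilon).
    ``anchor_mode`` selects how anchors are immobilised: ``"posres"`` emits
    stiff position restraints, ``"freeze"`` emits a comment documenting the
    freezegrps alternative (set in the MDP, not the topology).
    """
    if anchor_mode not in ("posres", "freeze"):
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    eps_kj = spec.epsilon_j_mol / J_PER_KJ
    lines = [
        "; Repulsive wall beads: fixed anchors + shell particles",
        "; generated by memcurve (deterministic)",
        "",
        "[ atomtypes ]",
        ";  name  at.num     mass   charge  ptype    sigma      epsilon",
        "   WANC       0    1.000    0.000      A    0.000000    0.000000",
        "   WSHL       0    1.000    0.000      A    0.000000    0.000000",
        "",
        "[ nonbond_params ]",
        ";   i      j   func    sigma     epsilon",
    ]
    for t in spec.tail_atom_types:
        lines.append(
            f"  WSHL  {t:>5s}      1  {spec.sigma:8.4f}  {eps_kj:12.6e}"
            f" ; epsilon = {spec.epsilon_j_mol:g} J/mol"
        )
    lines += [
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        "WALL    0",
        "",
        "[ atoms ]",
        ";   nr  type  resnr  resid  atom  cgnr  charge  mass",
    ]
    idx = 1
    for wall in ("outer", "inner"):
        for _ in range(geom.n_beads[wall]):
            resname = "WALO" if wall == "outer" else "WALI"
            lines.append(
                f"  {idx:4d}  WANC  {idx:5d}  {resname}   ANC  {idx:4d}   0.000   1.000"
            )
            idx += 1
    shell_offset = idx - 1
    for wall in ("outer", "inner"):
        for _ in range(geom.n_beads[wall]):
            resname = "WALO" if wall == "outer" else "WALI"
            lines.append(
                f"  {idx:4d}  WSHL  {idx:5d}  {resname}   SHL  {idx:4d}   0.000   1.000"
            )
            idx += 1
    lines += [
        "",
        "[ bonds ]",
        ";   ai    aj  func   length        k",
    ]
    for i in range(1, shell_offset + 1):
        lines.append(
            f"  {i:4d}  {i + shell_offset:4d}     1    {spec.bond_length:.3f}"
            f"  {spec.bond_k:8.3f}"
        )
    if anchor_mode == "posres":
        lines += [
            "",
            "[ position_restraints ]",
            "; anchors held by stiff restraints (alternative: freezegrps in the MDP)",
            ";   ai  func      kx      ky      kz",
        ]
        for i in range(1, shell_offset + 1):
            lines.append(f"  {i:4d}     1  1.0e6  1.0e6  1.0e6")
    else:
        lines += [
            "",
            "; anchors immobilised via MDP freeze groups:",
            ";   freezegrps = WALL_ANCHORS",
            ";   freezedim  = Y Y Y",
        ]
    return "\n".join(lines) + "\n"


def write_wall_files(geom: WallGeometry, spec: WallSpec, prefix,
                     dialect: str = "gromacs", anchor_mode: str = "posres"):
    """Write ``<prefix>.gro`` and ``<prefix>.itp`` for the wall beads.

    Returns the two paths.  Output is byte-stable for identical input.
    """
    if dialect != "gromacs":
        raise ValueError(f"unknown dialect {dialect!r}")
    if sum(geom.n_beads.values()) == 0:
        raise EmptyWallError("wall geometry has no beads")
    gro_path, itp_path = f"{prefix}.gro", f"{prefix}.itp"
    write_gro(wall_frame(geom), gro_path, title="memcurve repulsive walls")
    with open(itp_path, "w") as fh:
        fh.write(wall_itp(geom, spec, anchor_mode=anchor_mode))
    return gro_path, itp_path


@dataclass(frozen=True)
class BendingPlan:
    """Anchor-coordinate schedule bending flat walls to a target curvature.

    ``steps[0]`` is the flat input, ``steps[-1]`` the target geometry; step
    k is generated at curvature ``k/N * c_target`` (linear in curvature, not
    in Cartesian coordinates), which conserves bead counts and along-arc
    grid spacing at every step.
    """

    steps: list[WallGeometry]
    curvatures: np.ndarray
    displacement_limit: float = 0.05

    @property
    def n_steps(self) -> int:
        return len(self.steps) - 1

    @property
    def max_step_displacement(self) -> float:
        """Largest anchor move (nm) between consecutive steps."""
        worst = 0.0
        for a, b in zip(self.steps[:-1], self.steps[1:]):
            for wall in ("outer", "inner"):
                worst = max(worst, float(
                    np.linalg.norm(b.anchors[wall] - a.anchors[wall], axis=1).max()
                ))
        return worst

    def satisfies_displacement_limit(self, limit: float | None = None) -> bool:
        lim = self.displacement_limit if limit is None else limit
        return self.max_step_displacement <= lim


def plan_bending(flat_geom: WallGeometry, c_target: float, n_steps: int) -> BendingPlan:
    """Plan the gradual bending of flat walls to curvature ``c_target``.

    Each flat anchor's in-plane x coordinate becomes arc length on the
    target circle; intermediate steps regenerate the geometry at linearly
    interpolated curvature values.
    """
    if n_steps < 1:
        raise WallValidationError("n_steps must be >= 1")
    if flat_geom.mid_surface.kind != "plane":
        raise WallValidationError("bending starts from flat walls")
    curvatures = np.linspace(0.0, c_target, n_steps + 1)
    steps = [flat_geom]
    for c in curvatures[1:]:
        steps.append(generate_walls(replace(flat_geom.spec, curvature=float(c))))
    return BendingPlan(steps=steps, curvatures=curvatures)


def n_steps_for_limit(flat_geom: WallGeometry, c_target: float,
                      limit: float = 0.05, n_max: int = 100000) -> int:
    """Smallest step count keeping every anchor move within ``limit`` nm."""
    lo = 1
    while lo <= n_max:
        plan = plan_bending(flat_geom, c_target, lo)
        if plan.satisfies_displacement_limit(limit):
            return lo
        lo *= 2
    raise WallValidationError("no step count satisfies the displacement limit")
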