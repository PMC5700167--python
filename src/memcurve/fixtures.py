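"""Synthetic membrane configurations with known ground truth.

These generators build idealised flat and cylindrically curved asymmetric
bilayers whose analysis observables are known by construction, so every
builder and analysis operation can be exercised without any external data:

* lipid head groups are placed on a regular grid realising a target area
  per lipid, on the plane or on coaxial cylinder arcs;
* pseudo-tails carry explicit C-H pairs whose orientation is drawn from a
  fixed-cone distribution around the local normal, so the imposed S_CD
  profile is realised exactly in expectation (cos theta = sqrt((2S+1)/3),
  random azimuth);
* cholesterol is split into a vertical leaflet-bound majority and a
  horizontal mid-membrane minority at an exact requested count.

Everything is deterministic per seed.  The companion ground-truth record
stores every imposed quantity for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import CHOLESTEROL, Config, default_config
from .frame import MembraneFrame
from .geometry import SurfaceModel, make_surface, outer_normal
from .system import Composition, cholesterol_template

__all__ = [
    "FixtureSpec",
    "make_membrane_fixture",
    "make_trajectory_fixture",
    "write_ground_truth",
    "FixtureValidationError",
]


class FixtureValidationError(ValueError):
    """Infeasible fixture geometry (e.g. arc overrun or negative radius)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth parameters of a synthetic membrane configuration.

    Attributes
    ----------
    curvature : float
        Signed mid-surface curvature c (nm^-1); 0 builds a flat membrane.
    composition : Composition
        Per-species (outer, inner) molecule counts.
    apl : dict
        Target area per lipid (nm^2) per leaflet, realised at the head
        surface when ``spacing_reference = "leaflet"``; with ``"mid"`` the
        same angular grid is used for both leaflets (equal counts per site)
        and the per-leaflet areas scale as (R +- t)/R.
    scd_profile : dict
        Imposed S_CD per tail carbon index; carbons not listed default to
        ``scd_default``.
    minor_fraction_percent : float
        Percentage of all cholesterol placed horizontally at mid-membrane.
    noise_sigma : float
        Isotropic Gaussian rigid-body positional noise per molecule (nm).
    head_offset : float
        Signed-depth magnitude of the head surfaces t (nm).
    n_rows : int
        Grid rows along Y per leaflet.
    """

    curvature: float = 0.0
    composition: Composition = field(default_factory=Composition)
    apl: dict = field(default_factory=lambda: {"outer": 0.60, "inner": 0.60})
    scd_profile: dict = field(default_factory=dict)
    scd_default: float = 0.15
    minor_fraction_percent: float = 0.0
    noise_sigma: float = 0.0
    head_offset: float = 2.0
    chol_oh_offset: float = 1.5
    chol_tilt_deg: float = 0.0
    n_rows: int = 6
    spacing_reference: str = "leaflet"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise FixtureValidationError("seed is mandatory")
        if self.spacing_reference not in ("leaflet", "mid"):
            raise FixtureValidationError(
                f"unknown spacing_reference {self.spacing_reference!r}"
            )
        if not (0.0 <= self.minor_fraction_percent <= 100.0):
            raise FixtureValidationError("minor fraction must be in [0, 100]")


def _imposed_scd(spec: FixtureSpec, i: int) -> float:
    return float(spec.scd_profile.get(i, spec.scd_default))


def _tangent_basis(surface: SurfaceModel, point: np.ndarray, leaflet: str):
    n = outer_normal(surface, point, leaflet)
    e2 = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(e2, n)
    e1 /= np.linalg.norm(e1)
    return e1, e2, n


def _leaflet_sites(spec: FixtureSpec, surface: SurfaceModel, leaflet: str,
                   n_lipids: int):
    """Head positions realising the target APL on the leaflet head surface."""
    sgn = 1.0 if leaflet == "outer" else -1.0
    t = sgn * spec.head_offset
    ny = spec.n_rows
    nx = int(np.ceil(n_lipids / ny))
    if spec.spacing_reference == "leaflet":
        a = float(np.sqrt(spec.apl[leaflet]))
        b = a
    else:
        a0 = float(np.sqrt(spec.apl[leaflet]))
        a, b = a0, a0   # angular spacing fixed at the mid-surface below
    xs = (np.arange(nx) - (nx - 1) / 2.0)
    ys = (np.arange(ny) - (ny - 1) / 2.0) * b
    sites = []
    if surface.kind == "plane":
        for ix in range(nx):
            for iy in range(ny):
                sites.append(np.array([xs[ix] * a, ys[iy], surface.z0 + t]))
    else:
        s = surface.outer_sign
        R = surface.radius
        r = R + s * t
        if r <= 0:
            raise FixtureValidationError("head surface radius non-positive")
        # arc spacing: at the head surface ("leaflet") or mid-surface ("mid")
        dalpha = a / r if spec.spacing_reference == "leaflet" else a / R
        if (nx - 1) * dalpha >= np.pi:
            raise FixtureValidationError(
                "lipid grid arc exceeds the half-cylinder; reduce APL or counts"
            )
        cx, cz = surface.center
        rx, rz = surface.ref_dir
        for ix in range(nx):
            alpha = xs[ix] * dalpha
            ca, sa = np.cos(alpha), np.sin(alpha)
            dirx = rx * ca + rz * sa
            dirz = rz * ca - rx * sa
            for iy in range(ny):
                sites.append(np.array([cx + r * dirx, ys[iy], cz + r * dirz]))
    return sites[:n_lipids]


def _build_tail(spec: FixtureSpec, smap, surface: SurfaceModel, head: np.ndarray,
                leaflet: str, rng) -> tuple[list[str], list[str], list[np.ndarray]]:
    """Chain atoms below one head with C-H pairs realising the S_CD profile."""
    e1, e2, n = _tangent_basis(surface, head, leaflet)
    names, elements, pos = [], [], []
    cc, ch = 0.125, 0.109
    for ci, chain in enumerate(smap.chains):
        lateral = ((-0.2, 0.2)[ci % 2]) * e1
        for k, i in enumerate(range(smap.first_carbon, smap.last_carbon + 1)):
            c_pos = head + lateral - (k + 1) * cc * n
            names.append(smap.carbon_name(i, chain))
            elements.append("C")
            pos.append(c_pos)
            s_target = _imposed_scd(spec, i)
            cos_t = np.sqrt((2.0 * s_target + 1.0) / 3.0)
            sin_t = np.sqrt(max(1.0 - cos_t**2, 0.0))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            for j, hname in enumerate(smap.hydrogen_names(i, chain)):
                ang = phi + j * np.pi
                d = cos_t * n + sin_t * (np.cos(ang) * e1 + np.sin(ang) * e2)
                names.append(hname)
                elements.append("H")
                pos.append(c_pos + ch * d)
    return names, elements, pos


def make_membrane_fixture(spec: FixtureSpec, config: Config | None = None):
    """Build one synthetic configuration; returns ``(frame, ground_truth)``.

    Lipids sit on grids realising the target APL, pseudo-tails realise the
    imposed S_CD profile exactly in expectation, and cholesterol splits
    into vertical and horizontal populations at the requested minor count.
    """
    cfg = config or default_config()
    rng = np.random.default_rng(spec.seed)
    surface = make_surface(spec.curvature)

    names, resnames, resids, elements, leaflet_tags, positions = [], [], [], [], [], []
    rid = 0

    def add(resname, anames, aelems, apos, tag):
        nonlocal rid
        rid += 1
        shift = rng.normal(0.0, spec.noise_sigma, 3) if spec.noise_sigma > 0 else 0.0
        for nm, el, p in zip(anames, aelems, apos):
            names.append(nm)
            resnames.append(resname)
            resids.append(rid)
            elements.append(el)
            leaflet_tags.append(tag)
            positions.append(np.asarray(p, dtype=float) + shift)

    counts = {lf: spec.composition.phospholipids(lf) for lf in ("outer", "inner")}
    for lf in ("outer", "inner"):
        n_pl = sum(counts[lf].values())
        species_list = []
        for sp, cnt in sorted(counts[lf].items()):
            species_list += [sp] * cnt
        species_list = [species_list[i] for i in rng.permutation(len(species_list))]
        sites = _leaflet_sites(spec, surface, lf, n_pl)
        if len(sites) < n_pl:
            raise FixtureValidationError("grid cannot host the requested lipids")
        for sp, head in zip(species_list, sites):
            smap = cfg.species[sp]
            tnames, telems, tpos = _build_tail(spec, smap, surface, head, lf, rng)
            add(sp, [smap.head_atom] + tnames, ["P"] + telems, [head] + tpos, lf)

    # cholesterol: horizontal minor pool first (exact count), rest vertical
    n_chol = {lf: spec.composition.cholesterol(lf) for lf in ("outer", "inner")}
    total_chol = sum(n_chol.values())
    n_minor = int(round(spec.minor_fraction_percent / 100.0 * total_chol))
    if n_minor > total_chol:
        raise FixtureValidationError("minor count exceeds total cholesterol")
    take_outer = min(n_chol["outer"], (n_minor + 1) // 2)
    take = {"outer": take_outer, "inner": n_minor - take_outer}
    if take["inner"] > n_chol["inner"]:
        raise FixtureValidationError("not enough cholesterol for the minor pool")
    cmap = cfg.cholesterol
    _, c_elems, _ = cholesterol_template(cmap)
    axis_len = 0.9

    def chol_sites(n, lf, depth):
        sgn = 1.0 if lf == "outer" else -1.0
        span = 0.8 * np.sqrt(sum(counts[lf].values()) * spec.apl[lf])
        out = []
        for _ in range(n):
            x = rng.uniform(-span / 2, span / 2)
            y = rng.uniform(-spec.n_rows / 2, spec.n_rows / 2)
            if surface.kind == "plane":
                out.append(np.array([x, y, surface.z0 + sgn * depth]))
            else:
                s = surface.outer_sign
                r = surface.radius + s * sgn * depth
                alpha = x / r
                cx, cz = surface.center
                rx, rz = surface.ref_dir
                dirx = rx * np.cos(alpha) + rz * np.sin(alpha)
                dirz = rz * np.cos(alpha) - rx * np.sin(alpha)
                out.append(np.array([cx + r * dirx, y, cz + r * dirz]))
        return out

    for lf in ("outer", "inner"):
        n_vert = n_chol[lf] - take[lf]
        for p_oh in chol_sites(n_vert, lf, spec.chol_oh_offset):
            e1, e2, n = _tangent_basis(surface, p_oh, lf)
            tilt = np.radians(spec.chol_tilt_deg)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            axis = (np.cos(tilt) * n
                    + np.sin(tilt) * (np.cos(phi) * e1 + np.sin(phi) * e2))
            add(CHOLESTEROL, [cmap.oh_atom, cmap.branch_atom], c_elems,
                [p_oh, p_oh - axis_len * axis], lf)
        for p_oh in chol_sites(take[lf], lf, 0.0):
            # horizontal: long axis along Y, oxygen on the mid-surface
            add(CHOLESTEROL, [cmap.oh_atom, cmap.branch_atom], c_elems,
                [p_oh, p_oh - axis_len * np.array([0.0, 1.0, 0.0])], "central")

    positions = np.asarray(positions)
    span = positions.max(axis=0) - positions.min(axis=0) + 2.0
    frame = MembraneFrame(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        elements=np.array(elements, dtype=object),
        leaflet=np.array(leaflet_tags, dtype=object),
        positions=positions,
        box=span,
    )
    smap_any = next(iter(cfg.species.values()))
    truth = {
        "curvature": spec.curvature,
        "apl_outer": spec.apl["outer"],
        "apl_inner": spec.apl["inner"],
        "spacing_reference": spec.spacing_reference,
        "head_offset": spec.head_offset,
        "scd": {i: _imposed_scd(spec, i)
                for i in range(smap_any.first_carbon, smap_any.last_carbon + 1)},
        "n_cholesterol": total_chol,
        "n_minor": n_minor,
        "minor_fraction_percent": 100.0 * n_minor / total_chol if total_chol else 0.0,
        "chol_tilt_deg": spec.chol_tilt_deg,
        "seed": spec.seed,
    }
    return frame, truth


def make_trajectory_fixture(spec: FixtureSpec, n_frames: int, jitter: float = 0.0,
                            config: Config | None = None):
    """Independent jittered replicas of the base fixture.

    Each frame re-draws the per-molecule rigid noise and tail azimuths from
    a seed derived deterministically from ``spec.seed`` and the frame
    number; ground truth is unchanged in expectation.  ``jitter = 0`` with
    ``n_frames = 1`` reproduces the base frame exactly.
    """
    if n_frames < 1:
        raise FixtureValidationError("n_frames must be >= 1")
    frames = []
    truth = None
    for k in range(n_frames):
        fspec = spec if k == 0 else replace(
            spec, seed=(spec.seed + 1000003 * k) % (2**31 - 1)
        )
        if jitter > 0:
            fspec = replace(fspec, noise_sigma=jitter)
        frame, t = make_membrane_fixture(fspec, config)
        truth = truth or t
        frames.append(frame)
    return frames, truth


def write_ground_truth(truth: dict, path) -> None:
    """Sidecar key=value ground-truth record (deterministic ordering)."""
    lines = []
    for key in sorted(truth):
        val = truth[key]
        if isinstance(val, dict):
            for k2 in sorted(val):
                lines.append(f"{key}.{k2} = {val[k2]}")
        else:
            lines.append(f"{key} = {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
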