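"""Curvature-aware membrane analyses.

All analyses use the *signed depth* from the fitted mid-surface as the
transverse coordinate and the local outer normal of the lipid's own leaflet
as the reference direction, so the same code handles flat and cylindrically
curved configurations.  Analyses are restricted to a sector around the
bicelle symmetry plane to exclude the caps.

Implemented quantities:

* density profiles of atom groups along the depth coordinate, volume-
  corrected for the cylindrical geometry and normalised to unit integral;
* deuterium order parameters S_CD(i) = <(3 cos^2 theta - 1)/2> of the tail
  C-H bonds against the local outer normal;
* per-lipid areas from the Voronoi cell of each head group on its local
  tangent plane;
* cholesterol inclination/depth statistics and the minor (mid-membrane,
  horizontal) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import Voronoi, cKDTree

from .config import CHOLESTEROL, PHOSPHOLIPIDS, Config, default_config
from .frame import MembraneFrame
from .geometry import SectorSpec, SurfaceModel, outer_normal, sector_mask, signed_depth
from .system import NamingConventionError

__all__ = [
    "DensityProfile",
    "OrderParameterProfile",
    "AreaPerLipidReport",
    "CholesterolReport",
    "density_profiles",
    "default_groups",
    "order_parameters",
    "areas_per_lipid",
    "aggregate_apl",
    "cholesterol_metrics",
    "head_surface_depths",
    "EmptyGroupError",
    "ExplicitHydrogensError",
]


class EmptyGroupError(ValueError):
    """An atom-group selector resolved to zero atoms."""


class ExplicitHydrogensError(ValueError):
    """Order parameters require explicit tail hydrogens."""


def _as_surface_list(surfaces, n: int) -> list[SurfaceModel]:
    if isinstance(surfaces, SurfaceModel):
        return [surfaces] * n
    surfaces = list(surfaces)
    if len(surfaces) != n:
        raise ValueError("need one surface per frame")
    return surfaces


# ---------------------------------------------------------------- densities


@dataclass
class DensityProfile:
    """Normalised density along the signed-depth coordinate.

    ``profiles[(group, leaflet)]`` is a density array over ``centers``;
    each profile integrates to one.
    """

    centers: np.ndarray
    bin_width: float
    profiles: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def integral(self, key) -> float:
        return float(np.sum(self.profiles[key]) * self.bin_width)

    def peak_depth(self, key) -> float:
        return float(self.centers[int(np.argmax(self.profiles[key]))])


def default_groups(frame: MembraneFrame, config: Config | None = None):
    """Standard group masks: phospholipid head groups, tails, cholesterol."""
    cfg = config or default_config()
    resnames = frame.resnames.astype(str)
    names = frame.names.astype(str)
    is_pl = np.isin(resnames, PHOSPHOLIPIDS)
    heads = np.zeros(frame.n_atoms, dtype=bool)
    tails = np.zeros(frame.n_atoms, dtype=bool)
    for sp in PHOSPHOLIPIDS:
        smap = cfg.species[sp]
        sel = resnames == sp
        heads |= sel & (names == smap.head_atom)
        carbon_names = {
            smap.carbon_name(i, ch)
            for ch in smap.chains
            for i in range(smap.first_carbon, smap.last_carbon + 1)
        }
        tails |= sel & np.isin(names, sorted(carbon_names))
    chol = (resnames == CHOLESTEROL) & (frame.elements.astype(str) != "H")
    groups = {"heads": heads, "tails": tails, "chol": chol}
    return {k: v for k, v in groups.items() if np.any(v)}


def density_profiles(
    frames,
    surfaces,
    groups: dict[str, np.ndarray],
    bin_width: float = 0.01,
    sector: SectorSpec | None = None,
    weighting: str = "mass",
    split_leaflets: bool = True,
) -> DensityProfile:
    """Histogram atom groups along the signed depth, volume-corrected.

    The per-bin volume is constant for a plane and proportional to
    ``|R + depth|`` for a cylinder (cylindrical shell); after the volume
    correction every profile is normalised to unit integral.
    ``weighting`` is ``"mass"`` or ``"number"``.
    """
    frames = list(frames)
    surfaces = _as_surface_list(surfaces, len(frames))
    for gname, mask in groups.items():
        if not np.any(mask):
            raise EmptyGroupError(f"group {gname!r} selects no atoms")

    # first pass: global depth range over selected atoms
    union = np.zeros(frames[0].n_atoms, dtype=bool)
    for mask in groups.values():
        union |= mask
    dmin, dmax = np.inf, -np.inf
    for fr, surf in zip(frames, surfaces):
        d = signed_depth(surf, fr.positions[union])
        dmin, dmax = min(dmin, d.min()), max(dmax, d.max())
    lo = np.floor(dmin / bin_width) * bin_width
    hi = np.ceil(dmax / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    keys: dict[tuple[str, str], np.ndarray] = {}
    for fr, surf in zip(frames, surfaces):
        depth = signed_depth(surf, fr.positions)
        sec = sector_mask(surf, fr.positions, sector)
        w_all = fr.masses if weighting == "mass" else np.ones(fr.n_atoms)
        tags = fr.leaflet.astype(str)
        for gname, gmask in groups.items():
            leaflets = sorted(set(tags[gmask])) if split_leaflets else ["all"]
            for lf in leaflets:
                sel = gmask & sec
                if split_leaflets:
                    sel = sel & (tags == lf)
                if not np.any(sel):
                    continue
                hist, _ = np.histogram(depth[sel], bins=edges, weights=w_all[sel])
                keys.setdefault((gname, lf), np.zeros(len(centers)))
                keys[(gname, lf)] += hist

    profiles = {}
    for key, hist in keys.items():
        surf0 = surfaces[0]
        if surf0.kind == "cylinder":
            vol = np.abs(surf0.radius + centers)
            vol = np.where(vol < 1e-9, 1e-9, vol)
        else:
            vol = np.ones_like(centers)
        dens = hist / vol
        total = dens.sum() * bin_width
        if total > 0:
            dens = dens / total
        profiles[key] = dens
    return DensityProfile(centers=centers, bin_width=bin_width, profiles=profiles)


# ---------------------------------------------------------- order parameters


@dataclass
class OrderParameterProfile:
    """Per-carbon S_CD statistics for one species and leaflet."""

    species: str
    leaflet: str
    carbons: np.ndarray            # carbon indices i
    mean: np.ndarray               # <S_CD>(i)
    std: np.ndarray
    n_samples: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species, "leaflet": self.leaflet,
            "carbon": self.carbons, "scd_mean": self.mean,
            "scd_std": self.std, "n": self.n_samples,
        })


def _ch_topology(frame: MembraneFrame, species: str, cfg: Config):
    """Per-residue (carbon index, C atom row, H atom rows) for one species.

    The atom layout is assumed identical across frames (same topology), so
    this is computed once on the first frame.
    """
    smap = cfg.species[species]
    resnames = frame.resnames.astype(str)
    names = frame.names.astype(str)
    entries = []   # (resid, head_row, [(i, c_row, [h_rows]), ...])
    for atom_idx in frame.residue_indices(resnames == species):
        name_of = {names[i]: i for i in atom_idx}
        head = name_of.get(smap.head_atom)
        triples = []
        for chain in smap.chains:
            for i in range(smap.first_carbon, smap.last_carbon + 1):
                c = name_of.get(smap.carbon_name(i, chain))
                if c is None:
                    continue
                hs = [name_of[h] for h in smap.hydrogen_names(i, chain)
                      if h in name_of]
                if not hs:
                    raise ExplicitHydrogensError(
                        f"carbon {smap.carbon_name(i, chain)} of {species} "
                        "has no explicit hydrogens"
                    )
                triples.append((i, c, hs))
        if triples:
            entries.append((head if head is not None else atom_idx[0], triples))
    if not entries:
        raise EmptyGroupError(f"no {species} residues found")
    return entries


def order_parameters(
    frames,
    species: str,
    leaflet: str,
    surfaces,
    sector: SectorSpec | None = None,
    config: Config | None = None,
) -> OrderParameterProfile:
    """Deuterium order parameter profile of one species in one leaflet.

    For each tail carbon i, ``S_CD(i) = <(3 cos^2 theta - 1)/2>`` where
    theta is the angle between each C_i-H bond and the local outer normal of
    the lipid's leaflet, averaged over hydrogens, molecules and frames whose
    head reference atom lies in the analysis sector.
    """
    cfg = config or default_config()
    if species not in cfg.species:
        raise EmptyGroupError(f"unknown species {species!r}")
    frames = list(frames)
    surfaces = _as_surface_list(surfaces, len(frames))
    entries = _ch_topology(frames[0], species, cfg)

    acc: dict[int, list[np.ndarray]] = {}
    tags0 = frames[0].leaflet.astype(str)
    for fr, surf in zip(frames, surfaces):
        tags = fr.leaflet.astype(str)
        for head, triples in entries:
            if tags[head] != leaflet:
                continue
            if not sector_mask(surf, fr.positions[head], sector)[0]:
                continue
            for i, c, hs in triples:
                n = outer_normal(surf, fr.positions[c], leaflet)
                vec = fr.positions[hs] - fr.positions[c]
                vec = vec / np.linalg.norm(vec, axis=1)[:, None]
                cos = vec @ n
                acc.setdefault(i, []).append(0.5 * (3.0 * cos**2 - 1.0))

    if not acc:
        raise EmptyGroupError(
            f"no {species} molecules in leaflet {leaflet!r} within the sector"
        )
    carbons = np.array(sorted(acc))
    mean = np.array([np.concatenate(acc[i]).mean() for i in carbons])
    std = np.array([np.concatenate(acc[i]).std(ddof=0) for i in carbons])
    ns = np.array([sum(len(a) for a in acc[i]) for i in carbons])
    return OrderParameterProfile(species=species, leaflet=leaflet,
                                 carbons=carbons, mean=mean, std=std,
                                 n_samples=ns)


# ------------------------------------------------------------ area per lipid


def _head_sites(frame: MembraneFrame, cfg: Config):
    """(resid, species, leaflet, position) of every lipid head reference atom."""
    resnames = frame.resnames.astype(str)
    names = frame.names.astype(str)
    tags = frame.leaflet.astype(str)
    rows = []
    for atom_idx in frame.residue_indices():
        sp = resnames[atom_idx[0]]
        if sp in PHOSPHOLIPIDS:
            ref = cfg.species[sp].head_atom
        elif sp == CHOLESTEROL:
            ref = cfg.cholesterol.oh_atom
        else:
            continue
        sel = atom_idx[names[atom_idx] == ref]
        if len(sel) == 0:
            raise NamingConventionError(f"{sp} residue lacks head atom {ref!r}")
        i = int(sel[0])
        rows.append((int(frame.resids[i]), sp, tags[i], i))
    return rows


def _voronoi_cell_area(points2d: np.ndarray, max_vertex_dist: float = np.inf) -> float:
    """Area of the Voronoi cell of points2d[0]; NaN if unbounded.

    A cell with a vertex farther than ``max_vertex_dist`` from the target is
    treated as unbounded: it extends beyond the sampled neighbourhood, so
    its area is not trustworthy (typical for edge lipids).
    """
    if len(points2d) < 4:
        return np.nan
    try:
        vor = Voronoi(points2d)
    except Exception:
        return np.nan
    region = vor.regions[vor.point_region[0]]
    if -1 in region or len(region) < 3:
        return np.nan
    poly = vor.vertices[region]
    if np.any(np.linalg.norm(poly - points2d[0], axis=1) > max_vertex_dist):
        return np.nan
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def areas_per_lipid(
    frame: MembraneFrame,
    surface: SurfaceModel,
    cutoff: float = 1.5,
    sector: SectorSpec | None = None,
    config: Config | None = None,
) -> pd.DataFrame:
    """Tangent-plane Voronoi area of every lipid head group.

    For each lipid, neighbours' head positions within ``cutoff`` (nm) are
    projected onto the tangent plane defined by the local outer normal at
    the target head, and the area of the target's bounded Voronoi cell is
    returned.  Unbounded (edge) cells get ``area = NaN`` and
    ``bounded = False``; they are excluded from leaflet means downstream.
    Columns: resid, species, leaflet, area, bounded.
    """
    cfg = config or default_config()
    sites = _head_sites(frame, cfg)
    if len(sites) < 4:
        raise EmptyGroupError("need at least 4 lipids for the tessellation")
    pos = np.array([frame.positions[i] for *_x, i in sites])
    tags = np.array([t for _r, _s, t, _i in sites])
    in_sector = sector_mask(surface, pos, sector)
    tree = cKDTree(pos)

    records = []
    for k, (resid, sp, tag, _i) in enumerate(sites):
        if tag not in ("outer", "inner") or not in_sector[k]:
            continue
        neigh = [j for j in tree.query_ball_point(pos[k], cutoff)
                 if j != k and tags[j] == tag]
        area = np.nan
        if len(neigh) >= 3:
            n = outer_normal(surface, pos[k], "outer")
            e2 = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(e2, n)
            e1 /= np.linalg.norm(e1)
            rel = pos[[k] + neigh] - pos[k]
            pts2d = np.column_stack([rel @ e1, rel @ e2])
            area = _voronoi_cell_area(pts2d, max_vertex_dist=cutoff)
        records.append({
            "resid": resid, "species": sp, "leaflet": tag,
            "area": area, "bounded": bool(np.isfinite(area)),
        })
    return pd.DataFrame.from_records(records)


@dataclass
class AreaPerLipidReport:
    """Species x leaflet area-per-lipid statistics over molecule-frames."""

    table: pd.DataFrame   # species, leaflet, mean_nm2, std_nm2, n

    def mean(self, species: str | None = None, leaflet: str | None = None) -> float:
        t = self.table
        if species is not None:
            t = t[t.species == species]
        if leaflet is not None:
            t = t[t.leaflet == leaflet]
        w = t["n"].to_numpy(dtype=float)
        return float(np.average(t["mean_nm2"], weights=w))


def aggregate_apl(per_frame: list[pd.DataFrame]) -> AreaPerLipidReport:
    """Pool per-frame Voronoi areas into species x leaflet statistics.

    Unbounded cells are dropped; means and standard deviations run over all
    molecule-frames.
    """
    if not per_frame:
        raise EmptyGroupError("need at least one frame of areas")
    allf = pd.concat(per_frame, ignore_index=True)
    allf = allf[allf.bounded]
    g = allf.groupby(["species", "leaflet"])["area"]
    table = g.agg(mean_nm2="mean", std_nm2=lambda x: x.std(ddof=0), n="count")
    return AreaPerLipidReport(table=table.reset_index())


# -------------------------------------------------------------- cholesterol


@dataclass
class CholesterolReport:
    """Cholesterol orientation, depth and minor-fraction statistics.

    Histograms are probability masses (sum to 1).  ``minor_fraction_percent``
    counts molecules whose hydroxyl oxygen lies within the central half-width
    of the mid-surface, relative to all cholesterol in the sector.
    """

    angle_centers: np.ndarray
    angle_hist: dict[str, np.ndarray]          # leaflet -> mass histogram
    depth_centers: np.ndarray
    depth_hist: dict[str, np.ndarray]
    angle_peak_deg: dict[str, float]
    depth_peak_nm: dict[str, float]
    minor_fraction_percent: float
    n_total: int
    n_central: int


def head_surface_depths(frames, surfaces, config: Config | None = None):
    """Per-leaflet head-group surface depth: peak of the head density.

    Returns ``{"outer": d_out, "inner": d_in}`` (signed depths, nm).
    """
    cfg = config or default_config()
    frames = list(frames)
    all_groups = default_groups(frames[0], cfg)
    if "heads" not in all_groups:
        raise EmptyGroupError("no phospholipid head groups present")
    groups = {"heads": all_groups["heads"]}
    prof = density_profiles(frames, surfaces, groups, bin_width=0.025)
    out = {}
    for lf in ("outer", "inner"):
        key = ("heads", lf)
        if key in prof.profiles:
            out[lf] = prof.peak_depth(key)
    return out


def _smoothed_peak(centers: np.ndarray, hist: np.ndarray, bandwidth_bins: float = 2.0) -> float:
    if hist.sum() == 0:
        return float("nan")
    smooth = gaussian_filter1d(hist.astype(float), bandwidth_bins)
    return float(centers[int(np.argmax(smooth))])


def cholesterol_metrics(
    frames,
    surfaces,
    sector: SectorSpec | None = None,
    central_halfwidth: float = 0.5,
    head_depths: dict[str, float] | None = None,
    config: Config | None = None,
    angle_bin_deg: float = 2.0,
    depth_bin_nm: float = 0.025,
) -> CholesterolReport:
    """Inclination, depth-from-surface and minor-fraction statistics.

    The long axis of each cholesterol is the vector from the tail-branching
    carbon to the hydroxyl oxygen; the inclination is its angle against the
    local outer normal of the molecule's leaflet.  Depth is measured from
    the leaflet's head-group surface (peak of the head density, or the
    depths supplied in ``head_depths``) to the hydroxyl oxygen.  Molecules
    whose oxygen lies within ``central_halfwidth`` of the mid-surface form
    the minor (horizontal) pool.
    """
    cfg = config or default_config()
    frames = list(frames)
    surfaces = _as_surface_list(surfaces, len(frames))
    if head_depths is None:
        try:
            head_depths = head_surface_depths(frames, surfaces, cfg)
        except EmptyGroupError:
            head_depths = {}

    resnames0 = frames[0].resnames.astype(str)
    names0 = frames[0].names.astype(str)
    pairs = []   # (oh_row, branch_row)
    for atom_idx in frames[0].residue_indices(resnames0 == CHOLESTEROL):
        name_of = {names0[i]: i for i in atom_idx}
        try:
            pairs.append((name_of[cfg.cholesterol.oh_atom],
                          name_of[cfg.cholesterol.branch_atom]))
        except KeyError as exc:
            raise NamingConventionError(
                f"cholesterol residue lacks defining atom {exc}"
            ) from exc
    if not pairs:
        raise EmptyGroupError("no cholesterol residues found")

    angles = {"outer": [], "inner": [], "central": []}
    depths = {"outer": [], "inner": [], "central": []}
    n_total = 0
    n_central = 0
    for fr, surf in zip(frames, surfaces):
        for oh, br in pairs:
            p_oh = fr.positions[oh]
            if not sector_mask(surf, p_oh, sector)[0]:
                continue
            n_total += 1
            d_mid = signed_depth(surf, p_oh)
            central = abs(d_mid) <= central_halfwidth
            leaflet = "central" if central else ("outer" if d_mid > 0 else "inner")
            if central:
                n_central += 1
            ref_leaflet = "outer" if leaflet == "central" else leaflet
            n = outer_normal(surf, p_oh, ref_leaflet)
            axis = p_oh - fr.positions[br]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                raise NamingConventionError("degenerate cholesterol long axis")
            cos = float(np.clip(axis @ n / norm, -1.0, 1.0))
            angles[leaflet].append(np.degrees(np.arccos(cos)))
            surf_depth = head_depths.get(
                ref_leaflet, (1 if ref_leaflet == "outer" else -1) * 2.0
            )
            depths[leaflet].append(abs(surf_depth) - abs(d_mid))

    angle_edges = np.arange(0.0, 180.0 + angle_bin_deg, angle_bin_deg)
    angle_centers = 0.5 * (angle_edges[:-1] + angle_edges[1:])
    all_d = np.concatenate([np.asarray(v) for v in depths.values() if v]) if n_total else np.array([0.0])
    lo = np.floor(all_d.min() / depth_bin_nm) * depth_bin_nm
    hi = np.ceil(all_d.max() / depth_bin_nm) * depth_bin_nm + depth_bin_nm
    depth_edges = np.arange(lo, hi + depth_bin_nm / 2, depth_bin_nm)
    depth_centers = 0.5 * (depth_edges[:-1] + depth_edges[1:])

    angle_hist, depth_hist, angle_peak, depth_peak = {}, {}, {}, {}
    for lf in ("outer", "inner", "central"):
        if not angles[lf]:
            continue
        ah, _ = np.histogram(angles[lf], bins=angle_edges)
        dh, _ = np.histogram(depths[lf], bins=depth_edges)
        angle_hist[lf] = ah / ah.sum()
        depth_hist[lf] = dh / dh.sum()
        angle_peak[lf] = _smoothed_peak(angle_centers, ah)
        depth_peak[lf] = _smoothed_peak(depth_centers, dh)

    return CholesterolReport(
        angle_centers=angle_centers,
        angle_hist=angle_hist,
        depth_centers=depth_centers,
        depth_hist=depth_hist,
        angle_peak_deg=angle_peak,
        depth_peak_nm=depth_peak,
        minor_fraction_percent=100.0 * n_central / n_total if n_total else 0.0,
        n_total=n_total,
        n_central=n_central,
    )
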