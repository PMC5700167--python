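"""Initial asymmetric bicelle assembly and the selective inter-leaflet repulsion.

The starting structure places the phospholipids of each monolayer on a
rectangular grid (17 x 6 by default) with cholesterol intercalated at random
positions between them.  The species occupying the grid sites are shuffled
deterministically from a seed, so a given (composition, grid, seed) triple
always produces a byte-identical frame.

Because the lipid content of the two monolayers differs, their mixing
through the bicelle caps must be prevented: all heavy atoms of the
phospholipids — except the distal tail carbons below the 9-10 double bond —
receive a weak artificial Lennard-Jones repulsion (sigma 0.8 nm, epsilon
1e-7 J/mol) acting between opposite leaflets only.  Cholesterol is excluded
entirely so it can diffuse freely through the caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CHOLESTEROL, PHOSPHOLIPIDS, Config, SpeciesMap, default_config
from .frame import MembraneFrame
from .geometry import SurfaceModel, signed_depth

__all__ = [
    "Composition",
    "RepulsionSpec",
    "build_bicelle",
    "selective_repulsion_atoms",
    "assign_leaflets",
    "CompositionError",
    "SpeciesError",
    "TaggingError",
    "NamingConventionError",
]

J_PER_KJ = 1000.0


class CompositionError(ValueError):
    """Per-leaflet lipid counts do not match the requested grid capacity."""


class SpeciesError(ValueError):
    """Unknown lipid species."""


class TaggingError(ValueError):
    """Lipid atoms lack the leaflet tags an operation requires."""


class NamingConventionError(KeyError):
    """A defining atom (head phosphorus, cholesterol -OH...) is missing."""


@dataclass(frozen=True)
class Composition:
    """Per-species (outer, inner) molecule counts.

    The default is the asymmetric plasma-membrane composition: outer leaflet
    SM 42 / PC 46 / PE 14 / PS 0, inner leaflet SM 12 / PC 14 / PE 46 /
    PS 30, with 51 cholesterol per leaflet (102 phospholipids + 51
    cholesterol per monolayer).
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "SM": (42, 12),
        "PC": (46, 14),
        "PE": (14, 46),
        "PS": (0, 30),
        "CHOL": (51, 51),
    })

    def __post_init__(self) -> None:
        for sp, (o, i) in self.counts.items():
            if sp not in PHOSPHOLIPIDS and sp != CHOLESTEROL:
                raise SpeciesError(f"unknown species {sp!r}")
            if o < 0 or i < 0:
                raise CompositionError("counts must be non-negative")

    def phospholipids(self, leaflet: str) -> dict[str, int]:
        col = 0 if leaflet == "outer" else 1
        return {sp: c[col] for sp, c in self.counts.items() if sp != CHOLESTEROL}

    def cholesterol(self, leaflet: str) -> int:
        col = 0 if leaflet == "outer" else 1
        return self.counts.get(CHOLESTEROL, (0, 0))[col]

    def n_phospholipids(self, leaflet: str) -> int:
        return sum(self.phospholipids(leaflet).values())


@dataclass(frozen=True)
class RepulsionSpec:
    """Selective inter-monolayer repulsion parameters.

    Acts only between atoms of opposite leaflet tags; hydrogens and
    cholesterol are never included, and tail carbons at or beyond
    ``distal_from`` (per species map) are excluded so the tail ends of the
    two leaflets interdigitate normally in the bilayer region.
    """

    sigma: float = 0.8
    epsilon_j_mol: float = 1e-7


# --- pseudo-lipid templates ---------------------------------------------------
# Minimal single-conformer coordinates per species: head phosphorus, two
# acyl/sphingosine chains of explicit-H carbons.  Offsets are relative to the
# head position, with the chain extending toward the membrane centre (-z in
# template space); the inner leaflet uses the mirrored template.

_CC = 0.125   # per-carbon depth increment, nm
_CH = 0.109   # C-H bond length, nm


def lipid_template(species: str, smap: SpeciesMap):
    """(names, elements, offsets) of one phospholipid in template space."""
    names = [smap.head_atom]
    elements = ["P"]
    offsets = [(0.0, 0.0, 0.0)]
    for ci, chain in enumerate(smap.chains):
        xoff = (-0.2, 0.2)[ci % 2]
        for k, i in enumerate(range(smap.first_carbon, smap.last_carbon + 1)):
            z = -(k + 1) * _CC
            names.append(smap.carbon_name(i, chain))
            elements.append("C")
            offsets.append((xoff, 0.0, z))
            for j, hname in enumerate(smap.hydrogen_names(i, chain)):
                names.append(hname)
                elements.append("H")
                offsets.append((xoff + (_CH if j == 0 else -_CH), 0.0, z))
    return names, elements, np.asarray(offsets)


def cholesterol_template(cmap):
    """(names, elements, offsets) of the minimal cholesterol model.

    The hydroxyl oxygen sits at the placement point; the tail-branching
    carbon lies 0.9 nm deeper, so the long axis (branch -> OH) points along
    the leaflet normal in template space.
    """
    names = [cmap.oh_atom, cmap.branch_atom]
    elements = ["O", "C"]
    offsets = np.array([(0.0, 0.0, 0.0), (0.0, 0.0, -0.9)])
    return names, elements, offsets


def build_bicelle(
    comp: Composition,
    grid: tuple[int, int] = (17, 6),
    spacing: float = 0.8,
    chol_mode: str = "intercalated_random",
    seed: int = 0,
    head_depth: float = 2.0,
    chol_oh_depth: float = 1.6,
    config: Config | None = None,
) -> MembraneFrame:
    """Assemble the initial flat asymmetric bicelle.

    Each monolayer is an ``nx x ny`` grid of phospholipids (species shuffled
    deterministically by ``seed``) with its cholesterol intercalated at
    seeded random in-plane positions.  Heads sit at signed depth
    ``+-head_depth``; chains point toward the mid-plane.  Per-species
    per-leaflet counts in the result match ``comp`` exactly.
    """
    if chol_mode != "intercalated_random":
        raise SpeciesError(f"unknown chol_mode {chol_mode!r}")
    cfg = config or default_config()
    nx, ny = grid
    rng = np.random.default_rng(seed)

    names, resnames, resids, elements, leaflet, positions = [], [], [], [], [], []
    rid = 0

    def add_molecule(resname, anames, aelems, offs, origin, flip, tag):
        nonlocal rid
        rid += 1
        offs = offs.copy()
        if flip:
            offs[:, 2] = -offs[:, 2]
        for nm, el, off in zip(anames, aelems, offs):
            names.append(nm)
            resnames.append(resname)
            resids.append(rid)
            elements.append(el)
            leaflet.append(tag)
            positions.append(np.asarray(origin) + off)

    lx, ly = nx * spacing, ny * spacing
    for tag, zsign in (("outer", +1), ("inner", -1)):
        species_list = []
        for sp, count in sorted(comp.phospholipids(tag).items()):
            species_list += [sp] * count
        if len(species_list) != nx * ny:
            raise CompositionError(
                f"{tag} leaflet has {len(species_list)} phospholipids for a "
                f"{nx}x{ny} grid ({nx * ny} sites)"
            )
        species_list = [species_list[i] for i in rng.permutation(len(species_list))]
        site = 0
        for ix in range(nx):
            for iy in range(ny):
                sp = species_list[site]
                site += 1
                origin = (
                    (ix + 0.5) * spacing - lx / 2,
                    (iy + 0.5) * spacing - ly / 2,
                    zsign * head_depth,
                )
                anames, aelems, offs = lipid_template(sp, cfg.species[sp])
                add_molecule(sp, anames, aelems, offs, origin, zsign < 0, tag)
        for _ in range(comp.cholesterol(tag)):
            origin = (
                rng.uniform(-lx / 2, lx / 2),
                rng.uniform(-ly / 2, ly / 2),
                zsign * chol_oh_depth,
            )
            anames, aelems, offs = cholesterol_template(cfg.cholesterol)
            add_molecule(CHOLESTEROL, anames, aelems, offs, origin, zsign < 0, tag)

    return MembraneFrame(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        elements=np.array(elements, dtype=object),
        leaflet=np.array(leaflet, dtype=object),
        positions=np.asarray(positions),
        box=np.array([lx + 4.0, ly, 2 * head_depth + 4.0]),
    )


def _included_in_repulsion(frame: MembraneFrame, i: int, cfg: Config) -> bool:
    resname = str(frame.resnames[i])
    if resname not in PHOSPHOLIPIDS:
        return False                      # cholesterol, walls, solvent
    if str(frame.elements[i]) == "H":
        return False
    smap = cfg.species[resname]
    name = str(frame.names[i])
    for chain in smap.chains:
        ci = smap.carbon_index(name, chain)
        if ci is not None and ci >= smap.distal_from:
            return False                  # distal tail carbon
    return True


def selective_repulsion_atoms(
    frame: MembraneFrame,
    spec: RepulsionSpec = RepulsionSpec(),
    config: Config | None = None,
):
    """Atom sets and topology override implementing the inter-leaflet repulsion.

    Returns ``(outer_idx, inner_idx, override_text)``: the two disjoint
    index arrays of included atoms (heavy phospholipid atoms above the
    distal-tail boundary) and a GROMACS-style nonbond_params override text
    assigning the (sigma, epsilon) pair interaction between the two sets
    via duplicated per-leaflet atom types.
    """
    cfg = config or default_config()
    lipid = np.isin(frame.resnames.astype(str), PHOSPHOLIPIDS)
    tags = frame.leaflet.astype(str)
    if np.any(lipid & ~np.isin(tags, ("outer", "inner"))):
        raise TaggingError("phospholipid atoms without a leaflet tag")
    keep = np.array(
        [_included_in_repulsion(frame, i, cfg) for i in range(frame.n_atoms)],
        dtype=bool,
    )
    outer_idx = np.flatnonzero(keep & (tags == "outer"))
    inner_idx = np.flatnonzero(keep & (tags == "inner"))
    eps_kj = spec.epsilon_j_mol / J_PER_KJ
    override = "\n".join([
        "; Selective inter-monolayer repulsion (acts between leaflets only):",
        "; heavy phospholipid atoms above the distal-tail boundary carry",
        "; duplicated leaflet-specific atom types; the only modified pair",
        "; interaction is REPO x REPI.  Cholesterol and hydrogens excluded.",
        f"; included atoms: outer {len(outer_idx)}, inner {len(inner_idx)}",
        "[ nonbond_params ]",
        ";   i      j   func    sigma     epsilon",
        f"  REPO   REPI      1  {spec.sigma:8.4f}  {eps_kj:12.6e}"
        f" ; epsilon = {spec.epsilon_j_mol:g} J/mol",
    ]) + "\n"
    return outer_idx, inner_idx, override


def assign_leaflets(
    frame: MembraneFrame,
    surface: SurfaceModel,
    chol_central_halfwidth: float = 0.5,
    config: Config | None = None,
) -> MembraneFrame:
    """Tag every lipid by the signed depth of its head reference atom.

    Phospholipids are tagged outer/inner by the sign of the depth at their
    head phosphorus; cholesterol by its hydroxyl oxygen, or ``central`` when
    the oxygen lies within ``chol_central_halfwidth`` of the mid-surface.
    Non-lipid residues are tagged ``none``.
    """
    cfg = config or default_config()
    tags = np.full(frame.n_atoms, "none", dtype=object)
    for atom_idx in frame.residue_indices():
        resname = str(frame.resnames[atom_idx[0]])
        if resname in PHOSPHOLIPIDS:
            ref = cfg.species[resname].head_atom
        elif resname == CHOLESTEROL:
            ref = cfg.cholesterol.oh_atom
        else:
            continue
        sel = atom_idx[frame.names[atom_idx] == ref]
        if len(sel) == 0:
            raise NamingConventionError(
                f"residue {int(frame.resids[atom_idx[0]])} ({resname}) lacks "
                f"head reference atom {ref!r}"
            )
        depth = signed_depth(surface, frame.positions[sel[0]])
        if resname == CHOLESTEROL and abs(depth) <= chol_central_halfwidth:
            tag = "central"
        else:
            tag = "outer" if depth > 0 else "inner"
        tags[atom_idx] = tag
    out = frame.select(np.ones(frame.n_atoms, dtype=bool))
    out.leaflet = tags
    return out
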