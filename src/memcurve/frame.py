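"""Membrane configuration container and coordinate file IO.

A :class:`MembraneFrame` is a flat array-of-atoms view of one configuration:
atom and residue names, per-atom element and leaflet tags, positions in nm
and the (rectangular) box.  Files are written with an in-package fixed-column
GRO formatter so output is byte-stable; reading of GRO/PDB single frames and
XTC/TRR trajectories goes through MDAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["MembraneFrame", "write_gro", "read_frame", "read_trajectory", "ATOMIC_MASSES"]

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06,
    # dummy wall particles are massless for analysis purposes
    "X": 0.0,
}

LEAFLET_CODES = ("none", "outer", "inner", "central")


@dataclass
class MembraneFrame:
    """One membrane configuration.

    Attributes
    ----------
    names, resnames : arrays of str
        Atom and residue names.
    resids : int array
        Residue index, unique per molecule.
    elements : array of str
        Element symbols ("H", "C", ..., "X" for dummy particles).
    leaflet : array of str
        Per-atom leaflet tag: "outer", "inner", "central" or "none";
        all atoms of one lipid share a tag.
    positions : (N, 3) float array, nm.
    box : (3,) float array, nm (rectangular box lengths).
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    elements: np.ndarray
    leaflet: np.ndarray
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.elements = np.asarray(self.elements, dtype=object)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        for arr in (self.resnames, self.resids, self.elements, self.leaflet):
            if len(arr) != n:
                raise ValueError("per-atom arrays must share one length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements], dtype=float)

    def select(self, mask: np.ndarray) -> "MembraneFrame":
        """Sub-frame of the atoms where ``mask`` is true (tags preserved)."""
        return MembraneFrame(
            names=self.names[mask],
            resnames=self.resnames[mask],
            resids=self.resids[mask],
            elements=self.elements[mask],
            leaflet=self.leaflet[mask],
            positions=self.positions[mask],
            box=self.box.copy(),
        )

    def with_positions(self, positions: np.ndarray) -> "MembraneFrame":
        return replace(self, positions=np.asarray(positions, dtype=float))

    def residue_indices(self, mask: np.ndarray | None = None) -> list[np.ndarray]:
        """Atom-index groups, one per residue (in order of first appearance)."""
        idx = np.arange(self.n_atoms) if mask is None else np.flatnonzero(mask)
        groups: dict[int, list[int]] = {}
        for i in idx:
            groups.setdefault(int(self.resids[i]), []).append(int(i))
        return [np.array(v) for v in groups.values()]

    def atom_index_in_residue(self, resid: int, name: str) -> int:
        hit = np.flatnonzero((self.resids == resid) & (self.names == name))
        if len(hit) == 0:
            raise KeyError(f"atom {name!r} not found in residue {resid}")
        return int(hit[0])


def guess_element(name: str) -> str:
    """Element from an atom name: leading letter after stripping digits."""
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    first = stripped[0].upper()
    return first if first in ATOMIC_MASSES else "X"


def write_gro(frame: MembraneFrame, path, title: str = "memcurve frame") -> None:
    """Write a GRO file (fixed columns, nm, 3 decimals); deterministic."""
    lines = [title, f"{frame.n_atoms:5d}"]
    for i in range(frame.n_atoms):
        resid = int(frame.resids[i]) % 100000
        atomid = (i + 1) % 100000
        lines.append(
            f"{resid:5d}{str(frame.resnames[i])[:5]:<5s}"
            f"{str(frame.names[i])[:5]:>5s}{atomid:5d}"
            f"{frame.positions[i, 0]:8.3f}{frame.positions[i, 1]:8.3f}"
            f"{frame.positions[i, 2]:8.3f}"
        )
    lines.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _frame_from_universe(u, leaflet=None) -> MembraneFrame:
    ag = u.atoms
    names = ag.names.astype(object)
    elements = np.array([guess_element(n) for n in names], dtype=object)
    box = np.asarray(u.dimensions[:3], dtype=float) / 10.0  # A -> nm
    return MembraneFrame(
        names=names,
        resnames=ag.resnames.astype(object),
        resids=ag.resids.astype(int),
        elements=elements,
        leaflet=np.full(len(names), "none", dtype=object) if leaflet is None else leaflet,
        positions=ag.positions.astype(float) / 10.0,  # A -> nm
        box=box,
    )


def read_frame(path) -> MembraneFrame:
    """Read a single-frame GRO/PDB file into a MembraneFrame (positions in nm)."""
    import MDAnalysis as mda

    return _frame_from_universe(mda.Universe(str(path)))


def read_trajectory(topology, trajectory) -> list[MembraneFrame]:
    """Read every frame of an XTC/TRR (or multi-frame) trajectory."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    frames = []
    for _ts in u.trajectory:
        frames.append(_frame_from_universe(u))
    return frames


def write_trajectory(frames: list[MembraneFrame], path) -> None:
    """Write frames as an XTC/TRR trajectory via MDAnalysis (format from suffix)."""
    import MDAnalysis as mda

    base = frames[0]
    u = mda.Universe.empty(
        base.n_atoms,
        n_residues=len(np.unique(base.resids)),
        atom_resindex=np.unique(base.resids, return_inverse=True)[1],
        trajectory=True,
    )
    u.dimensions = [*(base.box * 10.0), 90.0, 90.0, 90.0]
    with mda.Writer(str(path), n_atoms=base.n_atoms) as w:
        for fr in frames:
            u.atoms.positions = fr.positions * 10.0  # nm -> A
            u.dimensions = [*(fr.box * 10.0), 90.0, 90.0, 90.0]
            w.write(u.atoms)
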