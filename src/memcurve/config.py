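"""Resolved configuration: species naming maps and physical defaults.

Default parameter values are the ones used for the curvature-restrained
bicelle setup: wall LJ sigma 0.85 nm / epsilon 1e-5 J/mol, anchor-shell bond
force constant 10 kJ mol^-1 nm^-2, wall separation 5.0 nm, bead grid spacing
0.51 nm, selective inter-monolayer repulsion sigma 0.8 nm / epsilon
1e-7 J/mol.  Atom naming is configurable; the defaults below describe the
pseudo-lipid templates shipped with the package (Slipids-style names can be
substituted via YAML).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["SpeciesMap", "Config", "default_config", "PHOSPHOLIPIDS", "CHOLESTEROL"]

PHOSPHOLIPIDS = ("SM", "PC", "PE", "PS")
CHOLESTEROL = "CHOL"


@dataclass
class SpeciesMap:
    """Atom-naming convention for one lipid species.

    ``chains`` are chain letters; tail carbon *i* of chain X is named by
    ``carbon_template`` (default ``C{i}{X}``) and carries hydrogens named by
    ``hydrogen_template`` (``H{i}{X}{j}`` for j in 1..2).  ``first_carbon``/
    ``last_carbon`` bound the tail numbering; ``distal_from`` is the first
    carbon index counted as distal (below the 9-10 double bond), excluded
    from the selective inter-leaflet repulsion.
    """

    head_atom: str = "P"
    chains: tuple[str, ...] = ("A", "B")
    carbon_template: str = "C{i}{chain}"
    hydrogen_template: str = "H{i}{chain}{j}"
    first_carbon: int = 2
    last_carbon: int = 18
    distal_from: int = 10

    def carbon_name(self, i: int, chain: str) -> str:
        return self.carbon_template.format(i=i, chain=chain)

    def hydrogen_names(self, i: int, chain: str) -> list[str]:
        return [self.hydrogen_template.format(i=i, chain=chain, j=j) for j in (1, 2)]

    def carbon_index(self, name: str, chain: str) -> int | None:
        """Tail-carbon index encoded in ``name`` for ``chain``, else None."""
        for i in range(self.first_carbon, self.last_carbon + 1):
            if name == self.carbon_name(i, chain):
                return i
        return None


@dataclass
class CholesterolMap:
    """Defining atoms of cholesterol: hydroxyl oxygen and tail-branching carbon."""

    oh_atom: str = "O3"
    branch_atom: str = "C17"
    ring_carbons: tuple[str, ...] = ("C17",)


@dataclass
class Config:
    """Umbrella configuration with YAML round trip."""

    species: dict = field(default_factory=lambda: {
        "SM": SpeciesMap(last_carbon=16),
        "PC": SpeciesMap(),
        "PE": SpeciesMap(),
        "PS": SpeciesMap(),
    })
    cholesterol: CholesterolMap = field(default_factory=CholesterolMap)
    # wall defaults (published setup values)
    wall_separation_nm: float = 5.0
    wall_spacing_nm: float = 0.51
    wall_sigma_nm: float = 0.85
    wall_epsilon_j_mol: float = 1e-5
    wall_bond_k: float = 10.0          # kJ mol^-1 nm^-2
    cutoff_nm: float = 0.8
    # selective repulsion defaults
    repulsion_sigma_nm: float = 0.8
    repulsion_epsilon_j_mol: float = 1e-7
    # analysis defaults
    sector_half_angle_deg: float = 30.0
    sector_half_width_fraction: float = 0.3   # of the bicelle X extent, flat case
    chol_central_halfwidth_nm: float = 0.5
    density_bin_nm: float = 0.01
    depth_bin_nm: float = 0.025
    angle_bin_deg: float = 2.0
    voronoi_cutoff_nm: float = 1.5
    seed: int = 42

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        species = {
            name: SpeciesMap(**{k: tuple(v) if k == "chains" else v
                                for k, v in sm.items()})
            for name, sm in data.pop("species").items()
        }
        chol = data.pop("cholesterol")
        chol = CholesterolMap(
            oh_atom=chol["oh_atom"],
            branch_atom=chol["branch_atom"],
            ring_carbons=tuple(chol["ring_carbons"]),
        )
        return cls(species=species, cholesterol=chol, **data)


def default_config() -> Config:
    return Config()
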