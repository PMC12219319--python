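"""Molecular topology: atoms, bonded terms, exclusion policy.

A :class:`MolecularTopology` is the single source of truth for a system's
composition.  Atoms carry their Lennard-Jones parameters and point charges;
bonds are either harmonic, ½k(r−r₀)², or Morse, D(1−e^{−a(r−r₀)})² — the
anharmonic form used for X–H stretches (hydroxyls, amines, thiols) where
zero-point motion probes the asymmetry of the well.  Deuteration is a pure
mass substitution: classical statistical mechanics is mass-independent for
equilibrium structure, so any isotope effect measured downstream is a
nuclear quantum effect by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np

VALID_ELEMENTS = {
    "H", "D", "C", "N", "O", "F", "S", "Cl", "Br", "I", "P",
    "X", "Y", "Z",  # generic toy-site labels
}

#: mass of hydrogen / deuterium, g/mol
H_MASS = 1.008
D_MASS = 2.014


class TopologyError(ValueError):
    """Raised for invalid topology definitions."""


@dataclass(frozen=True)
class AtomSpec:
    """One atom: element, mass (g/mol), charge (e), LJ σ (Å) / ε (kJ/mol)."""

    element: str
    mass: float
    charge: float = 0.0
    sigma: float = 1.0
    epsilon: float = 0.0
    type_label: str = ""

    def __post_init__(self):
        if self.element not in VALID_ELEMENTS:
            raise TopologyError(
                f"unknown element {self.element!r}; valid: {sorted(VALID_ELEMENTS)}"
            )
        if not self.mass > 0:
            raise TopologyError(f"mass must be positive, got {self.mass}")
        if not self.sigma > 0:
            raise TopologyError(f"sigma must be positive, got {self.sigma}")
        if self.epsilon < 0:
            raise TopologyError(f"epsilon must be non-negative, got {self.epsilon}")


@dataclass(frozen=True)
class BondTerm:
    """Bonded pair with either a harmonic or a Morse potential."""

    i: int
    j: int
    form: Literal["harmonic", "morse"] = "harmonic"
    k: float | None = None      # kJ/mol/Å², harmonic
    r0: float = 1.0             # Å
    D: float | None = None      # kJ/mol, Morse well depth
    a: float | None = None      # Å⁻¹, Morse width

    def __post_init__(self):
        if self.i == self.j:
            raise TopologyError("bond between an atom and itself")
        if self.form == "harmonic":
            if self.k is None or not self.k > 0:
                raise TopologyError("harmonic bond requires k > 0")
        elif self.form == "morse":
            if self.D is None or self.a is None:
                raise TopologyError("morse bond requires fields D and a")
            if not (self.D > 0 and self.a > 0):
                raise TopologyError("morse bond requires D > 0 and a > 0")
        else:
            raise TopologyError(f"unknown bond form {self.form!r}")


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle ½k_θ(θ−θ₀)²; k_θ in kJ/mol/rad², θ₀ in rad."""

    i: int
    j: int  # vertex
    k: int
    k_theta: float = 0.0
    theta0: float = np.pi

    def __post_init__(self):
        if self.k_theta < 0:
            raise TopologyError("k_theta must be non-negative")
        if len({self.i, self.j, self.k}) != 3:
            raise TopologyError("angle requires three distinct atoms")


@dataclass(frozen=True)
class DihedralTerm:
    """Cosine-series dihedral Σ_n c_n[1+cos(nφ−φ₀_n)]. Optional for toys."""

    i: int
    j: int
    k: int
    l: int
    coefficients: tuple[float, ...] = ()      # c_n, kJ/mol, n = 1..len
    phases: tuple[float, ...] = ()            # φ₀_n, rad


@dataclass(frozen=True)
class TetherTerm:
    """Harmonic restraint ½k|x−x₀|² to a fixed lab-frame point.

    Used for validation systems (e.g. the exactly solvable harmonic
    oscillator); not part of any liquid topology.
    """

    i: int
    k: float
    x0: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class MolecularTopology:
    """Atoms plus bonded terms and the nonbonded exclusion policy.

    ``scale_14`` multiplies LJ and Coulomb interactions between atoms three
    bonds apart; 1-2 and 1-3 pairs are always fully excluded.
    """

    atoms: list[AtomSpec]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    tethers: list[TetherTerm] = field(default_factory=list)
    scale_14: float = 0.5
    name: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise TopologyError(f"bond index out of range: ({b.i},{b.j})")
        for t in self.tethers:
            if not 0 <= t.i < n:
                raise TopologyError(f"tether index out of range: {t.i}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def total_mass(self) -> float:
        """g/mol summed over all atoms in the box."""
        return float(self.masses.sum())

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def molecules(self) -> list[list[int]]:
        """Connected components of the bond graph, each sorted."""
        comps = nx.connected_components(self.bond_graph())
        return sorted([sorted(c) for c in comps])

    @property
    def n_molecules(self) -> int:
        return len(self.molecules())

    def molecule_index(self) -> np.ndarray:
        """Per-atom molecule id."""
        idx = np.empty(self.n_atoms, dtype=int)
        for m, comp in enumerate(self.molecules()):
            idx[comp] = m
        return idx

    def exclusion_pairs(self) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
        """(fully excluded 1-2/1-3 pairs, scaled 1-4 pairs), i<j ordered."""
        g = self.bond_graph()
        excluded: set[tuple[int, int]] = set()
        scaled: set[tuple[int, int]] = set()
        lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
        for i, dists in lengths.items():
            for j, d in dists.items():
                if j <= i:
                    continue
                if d in (1, 2):
                    excluded.add((i, j))
                elif d == 3:
                    scaled.add((i, j))
        return excluded, scaled

    def deuterated(self) -> "MolecularTopology":
        """Replace every H by D (mass substitution only: same charge/LJ)."""
        new_atoms = [
            replace(a, element="D", mass=D_MASS) if a.element == "H" else a
            for a in self.atoms
        ]
        return replace_atoms(self, new_atoms, name=self.name + "-D")


def replace_atoms(
    top: MolecularTopology, atoms: Sequence[AtomSpec], name: str | None = None
) -> MolecularTopology:
    return MolecularTopology(
        atoms=list(atoms),
        bonds=top.bonds,
        angles=top.angles,
        dihedrals=top.dihedrals,
        tethers=top.tethers,
        scale_14=top.scale_14,
        name=top.name if name is None else name,
    )


def replicate(top: MolecularTopology, n_copies: int) -> MolecularTopology:
    """Tile a single-molecule topology into n identical molecules."""
    atoms: list[AtomSpec] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    dihedrals: list[DihedralTerm] = []
    n = top.n_atoms
    for c in range(n_copies):
        off = c * n
        atoms.extend(top.atoms)
        bonds.extend(replace(b, i=b.i + off, j=b.j + off) for b in top.bonds)
        angles.extend(
            replace(t, i=t.i + off, j=t.j + off, k=t.k + off) for t in top.angles
        )
        dihedrals.extend(
            replace(t, i=t.i + off, j=t.j + off, k=t.k + off, l=t.l + off)
            for t in top.dihedrals
        )
    return MolecularTopology(
        atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals,
        scale_14=top.scale_14, name=top.name,
    )
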