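"""Distance-resolved intermolecular interaction analyses.

Three profiles over the center-of-mass separation r_CM of molecule pairs,
discretized into 50 bins between 3.3 and 9 Å:

* hydrogen-bond density n_HB(r): geometric criterion — donor–acceptor
  distance ≤ 3.6 Å and D–H···A angle at the hydrogen ≥ 150°, intermolecular
  only; counts per bin divided by the system volume;
* pairwise interaction energy E_int(r): the summed nonbonded (LJ +
  Coulomb) energy between the two molecules of each pair;
* orientation ⟨cos θ⟩(r): mean cosine of the angle between one selected
  bond vector per molecule (e.g. the C–O bond of an alcohol).

SEMs come from the scatter across independent replicas.  All distances use
the minimum-image convention in a cubic box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .forcefield import minimum_image, waldman_hagler_mix
from .constants import COULOMB
from .topology import MolecularTopology

DONOR_ELEMENTS = frozenset({"O", "N", "S"})
ACCEPTOR_ELEMENTS = frozenset({"O", "N"})

R_MIN, R_MAX, N_BINS = 3.3, 9.0, 50


class SelectionError(ValueError):
    """Raised when a donor/acceptor/bond selector cannot be resolved."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (closed boundaries)."""

    distance_cutoff: float = 3.6   # Å, donor–acceptor
    angle_cutoff: float = 150.0    # degrees, D–H···A at the hydrogen
    donor_elements: frozenset = DONOR_ELEMENTS
    acceptor_elements: frozenset = ACCEPTOR_ELEMENTS

    def __post_init__(self):
        if not self.distance_cutoff > 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 <= self.angle_cutoff <= 180.0:
            raise ValueError("angle cutoff must be within [0°, 180°]")


@dataclass
class Frame:
    """One configuration: positions (N,3) Å and cubic box edge (Å)."""

    positions: np.ndarray
    box: float


@dataclass
class DistanceProfile:
    edges: np.ndarray     # 51 monotone bin edges, Å
    values: np.ndarray    # per-bin mean
    sems: np.ndarray      # per-bin SEM across replicas (0 for one replica)
    tag: str              # "n_HB" | "E_int" | "cos_theta"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def default_edges() -> np.ndarray:
    return np.linspace(R_MIN, R_MAX, N_BINS + 1)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def _donor_hydrogens(topology: MolecularTopology, criteria: HBondCriteria):
    """(donor_index, hydrogen_index) pairs from the bond graph."""
    elems = topology.elements
    pairs = []
    for b in topology.bonds:
        for d, h in ((b.i, b.j), (b.j, b.i)):
            if elems[h] in ("H", "D") and elems[d] in criteria.donor_elements:
                pairs.append((d, h))
    return pairs


def _acceptors(topology: MolecularTopology, criteria: HBondCriteria):
    return [i for i, e in enumerate(topology.elements) if e in criteria.acceptor_elements]


def find_hbonds(
    frame: Frame,
    topology: MolecularTopology,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, int, int]]:
    """All intermolecular (donor, H, acceptor) triples meeting the criteria.

    Boundary values (exactly 3.6 Å or exactly 150°) count as bonded.
    """
    dh = _donor_hydrogens(topology, criteria)
    acc = _acceptors(topology, criteria)
    if not dh or not acc:
        import warnings

        warnings.warn("no donors or acceptors in selection", stacklevel=2)
        return []
    pos, box = frame.positions, frame.box
    mol = topology.molecule_index()
    out = []
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    acc = np.asarray(acc)
    for d, h in dh:
        da = minimum_image(pos[acc] - pos[d], box)
        dist = np.linalg.norm(da, axis=1)
        ok = (dist <= criteria.distance_cutoff) & (mol[acc] != mol[d])
        for a_idx, da_vec in zip(acc[ok], da[ok]):
            hd = minimum_image(pos[d] - pos[h], box)
            ha = minimum_image(pos[a_idx] - pos[h], box)
            cos = (hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
            # angle ≥ cutoff  ⇔  cos(angle) ≤ cos(cutoff)
            if cos <= cos_cut + 1e-12:
                out.append((d, h, int(a_idx)))
    return out


def molecule_com(positions: np.ndarray, masses: np.ndarray, box: float) -> np.ndarray:
    """Center of mass with the molecule unwrapped about its first atom."""
    rel = minimum_image(positions - positions[0], box)
    com = positions[0] + (masses[:, None] * rel).sum(0) / masses.sum()
    return com


def com_distance(
    mol_a: Sequence[int], mol_b: Sequence[int], frame: Frame, topology: MolecularTopology
) -> float:
    """Minimum-image center-of-mass separation of two molecules, Å."""
    m = topology.masses
    ca = molecule_com(frame.positions[list(mol_a)], m[list(mol_a)], frame.box)
    cb = molecule_com(frame.positions[list(mol_b)], m[list(mol_b)], frame.box)
    return float(np.linalg.norm(minimum_image(ca - cb, frame.box)))


def _all_com(frame: Frame, topology: MolecularTopology) -> np.ndarray:
    m = topology.masses
    return np.array(
        [molecule_com(frame.positions[mol], m[mol], frame.box)
         for mol in topology.molecules()]
    )


def _pair_com_distances(frame: Frame, topology: MolecularTopology):
    """(i, j, r_CM) for all molecule pairs i<j."""
    coms = _all_com(frame, topology)
    n = len(coms)
    iu, ju = np.triu_indices(n, k=1)
    d = minimum_image(coms[iu] - coms[ju], frame.box)
    return iu, ju, np.linalg.norm(d, axis=1)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def _replica_profile(per_replica: list[np.ndarray], tag: str,
                     edges: np.ndarray) -> DistanceProfile:
    import warnings as _warnings

    arr = np.asarray(per_replica, dtype=float)
    with _warnings.catch_warnings():
        # bins with no pairs in any replica are legitimately all-NaN
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(arr, axis=0)
        if arr.shape[0] > 1:
            sems = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(arr.shape[0])
        else:
            sems = np.zeros_like(values)
    return DistanceProfile(edges=edges, values=values, sems=np.nan_to_num(sems), tag=tag)


def hbond_density_profile(
    replicas: list[list[Frame]],
    topology: MolecularTopology,
    criteria: HBondCriteria = HBondCriteria(),
    edges: np.ndarray | None = None,
) -> DistanceProfile:
    """Hydrogen bonds per bin per volume, averaged over frames and replicas.

    A bond is binned at the r_CM of its donor/acceptor molecule pair;
    pairs outside [3.3, 9] Å are dropped.
    """
    edges = default_edges() if edges is None else edges
    if not replicas or not any(replicas):
        raise ValueError("need at least one frame")
    mol_idx = topology.molecule_index()
    per_rep = []
    for frames in replicas:
        counts = np.zeros(len(edges) - 1)
        vol_sum = 0.0
        for frame in frames:
            vol_sum += frame.box**3
            for d, h, a in find_hbonds(frame, topology, criteria):
                mols = topology.molecules()
                r = com_distance(mols[mol_idx[d]], mols[mol_idx[a]], frame, topology)
                b = np.searchsorted(edges, r, side="right") - 1
                if 0 <= b < len(counts):
                    counts[b] += 1.0
        mean_vol = vol_sum / len(frames)
        per_rep.append(counts / len(frames) / mean_vol)
    return _replica_profile(per_rep, "n_HB", edges)


def pair_interaction_energy(
    frame: Frame,
    topology: MolecularTopology,
    mol_a: Sequence[int],
    mol_b: Sequence[int],
    cutoff: float = 14.0,
) -> float:
    """Summed LJ + bare Coulomb energy between two molecules, kJ/mol."""
    pos, box = frame.positions, frame.box
    atoms = topology.atoms
    e = 0.0
    for i in mol_a:
        d = minimum_image(pos[list(mol_b)] - pos[i], box)
        r = np.linalg.norm(d, axis=1)
        for j_local, j in enumerate(mol_b):
            rij = r[j_local]
            if rij > cutoff:
                continue
            p = waldman_hagler_mix(atoms[i], atoms[j])
            s6 = (p.sigma_ij / rij) ** 6
            e += 4.0 * p.epsilon_ij * (s6 * s6 - s6)
            e += COULOMB * atoms[i].charge * atoms[j].charge / rij
    return float(e)


def interaction_energy_profile(
    replicas: list[list[Frame]],
    topology: MolecularTopology,
    cutoff: float = 14.0,
    edges: np.ndarray | None = None,
) -> DistanceProfile:
    """Mean molecule–molecule nonbonded energy per r_CM bin (no tail)."""
    edges = default_edges() if edges is None else edges
    mols = topology.molecules()
    per_rep = []
    for frames in replicas:
        sums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1)
        for frame in frames:
            iu, ju, r = _pair_com_distances(frame, topology)
            for i, j, rij in zip(iu, ju, r):
                b = np.searchsorted(edges, rij, side="right") - 1
                if 0 <= b < len(sums):
                    sums[b] += pair_interaction_energy(
                        frame, topology, mols[i], mols[j], cutoff
                    )
                    counts[b] += 1.0
        with np.errstate(invalid="ignore"):
            per_rep.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    return _replica_profile(per_rep, "E_int", edges)


def _resolve_bond_vectors(
    frame: Frame,
    topology: MolecularTopology,
    bond_selector: Callable[[str, str], bool] | tuple[str, str],
) -> np.ndarray:
    """One unit bond vector per molecule; error unless exactly one match."""
    if isinstance(bond_selector, tuple):
        pair = tuple(sorted(bond_selector))
        selector = lambda a, b: tuple(sorted((a, b))) == pair  # noqa: E731
    else:
        selector = bond_selector
    elems = topology.elements
    mol_idx = topology.molecule_index()
    n_mol = topology.n_molecules
    vecs: list[list[np.ndarray]] = [[] for _ in range(n_mol)]
    for b in topology.bonds:
        if selector(elems[b.i], elems[b.j]):
            # orient consistently: from the lexicographically smaller element
            i, j = (b.i, b.j) if elems[b.i] <= elems[b.j] else (b.j, b.i)
            v = minimum_image(frame.positions[j] - frame.positions[i], frame.box)
            vecs[mol_idx[b.i]].append(v / np.linalg.norm(v))
    bad = [m for m, v in enumerate(vecs) if len(v) != 1]
    if bad:
        raise SelectionError(
            f"bond selector must match exactly one bond per molecule; "
            f"molecules {bad[:5]} match {[len(vecs[m]) for m in bad[:5]]}"
        )
    return np.array([v[0] for v in vecs])


def orientation_profile(
    replicas: list[list[Frame]],
    topology: MolecularTopology,
    bond_selector,
    edges: np.ndarray | None = None,
) -> DistanceProfile:
    """⟨cos θ⟩ between the selected bond vectors of molecule pairs per bin."""
    edges = default_edges() if edges is None else edges
    per_rep = []
    for frames in replicas:
        sums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1)
        for frame in frames:
            vecs = _resolve_bond_vectors(frame, topology, bond_selector)
            iu, ju, r = _pair_com_distances(frame, topology)
            cos = (vecs[iu] * vecs[ju]).sum(axis=1)
            for rij, c in zip(r, cos):
                b = np.searchsorted(edges, rij, side="right") - 1
                if 0 <= b < len(sums):
                    sums[b] += c
                    counts[b] += 1.0
        with np.errstate(invalid="ignore"):
            per_rep.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    return _replica_profile(per_rep, "cos_theta", edges)
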