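"""Generators for every input the pipeline needs, with known ground truth.

Three families:

* **Toy liquids** — 2–4 site flexible molecules (a stiff X–H diatomic, a
  bent triatomic, a 4-site chain with one polar hydroxyl head), 20–50
  molecules per box: large enough for barostat and dielectric statistics,
  small enough for minutes-scale 32-bead path-integral runs.  Stiff X–H
  stretches (k ≈ 3000 kJ/mol/Å²; βħω ≈ 13 at 298 K, ≈ 26 at the 150 K
  study temperature) make the hydrogen sites strongly quantum, so
  ring-polymer delocalization visibly expands the liquid relative to its
  classical counterpart.  Deuteration is a mass substitution
  (1.008 → 2.014 g/mol).

* **Observable fixtures** — synthetic time series whose population
  statistics hit requested property targets exactly in expectation
  (Gaussian volumes with variance κ_T·k_B T·⟨V⟩, Gaussian dipoles sized to
  a requested ε_r(0), mean-volume triplets encoding a requested α_P), used
  to validate the estimators against their generating parameters.

* **Feature datasets** — 92-row molecule tables with the generative
  structure Δ_vm = g(m_w, n_H)·α_P + noise, where the latent reduced
  temperature g is smooth, saturating-increasing in n_H and non-monotone
  (bump-shaped) in m_w, and α_P carries a weak negative correlation with
  n_H.  The latent g is returned for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ATM, COULOMB, KB, NA
from .observables import ObservableSeries
from .topology import (
    AngleTerm,
    AtomSpec,
    BondTerm,
    MolecularTopology,
    replicate,
)


class PackingError(RuntimeError):
    """Raised when molecules cannot be placed without hard overlaps."""


# ---------------------------------------------------------------------------
# toy liquids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyLiquidSpec:
    """Study conditions for a toy molecular liquid."""

    template: str = "diatomic"  # diatomic | triatomic | chain4
    n_molecules: int = 32
    box: float = 8.7  # Å — near the 1 atm equilibrium density at 150 K
    bond_form: str = "harmonic"  # harmonic | morse for X–H stretches
    deuterate: bool = False

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.template not in ("diatomic", "triatomic", "chain4"):
            raise ValueError(f"unknown template {self.template!r}")


def _xh_bond(i: int, j: int, form: str, k: float = 3000.0, r0: float = 1.0) -> BondTerm:
    if form == "morse":
        # D, a chosen so 2Da² = k (same curvature at the minimum)
        D = 450.0
        a = np.sqrt(k / (2.0 * D))
        return BondTerm(i, j, form="morse", D=D, a=a, r0=r0)
    return BondTerm(i, j, form="harmonic", k=k, r0=r0)


def _template_topology(template: str, bond_form: str) -> MolecularTopology:
    if template == "diatomic":
        # stiff X–H (βħω ≈ 26 at the 150 K study temperature): the hydrogen
        # is strongly quantum, its ring-polymer spread (~0.6 Å) inflates the
        # repulsive core, and the well depths keep the classical fluid bound
        # at ~6 k_BT per molecule while leaving it mobile on the ps scale
        atoms = [
            AtomSpec("X", 30.0, -0.24, sigma=2.4, epsilon=1.4, type_label="X"),
            AtomSpec("H", 1.008, +0.24, sigma=2.2, epsilon=0.25, type_label="HX"),
        ]
        bonds = [_xh_bond(0, 1, bond_form, k=3000.0, r0=0.95)]
        return MolecularTopology(atoms, bonds, name=f"diatomic-{bond_form}")
    if template == "triatomic":
        atoms = [
            AtomSpec("O", 15.999, -0.70, sigma=2.6, epsilon=2.5, type_label="O"),
            AtomSpec("H", 1.008, +0.35, sigma=2.0, epsilon=0.25, type_label="HO"),
            AtomSpec("H", 1.008, +0.35, sigma=2.0, epsilon=0.25, type_label="HO"),
        ]
        bonds = [
            _xh_bond(0, 1, bond_form, k=3200.0, r0=0.97),
            _xh_bond(0, 2, bond_form, k=3200.0, r0=0.97),
        ]
        angles = [AngleTerm(1, 0, 2, k_theta=300.0, theta0=np.deg2rad(104.5))]
        return MolecularTopology(atoms, bonds, angles, name=f"triatomic-{bond_form}")
    # chain4: H–O–C–C with a polar hydroxyl head
    atoms = [
        AtomSpec("H", 1.008, +0.40, sigma=2.0, epsilon=0.20, type_label="HO"),
        AtomSpec("O", 15.999, -0.55, sigma=2.8, epsilon=2.0, type_label="O"),
        AtomSpec("C", 14.027, +0.15, sigma=3.2, epsilon=1.2, type_label="C2"),
        AtomSpec("C", 15.035, 0.00, sigma=3.3, epsilon=1.5, type_label="C3"),
    ]
    bonds = [
        _xh_bond(0, 1, bond_form, k=3200.0, r0=0.97),
        BondTerm(1, 2, form="harmonic", k=2500.0, r0=1.43),
        BondTerm(2, 3, form="harmonic", k=2000.0, r0=1.53),
    ]
    angles = [
        AngleTerm(0, 1, 2, k_theta=250.0, theta0=np.deg2rad(108.5)),
        AngleTerm(1, 2, 3, k_theta=250.0, theta0=np.deg2rad(109.5)),
    ]
    return MolecularTopology(atoms, bonds, angles, name=f"chain4-{bond_form}")


def _reference_geometry(top: MolecularTopology) -> np.ndarray:
    """Near-equilibrium intramolecular coordinates for one molecule."""
    n = top.n_atoms
    if n == 2:
        r0 = top.bonds[0].r0
        return np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    if n == 3:
        r0 = top.bonds[0].r0
        th = top.angles[0].theta0
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [r0, 0.0, 0.0],
                [r0 * np.cos(th), r0 * np.sin(th), 0.0],
            ]
        )
    # chain4: zig-zag
    pos = np.zeros((4, 3))
    pos[1] = [0.97, 0.0, 0.0]
    pos[2] = pos[1] + [1.43 * np.cos(0.6), 1.43 * np.sin(0.6), 0.0]
    pos[3] = pos[2] + [1.53 * np.cos(-0.6), 1.53 * np.sin(-0.6), 0.0]
    return pos


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_toy_liquid(
    spec: ToyLiquidSpec, seed: int = 0
) -> tuple[MolecularTopology, np.ndarray, float]:
    """Random-position/orientation packing of a toy liquid.

    Returns (topology, positions (N,3) Å, box Å).  Reproducible under a
    fixed seed; raises :class:`PackingError` if the requested density
    cannot be placed without hard overlaps.
    """
    mol = _template_topology(spec.template, spec.bond_form)
    top = replicate(mol, spec.n_molecules)
    top.name = mol.name
    if spec.deuterate:
        top = top.deuterated()
    ref = _reference_geometry(mol)
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    min_sep = 1.6  # Å between any two atoms of different molecules
    for _ in range(spec.n_molecules):
        ok = False
        for _attempt in range(2000):
            R = _random_rotation(rng)
            center = rng.uniform(0.0, spec.box, size=3)
            cand = (ref - ref.mean(axis=0)) @ R.T + center
            ok = True
            for other in placed:
                d = cand[:, None, :] - other[None, :, :]
                d -= spec.box * np.round(d / spec.box)
                if (d**2).sum(-1).min() < min_sep**2:
                    ok = False
                    break
            if ok:
                placed.append(cand)
                break
        if not ok:
            raise PackingError(
                f"could not place {spec.n_molecules} molecules in box {spec.box} Å"
            )
    return top, np.vstack(placed), spec.box


# ---------------------------------------------------------------------------
# observable fixtures
# ---------------------------------------------------------------------------


def make_observable_fixture(
    targets: dict[str, float],
    T: float = 298.15,
    n_frames: int = 20000,
    n_molecules: int = 32,
    molar_mass: float = 18.015,
    n_beads: int = 1,
    seed: int = 0,
):
    """Synthetic series hitting the requested property targets in expectation.

    ``targets`` keys: ``v_m`` (cm³/mol), ``kappa_T`` (atm⁻¹), ``eps_r0``
    (dimensionless ≥ 1), ``alpha_P`` (K⁻¹).  Without ``alpha_P`` a single
    :class:`ObservableSeries` is returned; with it, a dict of three series
    keyed by temperature (T±5 and T), whose mean volumes encode the target.
    """
    rng = np.random.default_rng(seed)
    kappa = targets.get("kappa_T", 0.0)
    eps = targets.get("eps_r0", 1.0)
    if kappa < 0:
        raise ValueError("kappa_T target must be non-negative")
    if eps < 1.0:
        raise ValueError("eps_r0 target must be >= 1")
    if "v_m" in targets:
        v0_nm3 = targets["v_m"] * n_molecules / NA * 1e21
    else:
        v0_nm3 = 30.0
    v0_a3 = v0_nm3 * 1e3

    def one_series(v_mean_a3: float, rng: np.random.Generator) -> ObservableSeries:
        var_v = (kappa / ATM) * KB * T * v_mean_a3  # Å⁶
        vols = v_mean_a3 + np.sqrt(var_v) * rng.standard_normal(n_frames)
        s2 = (eps - 1.0) * v_mean_a3 * KB * T / (4.0 * np.pi * COULOMB)
        dip = np.sqrt(s2) * rng.standard_normal((n_frames, n_beads, 3))
        zeros = np.zeros(n_frames)
        return ObservableSeries(
            times=np.arange(n_frames, dtype=float),
            volumes=vols * 1e-3,
            potential_beads=np.zeros((n_frames, n_beads)),
            kinetic_cv=zeros.copy(),
            kinetic_primitive=zeros.copy(),
            spring=zeros.copy(),
            dipoles=dip,
            T=T,
            pressure=1.0,
            n_beads=n_beads,
            n_molecules=n_molecules,
            metadata={"synthetic": True, "targets": dict(targets), "seed": seed},
        )

    if "alpha_P" in targets:
        alpha = targets["alpha_P"]
        out = {}
        for dT in (-5.0, 0.0, 5.0):
            s = one_series(v0_a3 * (1.0 + alpha * dT), rng)
            s.T = T + dT
            out[T + dT] = s
        return out
    return one_series(v0_a3, rng)


# ---------------------------------------------------------------------------
# feature datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureGenSpec:
    """Generative conditions for the molecule/property table."""

    n_molecules: int = 92
    m_w_range: tuple[float, float] = (4.0, 16.0)     # g/mol, average atomic mass
    n_h_range: tuple[float, float] = (0.01, 0.07)    # Å⁻³
    alpha_base: float = 1.9e-3                       # K⁻¹ before n_H coupling
    alpha_slope: float = 0.008                       # K⁻¹ per Å⁻³ (negative coupling)
    alpha_noise: float = 0.5e-3                      # uniform half-width, K⁻¹
    noise_t: float = 1.5                             # K, additive on latent T_vm
    noise_delta: float = 0.0015                      # absolute, on Δ_vm fraction
    seed: int = 0

    def __post_init__(self):
        if self.noise_t < 0 or self.noise_delta < 0 or self.alpha_noise < 0:
            raise ValueError("noise scales must be non-negative")
        if self.m_w_range[0] <= 0 or self.n_h_range[0] < 0:
            raise ValueError("ranges must be positive")


def latent_t_vm(m_w, n_h) -> np.ndarray:
    """Ground-truth reduced temperature g(m_w, n_H), K.

    Saturating increase in n_H (hydrogen-rich liquids feel stronger NQEs)
    times a smooth bump in m_w (non-monotone: light average composition
    amplifies quantum effects, very light implies few heavy anchors).
    """
    m_w = np.asarray(m_w, dtype=float)
    n_h = np.asarray(n_h, dtype=float)
    h_part = 8.0 + 55.0 * (1.0 - np.exp(-n_h / 0.03))
    m_part = 0.35 + 0.65 * np.exp(-(((m_w - 7.0) / 4.0) ** 2))
    return h_part * m_part


def make_feature_dataset(spec: FeatureGenSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Molecule table with Δ_vm = g(m_w,n_H)·α_P + ε and its latent g.

    The α_P column is weakly negatively correlated with n_H, mirroring the
    stability/hydrogen-density trade-off in real liquids.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules
    m_w = rng.uniform(*spec.m_w_range, size=n)
    n_h = rng.uniform(*spec.n_h_range, size=n)
    alpha = (
        spec.alpha_base
        - spec.alpha_slope * n_h
        + rng.uniform(-spec.alpha_noise, spec.alpha_noise, size=n)
    )
    g = latent_t_vm(m_w, n_h)
    t_noisy = g + spec.noise_t * rng.standard_normal(n)
    delta = t_noisy * alpha + spec.noise_delta * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "name": [f"mol{i:03d}" for i in range(n)],
            "m_w": m_w,
            "n_H": n_h,
            "alpha_P": alpha,
            "delta_vm": delta,
        }
    )
    return df, g


# ---------------------------------------------------------------------------
# hydrogen-bond fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimerSpec:
    """One hand-placed hydroxyl dimer with prescribed H-bond geometry."""

    d_da: float = 2.8        # donor–acceptor O···O distance, Å
    angle_deg: float = 170.0  # D–H···A angle at the hydrogen


def make_hbond_fixture(
    dimers: list[DimerSpec], box: float = 100.0, spacing: float = 25.0
) -> tuple[MolecularTopology, np.ndarray, float]:
    """Grid of O–H dimers with exactly known H-bond counts and r_CM values.

    Each dimer is two hydroxyl (O–H) molecules; the donor's hydrogen points
    at the acceptor oxygen with the prescribed O···O distance and D–H···A
    angle, and the acceptor's own hydrogen points away so it cannot donate
    back.  A dimer satisfies the (3.6 Å, 150°) criterion iff its spec does.
    """
    oh = MolecularTopology(
        atoms=[
            AtomSpec("O", 15.999, -0.4, sigma=3.1, epsilon=0.65),
            AtomSpec("H", 1.008, +0.4, sigma=2.0, epsilon=0.10),
        ],
        bonds=[BondTerm(0, 1, form="harmonic", k=3200.0, r0=0.97)],
        name="hydroxyl",
    )
    top = replicate(oh, 2 * len(dimers))
    positions = []
    per_row = max(1, int(box // spacing))
    for idx, dim in enumerate(dimers):
        origin = np.array(
            [spacing * (idx % per_row), spacing * (idx // per_row), 0.0]
        ) + 5.0
        r_oh = 0.97
        donor_o = origin
        donor_h = origin + np.array([r_oh, 0.0, 0.0])
        theta = np.deg2rad(dim.angle_deg)
        u = np.array([-1.0, 0.0, 0.0])  # unit H→D
        direction = np.cos(theta) * u + np.sin(theta) * np.array([0.0, 1.0, 0.0])
        # |A−D| = d_da with A = H + r·direction:
        # r² + 2r(H−D)·dir + r_oh² − d_da² = 0, where (H−D)·dir = −r_oh cosθ
        half_b = -r_oh * np.cos(theta)
        disc = half_b**2 - (r_oh**2 - dim.d_da**2)
        if disc <= 0:
            raise ValueError(f"dimer geometry unsatisfiable: {dim}")
        r = -half_b + np.sqrt(disc)
        acceptor_o = donor_h + r * direction
        acceptor_h = acceptor_o + np.array([0.0, 0.0, r_oh])  # points away
        positions.extend([donor_o, donor_h, acceptor_o, acceptor_h])
    return top, np.asarray(positions), box
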