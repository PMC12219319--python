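"""Thermophysical property estimators from simulation observables.

Five properties, each from equilibrium averages or fluctuations:

* molar volume            v_m  = M/⟨ρ⟩                       (cm³/mol)
* thermal expansivity     α_P  = (⟨V⟩_T₊ − ⟨V⟩_T₋)/(ΔT·⟨V⟩)   (K⁻¹),
  a central difference over runs at 293.15/298.15/303.15 K
* isothermal compressibility  κ_T = (⟨V²⟩−⟨V⟩²)/(k_B T ⟨V⟩)  (atm⁻¹, GPa⁻¹)
* static dielectric       ε_r(0) = (1/P)Σ_i [1 + (4π/3)(⟨M_i²⟩−⟨M_i⟩²)·k_e/(V k_B T)],
  the per-bead dipole-fluctuation formula averaged over beads
* enthalpy of vaporization    Δh_vap = (1/P)ΣE_i^(g) + k_B T − (1/P)ΣE_i^(l),
  with per-bead total internal energies (potential + quantum kinetic energy
  from the centroid-virial estimator for P ≥ 2).

Replica scatter provides SEMs (four independent runs in the reference
protocol); single-series SEMs, where offered, use first-order propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ATM, COULOMB, KB, NA
from .observables import ObservableSeries


class DegenerateInputError(ValueError):
    """Raised when a series cannot support the requested estimator."""


#: 1/atm → 1/GPa
PER_ATM_TO_PER_GPA = 1e9 / 101325.0


@dataclass(frozen=True)
class PropertyEstimate:
    """A property value with its replicate statistics."""

    value: float
    sem: float
    n_replicas: int
    tag: str  # ∈ {"v_m", "alpha_P", "kappa_T", "eps_r0", "dh_vap"}

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")


def molar_volume(series: ObservableSeries, molar_mass: float) -> float:
    """v_m = M/⟨ρ⟩ in cm³/mol, for molar mass M (g/mol per molecule).

    ⟨ρ⟩ is the mean mass density from the volume series and the total box
    mass; equivalently v_m = ⟨V⟩·N_A/N_mol, reported per mole of molecules.
    """
    v_mean = float(np.mean(series.volumes))  # nm³
    if v_mean <= 0:
        raise DegenerateInputError("mean volume must be positive")
    total_mass = molar_mass * series.n_molecules  # g/mol in the box
    rho = total_mass / NA / (v_mean * 1e-21)  # g/cm³
    return molar_mass / rho


def mean_density(series: ObservableSeries, molar_mass: float) -> float:
    """⟨ρ⟩ in g/cm³."""
    return molar_mass / molar_volume(series, molar_mass)


def thermal_expansion(
    v_low: tuple[float, float],
    v_mid: tuple[float, float],
    v_high: tuple[float, float],
    dT: float = 10.0,
) -> tuple[float, float]:
    """α_P from mean volumes (value, SEM) at T−5, T, T+5 K.

    α_P = (⟨V⟩_high − ⟨V⟩_low)/(dT·⟨V⟩_mid); the SEM is propagated in
    quadrature through the difference quotient.
    """
    (vl, sl), (vm, sm), (vh, sh) = v_low, v_mid, v_high
    if vm <= 0:
        raise DegenerateInputError("mid-temperature mean volume must be positive")
    alpha = (vh - vl) / (dT * vm)
    # ∂α/∂vh = 1/(dT vm); ∂α/∂vl = −1/(dT vm); ∂α/∂vm = −α/vm
    sem = np.sqrt((sh**2 + sl**2) / (dT * vm) ** 2 + (alpha * sm / vm) ** 2)
    return float(alpha), float(sem)


def thermal_expansion_from_series(
    series_by_T: dict[float, ObservableSeries],
) -> tuple[float, float]:
    """α_P from three ObservableSeries keyed by their temperatures."""
    if len(series_by_T) != 3:
        raise DegenerateInputError(
            f"need series at exactly three temperatures, got {sorted(series_by_T)}"
        )
    Ts = sorted(series_by_T)
    stats = []
    for T in Ts:
        v = series_by_T[T].volumes
        stats.append((float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(len(v)))))
    return thermal_expansion(stats[0], stats[1], stats[2], dT=Ts[2] - Ts[0])


def isothermal_compressibility(
    series: ObservableSeries, T: float | None = None, warn_drift: bool = True
) -> float:
    """κ_T = (⟨V²⟩−⟨V⟩²)/(k_B T ⟨V⟩) in atm⁻¹.

    Volumes are nm³; the fluctuation formula is evaluated in Å³ and
    converted with 1 atm = 6.1019×10⁻⁵ kJ/mol/Å³.
    """
    T = series.T if T is None else T
    v = np.asarray(series.volumes) * 1e3  # Å³
    if len(v) < 2:
        raise DegenerateInputError("variance undefined for a single frame")
    if warn_drift and len(v) >= 8:
        h = len(v) // 2
        a, b = v[:h], v[h:]
        sem = np.sqrt(np.var(a, ddof=1) / h + np.var(b, ddof=1) / (len(v) - h))
        if sem > 0 and abs(a.mean() - b.mean()) > 3 * sem:
            import warnings

            warnings.warn("volume series mean drifts > 3 SEM between halves", stacklevel=2)
    kappa_internal = np.var(v, ddof=0) / (KB * T * v.mean())  # 1/(kJ/mol/Å³)
    return float(kappa_internal * ATM)  # 1/atm


def kappa_in_per_gpa(kappa_per_atm: float) -> float:
    return kappa_per_atm * PER_ATM_TO_PER_GPA


def static_dielectric(
    dipoles: np.ndarray,
    volume: float,
    T: float,
    n_beads: int | None = None,
) -> float:
    """ε_r(0) from per-bead box-dipole fluctuations.

    ε_r(0) = (1/P) Σ_{i=1}^{P} [1 + (4π/3)·k_e·(⟨M_i²⟩−⟨M_i⟩²)/(V k_B T)]

    evaluated per bead and averaged over beads exactly as printed (P = 1 is
    the textbook classical fluctuation formula).  ``dipoles`` has shape
    (n_frames, P, 3) in e·Å; ``volume`` is the mean volume in Å³; k_e is
    the Coulomb constant converting (e·Å)²/Å³ to kJ/mol.
    """
    d = np.asarray(dipoles, dtype=float)
    if d.ndim == 2:
        d = d[:, None, :]
    P = d.shape[1]
    if n_beads is not None and n_beads != P:
        raise ValueError(f"dipole array has {P} beads, expected {n_beads}")
    var = (d**2).sum(-1).mean(0) - (d.mean(0) ** 2).sum(-1)  # ⟨M²⟩−⟨M⟩², per bead
    eps_per_bead = 1.0 + (4.0 * np.pi / 3.0) * COULOMB * var / (volume * KB * T)
    return float(eps_per_bead.mean())


def static_dielectric_from_series(series: ObservableSeries) -> float:
    v_mean = float(np.mean(series.volumes)) * 1e3  # Å³
    return static_dielectric(series.dipoles, v_mean, series.T, series.n_beads)


def enthalpy_of_vaporization(
    gas_energies: np.ndarray,
    liquid_energies: np.ndarray,
    T: float,
) -> float:
    """Δh_vap = (1/P)Σ⟨E_i^(g)⟩ + k_B T − (1/P)Σ⟨E_i^(l)⟩, kJ/mol.

    ``*_energies`` are per-frame, per-bead total internal energies per mole
    of molecules, shape (n_frames, P).  Adding a constant to both phases
    leaves the result unchanged.
    """
    g = np.atleast_2d(np.asarray(gas_energies, dtype=float))
    l = np.atleast_2d(np.asarray(liquid_energies, dtype=float))
    return float(g.mean(axis=0).mean() + KB * T - l.mean(axis=0).mean())


def enthalpy_of_vaporization_from_series(
    gas: ObservableSeries, liquid: ObservableSeries
) -> float:
    """Δh_vap assembling per-bead energies from two runs at the same T.

    Per-bead internal energy E_i = U(x_i) + K_cv/P per mole of molecules;
    the quantum kinetic energy uses the centroid-virial estimator (lower
    variance than the primitive one).
    """
    if gas.phase != "gas" or liquid.phase != "liquid":
        raise DegenerateInputError(
            f"phase tags must be gas/liquid, got {gas.phase}/{liquid.phase}"
        )
    if gas.n_beads != liquid.n_beads:
        raise DegenerateInputError("both phases must use the same bead count")
    if abs(gas.T - liquid.T) > 1e-9:
        raise DegenerateInputError("both phases must be at the same temperature")

    def per_mole(series: ObservableSeries) -> np.ndarray:
        e = series.potential_beads + series.kinetic_cv[:, None] / series.n_beads
        return e / series.n_molecules

    return enthalpy_of_vaporization(per_mole(gas), per_mole(liquid), gas.T)
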