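"""Classical and ring-polymer (path-integral) molecular dynamics.

The path-integral isomorphism maps each quantum nucleus onto a cyclic chain
of ``P`` beads joined by harmonic springs.  This engine uses the
sample-at-physical-temperature convention: the extended system is
thermostatted at the physical T, the spring frequency is

    ω_n = √P · k_B T / ħ,

and the physical potential enters scaled by 1/P (each bead feels U/P), so
that the bead distribution ∝ exp(−βH̃) reproduces the quantum Boltzmann
statistics of the discretized path integral.  ``P = 1`` is exactly
classical MD: the spring term vanishes and U/P = U.

Integration is a symmetric OBABO splitting: half thermostat, half momentum
kick, *exact* free-ring-polymer evolution in normal modes, half kick, half
thermostat.  Exact normal-mode propagation keeps the stiff spring modes
stable at P = 32 with a 0.5 fs timestep.  The PILE thermostat applies an
Ornstein–Uhlenbeck update per normal mode: the centroid at the physical
friction (default 1 ps⁻¹), internal mode k critically damped at γ_k = 2ω_k.

Constant pressure uses a Monte Carlo barostat attempted every 25 fs:
a uniform volume perturbation, molecules displaced rigidly by their
(centroid) center of mass, accepted with
exp{−β[ΔU + P_ext ΔV − N_mol k_B T ln(V'/V)]}, where U is the
bead-averaged potential — the weight appropriate for a uniform-ΔV proposal
with molecular scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .constants import ATM, HBAR, KB, dynamical_masses
from .forcefield import ForceField
from .observables import ObservableSeries
from .topology import MolecularTopology


class PropagationError(RuntimeError):
    """Raised when the integrator encounters non-finite forces."""


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class RingPolymerState:
    """Bead positions/momenta of shape (n_beads, n_atoms, 3), cubic box (Å).

    Momenta are stored in "dynamical" units (mass pre-scaled so that
    p²/2m is kJ/mol with velocities in Å/ps).
    """

    positions: np.ndarray
    momenta: np.ndarray
    box: float
    masses: np.ndarray  # g/mol, per atom

    def __post_init__(self):
        self.positions = np.atleast_3d(np.asarray(self.positions, dtype=float))
        self.momenta = np.atleast_3d(np.asarray(self.momenta, dtype=float))
        if self.positions.shape != self.momenta.shape:
            raise ValueError("positions and momenta shapes differ")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if not self.box > 0:
            raise ValueError("box must be positive")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def dyn_masses(self) -> np.ndarray:
        return dynamical_masses(self.masses)

    @property
    def centroid(self) -> np.ndarray:
        """Bead-averaged positions, shape (n_atoms, 3)."""
        return self.positions.mean(axis=0)

    def copy(self) -> "RingPolymerState":
        return RingPolymerState(
            self.positions.copy(), self.momenta.copy(), self.box, self.masses.copy()
        )


def initialize_state(
    topology: MolecularTopology,
    positions: np.ndarray,
    box: float,
    n_beads: int,
    T: float,
    rng: np.random.Generator,
) -> RingPolymerState:
    """Collapsed ring polymers at the classical positions, Maxwell momenta."""
    pos = np.repeat(np.asarray(positions, dtype=float)[None], n_beads, axis=0)
    m_dyn = dynamical_masses(topology.masses)
    p = rng.standard_normal(pos.shape) * np.sqrt(KB * T * m_dyn)[None, :, None]
    return RingPolymerState(pos, p, float(box), topology.masses)


# ---------------------------------------------------------------------------
# normal modes and springs
# ---------------------------------------------------------------------------


def normal_mode_matrix(n_beads: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal transform diagonalizing the cyclic spring matrix.

    Returns ``(C, factors)`` where mode coordinates are ``C @ beads`` and
    ``factors[m] = 2 sin(k_m π / P)`` gives mode frequencies
    ω_m = ω_n · factors[m].  Mode 0 is √P × the centroid.
    """
    P = n_beads
    C = np.empty((P, P))
    factors = np.empty(P)
    j = np.arange(P)
    C[0] = 1.0 / np.sqrt(P)
    factors[0] = 0.0
    row = 1
    for k in range(1, (P + 1) // 2):
        C[row] = np.sqrt(2.0 / P) * np.cos(2.0 * np.pi * k * j / P)
        factors[row] = 2.0 * np.sin(np.pi * k / P)
        row += 1
        C[row] = np.sqrt(2.0 / P) * np.sin(2.0 * np.pi * k * j / P)
        factors[row] = 2.0 * np.sin(np.pi * k / P)
        row += 1
    if P % 2 == 0 and P > 1:
        C[row] = ((-1.0) ** j) / np.sqrt(P)
        factors[row] = 2.0
    return C, factors


def spring_frequency(n_beads: int, T: float) -> float:
    """ω_n = √P k_B T / ħ, the ring-polymer spring frequency (ps⁻¹)."""
    return np.sqrt(n_beads) * KB * T / HBAR


def spring_energy(state: RingPolymerState, T: float) -> float:
    """Σ_atoms Σ_k ½ m ω_n² |x_k − x_{k+1}|², cyclic; 0 for n_beads = 1."""
    if state.n_beads == 1:
        return 0.0
    w = spring_frequency(state.n_beads, T)
    d = state.positions - np.roll(state.positions, -1, axis=0)
    return float(0.5 * w**2 * (state.dyn_masses[None, :, None] * d**2).sum())


def spring_forces(state: RingPolymerState, T: float) -> np.ndarray:
    if state.n_beads == 1:
        return np.zeros_like(state.positions)
    w = spring_frequency(state.n_beads, T)
    x = state.positions
    lap = 2.0 * x - np.roll(x, 1, axis=0) - np.roll(x, -1, axis=0)
    return -(w**2) * state.dyn_masses[None, :, None] * lap


# ---------------------------------------------------------------------------
# thermostats
# ---------------------------------------------------------------------------


def pile_step(
    momenta_modes: np.ndarray,
    dt: float,
    friction_centroid: float,
    T: float,
    dyn_masses: np.ndarray,
    mode_freqs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Ornstein–Uhlenbeck substep on normal-mode momenta.

    Centroid mode uses ``friction_centroid``; internal mode k uses
    γ_k = 2ω_k (critical damping of the free ring-polymer vibration).
    Exactly preserves the Maxwell–Boltzmann distribution at T.
    """
    if friction_centroid < 0:
        raise ValueError("friction must be non-negative")
    gammas = 2.0 * mode_freqs
    gammas[0] = friction_centroid
    c1 = np.exp(-gammas * dt)[:, None, None]
    c2 = np.sqrt((1.0 - c1**2) * (KB * T * dyn_masses)[None, :, None])
    noise = rng.standard_normal(momenta_modes.shape)
    return c1 * momenta_modes + c2 * noise


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def kinetic_estimators(
    state: RingPolymerState,
    bead_forces: np.ndarray,
    T: float,
) -> dict[str, float]:
    """Primitive and centroid-virial quantum kinetic-energy estimators.

    primitive       = (3N·P/2) k_B T − E_spring
    centroid_virial = (3N/2) k_B T − ½ Σ_b (x_b − x̄)·f_b/P

    ``bead_forces`` are the physical per-bead forces −∇U(x_b) (unscaled).
    Both reduce to (3N/2) k_B T for P = 1.
    """
    N, P = state.n_atoms, state.n_beads
    prim = 1.5 * N * P * KB * T - spring_energy(state, T)
    disp = state.positions - state.centroid[None]
    cv = 1.5 * N * KB * T - 0.5 * float((disp * bead_forces).sum()) / P
    return {"primitive": float(prim), "centroid_virial": float(cv)}


def box_dipole_per_bead(
    state: RingPolymerState, topology: MolecularTopology
) -> np.ndarray:
    """Total box dipole per bead (e·Å), assembled molecule-wise.

    Each molecule's dipole uses coordinates unwrapped relative to its first
    atom; for neutral molecules the result is independent of the reference
    and of periodic wrapping.
    """
    mol_idx = topology.molecule_index()
    q = topology.charges
    first = np.zeros(topology.n_atoms, dtype=int)
    for mol in topology.molecules():
        first[mol] = mol[0]
    rel = state.positions - state.positions[:, first]
    rel -= state.box * np.round(rel / state.box)
    return (q[None, :, None] * rel).sum(axis=1)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


@dataclass
class IntegratorConfig:
    timestep: float = 0.0005  # ps (0.5 fs)
    thermostat: Literal["none", "langevin", "pile", "andersen"] = "pile"
    friction: float = 1.0  # ps⁻¹, centroid / classical friction
    andersen_rate: float = 10.0  # ps⁻¹, collision frequency (gas phase)
    barostat: Literal["none", "monte_carlo"] = "none"
    barostat_interval: float = 0.025  # ps (25 fs)
    T: float = 298.15
    pressure: float = 1.0  # atm
    remove_com_motion: bool = False  # gas-phase mode

    def __post_init__(self):
        if not self.timestep > 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


class Integrator:
    """OBABO propagator for a RingPolymerState over a ForceField."""

    def __init__(
        self,
        forcefield: ForceField,
        state: RingPolymerState,
        config: IntegratorConfig,
        rng: np.random.Generator,
    ):
        self.ff = forcefield
        self.state = state
        self.cfg = config
        self.rng = rng
        P = state.n_beads
        self._C, self._freq_factors = normal_mode_matrix(P)
        self._bead_forces = self._compute_forces()
        self._barostat_steps = max(1, int(round(config.barostat_interval / config.timestep)))
        self._step_count = 0
        self.barostat_attempts = 0
        self.barostat_accepts = 0
        self._dv_max = 0.02 * state.box**3

    # -- helpers -----------------------------------------------------------

    def _compute_forces(self) -> np.ndarray:
        energy, forces = self.ff.evaluate(self.state.positions, self.state.box)
        self._bead_potentials = np.atleast_1d(energy)
        if not np.all(np.isfinite(forces)):
            raise PropagationError("non-finite forces")
        return forces

    @property
    def bead_potentials(self) -> np.ndarray:
        """Physical potential U(x_b) per bead at the current positions."""
        return self._bead_potentials

    def potential(self) -> float:
        """Bead-averaged potential (1/P)ΣU(x_b) — the PI potential estimator."""
        return float(self._bead_potentials.mean())

    def kinetic(self) -> float:
        m = self.state.dyn_masses[None, :, None]
        return float((self.state.momenta**2 / (2.0 * m)).sum())

    def extended_energy(self) -> float:
        """Conserved quantity with thermostats off."""
        return self.kinetic() + spring_energy(self.state, self.cfg.T) + self.potential()

    def _to_modes(self, arr: np.ndarray) -> np.ndarray:
        P = self.state.n_beads
        return (self._C @ arr.reshape(P, -1)).reshape(arr.shape)

    def _from_modes(self, arr: np.ndarray) -> np.ndarray:
        P = self.state.n_beads
        return (self._C.T @ arr.reshape(P, -1)).reshape(arr.shape)

    # -- thermostat substeps ----------------------------------------------

    def _thermostat_half(self, T: float) -> None:
        cfg = self.cfg
        dt2 = 0.5 * cfg.timestep
        s = self.state
        if cfg.thermostat == "none":
            return
        if cfg.thermostat == "andersen":
            return  # applied once per full step, not as an OU half
        if cfg.thermostat == "langevin" or s.n_beads == 1:
            c1 = np.exp(-cfg.friction * dt2)
            c2 = np.sqrt((1.0 - c1**2) * KB * T * s.dyn_masses)[None, :, None]
            s.momenta = c1 * s.momenta + c2 * self.rng.standard_normal(s.momenta.shape)
            return
        # PILE
        w_n = spring_frequency(s.n_beads, T)
        p_modes = self._to_modes(s.momenta)
        p_modes = pile_step(
            p_modes, dt2, cfg.friction, T, s.dyn_masses,
            self._freq_factors * w_n, self.rng,
        )
        s.momenta = self._from_modes(p_modes)

    def _andersen_collisions(self, T: float) -> None:
        s = self.state
        prob = self.cfg.andersen_rate * self.cfg.timestep
        hit = self.rng.random(s.n_atoms) < prob
        if hit.any():
            scale = np.sqrt(KB * T * s.dyn_masses[hit])[None, :, None]
            s.momenta[:, hit] = scale * self.rng.standard_normal(
                (s.n_beads, int(hit.sum()), 3)
            )

    def _remove_com_motion(self) -> None:
        """Zero net linear and (centroid) angular momentum — gas phase."""
        s = self.state
        m = s.dyn_masses
        ptot = s.momenta.sum(axis=(0, 1)) / s.n_beads
        s.momenta -= (m / m.sum())[None, :, None] * ptot[None, None, :]
        # angular momentum about the centroid center of mass
        xc = s.centroid
        pc = s.momenta.mean(axis=0)
        com = (m[:, None] * xc).sum(0) / m.sum()
        r = xc - com
        L = np.cross(r, pc).sum(axis=0)
        inertia = (m[:, None, None] * ((r**2).sum(-1)[:, None, None] * np.eye(3)
                   - r[:, :, None] * r[:, None, :])).sum(axis=0)
        try:
            omega = np.linalg.solve(inertia, L)
        except np.linalg.LinAlgError:
            return
        s.momenta -= m[None, :, None] * np.cross(omega[None, None, :], r[None])

    # -- free ring-polymer step -------------------------------------------

    def _free_rp_step(self, T: float) -> None:
        s = self.state
        dt = self.cfg.timestep
        m = s.dyn_masses[None, :, None]
        if s.n_beads == 1:
            s.positions = s.positions + dt * s.momenta / m
            return
        w_n = spring_frequency(s.n_beads, T)
        omegas = self._freq_factors * w_n
        q = self._to_modes(s.positions)
        p = self._to_modes(s.momenta)
        q0 = q[0] + dt * p[0] / m[0]
        w = omegas[1:, None, None]
        c, sn = np.cos(w * dt), np.sin(w * dt)
        q_new = q[1:] * c + p[1:] * sn / (m * w)
        p_new = p[1:] * c - q[1:] * (m * w) * sn
        q[0], q[1:] = q0, q_new
        p[1:] = p_new
        s.positions = self._from_modes(q)
        s.momenta = self._from_modes(p)

    # -- barostat ----------------------------------------------------------

    def mc_barostat_move(self) -> bool:
        """One Monte Carlo volume move; returns True if accepted."""
        s = self.state
        cfg = self.cfg
        top = self.ff.topology
        self.barostat_attempts += 1
        V = s.box**3
        dV = self.rng.uniform(-self._dv_max, self._dv_max)
        V_new = V + dV
        box_new = V_new ** (1.0 / 3.0) if V_new > 0 else -1.0
        # a box smaller than 2×cutoff breaks the minimum-image convention
        if box_new <= 0 or (self.ff.periodic and box_new < 2.0 * self.ff.cutoff):
            return self._barostat_adapt(False)
        s_factor = box_new / s.box
        mols = top.molecules()
        masses = s.masses
        new_pos = s.positions.copy()
        for mol in mols:
            w = masses[mol] / masses[mol].sum()
            com = (w[:, None] * s.centroid[mol]).sum(axis=0)
            new_pos[:, mol] += ((s_factor - 1.0) * com)[None, None, :]
        u_old = self.potential()
        try:
            e_new, f_new = self.ff.evaluate(new_pos, box_new)
        except Exception:
            return self._barostat_adapt(False)
        u_new = float(np.atleast_1d(e_new).mean())
        beta = 1.0 / (KB * cfg.T)
        n_mol = len(mols)
        p_int = cfg.pressure * ATM
        w_arg = -(u_new - u_old + p_int * dV - n_mol * KB * cfg.T * np.log(V_new / V)) * beta
        if np.log(self.rng.random()) < w_arg:
            s.positions = new_pos
            s.box = box_new
            self._bead_potentials = np.atleast_1d(e_new)
            self._bead_forces = f_new
            return self._barostat_adapt(True)
        return self._barostat_adapt(False)

    #: volume-move adaptation stops after this many attempts so the frozen
    #: proposal satisfies detailed balance over the production run
    N_ADAPT_ATTEMPTS = 300

    def _barostat_adapt(self, accepted: bool) -> bool:
        if accepted:
            self.barostat_accepts += 1
        if (
            self.barostat_attempts <= self.N_ADAPT_ATTEMPTS
            and self.barostat_attempts % 10 == 0
        ):
            recent = self.barostat_accepts / self.barostat_attempts
            if recent > 0.6:
                self._dv_max *= 1.1
            elif recent < 0.3:
                self._dv_max *= 0.9
        return accepted

    # -- main step ---------------------------------------------------------

    def step(self, T: float | None = None) -> None:
        cfg = self.cfg
        T = cfg.T if T is None else T
        s = self.state
        dt2 = 0.5 * cfg.timestep
        self._thermostat_half(T)
        s.momenta = s.momenta + dt2 * self._bead_forces / s.n_beads
        self._free_rp_step(T)
        self._bead_forces = self._compute_forces()
        s.momenta = s.momenta + dt2 * self._bead_forces / s.n_beads
        self._thermostat_half(T)
        if cfg.thermostat == "andersen":
            self._andersen_collisions(T)
        if cfg.remove_com_motion:
            self._remove_com_motion()
        self._step_count += 1
        if cfg.barostat == "monte_carlo" and self._step_count % self._barostat_steps == 0:
            old_T, self.cfg.T = self.cfg.T, T
            self.mc_barostat_move()
            self.cfg.T = old_T

    def run(self, n_steps: int, T_schedule: Sequence[float] | None = None) -> None:
        for i in range(n_steps):
            self.step(None if T_schedule is None else T_schedule[i])


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


@dataclass
class Leg:
    """One protocol leg: ensemble, temperatures, pressure, duration."""

    ensemble: Literal["nve", "nvt", "npt"]
    duration: float  # ps
    T: float = 298.15
    T_end: float | None = None  # linear ramp if set
    pressure: float = 1.0  # atm
    record: bool = False
    stride: int = 10  # steps between recorded frames

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("leg duration must be non-negative")
        if self.T <= 0 or (self.T_end is not None and self.T_end <= 0):
            raise ValueError("leg temperature must be positive")


@dataclass
class SimulationProtocol:
    legs: list[Leg] = field(default_factory=list)
    timestep: float = 0.0005  # ps
    thermostat: Literal["langevin", "pile", "andersen"] = "pile"
    friction: float = 1.0
    andersen_rate: float = 10.0
    barostat_interval: float = 0.025
    gas_phase: bool = False
    minimize_first: bool = False


def minimize_energy(
    topology: MolecularTopology,
    positions: np.ndarray,
    box: float,
    forcefield: ForceField | None = None,
    tol: float = 10.0,
) -> np.ndarray:
    """L-BFGS energy minimization (classical coordinates), gradient-based."""
    ff = forcefield or ForceField(topology)
    x0 = np.asarray(positions, dtype=float).ravel()
    n = topology.n_atoms

    def fun(x):
        e, f = ff.evaluate(x.reshape(n, 3), box)
        return e, -f.ravel()

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "gtol": tol})
    return res.x.reshape(n, 3)


def run_simulation(
    topology: MolecularTopology,
    protocol: SimulationProtocol,
    positions: np.ndarray,
    box: float,
    n_beads: int,
    seed: int,
    replica: int = 0,
    cutoff: float | None = None,
    name: str = "",
) -> ObservableSeries:
    """Execute protocol legs in order and collect observables.

    Deterministic under a fixed seed.  Returns an :class:`ObservableSeries`
    with frames from every leg flagged ``record=True``.
    """
    from .forcefield import DEFAULT_CUTOFF

    rc = DEFAULT_CUTOFF if cutoff is None else cutoff
    periodic = not protocol.gas_phase
    if periodic:
        # leave the barostat ~20% compression headroom before the
        # minimum-image auto-reject (box must stay ≥ 2×cutoff), so start
        # boxes near their equilibrium density
        rc = min(rc, 0.40 * box)
    ff = ForceField(topology, cutoff=rc, periodic=periodic,
                    tail_correction=periodic)
    rng = np.random.default_rng([seed, replica])

    if protocol.minimize_first:
        positions = minimize_energy(topology, positions, box, ff)

    T0 = protocol.legs[0].T if protocol.legs else 298.15
    state = initialize_state(topology, positions, box, n_beads, T0, rng)

    times, volumes, pot_beads, kin_cv, kin_prim, springs, dipoles = (
        [], [], [], [], [], [], []
    )
    t = 0.0
    last_T, last_P = T0, 1.0
    for leg in protocol.legs:
        n_steps = int(round(leg.duration / protocol.timestep))
        thermostat = "none" if leg.ensemble == "nve" else protocol.thermostat
        cfg = IntegratorConfig(
            timestep=protocol.timestep,
            thermostat=thermostat,
            friction=protocol.friction,
            andersen_rate=protocol.andersen_rate,
            barostat="monte_carlo" if leg.ensemble == "npt" else "none",
            barostat_interval=protocol.barostat_interval,
            T=leg.T,
            pressure=leg.pressure,
            remove_com_motion=protocol.gas_phase,
        )
        integ = Integrator(ff, state, cfg, rng)
        if leg.T_end is not None and n_steps > 0:
            schedule = np.linspace(leg.T, leg.T_end, n_steps)
        else:
            schedule = None
        for i in range(n_steps):
            integ.step(None if schedule is None else schedule[i])
            if leg.record and (i + 1) % leg.stride == 0:
                T_now = leg.T if schedule is None else float(schedule[i])
                est = kinetic_estimators(state, integ._bead_forces, T_now)
                times.append(t + (i + 1) * protocol.timestep)
                volumes.append(state.box**3 * 1e-3)  # nm³
                pot_beads.append(integ.bead_potentials.copy())
                kin_cv.append(est["centroid_virial"])
                kin_prim.append(est["primitive"])
                springs.append(spring_energy(state, T_now))
                dipoles.append(box_dipole_per_bead(state, topology))
        t += leg.duration
        state = integ.state
        last_T = leg.T if leg.T_end is None else leg.T_end
        last_P = leg.pressure

    return ObservableSeries(
        times=np.array(times),
        volumes=np.array(volumes),
        potential_beads=np.array(pot_beads).reshape(len(times), n_beads),
        kinetic_cv=np.array(kin_cv),
        kinetic_primitive=np.array(kin_prim),
        spring=np.array(springs),
        dipoles=np.array(dipoles).reshape(len(times), n_beads, 3),
        T=last_T,
        pressure=last_P,
        n_beads=n_beads,
        n_molecules=topology.n_molecules,
        phase="gas" if protocol.gas_phase else "liquid",
        replica=replica,
        metadata={
            "seed": seed,
            "cutoff": rc,
            "coulomb": ff.coulomb,
            "timestep_ps": protocol.timestep,
            "thermostat": protocol.thermostat,
            "name": name or topology.name,
        },
        final_state=state,
    )
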