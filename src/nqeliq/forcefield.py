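"""Potential energy and forces for small flexible-molecule systems.

Functional forms: harmonic / Morse bonds, harmonic angles, optional
cosine-series dihedrals, 12-6 Lennard-Jones with Waldman–Hagler mixing and
an analytic isotropic tail correction, and shifted-force real-space Coulomb
electrostatics under the minimum-image convention in a cubic box.

The engine targets desk-scale toy liquids, so electrostatics are evaluated
purely in real space with a shifted-force cutoff (default min(14 Å, L/2))
rather than with a reciprocal-space mesh; the cutoff is recorded in run
metadata.  Forces are exact analytic gradients; the test-suite checks them
against central finite differences.

A :class:`ForceField` is compiled once from a topology into flat numpy
index/parameter arrays and evaluates energies and forces for position
arrays with an optional leading bead axis (shape ``(P, N, 3)``), returning
per-bead energies — the layout path-integral dynamics needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB
from .topology import AtomSpec, BondTerm, MolecularTopology, TopologyError

DEFAULT_CUTOFF = 14.0  # Å, real-space nonbonded truncation

try:  # JIT pair kernel; the numpy path below is the reference implementation
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@_njit(cache=False, fastmath=True)
def _nb_kernel(pos, box, ii, jj, sigma, eps, qq, rc, shifted, periodic, forces):
    """Per-bead LJ + Coulomb energy/forces over a static pair list."""
    P = pos.shape[0]
    M = ii.shape[0]
    energies = np.zeros(P)
    rc2 = rc * rc
    inv_rc = 1.0 / rc
    inv_rc2 = inv_rc * inv_rc
    for b in range(P):
        e = 0.0
        for m in range(M):
            i = ii[m]
            j = jj[m]
            dx = pos[b, i, 0] - pos[b, j, 0]
            dy = pos[b, i, 1] - pos[b, j, 1]
            dz = pos[b, i, 2] - pos[b, j, 2]
            if periodic:
                dx -= box * np.rint(dx / box)
                dy -= box * np.rint(dy / box)
                dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 == 0.0:  # exact overlap of interacting sites
                e = np.inf
                break
            if r2 >= rc2:
                continue
            inv_r2 = 1.0 / r2
            s2 = sigma[m] * sigma[m] * inv_r2
            s6 = s2 * s2 * s2
            e += 4.0 * eps[m] * (s6 * s6 - s6)
            f_over_r = 24.0 * eps[m] * (2.0 * s6 * s6 - s6) * inv_r2
            if qq[m] != 0.0:
                r = np.sqrt(r2)
                if shifted:
                    e += qq[m] * (1.0 / r - inv_rc + (r - rc) * inv_rc2)
                    f_over_r += qq[m] * (inv_r2 - inv_rc2) / r
                else:
                    e += qq[m] / r
                    f_over_r += qq[m] * inv_r2 / r
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            forces[b, i, 0] += fx
            forces[b, i, 1] += fy
            forces[b, i, 2] += fz
            forces[b, j, 0] -= fx
            forces[b, j, 1] -= fy
            forces[b, j, 2] -= fz
        energies[b] = e
    return energies


class ConfigurationError(RuntimeError):
    """Raised for unphysical configurations (overlap, NaN, box too small)."""


@dataclass(frozen=True)
class PairParams:
    """Mixed Lennard-Jones parameters for an unlike pair."""

    sigma_ij: float  # Å
    epsilon_ij: float  # kJ/mol


def waldman_hagler_mix(a: AtomSpec, b: AtomSpec) -> PairParams:
    """σ⁶-based combination rules for unlike LJ pairs.

    σ_ij = ((σ_i⁶+σ_j⁶)/2)^{1/6},
    ε_ij = 2√(ε_iε_j)·σ_i³σ_j³/(σ_i⁶+σ_j⁶).

    Reduces to σ_ij = σ, ε_ij = √(ε_iε_j) when σ_i = σ_j.
    """
    if not (np.isfinite(a.sigma) and np.isfinite(b.sigma)) or a.sigma <= 0 or b.sigma <= 0:
        raise TopologyError("Waldman-Hagler mixing requires positive finite sigmas")
    s6i, s6j = a.sigma**6, b.sigma**6
    sigma_ij = ((s6i + s6j) / 2.0) ** (1.0 / 6.0)
    epsilon_ij = 2.0 * np.sqrt(a.epsilon * b.epsilon) * (a.sigma**3 * b.sigma**3) / (s6i + s6j)
    return PairParams(sigma_ij=float(sigma_ij), epsilon_ij=float(epsilon_ij))


def bond_energy(term: BondTerm, r: float | np.ndarray):
    """Bond energy and dU/dr at separation r (Å).

    harmonic: ½k(r−r₀)²;  morse: D(1−e^{−a(r−r₀)})².  Both are zero with
    zero derivative at r₀; the Morse form plateaus at D as r → ∞ and
    matches the harmonic form with k = 2Da² at small displacement.
    """
    r = np.asarray(r, dtype=float)
    dr = r - term.r0
    if term.form == "harmonic":
        return 0.5 * term.k * dr**2, term.k * dr
    ex = np.exp(-term.a * dr)
    u = term.D * (1.0 - ex) ** 2
    du = 2.0 * term.D * term.a * ex * (1.0 - ex)
    return u, du


def lj_tail_correction(
    n_atoms_by_type: np.ndarray,
    sigma_matrix: np.ndarray,
    epsilon_matrix: np.ndarray,
    volume: float,
    cutoff: float,
) -> float:
    """Analytic isotropic LJ energy tail beyond the cutoff, kJ/mol.

    U_tail = (8π/3V) Σ_{a,b} N_a N_b ε_ab σ_ab³ [⅓(σ_ab/r_c)⁹ − (σ_ab/r_c)³]
    over ordered type pairs (the single-species case reduces to the textbook
    (8/3)πρNεσ³[⅓(σ/r_c)⁹−(σ/r_c)³] with ρ = N/V).
    """
    n = np.asarray(n_atoms_by_type, dtype=float)
    x = sigma_matrix / cutoff
    per_pair = epsilon_matrix * sigma_matrix**3 * (x**9 / 3.0 - x**3)
    total = n[:, None] * n[None, :] * per_pair
    return float(8.0 * np.pi / (3.0 * volume) * total.sum())


def minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


class ForceField:
    """Compiled evaluator for a :class:`MolecularTopology`.

    Parameters
    ----------
    topology : the system.
    cutoff : real-space nonbonded cutoff, Å.  Clamped to L/2 at evaluation
        if the box is smaller than 2×cutoff only when ``clamp_cutoff``;
        otherwise a too-small box raises :class:`ConfigurationError`.
    tail_correction : add the analytic LJ tail to the energy.
    periodic : minimum-image convention; gas-phase systems set this False.
    """

    def __init__(
        self,
        topology: MolecularTopology,
        cutoff: float = DEFAULT_CUTOFF,
        tail_correction: bool = True,
        periodic: bool = True,
        coulomb: str = "shifted_force",
        use_numba: bool = True,
    ):
        if coulomb not in ("shifted_force", "bare"):
            raise ValueError("coulomb must be 'shifted_force' or 'bare'")
        self.use_numba = bool(use_numba)
        self.topology = topology
        self.cutoff = float(cutoff)
        self.tail_correction = bool(tail_correction)
        self.periodic = bool(periodic)
        self.coulomb = coulomb
        self._compile()

    # -- compilation -------------------------------------------------------

    def _compile(self) -> None:
        top = self.topology
        n = top.n_atoms

        hb = [b for b in top.bonds if b.form == "harmonic"]
        mb = [b for b in top.bonds if b.form == "morse"]
        self._hb_ij = np.array([[b.i, b.j] for b in hb], dtype=int).reshape(-1, 2)
        self._hb_k = np.array([b.k for b in hb])
        self._hb_r0 = np.array([b.r0 for b in hb])
        self._mb_ij = np.array([[b.i, b.j] for b in mb], dtype=int).reshape(-1, 2)
        self._mb_D = np.array([b.D for b in mb])
        self._mb_a = np.array([b.a for b in mb])
        self._mb_r0 = np.array([b.r0 for b in mb])

        ang = top.angles
        self._ang_ijk = np.array([[t.i, t.j, t.k] for t in ang], dtype=int).reshape(-1, 3)
        self._ang_k = np.array([t.k_theta for t in ang])
        self._ang_t0 = np.array([t.theta0 for t in ang])

        self._dihedrals = list(top.dihedrals)

        tet = top.tethers
        self._tet_i = np.array([t.i for t in tet], dtype=int)
        self._tet_k = np.array([t.k for t in tet])
        self._tet_x0 = np.array([t.x0 for t in tet]).reshape(-1, 3)

        # nonbonded pair list: all i<j minus exclusions; 1-4 pairs scaled
        excluded, scaled = top.exclusion_pairs()
        ii, jj, scale = [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded:
                    continue
                s = top.scale_14 if (i, j) in scaled else 1.0
                if s == 0.0:
                    continue
                ii.append(i)
                jj.append(j)
                scale.append(s)
        self._nb_i = np.array(ii, dtype=int)
        self._nb_j = np.array(jj, dtype=int)
        nb_scale = np.array(scale)

        atoms = top.atoms
        sig = np.empty(len(ii))
        eps = np.empty(len(ii))
        for m, (i, j) in enumerate(zip(ii, jj)):
            p = waldman_hagler_mix(atoms[i], atoms[j])
            sig[m] = p.sigma_ij
            eps[m] = p.epsilon_ij
        eps = eps * nb_scale
        q = top.charges
        qq = COULOMB * q[self._nb_i] * q[self._nb_j] * nb_scale
        # drop pairs with neither LJ nor Coulomb interaction
        active = (eps != 0.0) | (qq != 0.0)
        self._nb_i = self._nb_i[active]
        self._nb_j = self._nb_j[active]
        self._nb_sigma = sig[active]
        self._nb_eps = eps[active]
        self._nb_qq = qq[active]

        # tail correction bookkeeping by (sigma, epsilon) type
        types: dict[tuple[float, float], int] = {}
        counts: list[int] = []
        for a in atoms:
            key = (a.sigma, a.epsilon)
            if key not in types:
                types[key] = len(types)
                counts.append(0)
            counts[types[key]] += 1
        self._tail_counts = np.array(counts, dtype=float)
        tkeys = list(types)
        nt = len(tkeys)
        sm = np.empty((nt, nt))
        em = np.empty((nt, nt))
        for a_ in range(nt):
            for b_ in range(nt):
                pa = AtomSpec("X", 1.0, 0.0, tkeys[a_][0], tkeys[a_][1])
                pb = AtomSpec("X", 1.0, 0.0, tkeys[b_][0], tkeys[b_][1])
                p = waldman_hagler_mix(pa, pb)
                sm[a_, b_] = p.sigma_ij
                em[a_, b_] = p.epsilon_ij
        self._tail_sigma = sm
        self._tail_eps = em

    # -- evaluation --------------------------------------------------------

    def effective_cutoff(self, box: float) -> float:
        if not self.periodic:
            return self.cutoff
        if box < 2.0 * self.cutoff:
            raise ConfigurationError(
                f"box edge {box:.3f} Å < 2×cutoff ({2 * self.cutoff:.3f} Å): "
                "minimum-image convention broken"
            )
        return self.cutoff

    def evaluate(self, positions: np.ndarray, box: float):
        """Energy (kJ/mol) and forces (kJ/mol/Å).

        ``positions`` of shape (N,3) returns a scalar energy and (N,3)
        forces; shape (P,N,3) returns per-bead energies (P,) and (P,N,3)
        forces (each bead is an independent copy of the physical system).
        """
        pos = np.asarray(positions, dtype=float)
        squeeze = pos.ndim == 2
        if squeeze:
            pos = pos[None]
        P, N, _ = pos.shape
        if N != self.topology.n_atoms:
            raise ConfigurationError(
                f"positions for {N} atoms but topology has {self.topology.n_atoms}"
            )
        energy = np.zeros(P)
        forces = np.zeros_like(pos)

        self._add_bonds(pos, box, energy, forces)
        self._add_angles(pos, energy, forces)
        self._add_dihedrals(pos, energy, forces)
        self._add_tethers(pos, energy, forces)
        self._add_nonbonded(pos, box, energy, forces)

        if not np.all(np.isfinite(energy)) or not np.all(np.isfinite(forces)):
            raise ConfigurationError("non-finite energy or force (overlap?)")
        if squeeze:
            return float(energy[0]), forces[0]
        return energy, forces

    def _pair_disp(self, pos, box, idx):
        d = pos[:, idx[:, 0]] - pos[:, idx[:, 1]]
        if self.periodic:
            d = minimum_image(d, box)
        return d

    @staticmethod
    def _accumulate(forces, idx, fvec, sign=1.0):
        """Scatter-add fvec (P,M,3) onto forces (P,N,3) at atom indices idx."""
        P, N = forces.shape[0], forces.shape[1]
        flat = (np.arange(P)[:, None] * N + idx[None, :]).ravel()
        fv = fvec.reshape(-1, 3)
        ff = forces.reshape(P * N, 3)
        for c in range(3):
            ff[:, c] += sign * np.bincount(flat, weights=fv[:, c], minlength=P * N)

    def _scatter(self, forces, idx_i, idx_j, fvec):
        self._accumulate(forces, idx_i, fvec, 1.0)
        self._accumulate(forces, idx_j, fvec, -1.0)

    def _add_bonds(self, pos, box, energy, forces):
        if len(self._hb_ij):
            d = self._pair_disp(pos, box, self._hb_ij)
            r = np.linalg.norm(d, axis=-1)
            dr = r - self._hb_r0
            energy += 0.5 * (self._hb_k * dr**2).sum(axis=-1)
            fmag = -self._hb_k * dr / r  # dU/dr along unit vector
            self._scatter(forces, self._hb_ij[:, 0], self._hb_ij[:, 1], fmag[..., None] * d)
        if len(self._mb_ij):
            d = self._pair_disp(pos, box, self._mb_ij)
            r = np.linalg.norm(d, axis=-1)
            dr = r - self._mb_r0
            ex = np.exp(-self._mb_a * dr)
            energy += (self._mb_D * (1.0 - ex) ** 2).sum(axis=-1)
            du = 2.0 * self._mb_D * self._mb_a * ex * (1.0 - ex)
            fmag = -du / r
            self._scatter(forces, self._mb_ij[:, 0], self._mb_ij[:, 1], fmag[..., None] * d)

    def _add_angles(self, pos, energy, forces):
        if not len(self._ang_ijk):
            return
        # angles are intramolecular: no minimum image needed for sane molecules
        ri = pos[:, self._ang_ijk[:, 0]]
        rj = pos[:, self._ang_ijk[:, 1]]
        rk = pos[:, self._ang_ijk[:, 2]]
        a = ri - rj
        b = rk - rj
        na = np.linalg.norm(a, axis=-1)
        nb = np.linalg.norm(b, axis=-1)
        cos = (a * b).sum(-1) / (na * nb)
        cos = np.clip(cos, -1.0 + 1e-12, 1.0 - 1e-12)
        theta = np.arccos(cos)
        dtheta = theta - self._ang_t0
        energy += 0.5 * (self._ang_k * dtheta**2).sum(axis=-1)
        dU = self._ang_k * dtheta  # dU/dθ
        sin = np.sqrt(1.0 - cos**2)
        # ∂θ/∂ri and ∂θ/∂rk (standard angle gradient)
        da = (cos[..., None] * a / na[..., None] - b / nb[..., None]) / (sin * na)[..., None]
        db = (cos[..., None] * b / nb[..., None] - a / na[..., None]) / (sin * nb)[..., None]
        fi = -dU[..., None] * da
        fk = -dU[..., None] * db
        self._accumulate(forces, self._ang_ijk[:, 0], fi, 1.0)
        self._accumulate(forces, self._ang_ijk[:, 2], fk, 1.0)
        self._accumulate(forces, self._ang_ijk[:, 1], fi + fk, -1.0)

    def _add_dihedrals(self, pos, energy, forces):
        if not self._dihedrals:
            return
        for t in self._dihedrals:
            b1 = pos[:, t.j] - pos[:, t.i]
            b2 = pos[:, t.k] - pos[:, t.j]
            b3 = pos[:, t.l] - pos[:, t.k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=-1)
            x = (n1 * n2).sum(-1)
            y = (np.cross(n1, n2) * (b2 / nb2[..., None])).sum(-1)
            phi = np.arctan2(y, x)
            u = np.zeros_like(phi)
            du = np.zeros_like(phi)
            for order, (c, p0) in enumerate(
                zip(t.coefficients, t.phases or (0.0,) * len(t.coefficients)), start=1
            ):
                u += c * (1.0 + np.cos(order * phi - p0))
                du += -c * order * np.sin(order * phi - p0)
            energy += u
            # analytic dihedral gradient (standard decomposition)
            n1sq = (n1 * n1).sum(-1)
            n2sq = (n2 * n2).sum(-1)
            fi = -du[..., None] * (nb2 / n1sq)[..., None] * n1
            fl = du[..., None] * (nb2 / n2sq)[..., None] * n2
            s = ((b1 * b2).sum(-1) / nb2**2)[..., None] * fi - (
                (b3 * b2).sum(-1) / nb2**2
            )[..., None] * fl
            fj = -fi + s
            fk = -fl - s
            forces[:, t.i] += fi
            forces[:, t.j] += fj
            forces[:, t.k] += fk
            forces[:, t.l] += fl

    def _add_tethers(self, pos, energy, forces):
        if not len(self._tet_i):
            return
        d = pos[:, self._tet_i] - self._tet_x0[None]
        energy += 0.5 * (self._tet_k * (d**2).sum(-1)).sum(-1)
        f = -self._tet_k[None, :, None] * d
        self._accumulate(forces, self._tet_i, f, 1.0)

    def _add_nonbonded(self, pos, box, energy, forces):
        if not len(self._nb_i):
            return
        rc = self.effective_cutoff(box)
        if HAVE_NUMBA and self.use_numba:
            energy += _nb_kernel(
                pos, box, self._nb_i, self._nb_j, self._nb_sigma,
                self._nb_eps, self._nb_qq, rc,
                self.coulomb == "shifted_force", self.periodic, forces,
            )
            if self.tail_correction and self.periodic:
                energy += lj_tail_correction(
                    self._tail_counts, self._tail_sigma, self._tail_eps, box**3, rc
                )
            return
        d = pos[:, self._nb_i] - pos[:, self._nb_j]
        if self.periodic:
            d = minimum_image(d, box)
        r2 = (d * d).sum(-1)
        within = r2 < rc * rc
        r2 = np.where(within, r2, rc * rc)  # dummy values outside, masked later
        inv_r2 = 1.0 / r2
        s2 = self._nb_sigma**2 * inv_r2
        s6 = s2**3
        u_lj = 4.0 * self._nb_eps * (s6 * s6 - s6)
        # dU/dr · (1/r): LJ
        f_over_r = (24.0 * self._nb_eps * (2.0 * s6 * s6 - s6)) * inv_r2
        r = np.sqrt(r2)
        if self.coulomb == "shifted_force":
            # u = qq[1/r − 1/rc + (r−rc)/rc²], f = qq[1/r² − 1/rc²]: force
            # and energy both continuous at the cutoff
            u_c = self._nb_qq * (1.0 / r - 1.0 / rc + (r - rc) / rc**2)
            f_over_r = f_over_r + self._nb_qq * (inv_r2 - 1.0 / rc**2) / r
        else:  # plain truncated 1/r
            u_c = self._nb_qq / r
            f_over_r = f_over_r + self._nb_qq * inv_r2 / r
        u = np.where(within, u_lj + u_c, 0.0)
        f_over_r = np.where(within, f_over_r, 0.0)
        energy += u.sum(axis=-1)
        self._scatter(forces, self._nb_i, self._nb_j, f_over_r[..., None] * d)

        if self.tail_correction and self.periodic:
            energy += lj_tail_correction(
                self._tail_counts, self._tail_sigma, self._tail_eps, box**3, rc
            )


def total_potential(
    positions: np.ndarray,
    topology: MolecularTopology,
    box: float,
    cutoff: float = DEFAULT_CUTOFF,
    tail_correction: bool = True,
    periodic: bool = True,
    coulomb: str = "shifted_force",
):
    """Convenience wrapper: compile and evaluate in one call."""
    ff = ForceField(
        topology, cutoff=cutoff, tail_correction=tail_correction,
        periodic=periodic, coulomb=coulomb,
    )
    return ff.evaluate(positions, box)
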