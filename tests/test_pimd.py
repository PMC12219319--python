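"""Ring-polymer dynamics: normal modes, thermostats, integrator conservation,
barostat sampling and quantum kinetic-energy estimators.

The harmonic cases have exact finite-P expectations from the Gaussian
ring-polymer covariance, used as the independent oracle throughout.
"""

import numpy as np
import pytest

from nqeliq.constants import ATM, HBAR, KB, dynamical_masses
from nqeliq.forcefield import ForceField
from nqeliq.pimd import (
    Integrator,
    IntegratorConfig,
    Leg,
    RingPolymerState,
    SimulationProtocol,
    initialize_state,
    kinetic_estimators,
    normal_mode_matrix,
    pile_step,
    run_simulation,
    spring_energy,
    spring_frequency,
)
from nqeliq.topology import AtomSpec, MolecularTopology

T0 = 298.15


def ring_laplacian(P):
    eye = np.eye(P)
    return 2 * eye - np.roll(eye, 1, 0) - np.roll(eye, -1, 0)


def exact_rp_energy(P, beta, m, omega):
    """Exact finite-P ⟨E⟩ per Cartesian dimension for a harmonic oscillator,
    from the Gaussian bead covariance (independent linear-algebra oracle)."""
    wn = np.sqrt(P) / (beta * HBAR)
    A = beta * (m * wn**2 * ring_laplacian(P) + (m * omega**2 / P) * np.eye(P))
    C = np.linalg.inv(A)
    e_spring = 0.5 * m * wn**2 * np.trace(ring_laplacian(P) @ C)
    u = 0.5 * m * omega**2 * np.trace(C) / P
    return 0.5 * P / beta - e_spring + u


class TestNormalModes:
    @pytest.mark.parametrize("P", [1, 2, 3, 8, 32])
    def test_round_trip_identity(self, P, rng):
        C, _ = normal_mode_matrix(P)
        x = rng.standard_normal((P, 5))
        np.testing.assert_allclose(C.T @ (C @ x), x, atol=1e-12)

    @pytest.mark.parametrize("P", [2, 4, 32])
    def test_mode0_is_sqrtP_times_centroid(self, P, rng):
        C, _ = normal_mode_matrix(P)
        x = rng.standard_normal((P, 3))
        np.testing.assert_allclose((C @ x)[0], np.sqrt(P) * x.mean(0), atol=1e-12)

    @pytest.mark.parametrize("P", [2, 5, 8, 32])
    def test_frequencies_match_spring_matrix_eigenvalues(self, P):
        C, factors = normal_mode_matrix(P)
        evals = np.linalg.eigvalsh(ring_laplacian(P))
        np.testing.assert_allclose(np.sort(factors**2), np.sort(evals), atol=1e-10)
        # and C actually diagonalizes it
        D = C @ ring_laplacian(P) @ C.T
        np.testing.assert_allclose(D, np.diag(factors**2), atol=1e-10)


class TestSpringEnergy:
    def test_collapsed_polymer_zero_and_classical_limit(self, rng):
        masses = np.array([1.008, 16.0])
        pos = np.repeat(rng.standard_normal((1, 2, 3)), 8, axis=0)
        s = RingPolymerState(pos, np.zeros_like(pos), 10.0, masses)
        assert spring_energy(s, T0) == 0.0
        s1 = RingPolymerState(pos[:1], np.zeros((1, 2, 3)), 10.0, masses)
        assert spring_energy(s1, T0) == 0.0

    def test_two_beads_direct_formula(self):
        # 1 atom, 2 beads separated by d along x: two springs, E = m ω_n² d²
        d, m_amu = 0.3, 1.008
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = d
        s = RingPolymerState(pos, np.zeros_like(pos), 10.0, np.array([m_amu]))
        m = dynamical_masses(np.array([m_amu]))[0]
        wn = spring_frequency(2, T0)
        assert spring_energy(s, T0) == pytest.approx(m * wn**2 * d**2, rel=1e-12)

    def test_invariant_under_rigid_translation(self, rng):
        pos = rng.standard_normal((8, 3, 3))
        s = RingPolymerState(pos, np.zeros_like(pos), 10.0, np.ones(3))
        e0 = spring_energy(s, T0)
        s2 = RingPolymerState(pos + 5.0, np.zeros_like(pos), 10.0, np.ones(3))
        assert spring_energy(s2, T0) == pytest.approx(e0, rel=1e-12)


class TestPileStep:
    def test_zero_friction_leaves_momenta_unchanged(self, rng):
        p = rng.standard_normal((4, 2, 3))
        out = pile_step(p.copy(), 0.01, 0.0, T0, dynamical_masses(np.ones(2)),
                        np.zeros(4), rng)
        np.testing.assert_allclose(out[0], p[0])  # centroid: γ=0 ⇒ identity

    def test_negative_friction_rejected(self, rng):
        with pytest.raises(ValueError):
            pile_step(np.zeros((1, 1, 3)), 0.01, -1.0, T0,
                      dynamical_masses(np.ones(1)), np.zeros(1), rng)

    def test_preserves_maxwell_boltzmann(self, rng):
        # repeated OU application equilibrates each mode to m k_B T variance
        P, N = 4, 3
        m = dynamical_masses(np.full(N, 2.0))
        C, factors = normal_mode_matrix(P)
        freqs = factors * spring_frequency(P, T0)
        p = np.zeros((P, N, 3))
        samples = []
        for i in range(4000):
            p = pile_step(p, 0.02, 5.0, T0, m, freqs.copy(), rng)
            if i > 500:
                samples.append(p.copy())
        ke = np.array([(s**2 / (2 * m[None, :, None])).sum() for s in samples])
        dof = 3 * N * P
        sem = ke.std(ddof=1) / np.sqrt(200)  # generous: correlated samples
        assert ke.mean() == pytest.approx(0.5 * dof * KB * T0, abs=3 * sem)

    def test_equal_seeds_identical_trajectories(self):
        p0 = np.ones((2, 1, 3))
        m = dynamical_masses(np.ones(1))
        freqs = np.array([0.0, 10.0])
        r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
        out1 = pile_step(p0.copy(), 0.01, 1.0, T0, m, freqs.copy(), r1)
        out2 = pile_step(p0.copy(), 0.01, 1.0, T0, m, freqs.copy(), r2)
        np.testing.assert_array_equal(out1, out2)


class TestIntegrator:
    def test_nve_energy_conservation(self, harmonic_diatomic, rng):
        top, pos = harmonic_diatomic
        ff = ForceField(top, periodic=False, tail_correction=False)
        state = initialize_state(top, pos, 50.0, 8, T0, rng)
        cfg = IntegratorConfig(timestep=0.0005, thermostat="none", T=T0)
        integ = Integrator(ff, state, cfg, rng)
        integ.run(50)  # move off the collapsed start
        energies = []
        for _ in range(1000):
            integ.step()
            energies.append(integ.extended_energy())
        e = np.asarray(energies)
        # secular drift: the symplectic splitting leaves a bounded (ωΔt)²
        # oscillation, so compare half-window means rather than endpoints
        drift = abs(e[500:].mean() - e[:500].mean()) / abs(e.mean())
        assert drift < 1e-5

    def test_classical_limit_matches_independent_langevin_oracle(
        self, harmonic_diatomic
    ):
        """P=1 with the OBABO splitting reproduced step by step in the test."""
        top, pos = harmonic_diatomic
        ff = ForceField(top, periodic=False, tail_correction=False)
        seed = 99
        state = initialize_state(top, pos, 50.0, 1, T0, np.random.default_rng(seed))
        cfg = IntegratorConfig(timestep=0.0005, thermostat="langevin",
                               friction=2.0, T=T0)
        integ = Integrator(ff, state, cfg, np.random.default_rng(seed))
        integ.run(200)

        # oracle: direct OBABO classical Langevin with the same noise streams
        # (one stream seeds the Maxwell draw, a second the thermostat noise,
        # mirroring the construction above)
        m = dynamical_masses(top.masses)[:, None]
        x = pos.copy()
        p = (np.random.default_rng(seed).standard_normal((1, 2, 3))
             * np.sqrt(KB * T0 * dynamical_masses(top.masses))[None, :, None])[0]
        rng = np.random.default_rng(seed)
        dt = 0.0005
        c1 = np.exp(-2.0 * dt / 2)
        c2 = np.sqrt((1 - c1**2) * KB * T0 * dynamical_masses(top.masses))[:, None]
        _, f = ff.evaluate(x, 50.0)
        for _ in range(200):
            p = c1 * p + c2 * rng.standard_normal((1, 2, 3))[0]
            p = p + 0.5 * dt * f
            x = x + dt * p / m
            _, f = ff.evaluate(x, 50.0)
            p = p + 0.5 * dt * f
            p = c1 * p + c2 * rng.standard_normal((1, 2, 3))[0]
        np.testing.assert_allclose(integ.state.positions[0], x, atol=1e-10)

    def test_free_ring_polymer_evolves_analytically(self):
        """Zero forces, no thermostat: each internal mode rotates at ω_k."""
        top = MolecularTopology(atoms=[AtomSpec("H", 1.008, 0.0, 1.0, 0.0)])
        ff = ForceField(top, periodic=False, tail_correction=False)
        P = 8
        rng = np.random.default_rng(3)
        state = initialize_state(top, np.zeros((1, 3)), 50.0, P, T0, rng)
        state.positions += 0.3 * rng.standard_normal(state.positions.shape)
        C, factors = normal_mode_matrix(P)
        m = dynamical_masses(top.masses)[0]
        q0 = (C @ state.positions.reshape(P, -1))
        p0 = (C @ state.momenta.reshape(P, -1))
        cfg = IntegratorConfig(timestep=0.0005, thermostat="none", T=T0)
        integ = Integrator(ff, state, cfg, rng)
        n_steps = 400
        integ.run(n_steps)
        t = n_steps * cfg.timestep
        w = factors * spring_frequency(P, T0)
        qt = np.empty_like(q0)
        for k in range(P):
            if w[k] == 0:
                qt[k] = q0[k] + p0[k] / m * t
            else:
                qt[k] = q0[k] * np.cos(w[k] * t) + p0[k] / (m * w[k]) * np.sin(w[k] * t)
        got = C @ integ.state.positions.reshape(P, -1)
        np.testing.assert_allclose(got, qt, atol=1e-8)


class TestBarostat:
    def test_ideal_gas_volume_matches_exact_ensemble_mean(self, sem_of):
        """U=0 molecular gas: stationary p(V) ∝ V^N e^{−βPV} ⇒ ⟨V⟩=(N+1)kT/P."""
        N = 10
        top = MolecularTopology(atoms=[AtomSpec("X", 10.0, 0.0, 1.0, 0.0)] * N)
        ff = ForceField(top, cutoff=1.0, tail_correction=False)
        rng = np.random.default_rng(11)
        p_atm = 200.0
        p_int = p_atm * ATM
        v_exact = (N + 1) * KB * T0 / p_int
        box0 = v_exact ** (1 / 3)
        state = initialize_state(top, rng.uniform(0, box0, (N, 3)), box0, 1, T0, rng)
        cfg = IntegratorConfig(timestep=0.002, thermostat="langevin", friction=5.0,
                               barostat="monte_carlo", barostat_interval=0.02,
                               T=T0, pressure=p_atm)
        integ = Integrator(ff, state, cfg, rng)
        integ.run(2000)
        vols = []
        for i in range(40000):
            integ.step()
            if i % 10 == 0:
                vols.append(integ.state.box**3)
        sem = sem_of(vols)
        assert np.mean(vols) == pytest.approx(v_exact, abs=3 * sem)
        assert 0.1 < integ.barostat_accepts / integ.barostat_attempts < 0.9

    def test_volume_move_preserves_intramolecular_geometry(self, toy_liquid):
        top, pos, box = toy_liquid
        ff = ForceField(top, cutoff=0.4 * box)
        rng = np.random.default_rng(2)
        state = initialize_state(top, pos, box, 4, 150.0, rng)
        state.positions += 0.05 * rng.standard_normal(state.positions.shape)
        cfg = IntegratorConfig(T=150.0, barostat="monte_carlo")
        integ = Integrator(ff, state, cfg, rng)
        mol = top.molecules()[0]
        before = state.positions[:, mol[1]] - state.positions[:, mol[0]]
        spring_before = spring_energy(state, 150.0)
        accepted = 0
        for _ in range(50):
            accepted += integ.mc_barostat_move()
        after = integ.state.positions[:, mol[1]] - integ.state.positions[:, mol[0]]
        assert accepted > 0
        np.testing.assert_allclose(after, before, atol=1e-10)
        assert spring_energy(integ.state, 150.0) == pytest.approx(
            spring_before, rel=1e-9
        )

    def test_lj_fluid_matches_independent_mc_reference(self, sem_of):
        """Small classical LJ fluid NPT: MD+MC barostat vs a pure Metropolis
        Monte Carlo NPT sampler written independently here."""
        N, T, p_atm = 16, 150.0, 50.0
        sigma, eps = 2.5, 1.0
        top = MolecularTopology(atoms=[AtomSpec("X", 30.0, 0.0, sigma, eps)] * N)
        rc = 3.6
        ff = ForceField(top, cutoff=rc, tail_correction=False)
        rng = np.random.default_rng(4)
        box0 = 9.5
        # loose lattice start
        g = np.stack(np.meshgrid(*[np.arange(3)] * 3), -1).reshape(-1, 3)[:N]
        pos0 = (g + 0.5) * box0 / 3
        state = initialize_state(top, pos0, box0, 1, T, rng)
        cfg = IntegratorConfig(timestep=0.002, thermostat="langevin", friction=2.0,
                               barostat="monte_carlo", barostat_interval=0.05,
                               T=T, pressure=p_atm)
        integ = Integrator(ff, state, cfg, rng)
        integ.run(3000)
        vols_md = []
        for i in range(25000):
            integ.step()
            if i % 10 == 0:
                vols_md.append(integ.state.box**3)

        # independent reference: Metropolis NPT MC (displacements + V moves)
        beta = 1.0 / (KB * T)
        p_int = p_atm * ATM

        def energy(x, L):
            d = x[:, None, :] - x[None, :, :]
            d -= L * np.round(d / L)
            r2 = (d**2).sum(-1)
            iu = np.triu_indices(N, 1)
            r2 = r2[iu]
            mask = r2 < rc**2
            s6 = (sigma**2 / r2[mask]) ** 3
            return float((4 * eps * (s6**2 - s6)).sum())

        mc_rng = np.random.default_rng(8)
        x, L = pos0.copy(), box0
        u = energy(x, L)
        vols_mc = []
        for sweep in range(6000):
            for _ in range(N):
                i = mc_rng.integers(N)
                old = x[i].copy()
                x[i] = (x[i] + mc_rng.uniform(-0.35, 0.35, 3)) % L
                u_new = energy(x, L)
                if mc_rng.random() < np.exp(min(0.0, -beta * (u_new - u))):
                    u = u_new
                else:
                    x[i] = old
            V = L**3
            V_new = V + mc_rng.uniform(-0.06, 0.06) * V
            L_new = V_new ** (1 / 3)
            if L_new >= 2 * rc:
                xs = x * (L_new / L)
                u_new = energy(xs, L_new)
                w = -beta * (u_new - u + p_int * (V_new - V)) + N * np.log(V_new / V)
                if mc_rng.random() < np.exp(min(0.0, w)):
                    x, L, u = xs, L_new, u_new
            if sweep > 1000:
                vols_mc.append(L**3)

        sem = np.hypot(sem_of(vols_md), sem_of(vols_mc))
        assert np.mean(vols_md) == pytest.approx(np.mean(vols_mc), abs=3 * sem)


class TestKineticEstimators:
    def test_classical_limit_reduces_to_equipartition_constant(self, rng):
        top = MolecularTopology(atoms=[AtomSpec("X", 10.0, 0.0, 1.0, 0.0)] * 5)
        state = initialize_state(top, rng.standard_normal((5, 3)), 20.0, 1, T0, rng)
        est = kinetic_estimators(state, np.zeros((1, 5, 3)), T0)
        expected = 1.5 * 5 * KB * T0
        assert est["primitive"] == pytest.approx(expected)
        assert est["centroid_virial"] == pytest.approx(expected)

    def test_harmonic_estimators_agree_with_exact_gaussian_oracle(self, qho_factory):
        """Sampled primitive and centroid-virial KE at βħω=2, P=16 both match
        the exact finite-P value within 3 SEM, and each other."""
        beta = 1.0 / (KB * T0)
        omega = 2.0 / (beta * HBAR)
        m = dynamical_masses(np.array([1.008]))[0]
        top = qho_factory(4, m * omega**2)
        ff = ForceField(top, periodic=False, tail_correction=False)
        rng = np.random.default_rng(21)
        P = 16
        x0 = np.array([t.x0 for t in top.tethers], dtype=float)
        state = initialize_state(top, x0, 200.0, P, T0, rng)
        cfg = IntegratorConfig(thermostat="pile", friction=omega, T=T0)
        integ = Integrator(ff, state, cfg, rng)
        integ.run(1500)
        prim, cv, pot = [], [], []
        for i in range(12000):
            integ.step()
            if i % 4 == 0:
                est = kinetic_estimators(state, integ._bead_forces, T0)
                prim.append(est["primitive"])
                cv.append(est["centroid_virial"])
                pot.append(integ.potential())
        e_exact = 3 * 4 * exact_rp_energy(P, beta, m, omega)
        nb = 15
        for name, ke in (("primitive", prim), ("centroid_virial", cv)):
            tot = np.asarray(ke) + np.asarray(pot)
            blocks = tot[: len(tot) // nb * nb].reshape(nb, -1).mean(1)
            sem = blocks.std(ddof=1) / np.sqrt(nb)
            assert np.mean(tot) == pytest.approx(e_exact, abs=3 * sem), name


class TestRunSimulation:
    def test_zero_duration_protocol_gives_empty_series(self, harmonic_diatomic):
        top, pos = harmonic_diatomic
        proto = SimulationProtocol(legs=[Leg("nvt", 0.0, record=True)])
        s = run_simulation(top, proto, pos, 50.0, n_beads=1, seed=0)
        assert s.n_frames == 0

    def test_reproducible_under_fixed_seed(self, harmonic_diatomic):
        top, pos = harmonic_diatomic
        proto = SimulationProtocol(
            legs=[Leg("nvt", 0.05, record=True, stride=10)]
        )
        a = run_simulation(top, proto, pos, 50.0, n_beads=4, seed=5)
        b = run_simulation(top, proto, pos, 50.0, n_beads=4, seed=5)
        np.testing.assert_array_equal(a.potential_beads, b.potential_beads)
        c = run_simulation(top, proto, pos, 50.0, n_beads=4, seed=6)
        assert not np.array_equal(a.potential_beads, c.potential_beads)

    def test_replicas_with_distinct_seeds_give_positive_sem(self, harmonic_diatomic):
        from nqeliq.nqe_stats import replicate_stats

        top, pos = harmonic_diatomic
        proto = SimulationProtocol(legs=[Leg("nvt", 0.1, record=True, stride=10)])
        means = [
            float(np.mean(run_simulation(
                top, proto, pos, 50.0, n_beads=1, seed=1, replica=r
            ).potential))
            for r in range(3)
        ]
        _, sem = replicate_stats(means)
        assert sem > 0

    def test_gas_phase_andersen_removes_com_motion(self):
        """Single molecule, NVE then Andersen NVT: no periodic images, net
        linear momentum removed, temperature near the setpoint."""
        from nqeliq.synthetic_data import ToyLiquidSpec, make_toy_liquid

        top, pos, box = make_toy_liquid(
            ToyLiquidSpec(n_molecules=1, box=50.0), seed=2
        )
        proto = SimulationProtocol(
            legs=[Leg("nve", 0.05, T=150.0),
                  Leg("nvt", 0.5, T=150.0, record=True, stride=10)],
            thermostat="andersen", gas_phase=True,
        )
        s = run_simulation(top, proto, pos, box, n_beads=1, seed=3)
        assert s.phase == "gas"
        state = s.final_state
        assert np.abs(state.momenta.sum(axis=(0, 1))).max() < 1e-10
        # molecule intact and thermalized at a sane scale (a diatomic keeps
        # ~1-3 effective DOF after COM/rotation removal)
        r = np.linalg.norm(state.positions[0, 1] - state.positions[0, 0])
        assert 0.7 < r < 1.3
        m = state.dyn_masses[None, :, None]
        ke = float((state.momenta**2 / (2 * m)).sum())
        assert 0.05 * KB * 150.0 < ke < 5 * KB * 150.0

    def test_temperature_ramp_leg_runs(self, harmonic_diatomic):
        top, pos = harmonic_diatomic
        proto = SimulationProtocol(
            legs=[Leg("nvt", 0.05, T=400.0, T_end=298.15, record=True, stride=20)]
        )
        s = run_simulation(top, proto, pos, 50.0, n_beads=2, seed=1)
        assert s.n_frames > 0
        assert s.T == pytest.approx(298.15)
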