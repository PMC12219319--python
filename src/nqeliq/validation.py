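"""Standard validation experiments, each with a known expected outcome.

These are the package's built-in benchmarks: the exactly solvable quantum
harmonic oscillator, generator/estimator round trips, the toy-liquid
isotope study, the composite-model recovery experiments, Shapley axioms
and the hydrogen-bond fixtures.  The acceptance script runs them from
scratch; the test-suite checks them against independent oracles.
"""

from __future__ import annotations

import numpy as np

from .constants import HBAR, KB, dynamical_masses
from .forcefield import ForceField
from .pimd import Integrator, IntegratorConfig, initialize_state, kinetic_estimators
from .topology import AtomSpec, MolecularTopology, TetherTerm

QHO_T = 298.15


def exact_qho_energy_per_dim(n_beads: int, beta: float, mass: float, omega: float) -> float:
    """Exact finite-P ⟨E⟩ per Cartesian dimension for the discretized
    harmonic oscillator, from the Gaussian bead covariance."""
    P = n_beads
    eye = np.eye(P)
    lap = 2 * eye - np.roll(eye, 1, 0) - np.roll(eye, -1, 0)
    wn = np.sqrt(P) / (beta * HBAR)
    A = beta * (mass * wn**2 * lap + (mass * omega**2 / P) * eye)
    C = np.linalg.inv(A)
    e_spring = 0.5 * mass * wn**2 * np.trace(lap @ C)
    u = 0.5 * mass * omega**2 * np.trace(C) / P
    return 0.5 * P / beta - e_spring + u


def quantum_qho_energy_per_dim(beta: float, omega: float) -> float:
    """(ħω/2)·coth(βħω/2), the exact quantum average energy."""
    return 0.5 * HBAR * omega / np.tanh(0.5 * beta * HBAR * omega)


def qho_energy_experiment(
    n_beads: int,
    beta_hbar_omega: float = 2.0,
    T: float = QHO_T,
    n_oscillators: int = 8,
    n_steps: int = 30000,
    n_burn: int = 1500,
    seed: int = 0,
) -> dict:
    """Sample ⟨E⟩ of tethered 3-D harmonic oscillators with PIMD.

    The centroid is thermostatted at critical coupling (γ₀ = ω) so the
    budgeted run decorrelates; internal modes use the standard PILE
    frictions.  Returns the sampled energy per dimension in units of ħω,
    a block-averaged SEM, and the exact finite-P / quantum references.
    """
    beta = 1.0 / (KB * T)
    omega = beta_hbar_omega / (beta * HBAR)
    m = dynamical_masses(np.array([1.008]))[0]
    k = m * omega**2
    atoms = [AtomSpec("H", 1.008, 0.0, 1.0, 0.0)] * n_oscillators
    tethers = [TetherTerm(i, k, x0=(10.0 * i, 0.0, 0.0)) for i in range(n_oscillators)]
    top = MolecularTopology(atoms=atoms, tethers=tethers)
    ff = ForceField(top, periodic=False, tail_correction=False)
    rng = np.random.default_rng(seed)
    x0 = np.array([t.x0 for t in tethers], dtype=float)
    state = initialize_state(top, x0, 1e4, n_beads, T, rng)
    cfg = IntegratorConfig(thermostat="pile", friction=omega, T=T)
    integ = Integrator(ff, state, cfg, rng)
    integ.run(n_burn)
    samples = []
    for i in range(n_steps):
        integ.step()
        if i % 5 == 0:
            est = kinetic_estimators(state, integ._bead_forces, T)
            samples.append(est["centroid_virial"] + integ.potential())
    hw = HBAR * omega
    e = np.asarray(samples) / (3 * n_oscillators * hw)
    n_blocks = 20
    blocks = e[: len(e) // n_blocks * n_blocks].reshape(n_blocks, -1).mean(axis=1)
    return {
        "n_beads": n_beads,
        "energy_per_hbar_omega": float(e.mean()),
        "sem": float(blocks.std(ddof=1) / np.sqrt(n_blocks)),
        "exact_finite_p": float(exact_qho_energy_per_dim(n_beads, beta, m, omega) / hw),
        "exact_quantum": float(quantum_qho_energy_per_dim(beta, omega) / hw),
        "classical": float(1.0 / beta / hw),
    }


def estimator_recovery_experiment(seed: int = 0, n_frames: int = 100000) -> dict:
    """Generator→estimator round trip: ratios of recovered to target values."""
    from .properties import (
        isothermal_compressibility,
        molar_volume,
        static_dielectric_from_series,
        thermal_expansion_from_series,
    )
    from .synthetic_data import make_observable_fixture

    targets = {"kappa_T": 8e-5, "eps_r0": 25.0, "v_m": 90.0}
    s = make_observable_fixture(targets, n_frames=n_frames, seed=seed)
    triple = make_observable_fixture(
        {"alpha_P": 1.5e-3, "kappa_T": 5e-5}, n_frames=n_frames, seed=seed + 1
    )
    alpha, alpha_sem = thermal_expansion_from_series(triple)
    return {
        "kappa_ratio": isothermal_compressibility(s) / targets["kappa_T"],
        "eps_ratio": static_dielectric_from_series(s) / targets["eps_r0"],
        "vm_ratio": molar_volume(s, 40.0) / targets["v_m"],
        "alpha_ratio": alpha / 1.5e-3,
        "alpha_sem": alpha_sem,
        "n_frames": n_frames,
    }


def toy_liquid_isotope_experiment(seed: int = 1, n_replicas: int = 4) -> dict:
    """The headline desk-scale study: classical vs PI vs deuterated PI.

    Four independently packed replicas per treatment; the cheap classical
    treatments run longer production for a sharper isotope-invariance
    baseline.  Returns Δ_vm, Δ_vm^{D→H} (fractions with SEMs) and the
    classical H-vs-D volume difference, which classical statistical
    mechanics requires to vanish.
    """
    from .nqe_stats import nqe_magnitude
    from .pipeline import StudyLegs, nqe_study
    from .synthetic_data import ToyLiquidSpec

    study = nqe_study(
        ToyLiquidSpec(), seed=seed, n_replicas=n_replicas,
        legs=StudyLegs(nvt_equil=1.0, npt_equil=8.0, production=18.0),
        classical_legs=StudyLegs(nvt_equil=1.0, npt_equil=8.0, production=40.0),
        treatments=("cl", "cl-D", "PI", "PI-D"),
    )
    v_cl, s_cl = study.volumes["cl"]
    v_cld, s_cld = study.volumes["cl-D"]
    cl_iso, cl_iso_sem = nqe_magnitude(v_cld, v_cl, s_cld, s_cl)
    return {
        "delta_vm": study.delta_vm,
        "delta_vm_sem": study.delta_vm_sem,
        "isotope_delta_vm": study.isotope_delta_vm,
        "isotope_delta_vm_sem": study.isotope_delta_vm_sem,
        "classical_hd_volume_diff": cl_iso,
        "classical_hd_volume_diff_sem": cl_iso_sem,
        "volumes_nm3": {t: v for t, (v, _) in study.volumes.items()},
        "volume_sems_nm3": {t: s for t, (_, s) in study.volumes.items()},
        "n_replicas": n_replicas,
    }


def ml_recovery_experiment(seed: int = 0, n_datasets: int = 10) -> dict:
    """Composite-model recovery: zero-noise LOO R² and the composite-vs-flat
    win count over replicate noisy datasets."""
    from .ml_pipeline import CompositeNQEModel, FlatNQEModel, loo_evaluate
    from .synthetic_data import FeatureGenSpec, make_feature_dataset

    clean, _ = make_feature_dataset(
        FeatureGenSpec(noise_t=0.0, noise_delta=0.0, seed=seed)
    )
    r2_clean = loo_evaluate(clean, n_seed_iterations=1, base_seed=seed)["r2_mean"]
    wins = 0
    noisy_r2 = []
    for i in range(n_datasets):
        df, _ = make_feature_dataset(FeatureGenSpec(seed=seed + i))
        rc = loo_evaluate(df, n_seed_iterations=1, base_seed=seed,
                          model_cls=CompositeNQEModel)
        rf = loo_evaluate(df, n_seed_iterations=1, base_seed=seed,
                          model_cls=FlatNQEModel)
        wins += int(rc["loo_rmse"] < rf["loo_rmse"])
        noisy_r2.append(rc["r2_mean"])
    return {
        "r2_zero_noise": float(r2_clean),
        "composite_wins": wins,
        "n_datasets": n_datasets,
        "r2_noisy_mean": float(np.mean(noisy_r2)),
    }


def shapley_axiom_experiment(seed: int = 0) -> dict:
    """Efficiency residual of exact Shapley attribution on a fitted model."""
    from .ml_pipeline import (
        composite_prediction_function, exact_shapley, fit_composite,
    )
    from .synthetic_data import FeatureGenSpec, make_feature_dataset

    df, _ = make_feature_dataset(FeatureGenSpec(seed=seed))
    model = fit_composite(df, seed=seed)
    f = composite_prediction_function(model)
    bg = df[["m_w", "n_H", "alpha_P"]].to_numpy()
    base = float(np.mean(f(bg)))
    worst = 0.0
    rng = np.random.default_rng(seed)
    for i in rng.choice(len(df), 10, replace=False):
        phi = exact_shapley(f, bg[i], bg)
        fx = float(f(bg[i][None])[0])
        denom = max(abs(fx - base), 1e-30)
        worst = max(worst, abs(phi.sum() - (fx - base)) / denom)
    return {"max_efficiency_residual": worst}


def hbond_fixture_experiment() -> dict:
    """Counts on constructed dimer fixtures with exactly known answers."""
    from .interactions import Frame, find_hbonds, hbond_density_profile
    from .synthetic_data import DimerSpec, make_hbond_fixture

    top1, pos1, box1 = make_hbond_fixture([DimerSpec(d_da=2.8, angle_deg=170.0)])
    top0, pos0, box0 = make_hbond_fixture([DimerSpec(d_da=2.8, angle_deg=120.0)])
    top10, pos10, box10 = make_hbond_fixture(
        [DimerSpec(d_da=3.5)] * 10, box=60.0, spacing=12.0
    )
    prof = hbond_density_profile([[Frame(pos10, box10)]], top10)
    return {
        "compliant_dimer_count": len(find_hbonds(Frame(pos1, box1), top1)),
        "bent_dimer_count": len(find_hbonds(Frame(pos0, box0), top0)),
        "grid_count": len(find_hbonds(Frame(pos10, box10), top10)),
        "grid_profile_integral": float(prof.values.sum() * box10**3),
    }
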