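"""End-to-end driver: toy liquid → simulations → properties → NQE table.

The study design mirrors the reference protocol at desk scale: for one
liquid, run the three treatments — classical (1 bead), path-integral
(32 beads), and deuterated path-integral — each over independent replicas,
estimate properties from the production segments, and reduce them to NQE
magnitudes Δ_λ, isotope effects Δ_λ^{D→H} and the reduced temperature T_vm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nqe_stats, properties
from .io import RunManifest, write_topology
from .observables import ObservableSeries
from .pimd import Leg, SimulationProtocol, run_simulation
from .synthetic_data import ToyLiquidSpec, make_toy_liquid
from .topology import MolecularTopology


@dataclass
class StudyLegs:
    """Durations (ps) of the equilibration/production schedule."""

    nvt_equil: float = 1.0
    npt_equil: float = 10.0
    production: float = 25.0
    T: float = 150.0
    pressure: float = 1.0
    stride: int = 25  # steps between recorded frames

    def build(self) -> list[Leg]:
        return [
            Leg("nvt", self.nvt_equil, T=self.T),
            Leg("npt", self.npt_equil, T=self.T, pressure=self.pressure),
            Leg("npt", self.production, T=self.T, pressure=self.pressure,
                record=True, stride=self.stride),
        ]


def run_liquid(
    topology: MolecularTopology,
    positions: np.ndarray,
    box: float,
    n_beads: int,
    seed: int,
    replica: int = 0,
    legs: StudyLegs | None = None,
) -> ObservableSeries:
    legs = legs or StudyLegs()
    protocol = SimulationProtocol(legs=legs.build(), minimize_first=True)
    return run_simulation(
        topology, protocol, positions, box, n_beads=n_beads,
        seed=seed, replica=replica,
    )


@dataclass
class NQEStudyResult:
    v_m: dict[str, nqe_stats.PropertyTriplet] = field(default_factory=dict)
    volumes: dict[str, tuple[float, float]] = field(default_factory=dict)
    delta_vm: float = np.nan
    delta_vm_sem: float = np.nan
    isotope_delta_vm: float = np.nan
    isotope_delta_vm_sem: float = np.nan
    series: dict[str, list[ObservableSeries]] = field(default_factory=dict)


def nqe_study(
    spec: ToyLiquidSpec,
    molar_mass: float | None = None,
    n_beads: int = 32,
    n_replicas: int = 4,
    seed: int = 0,
    legs: StudyLegs | None = None,
    classical_legs: StudyLegs | None = None,
    classical_replicas: int | None = None,
    treatments: tuple[str, ...] = ("cl", "PI", "PI-D"),
) -> NQEStudyResult:
    """Quantify the NQE on molar volume for one toy liquid.

    Treatments: ``cl`` / ``cl-D`` classical (1 bead, H or D masses), ``PI``
    path-integral (n_beads), ``PI-D`` deuterated path-integral.  Each runs
    independently packed, independently seeded replicas.  Classical runs
    cost a small fraction of the path-integral ones, so they may use their
    own (longer) ``classical_legs`` and replica count for sharper
    statistics on the classical isotope-invariance baseline.
    """
    legs = legs or StudyLegs()
    classical_legs = classical_legs or legs
    result = NQEStudyResult()
    beads = {"cl": 1, "cl-D": 1, "PI": n_beads, "PI-D": n_beads}
    vm: dict[str, list[float]] = {}
    for t_i, treatment in enumerate(treatments):
        tspec = ToyLiquidSpec(
            template=spec.template, n_molecules=spec.n_molecules, box=spec.box,
            bond_form=spec.bond_form, deuterate=treatment.endswith("-D"),
        )
        classical = beads[treatment] == 1
        t_legs = classical_legs if classical else legs
        t_reps = (classical_replicas or n_replicas) if classical else n_replicas
        series_list = []
        for rep in range(t_reps):
            top, pos, box = make_toy_liquid(tspec, seed=seed * 1000 + rep)
            s = run_simulation(
                top,
                SimulationProtocol(legs=t_legs.build(), minimize_first=True),
                pos, box, n_beads=beads[treatment],
                seed=seed + 7919 * (t_i + 1), replica=rep,
                name=f"{top.name}:{treatment}",
            )
            series_list.append(s)
        result.series[treatment] = series_list
        mm = molar_mass if molar_mass is not None else (
            series_list[0].final_state.masses.sum() / tspec.n_molecules
        )
        vm[treatment] = [properties.molar_volume(s, mm) for s in series_list]
        result.volumes[treatment] = nqe_stats.replicate_stats(
            [float(np.mean(s.volumes)) for s in series_list]
        )
    stats = {t: nqe_stats.replicate_stats(v) for t, v in vm.items()}
    if {"cl", "PI"} <= set(treatments):
        result.delta_vm, result.delta_vm_sem = nqe_stats.nqe_magnitude(
            stats["PI"][0], stats["cl"][0], stats["PI"][1], stats["cl"][1]
        )
    if {"PI", "PI-D"} <= set(treatments):
        result.isotope_delta_vm, result.isotope_delta_vm_sem = nqe_stats.isotope_effect(
            stats["PI"][0], stats["PI-D"][0], stats["PI"][1], stats["PI-D"][1]
        )
    result.v_m = {
        t: nqe_stats.PropertyTriplet(
            tag="v_m",
            classical=stats.get("cl", (np.nan, 0.0))[0],
            pi=stats.get("PI", (np.nan, 0.0))[0],
            pi_deuterated=stats.get("PI-D", (np.nan, 0.0))[0],
            sem_classical=stats.get("cl", (np.nan, 0.0))[1],
            sem_pi=stats.get("PI", (np.nan, 0.0))[1],
            sem_pi_deuterated=stats.get("PI-D", (np.nan, 0.0))[1],
        )
        for t in ("v_m",)
    }
    return result


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute configured stages and write CSV outputs plus a manifest.

    Config keys: ``seed``, ``liquid`` (ToyLiquidSpec fields), ``beads``,
    ``replicas``, ``legs`` (StudyLegs fields), ``stages`` (subset of
    synthesize/simulate/nqe).  Rerunning with the same config and seed
    reproduces all outputs bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ["synthesize", "simulate", "nqe"]))
    spec = ToyLiquidSpec(**config.get("liquid", {}))
    legs = StudyLegs(**config.get("legs", {}))
    manifest = RunManifest(seed=seed, protocol={**config, "stages": stages})

    top, pos, box = make_toy_liquid(spec, seed=seed)
    if "synthesize" in stages:
        write_topology(top, out / "topology.yaml")
        np.savetxt(out / "initial_positions.csv", pos, delimiter=",",
                   header="x_A,y_A,z_A")
        manifest.stages.append("synthesize")

    if "simulate" in stages or "nqe" in stages:
        study = nqe_study(
            spec,
            n_beads=int(config.get("beads", 32)),
            n_replicas=int(config.get("replicas", 2)),
            seed=seed,
            legs=legs,
        )
        for treatment, series_list in study.series.items():
            for s in series_list:
                s.to_csv(out / f"observables_{treatment}_rep{s.replica}.csv")
        manifest.stages.append("simulate")
        if "nqe" in stages:
            trip = study.v_m["v_m"]
            df = pd.DataFrame(
                [
                    {
                        "molecule": top.name,
                        "property": "v_m",
                        "delta_percent": 100 * study.delta_vm,
                        "delta_sem_percent": 100 * study.delta_vm_sem,
                        "isotope_delta_percent": 100 * study.isotope_delta_vm,
                        "isotope_delta_sem_percent": 100 * study.isotope_delta_vm_sem,
                        "v_m_cl_cm3_mol": trip.classical,
                        "v_m_PI_cm3_mol": trip.pi,
                        "v_m_PI_D_cm3_mol": trip.pi_deuterated,
                    }
                ]
            )
            df.to_csv(out / "nqe_table.csv", index=False)
            manifest.stages.append("nqe")

    manifest.write(out / "manifest.json")
    return out
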