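"""Time series of simulation observables and their CSV interchange format.

One :class:`ObservableSeries` holds everything the property estimators
need from a single run: volumes (nm³), per-bead physical potential
energies (kJ/mol), quantum kinetic-energy estimators, ring-polymer spring
energy, and the per-bead box dipole (e·Å).  The CSV layout is flat
(one row per frame, per-bead quantities expanded into columns) with a
``# key: value`` metadata header carrying units, seed and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class ObservableSeries:
    times: np.ndarray            # ps
    volumes: np.ndarray          # nm³
    potential_beads: np.ndarray  # (n_frames, n_beads), kJ/mol, physical U(x_b)
    kinetic_cv: np.ndarray       # kJ/mol, centroid-virial estimator
    kinetic_primitive: np.ndarray
    spring: np.ndarray           # kJ/mol
    dipoles: np.ndarray          # (n_frames, n_beads, 3), e·Å
    T: float                     # K (setpoint of recorded leg)
    pressure: float              # atm
    n_beads: int
    n_molecules: int
    phase: str = "liquid"        # "liquid" | "gas"
    replica: int = 0
    metadata: dict[str, Any] = field(default_factory=dict)
    final_state: Any = None      # RingPolymerState; not serialized

    def __post_init__(self):
        n = len(self.times)
        for name in ("volumes", "kinetic_cv", "kinetic_primitive", "spring"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name!r} length mismatch")
        if self.potential_beads.shape[:1] != (n,) or self.dipoles.shape[:1] != (n,):
            raise ValueError("per-bead series length mismatch")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def potential(self) -> np.ndarray:
        """Bead-averaged potential per frame (the PI potential estimator)."""
        return self.potential_beads.mean(axis=1)

    @property
    def total_energy(self) -> np.ndarray:
        """Internal energy per frame: bead-averaged potential + quantum KE."""
        return self.potential + self.kinetic_cv

    def subsample(self, stride: int) -> "ObservableSeries":
        sl = slice(None, None, stride)
        return ObservableSeries(
            times=self.times[sl], volumes=self.volumes[sl],
            potential_beads=self.potential_beads[sl],
            kinetic_cv=self.kinetic_cv[sl],
            kinetic_primitive=self.kinetic_primitive[sl],
            spring=self.spring[sl], dipoles=self.dipoles[sl],
            T=self.T, pressure=self.pressure, n_beads=self.n_beads,
            n_molecules=self.n_molecules, phase=self.phase,
            replica=self.replica, metadata=dict(self.metadata),
        )

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        meta = {
            "units": "time:ps volume:nm^3 energy:kJ/mol dipole:e*Angstrom",
            "T_K": self.T, "pressure_atm": self.pressure,
            "n_beads": self.n_beads, "n_molecules": self.n_molecules,
            "phase": self.phase, "replica": self.replica,
            **self.metadata,
        }
        cols: dict[str, np.ndarray] = {"time": self.times, "volume": self.volumes}
        for b in range(self.n_beads):
            cols[f"U_bead{b}"] = self.potential_beads[:, b]
        cols["K_cv"] = self.kinetic_cv
        cols["K_prim"] = self.kinetic_primitive
        cols["E_spring"] = self.spring
        for b in range(self.n_beads):
            for c, ax in enumerate("xyz"):
                cols[f"M{ax}_bead{b}"] = self.dipoles[:, b, c]
        df = pd.DataFrame(cols)
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservableSeries":
        meta: dict[str, Any] = {}
        path = Path(path)
        with open(path) as fh:
            pos = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                pos += len(line)
                k, _, v = line[1:].partition(":")
                k, v = k.strip(), v.strip()
                try:
                    meta[k] = json.loads(v)
                except (json.JSONDecodeError, ValueError):
                    meta[k] = v
            fh.seek(pos)
            df = pd.read_csv(fh)
        P = int(meta.pop("n_beads"))
        n = len(df)
        dip = np.empty((n, P, 3))
        for b in range(P):
            for c, ax in enumerate("xyz"):
                dip[:, b, c] = df[f"M{ax}_bead{b}"]
        pot = np.column_stack([df[f"U_bead{b}"] for b in range(P)])
        known = {"units", "T_K", "pressure_atm", "n_molecules", "phase", "replica"}
        return cls(
            times=df["time"].to_numpy(), volumes=df["volume"].to_numpy(),
            potential_beads=pot, kinetic_cv=df["K_cv"].to_numpy(),
            kinetic_primitive=df["K_prim"].to_numpy(),
            spring=df["E_spring"].to_numpy(), dipoles=dip,
            T=float(meta["T_K"]), pressure=float(meta["pressure_atm"]),
            n_beads=P, n_molecules=int(meta["n_molecules"]),
            phase=str(meta["phase"]), replica=int(meta["replica"]),
            metadata={k: v for k, v in meta.items() if k not in known},
        )
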