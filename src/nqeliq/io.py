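"""File formats: topology YAML, extended-XYZ trajectories, tables, manifests.

Topology files are a small versioned YAML schema (key–value plus tables of
atoms/bonds/angles); trajectories are extended-XYZ with a ``Lattice=`` box
comment line, written either as centroids or with all beads; tables are
CSV.  Every pipeline output directory carries a JSON run manifest with the
code version, seeds, protocol and input hashes, sufficient to reproduce
any output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import yaml

from . import __version__
from .topology import (
    AngleTerm,
    AtomSpec,
    BondTerm,
    DihedralTerm,
    MolecularTopology,
    TetherTerm,
    TopologyError,
)

SCHEMA = "nqeliq-topology-1"


class SchemaError(ValueError):
    """Raised for malformed topology/config files."""


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def write_topology(topology: MolecularTopology, path: str | Path) -> None:
    doc: dict[str, Any] = {
        "schema": SCHEMA,
        "name": topology.name,
        "scale_14": topology.scale_14,
        "atoms": [
            dict(element=a.element, mass=a.mass, charge=a.charge,
                 sigma=a.sigma, epsilon=a.epsilon, type_label=a.type_label)
            for a in topology.atoms
        ],
        "bonds": [
            {k: v for k, v in asdict(b).items() if v is not None}
            for b in topology.bonds
        ],
        "angles": [asdict(t) for t in topology.angles],
        "dihedrals": [
            dict(i=t.i, j=t.j, k=t.k, l=t.l,
                 coefficients=list(t.coefficients), phases=list(t.phases))
            for t in topology.dihedrals
        ],
        "tethers": [dict(i=t.i, k=t.k, x0=list(t.x0)) for t in topology.tethers],
    }

    def plain(obj):  # numpy scalars → YAML-representable builtins
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(plain(doc), sort_keys=False))


def read_topology(path: str | Path) -> MolecularTopology:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise SchemaError(f"{path}: not valid YAML: {e}") from e
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA:
        raise SchemaError(f"{path}: expected schema {SCHEMA!r}")
    try:
        atoms = [AtomSpec(**a) for a in doc.get("atoms", [])]
    except (TypeError, TopologyError) as e:
        raise SchemaError(f"{path}: atoms table: {e}") from e
    bonds = []
    for n, b in enumerate(doc.get("bonds", [])):
        form = b.get("form", "harmonic")
        if form not in ("harmonic", "morse"):
            raise SchemaError(f"{path}: bond {n}: unknown form tag {form!r}")
        if form == "morse":
            missing = [f_ for f_ in ("D", "a") if f_ not in b]
            if missing:
                raise SchemaError(f"{path}: bond {n}: morse bond missing field(s) {missing}")
        try:
            bonds.append(BondTerm(**b))
        except (TypeError, TopologyError) as e:
            raise SchemaError(f"{path}: bond {n}: {e}") from e
    angles = [AngleTerm(**t) for t in doc.get("angles", [])]
    dihedrals = [
        DihedralTerm(i=t["i"], j=t["j"], k=t["k"], l=t["l"],
                     coefficients=tuple(t.get("coefficients", ())),
                     phases=tuple(t.get("phases", ())))
        for t in doc.get("dihedrals", [])
    ]
    tethers = [TetherTerm(i=t["i"], k=t["k"], x0=tuple(t["x0"]))
               for t in doc.get("tethers", [])]
    return MolecularTopology(
        atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals,
        tethers=tethers, scale_14=float(doc.get("scale_14", 0.5)),
        name=str(doc.get("name", "")),
    )


# ---------------------------------------------------------------------------
# extended-XYZ trajectories
# ---------------------------------------------------------------------------


def write_trajectory(
    path: str | Path,
    frames,
    elements: list[str],
    bead_mode: str = "centroid",
) -> None:
    """Write extended-XYZ frames.

    ``frames`` is an iterable of (positions, box) where positions is (N,3)
    for ``bead_mode='centroid'`` or (P,N,3) for ``'all_beads'`` (beads are
    written consecutively per frame and the bead count recorded in the
    comment line).
    """
    if bead_mode not in ("centroid", "all_beads"):
        raise ValueError("bead_mode must be 'centroid' or 'all_beads'")
    with open(path, "w") as fh:
        for positions, box in frames:
            pos = np.asarray(positions, dtype=float)
            if bead_mode == "centroid":
                if pos.ndim == 3:
                    pos = pos.mean(axis=0)
                coords = pos
                nbeads = 1
            else:
                if pos.ndim == 2:
                    pos = pos[None]
                nbeads = pos.shape[0]
                coords = pos.reshape(-1, 3)
            n = coords.shape[0]
            fh.write(f"{n}\n")
            fh.write(
                f'Lattice="{box} 0.0 0.0 0.0 {box} 0.0 0.0 0.0 {box}" '
                f"Properties=species:S:1:pos:R:3 nbeads={nbeads}\n"
            )
            species = elements * (n // len(elements))
            for el, (x, y, z) in zip(species, coords):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def read_trajectory(path: str | Path, bead_mode: str = "centroid") -> Iterator:
    """Yield (positions, box, elements) per frame from extended-XYZ.

    ``bead_mode='all_beads'`` reshapes each frame to (n_beads, N, 3) using
    the ``nbeads`` comment field; ``'centroid'`` averages beads if present.
    """
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    n_atoms_first = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as e:
            raise SchemaError(f"{path}: line {i+1}: expected atom count") from e
        comment = lines[i + 1]
        box = _parse_lattice(comment, path, i + 2)
        nbeads = 1
        for tok in comment.split():
            if tok.startswith("nbeads="):
                nbeads = int(tok.split("=", 1)[1])
        rows = lines[i + 2 : i + 2 + n]
        if len(rows) < n:
            raise SchemaError(f"{path}: truncated frame at line {i+1}")
        elements = [r.split()[0] for r in rows]
        coords = np.array([[float(v) for v in r.split()[1:4]] for r in rows])
        if n_atoms_first is None:
            n_atoms_first = n
        elif n != n_atoms_first:
            raise SchemaError(
                f"{path}: frame {frame_no} has {n} atoms, first frame had {n_atoms_first}"
            )
        if nbeads > 1:
            coords = coords.reshape(nbeads, n // nbeads, 3)
            elements = elements[: n // nbeads]
            if bead_mode == "centroid":
                coords = coords.mean(axis=0)
        elif bead_mode == "all_beads":
            coords = coords[None]
        yield coords, box, elements
        i += 2 + n
        frame_no += 1


def _parse_lattice(comment: str, path, lineno: int) -> float:
    import re

    m = re.search(r'Lattice="([^"]+)"', comment)
    if not m:
        raise SchemaError(f"{path}: line {lineno}: missing Lattice box entry")
    vals = [float(v) for v in m.group(1).split()]
    return vals[0]


def read_configuration(path: str | Path):
    """Read a single configuration (positions, box, elements).

    extended-XYZ natively; PDB via MDAnalysis.
    """
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        box = float(u.dimensions[0]) if u.dimensions is not None else 0.0
        return u.atoms.positions.astype(float), box, [a.element if a.element else a.name[0] for a in u.atoms]
    return next(iter(read_trajectory(path)))


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance for a pipeline run; referenced by every output file."""

    code_version: str = __version__
    seed: int = 0
    unit_system: str = "kJ/mol, Angstrom, ps, K, e, g/mol"
    protocol: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    notes: str = "real-space shifted-force electrostatics (no reciprocal-space mesh)"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
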