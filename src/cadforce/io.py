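"""File formats: PDB structures, multi-frame XYZ trajectories, force-curve
and event tables (TSV), ground-truth sidecars and reports (JSON).

PDB parsing is delegated to biotite (first-listed altloc; insertion codes
are rejected because the package uses plain integer residue numbering);
multi-frame XYZ reading is delegated to MDAnalysis.  Curve TSVs carry the
columns ``index, piezo_nm, force_pN, segment`` plus ``#``-prefixed header
metadata for the calibration values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .force_spectroscopy import ForceCurve
from .structures import Structure, Trajectory

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_xyz_traj",
    "write_xyz_traj",
    "read_curve_tsv",
    "write_curve_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "write_report",
    "read_report",
]

CURVE_COLUMNS = ("index", "piezo_nm", "force_pN", "segment")


def read_pdb(path: str | Path, model: int = 1) -> Structure:
    """Read a PDB file (ATOM/HETATM records) into a :class:`Structure`.

    Uses the first-listed altloc; files with insertion codes are rejected
    with a message, since residue numbering here is plain integers.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="first", extra_fields=[])
    try:
        ins = atoms.ins_code
        if np.any(ins != ""):
            raise ValueError(
                f"{path}: insertion codes present; renumber residues first"
            )
    except AttributeError:
        pass
    return Structure(
        element=atoms.element,
        atom_name=atoms.atom_name,
        res_name=atoms.res_name,
        res_id=atoms.res_id,
        chain_id=atoms.chain_id,
        coords=atoms.coord,
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a single-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = struc.AtomArray(structure.n_atoms)
    atoms.coord = structure.coords
    atoms.element = structure.element
    atoms.atom_name = structure.atom_name
    atoms.res_name = structure.res_name
    atoms.res_id = structure.res_id
    atoms.chain_id = structure.chain_id
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_xyz_traj(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-frame XYZ (atom names, Å coordinates)."""
    names = traj.topology.element
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(f"frame {f} t={f * traj.timestep:.6g} ps\n")
            for name, (x, y, z) in zip(names, traj.frames[f]):
                fh.write(f"{name or 'X'} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_traj(
    path: str | Path, topology: Structure, timestep: float = 1.0
) -> Trajectory:
    """Read a multi-frame XYZ file against a known topology.

    The XYZ file supplies only coordinates; atom metadata (residues, chains,
    radii) comes from ``topology``.  A frame whose atom count differs from
    the topology is an error naming both counts.
    """
    import MDAnalysis as mda

    universe = mda.Universe(str(path), format="XYZ")
    n_file = len(universe.atoms)
    if n_file != topology.n_atoms:
        raise ValueError(
            f"{path}: XYZ frames have {n_file} atoms but topology has "
            f"{topology.n_atoms}"
        )
    frames = np.array([ts.positions.copy() for ts in universe.trajectory])
    return Trajectory(topology=topology, frames=frames, timestep=timestep)


def write_curve_tsv(curve: ForceCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spring_constant_pN_per_nm\t{curve.spring_constant!r}\n")
        fh.write(f"# velocity_um_per_s\t{curve.velocity!r}\n")
        fh.write(f"# temperature_K\t{curve.temperature!r}\n")
        fh.write("\t".join(CURVE_COLUMNS) + "\n")
        for i, (z, f, seg) in enumerate(
            zip(curve.piezo_position, curve.force, curve.segment_labels)
        ):
            fh.write(f"{i}\t{z:.6f}\t{f:.6f}\t{seg}\n")


def read_curve_tsv(path: str | Path) -> ForceCurve:
    """Read one force curve from TSV; errors name missing columns."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("\t")
            try:
                meta[key.strip()] = float(value)
            except ValueError:
                raise ValueError(f"{path}:{i + 1}: malformed metadata line")
            body_start = i + 1
        else:
            break
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    for col in CURVE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return ForceCurve(
        piezo_position=table["piezo_nm"].to_numpy(),
        force=table["force_pN"].to_numpy(),
        segment_labels=table["segment"].to_numpy(dtype="U8"),
        spring_constant=meta.get("spring_constant_pN_per_nm", 1.0),
        velocity=meta.get("velocity_um_per_s", 1.0),
        temperature=meta.get("temperature_K", 298.0),
    )


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
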