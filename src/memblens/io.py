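"""Coordinate and trajectory I/O through MDAnalysis.

Supported formats: GRO and PDB for single frames, XTC/DCD (or multi-model
PDB) for trajectories.  Internally everything is nm and ns; PDB files are
Angstrom at the boundary.  Only orthorhombic boxes are accepted — triclinic
cells would silently break the 2D minimum-image neighbor search.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

import MDAnalysis as mda

from .frames import BilayerFrame, FrameError, Trajectory
from .topology import PHOSPHOLIPID, RESNAME_MAP, RESNAME_UNMAP, TopologySpec

__all__ = [
    "read_frames",
    "write_frame",
    "write_trajectory",
    "ConsistencyError",
    "UnsupportedGeometryError",
]

NM_PER_ANG = 0.1
COORD_FORMATS = {".gro": "GRO", ".pdb": "PDB"}
TRAJ_FORMATS = {".xtc", ".dcd", ".pdb"}


class ConsistencyError(ValueError):
    """File contents disagree with the topology."""


class UnsupportedGeometryError(ValueError):
    """Non-orthorhombic simulation cell."""


def _to_universe(frames: Sequence[BilayerFrame]) -> mda.Universe:
    f0 = frames[0]
    rids, ridx = np.unique(f0.residue_id, return_inverse=True)
    n_res = len(rids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            f0.n_atoms,
            n_residues=n_res,
            atom_resindex=ridx,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(n) for n in f0.atom_name])
        first = np.sort(np.unique(f0.residue_id, return_index=True)[1])
        resnames = [RESNAME_MAP.get(str(s), str(s)) for s in f0.species[first]]
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.atoms.positions = f0.coords / NM_PER_ANG
    u.dimensions = np.array([*(f0.box / NM_PER_ANG), 90.0, 90.0, 90.0])
    return u


def write_frame(frame: BilayerFrame, path: str | Path, format: str | None = None) -> None:
    """Write one frame as GRO (nm) or PDB (Angstrom, CRYST1 box)."""
    path = Path(path)
    fmt = (format or COORD_FORMATS.get(path.suffix.lower(), "")).upper()
    if fmt not in ("GRO", "PDB"):
        raise ValueError(f"unsupported coordinate format {format or path.suffix!r}")
    u = _to_universe([frame])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=u.atoms.n_atoms, format=fmt) as w:
            w.write(u.atoms)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as XTC, DCD or multi-model PDB (by extension)."""
    path = Path(path)
    if path.suffix.lower() not in TRAJ_FORMATS:
        raise ValueError(f"unsupported trajectory format {path.suffix!r}")
    u = _to_universe(traj.frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
            for i, frame in enumerate(traj.frames):
                u.atoms.positions = frame.coords / NM_PER_ANG
                u.dimensions = np.array([*(frame.box / NM_PER_ANG), 90.0, 90.0, 90.0])
                u.trajectory.ts.time = (
                    (frame.time if frame.time is not None else float(i)) * 1000.0
                )  # ps
                u.trajectory.ts.frame = i
                w.write(u.atoms)


def _check_orthorhombic(dims: np.ndarray | None, where: str) -> np.ndarray:
    if dims is None or not np.all(dims[:3] > 0):
        raise FrameError(f"{where}: missing or invalid box")
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise UnsupportedGeometryError(
            f"{where}: triclinic box (angles {dims[3:]}) is not supported"
        )
    return np.asarray(dims[:3], dtype=np.float64) * NM_PER_ANG


def _validate_against_topology(frame: BilayerFrame, topology: TopologySpec) -> None:
    rids, first = np.unique(frame.residue_id, return_index=True)
    for rid, i in zip(rids, first):
        sp = str(frame.species[i])
        if sp not in topology:
            continue
        entry = topology[sp]
        names = set(frame.atom_name[frame.residue_id == rid])
        required: set[str] = set()
        if entry.role == PHOSPHOLIPID:
            required.add(entry.phosphate_atom)  # type: ignore[arg-type]
            for chain in entry.chain_atoms:
                required.update(chain)
        else:
            required.add(entry.sterol_ref_atom)  # type: ignore[arg-type]
            required.update(entry.sterol_axis_atoms)  # type: ignore[arg-type]
        missing = required - names
        if missing:
            raise ConsistencyError(
                f"residue {rid} ({sp}): missing atoms {sorted(missing)}"
            )


def read_frames(
    coord_path: str | Path,
    traj_path: str | Path | None = None,
    topology: TopologySpec | None = None,
) -> Trajectory:
    """Read a coordinate file (plus optional trajectory) into a Trajectory.

    Coordinates are converted to nm and wrapped into [0, box); residue
    (species) names are mapped back from their file spelling.  When a
    topology is given, every residue of a known species is checked for its
    required reference atoms.
    """
    coord_path = Path(coord_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if traj_path is not None:
            u = mda.Universe(str(coord_path), str(traj_path))
        else:
            u = mda.Universe(str(coord_path))
    species = np.array(
        [RESNAME_UNMAP.get(rn, rn) for rn in u.atoms.resnames], dtype=object
    )
    names = np.array([str(n) for n in u.atoms.names], dtype=object)
    rid = u.atoms.resindices + 1
    frames: list[BilayerFrame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            box = _check_orthorhombic(ts.dimensions, str(coord_path))
            coords = ts.positions.astype(np.float64) * NM_PER_ANG
            frame = BilayerFrame(
                coords=coords,
                box=box,
                residue_id=rid.copy(),
                species=species,
                atom_name=names,
                time=float(ts.time) / 1000.0 if ts.time is not None else None,  # ps->ns
            ).wrap()
            frames.append(frame)
    traj = Trajectory(frames)
    if topology is not None:
        _validate_against_topology(traj[0], topology)
    return traj
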