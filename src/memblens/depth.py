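"""Sterol insertion depth, reference-atom density profiles, sterol tilt.

Depth convention: Δz = mean(sterol reference-carbon z) − mean(phosphate z of
the same leaflet), with lower-leaflet values z-mirrored so that *negative*
always means buried toward the bilayer center.  Density profiles are number
densities of named reference atoms along z, measured relative to the
per-frame phosphate midplane.  Sterol tilt is the angle between the headward
ring axis (head atom − tail atom) and the outward leaflet normal, folded
into [0°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import (
    LOWER,
    UPPER,
    BilayerFrame,
    Trajectory,
    assign_leaflets,
)
from .blocking import blocking_se, naive_se
from .topology import PHOSPHOLIPID, STEROL, TopologyError, TopologySpec

__all__ = [
    "DepthResult",
    "TiltResult",
    "DensityProfile",
    "sterol_depth",
    "density_profile",
    "sterol_tilt",
]


def _se(series: np.ndarray) -> float:
    series = np.asarray(series, dtype=np.float64)
    if len(series) >= 8:
        return blocking_se(series).se
    return naive_se(series)


@dataclass(frozen=True)
class DepthResult:
    """Signed insertion depth Δz (nm) per leaflet and pooled."""

    species: str
    delta_z_nm: float  # pooled over leaflets and frames
    se_nm: float  # blocking SE of the per-frame pooled series
    per_leaflet_nm: dict[str, float]  # leaflets without sterols are absent
    n_frames: int


@dataclass(frozen=True)
class TiltResult:
    """Sterol ring-axis tilt distribution."""

    species: str
    mean_tilt_deg: float
    se_deg: float  # blocking SE of per-frame means
    bin_centers_deg: np.ndarray
    density_per_deg: np.ndarray  # integrates to 1 over [0, 90]
    n_samples: int


@dataclass(frozen=True)
class DensityProfile:
    """Number density (atoms/nm^3) vs z relative to the phosphate midplane."""

    bin_centers_nm: np.ndarray
    density: dict[str, np.ndarray]  # per atom class
    bin_width_nm: float
    area_nm2: float
    n_frames: int

    def integral(self, atom_class: str) -> float:
        """Mean atom count per frame represented by the profile."""
        return float(
            self.density[atom_class].sum() * self.bin_width_nm * self.area_nm2
        )


def _as_traj(traj: Trajectory | BilayerFrame) -> Trajectory:
    return Trajectory([traj]) if isinstance(traj, BilayerFrame) else traj


def _leaflet_mean_z(
    frame: BilayerFrame, rids: np.ndarray, z: np.ndarray, leaflets, which: str
) -> float | None:
    mask = np.array([leaflets[int(r)] == which for r in rids])
    if not mask.any():
        return None
    return float(z[mask].mean())


def sterol_depth(
    traj: Trajectory | BilayerFrame, topology: TopologySpec, species: str
) -> DepthResult:
    """Time-averaged sterol insertion depth with blocking error."""
    traj = _as_traj(traj)
    entry = topology[species]
    if entry.role != STEROL:
        raise TopologyError(f"{species} is not a sterol")
    ref = entry.sterol_ref_atom
    per_frame: list[float] = []
    per_leaflet_acc: dict[str, list[float]] = {UPPER: [], LOWER: []}
    for frame in traj:
        leaflets = assign_leaflets(frame, topology)
        vals = []
        for which, sign in ((UPPER, 1.0), (LOWER, -1.0)):
            phos_z = []
            for sp in topology.phospholipids():
                m = frame.select(species=sp, atom_name=topology[sp].phosphate_atom)
                if m.any():
                    zm = _leaflet_mean_z(
                        frame, frame.residue_id[m], frame.coords[m, 2], leaflets, which
                    )
                    if zm is not None:
                        phos_z.append(
                            (zm, int(m.sum()))
                        )
            if not phos_z:
                continue
            # count-weighted mean over species = plain mean over phosphates
            tot = sum(n for _, n in phos_z)
            phos_mean = sum(z * n for z, n in phos_z) / tot
            m = frame.select(species=species, atom_name=ref)
            if not m.any():
                continue
            zm = _leaflet_mean_z(
                frame, frame.residue_id[m], frame.coords[m, 2], leaflets, which
            )
            if zm is None:
                continue
            dz = sign * (zm - phos_mean)  # mirror the lower leaflet
            per_leaflet_acc[which].append(dz)
            vals.append(dz)
        if vals:
            per_frame.append(float(np.mean(vals)))
    if not per_frame:
        raise TopologyError(f"no {species} sterols found in any leaflet")
    per_leaflet = {
        which: float(np.mean(v)) for which, v in per_leaflet_acc.items() if v
    }
    series = np.array(per_frame)
    return DepthResult(
        species=species,
        delta_z_nm=float(series.mean()),
        se_nm=_se(series),
        per_leaflet_nm=per_leaflet,
        n_frames=len(traj),
    )


def _parse_atom_class(cls: str) -> tuple[str | None, str]:
    """"P" matches any species; "CHOL:C3" restricts to one species."""
    if ":" in cls:
        sp, name = cls.split(":", 1)
        return sp, name
    return None, cls


def density_profile(
    traj: Trajectory | BilayerFrame,
    topology: TopologySpec,
    atom_classes: list[str],
    bin_width_nm: float = 0.1,
) -> DensityProfile:
    """Histogram reference atoms along z relative to the phosphate midplane."""
    traj = _as_traj(traj)
    if bin_width_nm <= 0:
        raise ValueError("bin width must be > 0")
    box = traj[0].box
    if bin_width_nm > box[2]:
        raise ValueError("bin width exceeds the box height")
    half = box[2] / 2.0
    edges = np.arange(-half, half + bin_width_nm, bin_width_nm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = float(box[0] * box[1])
    counts = {cls: np.zeros(len(centers)) for cls in atom_classes}
    for frame in traj:
        phos = []
        for sp in topology.phospholipids():
            m = frame.select(species=sp, atom_name=topology[sp].phosphate_atom)
            if m.any():
                phos.append(frame.coords[m, 2])
        if not phos:
            raise TopologyError("no phosphates: cannot define the midplane")
        mid = float(np.concatenate(phos).mean())
        for cls in atom_classes:
            sp, name = _parse_atom_class(cls)
            m = frame.select(species=sp, atom_name=name)
            if not m.any():
                continue
            z = frame.coords[m, 2] - mid
            h, _ = np.histogram(z, bins=edges)
            counts[cls] += h
    n = len(traj)
    density = {cls: c / (area * bin_width_nm * n) for cls, c in counts.items()}
    return DensityProfile(
        bin_centers_nm=centers,
        density=density,
        bin_width_nm=bin_width_nm,
        area_nm2=area,
        n_frames=n,
    )


def sterol_tilt(
    traj: Trajectory | BilayerFrame,
    topology: TopologySpec,
    species: str,
    bin_width_deg: float = 2.0,
) -> TiltResult:
    """Distribution of the sterol ring-axis tilt angle."""
    traj = _as_traj(traj)
    entry = topology[species]
    if entry.role != STEROL:
        raise TopologyError(f"{species} is not a sterol")
    head_name, tail_name = entry.sterol_axis_atoms  # type: ignore[misc]
    angles_all: list[np.ndarray] = []
    frame_means: list[float] = []
    for frame in traj:
        leaflets = assign_leaflets(frame, topology)
        mh = frame.select(species=species, atom_name=head_name)
        mt = frame.select(species=species, atom_name=tail_name)
        if not mh.any():
            raise TopologyError(f"species {species!r} absent from frame")
        rh, rt = frame.residue_id[mh], frame.residue_id[mt]
        oh, ot = np.argsort(rh), np.argsort(rt)
        axis = frame.coords[mh][oh] - frame.coords[mt][ot]  # headward
        norms = np.linalg.norm(axis, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"{species}: coincident axis atoms")
        rids = np.asarray(rh)[oh]
        outward = np.array(
            [1.0 if leaflets[int(r)] == UPPER else -1.0 for r in rids]
        )
        cos_t = axis[:, 2] * outward / norms
        theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        theta = np.where(theta > 90.0, 180.0 - theta, theta)  # fold
        angles_all.append(theta)
        frame_means.append(float(theta.mean()))
    angles = np.concatenate(angles_all)
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    hist, _ = np.histogram(angles, bins=edges, density=True)
    return TiltResult(
        species=species,
        mean_tilt_deg=float(angles.mean()),
        se_deg=_se(np.array(frame_means)),
        bin_centers_deg=0.5 * (edges[:-1] + edges[1:]),
        density_per_deg=hist,
        n_samples=len(angles),
    )
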