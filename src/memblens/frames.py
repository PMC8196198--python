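"""In-memory frame model and leaflet assignment.

Coordinates are in nm throughout, the z-axis is the bilayer normal, and boxes
are orthorhombic.  A :class:`BilayerFrame` is a flat atom table (coordinates
plus residue id / species / atom name per atom); a :class:`Trajectory` is an
ordered list of frames sharing one topology.

Leaflets are assigned per frame from phosphate positions: the midplane is the
mean phosphate z over all phospholipids, phospholipids go by their phosphate z,
sterols by their reference carbon z.  Atoms exactly on the midplane are
assigned to the upper leaflet (deterministic tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .topology import PHOSPHOLIPID, TopologySpec

__all__ = [
    "BilayerFrame",
    "Trajectory",
    "LeafletMap",
    "FrameError",
    "DegenerateBilayerError",
    "assign_leaflets",
    "minimum_image",
]

UPPER = "upper"
LOWER = "lower"


class FrameError(ValueError):
    """Invalid frame contents."""


class DegenerateBilayerError(FrameError):
    """All phosphates on one side of the midplane: not a bilayer."""


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the nearest periodic image."""
    return disp - box * np.round(disp / box)


@dataclass
class BilayerFrame:
    """One time point: coordinates (nm) plus per-atom metadata."""

    coords: np.ndarray  # (n_atoms, 3) float64, nm
    box: np.ndarray  # (3,) float64, nm
    residue_id: np.ndarray  # (n_atoms,) int
    species: np.ndarray  # (n_atoms,) str
    atom_name: np.ndarray  # (n_atoms,) str
    time: float | None = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.residue_id = np.asarray(self.residue_id)
        self.species = np.asarray(self.species, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        n = len(self.coords)
        if n == 0:
            raise FrameError("frame has no atoms")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise FrameError("coordinates must be a finite (n, 3) array")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise FrameError("box must be three positive edge lengths")
        for arr, what in (
            (self.residue_id, "residue_id"),
            (self.species, "species"),
            (self.atom_name, "atom_name"),
        ):
            if len(arr) != n:
                raise FrameError(f"{what} length {len(arr)} != n_atoms {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, species: str | None = None, atom_name: str | None = None) -> np.ndarray:
        """Boolean mask over atoms matching the given species/atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if species is not None:
            mask &= self.species == species
        if atom_name is not None:
            mask &= self.atom_name == atom_name
        return mask

    def residues(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique residue ids in first-appearance order with their species."""
        _, first = np.unique(self.residue_id, return_index=True)
        first = np.sort(first)
        return self.residue_id[first], self.species[first]

    def wrap(self) -> "BilayerFrame":
        """Return a copy with coordinates wrapped into [0, box)."""
        coords = np.mod(self.coords, self.box)
        return BilayerFrame(
            coords, self.box.copy(), self.residue_id, self.species, self.atom_name, self.time
        )


@dataclass
class Trajectory:
    """Ordered frames sharing atom order and topology."""

    frames: list[BilayerFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise FrameError("trajectory has no frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[BilayerFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> BilayerFrame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array(
            [f.time if f.time is not None else float(i) for i, f in enumerate(self.frames)]
        )


@dataclass(frozen=True)
class LeafletMap:
    """residue id -> leaflet label, plus the midplane used."""

    leaflet: Mapping[int, str]
    midplane_z: float

    def residues(self, which: str) -> np.ndarray:
        return np.array([r for r, l in self.leaflet.items() if l == which])

    def __getitem__(self, residue: int) -> str:
        return self.leaflet[residue]


def assign_leaflets(frame: BilayerFrame, topology: TopologySpec) -> LeafletMap:
    """Assign every lipid residue to the upper or lower leaflet.

    The midplane is the mean phosphate z over all phospholipids in the frame.
    Phospholipids with phosphate z >= midplane are "upper", otherwise "lower";
    sterols are assigned the same way using their reference carbon.  Raises
    :class:`DegenerateBilayerError` when all phosphates fall on one side.
    """
    phos_z: list[float] = []
    ref_z: dict[int, float] = {}
    rid_arr = frame.residue_id
    for sp in set(frame.species):
        if sp not in topology:
            continue
        ref = topology.reference_atom(sp)
        mask = frame.select(species=sp, atom_name=ref)
        if not mask.any():
            continue
        zs = frame.coords[mask, 2]
        rids = rid_arr[mask]
        for r, z in zip(rids, zs):
            ref_z[int(r)] = float(z)
        if topology[sp].role == PHOSPHOLIPID:
            phos_z.extend(zs)
    if len(phos_z) < 2:
        raise DegenerateBilayerError("need at least two phospholipid phosphates")
    midplane = float(np.mean(phos_z))
    if all(z >= midplane for z in phos_z) or all(z < midplane for z in phos_z):
        raise DegenerateBilayerError("all phosphates on one side of the midplane")
    leaflet = {r: (UPPER if z >= midplane else LOWER) for r, z in ref_z.items()}
    return LeafletMap(leaflet=leaflet, midplane_z=midplane)
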