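"""Lateral segregation: DPPC-neighbor fraction around a center species.

For every lipid of the center species, neighbors are the *phospholipids* of
the same leaflet whose reference atoms (phosphates; sterol reference carbons
for sterol centers) lie within a lateral cutoff under the 2D minimum-image
convention.  The per-lipid statistic is the fraction of DPPC among those
phospholipid neighbors (sterols never enter the denominator); the per-frame
value is the mean over center lipids with at least one phospholipid neighbor.
Reference levels from patch-forming DPPC/DLiPC systems: ~0.9 marks complete
segregation, 0.4 random mixing at a 2:3 DPPC/DLiPC composition.

Time series are summarized by the mean over the last quarter of frames (the
tail) with a blocking-method standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import BilayerFrame, LeafletMap, Trajectory, assign_leaflets
from .blocking import blocking_se, naive_se
from .topology import PHOSPHOLIPID, TopologySpec

__all__ = [
    "NeighborParams",
    "FrameFraction",
    "SegregationSeries",
    "neighbor_fraction",
    "segregation_series",
]

REF_SEGREGATED = 0.9
REF_RANDOM = 0.4


@dataclass(frozen=True)
class NeighborParams:
    """Lateral neighbor criterion."""

    cutoff_nm: float = 1.0
    member_species: str = "DPPC"  # the species counted in the numerator
    same_leaflet_only: bool = True

    def validate(self, box: np.ndarray) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be > 0")
        if self.cutoff_nm >= min(box[0], box[1]) / 2.0:
            raise ValueError(
                f"cutoff {self.cutoff_nm} nm >= half the smallest lateral box "
                f"edge; minimum-image distances would be ambiguous"
            )


@dataclass(frozen=True)
class FrameFraction:
    fraction: float  # mean over contributing centers; nan if none contribute
    per_center: dict[int, float]  # residue id -> fraction
    excluded_centers: int  # centers with zero phospholipid neighbors


def _reference_positions(
    frame: BilayerFrame, topology: TopologySpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """xy positions, residue ids, species and is-phospholipid mask of all
    reference atoms present in the frame."""
    xy: list[np.ndarray] = []
    rids: list[np.ndarray] = []
    species: list[np.ndarray] = []
    is_pl: list[np.ndarray] = []
    for sp in topology.species:
        mask = frame.select(species=sp, atom_name=topology.reference_atom(sp))
        if not mask.any():
            continue
        xy.append(frame.coords[mask, :2])
        rids.append(frame.residue_id[mask])
        species.append(frame.species[mask])
        is_pl.append(
            np.full(int(mask.sum()), topology[sp].role == PHOSPHOLIPID)
        )
    if not xy:
        raise ValueError("no reference atoms found")
    return (
        np.concatenate(xy),
        np.concatenate(rids),
        np.concatenate(species),
        np.concatenate(is_pl),
    )


def neighbor_fraction(
    frame: BilayerFrame,
    leaflets: LeafletMap,
    topology: TopologySpec,
    center_species: str,
    params: NeighborParams | None = None,
) -> FrameFraction:
    """Fraction of member-species neighbors among PL neighbors per center."""
    params = params or NeighborParams()
    params.validate(frame.box)
    if not frame.select(species=center_species).any():
        raise ValueError(f"center species {center_species!r} absent from frame")
    xy, rids, species, is_pl = _reference_positions(frame, topology)
    leaf = np.array([leaflets[int(r)] for r in rids])
    boxxy = frame.box[:2]
    per_center: dict[int, float] = {}
    excluded = 0
    for which in np.unique(leaf) if params.same_leaflet_only else ["all"]:
        sel = leaf == which if params.same_leaflet_only else np.ones(len(xy), bool)
        pts = np.mod(xy[sel], boxxy)
        tree = cKDTree(pts, boxsize=boxxy)
        pairs = tree.query_pairs(params.cutoff_nm, output_type="ndarray")
        n_local = len(pts)
        sp_l = species[sel]
        rid_l = rids[sel]
        pl_l = is_pl[sel]
        n_pl = np.zeros(n_local, dtype=int)
        n_member = np.zeros(n_local, dtype=int)
        for a, b in pairs:
            if pl_l[b]:
                n_pl[a] += 1
                n_member[a] += sp_l[b] == params.member_species
            if pl_l[a]:
                n_pl[b] += 1
                n_member[b] += sp_l[a] == params.member_species
        centers = np.where(sp_l == center_species)[0]
        for c in centers:
            if n_pl[c] == 0:
                excluded += 1
                continue
            per_center[int(rid_l[c])] = n_member[c] / n_pl[c]
    fraction = (
        float(np.mean(list(per_center.values()))) if per_center else float("nan")
    )
    return FrameFraction(
        fraction=fraction, per_center=per_center, excluded_centers=excluded
    )


@dataclass(frozen=True)
class SegregationSeries:
    """Neighbor-fraction time series with tail statistics."""

    times_ns: np.ndarray
    f_t: np.ndarray
    center_species: str
    tail_mean: float
    tail_se: float
    tail_fraction: float
    excluded_centers: int  # summed over frames
    ref_segregated: float = REF_SEGREGATED
    ref_random: float = REF_RANDOM
    params: NeighborParams = field(default_factory=NeighborParams)


def segregation_series(
    traj: Trajectory,
    topology: TopologySpec,
    center_species: str,
    params: NeighborParams | None = None,
    tail_fraction: float = 0.25,
) -> SegregationSeries:
    """Per-frame neighbor fractions, tail mean and blocking SE.

    Leaflets are reassigned every frame.  The tail covers the last
    ceil(tail_fraction * n_frames) frames; its SE comes from the blocking
    method (naive SE for tails shorter than 8 frames).
    """
    if len(traj) < 4:
        raise ValueError("need at least 4 frames for a meaningful tail")
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must be in (0, 1]")
    params = params or NeighborParams()
    f_t = np.empty(len(traj))
    excluded = 0
    for i, frame in enumerate(traj):
        leaflets = assign_leaflets(frame, topology)
        ff = neighbor_fraction(frame, leaflets, topology, center_species, params)
        f_t[i] = ff.fraction
        excluded += ff.excluded_centers
    n_tail = math.ceil(tail_fraction * len(traj))
    tail = f_t[-n_tail:]
    if np.ptp(tail) == 0.0:
        se = 0.0
    elif len(tail) >= 8:
        se = blocking_se(tail).se
    else:
        se = naive_se(tail)
    return SegregationSeries(
        times_ns=traj.times,
        f_t=f_t,
        center_species=center_species,
        tail_mean=float(np.nanmean(tail)),
        tail_se=se,
        tail_fraction=tail_fraction,
        excluded_centers=excluded,
        params=params,
    )
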