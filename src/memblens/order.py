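"""Leaflet-tilt-referenced acyl-chain order parameters.

The order parameter of a chain segment is the second Legendre polynomial
S = (3 cos^2(alpha) - 1) / 2, where alpha is the angle between the segment
vector (carbon i to carbon i+2, "every second carbon") and the *average
leaflet tilt*: the normalized average, over all phospholipid chains of a
leaflet, of the vector from the first to the last chain carbon.  S = 1 for
segments parallel to the tilt, -0.5 perpendicular, 0 isotropic.  A bilayer
with aggregate S above a threshold (default 0.7, strict) is classified as
ordered, otherwise disordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import (
    UPPER,
    BilayerFrame,
    LeafletMap,
    Trajectory,
    assign_leaflets,
    minimum_image,
)
from .topology import PHOSPHOLIPID, TopologyError, TopologySpec

__all__ = [
    "OrderResult",
    "second_legendre",
    "segment_order",
    "leaflet_tilt",
    "compute_order",
    "classify_phase",
]

DEFAULT_THRESHOLD = 0.7


class SelectionError(ValueError):
    """Requested species/atoms not present."""


class DegenerateTiltError(ValueError):
    """Chain vectors cancel; no average tilt direction exists."""


def second_legendre(cos_alpha: np.ndarray | float) -> np.ndarray | float:
    """P2(cos alpha) = (3 cos^2 alpha - 1) / 2."""
    c = np.asarray(cos_alpha)
    out = 0.5 * (3.0 * c * c - 1.0)
    return float(out) if out.ndim == 0 else out


def segment_order(segments: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """P2 of the angle between each segment vector and a reference axis.

    ``segments``: (n, 3) vectors (need not be normalized); ``axis``: (3,)
    reference direction.  Orientation signs cancel (cos^2).
    """
    segments = np.asarray(segments, dtype=np.float64)
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    norms = np.linalg.norm(segments, axis=-1)
    if np.any(norms == 0):
        raise ValueError("zero-length segment vector")
    cos_a = segments @ axis / norms
    return second_legendre(np.clip(cos_a, -1.0, 1.0))


@dataclass(frozen=True)
class OrderResult:
    """Per-segment / per-lipid order parameters and the phase call."""

    per_segment_S: np.ndarray  # (n_lipids, n_segments), frame-averaged
    per_lipid_S: np.ndarray  # (n_lipids,)
    lipid_ids: np.ndarray  # residue ids matching the rows
    aggregate_S: dict[str, float]  # {"median": ..., "mean": ...}
    statistic: str
    phase: str
    phase_threshold: float
    leaflet_tilt_deg: dict[str, float]  # mean over frames per leaflet
    n_frames_used: int

    @property
    def S(self) -> float:
        return self.aggregate_S[self.statistic]


def classify_phase(aggregate_S: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """"ordered" iff S strictly exceeds the threshold; S = threshold is disordered."""
    if not (-0.5 - 1e-12 <= aggregate_S <= 1.0 + 1e-12):
        raise ValueError(f"order parameter {aggregate_S} outside [-0.5, 1]")
    return "ordered" if aggregate_S > threshold else "disordered"


def _chain_vectors(
    frame: BilayerFrame, topology: TopologySpec, species_filter: set[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    """First->last carbon vector of every phospholipid chain (min. image).

    Returns (vectors (n_chains, 3), residue id per chain).
    """
    vecs: list[np.ndarray] = []
    rids: list[np.ndarray] = []
    for sp in topology.phospholipids():
        if species_filter is not None and sp not in species_filter:
            continue
        entry = topology[sp]
        for chain in entry.chain_atoms:
            first = frame.select(species=sp, atom_name=chain[0])
            last = frame.select(species=sp, atom_name=chain[-1])
            if not first.any():
                continue
            r_first = frame.residue_id[first]
            r_last = frame.residue_id[last]
            order_f, order_l = np.argsort(r_first), np.argsort(r_last)
            d = minimum_image(
                frame.coords[last][order_l] - frame.coords[first][order_f], frame.box
            )
            vecs.append(d)
            rids.append(np.asarray(r_first)[order_f])
    if not vecs:
        raise SelectionError("no phospholipid chains found for tilt computation")
    return np.concatenate(vecs), np.concatenate(rids)


def leaflet_tilt(
    frame: BilayerFrame,
    leaflets: LeafletMap,
    topology: TopologySpec,
    species_filter: set[str] | None = None,
) -> dict[str, tuple[np.ndarray, float]]:
    """Average tilt vector and angle (degrees) per leaflet.

    Chain vectors are normalized, oriented to point along the leaflet's
    inward normal, and averaged; the tilt angle is measured between the
    normalized average and the inward normal.
    """
    vecs, rids = _chain_vectors(frame, topology, species_filter)
    labels = np.array([leaflets[int(r)] for r in rids])
    out: dict[str, tuple[np.ndarray, float]] = {}
    for leaf in (UPPER, "lower"):
        mask = labels == leaf
        if not mask.any():
            continue
        v = vecs[mask]
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        inward = np.array([0.0, 0.0, -1.0 if leaf == UPPER else 1.0])
        sign = np.where(v @ inward >= 0, 1.0, -1.0)
        mean = (v * sign[:, None]).mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm < 1e-12:
            raise DegenerateTiltError(f"{leaf} leaflet: chain vectors cancel")
        mean /= norm
        angle = float(np.degrees(np.arccos(np.clip(mean @ inward, -1.0, 1.0))))
        out[leaf] = (mean, angle)
    return out


def _segments_for_chain(
    coords: np.ndarray, box: np.ndarray, stride2_only: bool
) -> np.ndarray:
    """Second-carbon segment vectors of one chain, (n_segments, 3)."""
    d = minimum_image(coords[2:] - coords[:-2], box)
    return d[::2] if stride2_only else d


def compute_order(
    traj: Trajectory | BilayerFrame,
    topology: TopologySpec,
    species: str,
    statistic: str = "median",
    phase_threshold: float = DEFAULT_THRESHOLD,
    stride2_only: bool = False,
    tilt_species_filter: set[str] | None = None,
) -> OrderResult:
    """Chain order parameters of ``species`` over a trajectory.

    For every frame, leaflets and the per-leaflet average tilt are recomputed;
    every second-carbon segment of both acyl chains contributes
    P2(cos alpha) against the same-frame tilt of its leaflet.  Per-segment
    values are averaged over frames, per-lipid values over a lipid's pooled
    segments, and the aggregate is the requested statistic (default median)
    across lipids.  ``stride2_only`` restricts segments to non-overlapping
    stride-2 endpoints (C1->C3, C3->C5, ...).
    """
    if isinstance(traj, BilayerFrame):
        traj = Trajectory([traj])
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    entry = topology[species]
    if entry.role != PHOSPHOLIPID:
        raise TopologyError(f"{species} is not a phospholipid")
    if min(len(c) for c in entry.chain_atoms) < 3:
        raise TopologyError(f"{species}: chains too short for segments")

    acc: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    tilt_deg_sums = {"upper": 0.0, "lower": 0.0}
    tilt_counts = {"upper": 0, "lower": 0}

    for frame in traj:
        if not frame.select(species=species).any():
            raise SelectionError(f"species {species!r} absent from frame")
        leaflets = assign_leaflets(frame, topology)
        tilts = leaflet_tilt(frame, leaflets, topology, tilt_species_filter)
        for leaf, (_, ang) in tilts.items():
            tilt_deg_sums[leaf] += ang
            tilt_counts[leaf] += 1
        # gather per-lipid chain coordinates
        mask = frame.select(species=species)
        rid_atoms = frame.residue_id[mask]
        name_atoms = frame.atom_name[mask]
        coords_atoms = frame.coords[mask]
        for rid in np.unique(rid_atoms):
            sel = rid_atoms == rid
            names = {str(n): k for k, n in enumerate(name_atoms[sel])}
            cxyz = coords_atoms[sel]
            seg_vals: list[np.ndarray] = []
            for chain in entry.chain_atoms:
                idx = [names[a] for a in chain if a in names]
                if len(idx) != len(chain):
                    raise TopologyError(
                        f"residue {rid} ({species}): incomplete chain atoms"
                    )
                segs = _segments_for_chain(cxyz[idx], frame.box, stride2_only)
                axis, _ = tilts[leaflets[int(rid)]]
                seg_vals.append(segment_order(segs, axis))
            vals = np.concatenate(seg_vals)
            key = int(rid)
            if key not in acc:
                acc[key] = np.zeros_like(vals)
                counts[key] = 0
            acc[key] += vals
            counts[key] += 1

    lipid_ids = np.array(sorted(acc))
    per_segment = np.array([acc[r] / counts[r] for r in lipid_ids])
    per_lipid = per_segment.mean(axis=1)
    aggregate = {"median": float(np.median(per_lipid)), "mean": float(per_lipid.mean())}
    tilt_mean = {
        leaf: (tilt_deg_sums[leaf] / tilt_counts[leaf]) if tilt_counts[leaf] else float("nan")
        for leaf in ("upper", "lower")
    }
    return OrderResult(
        per_segment_S=per_segment,
        per_lipid_S=per_lipid,
        lipid_ids=lipid_ids,
        aggregate_S=aggregate,
        statistic=statistic,
        phase=classify_phase(aggregate[statistic], phase_threshold),
        phase_threshold=phase_threshold,
        leaflet_tilt_deg=tilt_mean,
        n_frames_used=len(traj),
    )
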