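"""Synthetic planar bilayer generator.

Builds two-leaflet bilayer configurations with *known, imposed* structural
properties, standing in for atomistic MD trajectories when testing the
analysis code:

* acyl chains are ideal zigzags whose carbon-to-second-carbon segment
  directions are the leaflet chain axis perturbed by independent Gaussian
  angular jitter (``order_noise_sigma``), giving an analytically controllable
  chain order parameter;
* lipids sit on a square lattice, one lipid per site, with species placed
  randomly, as a pre-formed patch, or as a checkerboard (``mixing_mode``);
* sterols are minimal three-atom bodies (C3 reference carbon, C17 axis tail,
  R1 ring-centroid proxy) with an imposed insertion depth relative to the
  phosphate plane and an imposed axis tilt with uniformly random azimuth;
* trajectories carry frame-to-frame correlated lateral fluctuations realized
  by random transpositions of lattice sites (see :func:`generate_trajectory`);
  chain/sterol jitter is redrawn independently per frame.

All coordinates are in nm; configurations are geometric constructions with no
force-field energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .frames import BilayerFrame, Trajectory
from .topology import (
    PHOSPHOLIPID,
    STEROL,
    SpeciesEntry,
    TopologyError,
    TopologySpec,
)

__all__ = [
    "SynthConfig",
    "ChainTemplate",
    "SizingError",
    "generate_frame",
    "generate_trajectory",
    "synthetic_topology",
]

KNOWN_SPECIES = ("DPPC", "DLiPC", "POPS", "CHOL", "CHIM")
STEROL_SPECIES = ("CHOL", "CHIM")

STEROL_AXIS_LEN_NM = 0.9  # C3 -> C17 ring diagonal
CHAIN_START_DROP_NM = 0.12  # first carbon sits just below the phosphate
CHAIN_XY_OFFSET_NM = 0.15  # the two chains straddle the phosphate
WATER_MARGIN_NM = 2.0  # box headroom above each phosphate plane
FRAME_DT_NS = 1.0


class SizingError(ValueError):
    """Composition incompatible with the lattice size or mixing mode."""


@dataclass(frozen=True)
class ChainTemplate:
    """Geometric acyl-chain model: an ideal zigzag.

    ``zigzag_step_nm`` is the along-axis rise per carbon (0.127 nm, the
    all-trans C-C projection); ``zigzag_amplitude_nm`` the lateral alternation
    of odd/even carbons.  Segments spanning every second carbon are parallel
    to the chain axis regardless of the amplitude.
    """

    n_carbons: int = 16
    zigzag_step_nm: float = 0.127
    zigzag_amplitude_nm: float = 0.05

    def __post_init__(self) -> None:
        if self.n_carbons < 4 or self.n_carbons % 2:
            raise ValueError("n_carbons must be even and >= 4")
        if self.zigzag_step_nm <= 0 or self.zigzag_amplitude_nm < 0:
            raise ValueError("zigzag steps must be positive")

    @property
    def extent_nm(self) -> float:
        return (self.n_carbons - 1) * self.zigzag_step_nm


@dataclass(frozen=True)
class SynthConfig:
    """All tunable properties of a synthetic bilayer.

    ``composition`` maps species to mole fractions (must sum to 1); the
    default is the 2:3 DPPC/DLiPC phospholipid mix of the patched segregation
    systems.  ``order_noise_sigma`` is the per-segment angular jitter in
    radians; 0 gives a frozen all-trans leaflet with S = 1.
    """

    lattice_nx: int = 12
    lattice_ny: int = 12
    composition: Mapping[str, float] = field(
        default_factory=lambda: {"DPPC": 0.4, "DLiPC": 0.6}
    )
    mixing_mode: str = "random"  # random | patch | checkerboard
    patch_shape: str = "square"  # square | disc
    patch_n: int | None = None  # lipids in the patch; default = patch species count
    order_noise_sigma: float = 0.3  # rad
    leaflet_tilt_deg: float = 0.0
    sterol_depth_nm: float = -0.45  # C3 below the phosphate plane
    sterol_tilt_deg: float = 15.0
    head_jitter_nm: float = 0.02  # z jitter of phosphates and sterol bodies
    n_frames: int = 50
    frame_corr_rho: float = 0.5
    lattice_spacing_nm: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise SizingError(f"composition fractions sum to {total}, not 1")
        for sp in self.composition:
            if sp not in KNOWN_SPECIES:
                raise TopologyError(f"unknown species {sp!r}")
        if any(f < 0 for f in self.composition.values()):
            raise SizingError("negative mole fraction")
        if self.lattice_nx < 1 or self.lattice_ny < 1:
            raise SizingError("lattice must have at least one site per edge")
        if self.mixing_mode not in ("random", "patch", "checkerboard"):
            raise SizingError(f"unknown mixing_mode {self.mixing_mode!r}")
        if self.patch_shape not in ("square", "disc"):
            raise SizingError(f"unknown patch_shape {self.patch_shape!r}")
        if self.order_noise_sigma < 0:
            raise SizingError("order_noise_sigma must be >= 0")
        if not (0.0 <= self.frame_corr_rho < 1.0):
            raise SizingError("frame_corr_rho must be in [0, 1)")
        if self.lattice_spacing_nm <= 0:
            raise SizingError("lattice_spacing_nm must be > 0")
        if self.head_jitter_nm < 0:
            raise SizingError("head_jitter_nm must be >= 0")
        if self.n_frames < 1:
            raise SizingError("n_frames must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.lattice_nx * self.lattice_ny


def synthetic_topology(
    config: SynthConfig, template: ChainTemplate | None = None
) -> TopologySpec:
    """Topology matching frames from :func:`generate_frame`.

    Every phospholipid species carries two template-length chains (the
    generator is a geometric stand-in, not a chemical model); sterols use the
    C3/C17 reference and axis atoms.
    """
    template = template or ChainTemplate()
    n = template.n_carbons
    entries: dict[str, SpeciesEntry] = {}
    for sp in config.composition:
        if sp in STEROL_SPECIES:
            entries[sp] = SpeciesEntry(
                role=STEROL, sterol_ref_atom="C3", sterol_axis_atoms=("C3", "C17")
            )
        else:
            entries[sp] = SpeciesEntry(
                role=PHOSPHOLIPID,
                chain_atoms=(
                    tuple(f"C2{i}" for i in range(1, n + 1)),
                    tuple(f"C3{i}" for i in range(1, n + 1)),
                ),
                phosphate_atom="P",
            )
    return TopologySpec(entries)


# ---------------------------------------------------------------------------
# lattice species assignment


def _species_counts(config: SynthConfig) -> dict[str, int]:
    """Largest-remainder rounding of mole fractions to lattice-site counts."""
    n = config.n_sites
    items = list(config.composition.items())
    floors = {sp: int(math.floor(f * n)) for sp, f in items}
    short = n - sum(floors.values())
    remainders = sorted(
        items, key=lambda kv: (-(kv[1] * n - math.floor(kv[1] * n)), kv[0])
    )
    for sp, _ in remainders[:short]:
        floors[sp] += 1
    if sum(floors.values()) != n:
        raise SizingError("composition incompatible with lattice size")
    return floors


def _patch_species(config: SynthConfig) -> str:
    return "DPPC" if "DPPC" in config.composition else next(iter(config.composition))


def _assign_species(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Species label per lattice site (row-major ix*ny + iy), one leaflet."""
    counts = _species_counts(config)
    nx, ny = config.lattice_nx, config.lattice_ny
    labels = np.empty(config.n_sites, dtype=object)
    if config.mixing_mode == "checkerboard":
        species = [sp for sp, c in counts.items() if c > 0]
        if len(species) != 2 or counts[species[0]] != counts[species[1]]:
            raise SizingError("checkerboard needs exactly two species in a 1:1 ratio")
        ix, iy = np.divmod(np.arange(config.n_sites), ny)
        parity = (ix + iy) % 2
        labels[parity == 0] = species[0]
        labels[parity == 1] = species[1]
        return labels
    if config.mixing_mode == "patch":
        patch_sp = _patch_species(config)
        n_patch = config.patch_n if config.patch_n is not None else counts[patch_sp]
        if n_patch != counts[patch_sp]:
            raise SizingError(
                f"patch_n={n_patch} != composition count {counts[patch_sp]} "
                f"for {patch_sp}"
            )
        ix, iy = np.divmod(np.arange(config.n_sites), ny)
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        if config.patch_shape == "square":
            dist = np.maximum(np.abs(ix - cx), np.abs(iy - cy))
        else:
            dist = np.hypot(ix - cx, iy - cy)
        order = np.lexsort((iy, ix, dist))  # deterministic tie-break
        patch_sites = order[:n_patch]
        rest_sites = order[n_patch:]
        labels[patch_sites] = patch_sp
        pool: list[str] = []
        for sp, c in counts.items():
            if sp != patch_sp:
                pool.extend([sp] * c)
        pool_arr = np.array(pool, dtype=object)
        rng.shuffle(pool_arr)
        labels[rest_sites] = pool_arr
        return labels
    # random
    pool = []
    for sp, c in counts.items():
        pool.extend([sp] * c)
    pool_arr = np.array(pool, dtype=object)
    rng.shuffle(pool_arr)
    return pool_arr


# ---------------------------------------------------------------------------
# geometry


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u (and each other)."""
    a = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _jittered_directions(
    u: np.ndarray, shape: tuple[int, ...], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit vectors: u rotated by polar angle ~N(0, sigma), uniform azimuth."""
    e1, e2 = _perp_basis(u)
    theta = rng.normal(0.0, sigma, size=shape) if sigma > 0 else np.zeros(shape)
    phi = rng.uniform(0.0, 2 * np.pi, size=shape)
    st, ct = np.sin(theta), np.cos(theta)
    return (
        ct[..., None] * u
        + st[..., None] * (np.cos(phi)[..., None] * e1 + np.sin(phi)[..., None] * e2)
    )


def _build_chains(
    starts: np.ndarray,
    u: np.ndarray,
    template: ChainTemplate,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Carbon positions (n_chains, n_carbons, 3) for chains along axis u.

    Carbon positions obey p[i+2] - p[i] = L * d_i with independent jittered
    unit directions d_i and L twice the per-carbon rise, so every second-carbon
    segment realizes exactly one jitter draw.  The zigzag amplitude displaces
    the odd carbon sub-chain laterally (random azimuth per chain) and does not
    enter any segment vector.
    """
    n_chains = len(starts)
    n = template.n_carbons
    m = n - 2  # segments
    L = 2.0 * template.zigzag_step_nm
    d = _jittered_directions(u, (n_chains, m), sigma, rng)
    e1, e2 = _perp_basis(u)
    psi = rng.uniform(0.0, 2 * np.pi, size=n_chains)
    lateral = (
        np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
    ) * template.zigzag_amplitude_nm
    p0 = starts
    p1 = starts + template.zigzag_step_nm * u + lateral
    pos = np.empty((n_chains, n, 3))
    even = np.concatenate(
        [np.zeros((n_chains, 1, 3)), np.cumsum(L * d[:, 0::2], axis=1)], axis=1
    )
    odd = np.concatenate(
        [np.zeros((n_chains, 1, 3)), np.cumsum(L * d[:, 1::2], axis=1)], axis=1
    )
    pos[:, 0::2] = p0[:, None, :] + even[:, : (n + 1) // 2]
    pos[:, 1::2] = p1[:, None, :] + odd[:, : n // 2]
    return pos


def _leaflet_atoms(
    config: SynthConfig,
    template: ChainTemplate,
    labels: np.ndarray,
    z_phos: float,
    inward: float,  # -1 for the upper leaflet (chains point down), +1 lower
    rng: np.random.Generator,
    rid_start: int,
) -> tuple[np.ndarray, list[int], list[str], list[str], int]:
    a = config.lattice_spacing_nm
    nx, ny = config.lattice_nx, config.lattice_ny
    ix, iy = np.divmod(np.arange(config.n_sites), ny)
    sx = (ix + 0.5) * a
    sy = (iy + 0.5) * a

    tilt = math.radians(config.leaflet_tilt_deg)
    # collective tilt toward +x; the z component points into the bilayer
    u = np.array([math.sin(tilt), 0.0, inward * math.cos(tilt)])

    coords: list[np.ndarray] = []
    rids: list[int] = []
    species_out: list[str] = []
    names: list[str] = []
    rid = rid_start
    n = template.n_carbons
    chain_names = [
        [f"C2{i}" for i in range(1, n + 1)],
        [f"C3{i}" for i in range(1, n + 1)],
    ]

    is_sterol = np.array([sp in STEROL_SPECIES for sp in labels])
    jitter = (
        rng.normal(0.0, config.head_jitter_nm, size=config.n_sites)
        if config.head_jitter_nm > 0
        else np.zeros(config.n_sites)
    )

    # phospholipids: P + two chains, chains built in one vectorized batch
    pl_sites = np.where(~is_sterol)[0]
    if len(pl_sites):
        z_p = z_phos + jitter[pl_sites]
        starts = []
        for dx in (-CHAIN_XY_OFFSET_NM, CHAIN_XY_OFFSET_NM):
            s = np.column_stack(
                [sx[pl_sites] + dx, sy[pl_sites], z_p + inward * CHAIN_START_DROP_NM]
            )
            starts.append(s)
        chains = [
            _build_chains(s, u, template, config.order_noise_sigma, rng) for s in starts
        ]
    # sterols: rigid three-atom body with imposed depth and tilt
    st_tilt = math.radians(config.sterol_tilt_deg)

    for k, site in enumerate(np.arange(config.n_sites)):
        sp = labels[site]
        if is_sterol[site]:
            # depth < 0 means buried: displace along the inward direction
            z_ref = z_phos + jitter[site] - inward * config.sterol_depth_nm
            head = np.array([sx[site], sy[site], z_ref])
            phi = rng.uniform(0.0, 2 * np.pi)
            axis_dir = np.array(
                [
                    math.sin(st_tilt) * math.cos(phi),
                    math.sin(st_tilt) * math.sin(phi),
                    inward * math.cos(st_tilt),
                ]
            )
            tail = head + STEROL_AXIS_LEN_NM * axis_dir
            mid = 0.5 * (head + tail)
            coords.extend([head[None], tail[None], mid[None]])
            rids.extend([rid] * 3)
            species_out.extend([sp] * 3)
            names.extend(["C3", "C17", "R1"])
        else:
            j = np.searchsorted(pl_sites, site)
            p = np.array([sx[site], sy[site], z_phos + jitter[site]])
            coords.append(p[None])
            rids.append(rid)
            species_out.append(sp)
            names.append("P")
            for c in range(2):
                coords.append(chains[c][j])
                rids.extend([rid] * n)
                species_out.extend([sp] * n)
                names.extend(chain_names[c])
        rid += 1
    return np.concatenate(coords, axis=0), rids, species_out, names, rid


def _frame_from_labels(
    config: SynthConfig,
    template: ChainTemplate,
    labels: np.ndarray,
    rng: np.random.Generator,
    time_ns: float | None = None,
) -> BilayerFrame:
    chain_depth = CHAIN_START_DROP_NM + template.extent_nm
    d_phos = chain_depth  # phosphate plane to midplane
    box_z = 2.0 * (d_phos + WATER_MARGIN_NM)
    z_mid = box_z / 2.0
    box = np.array(
        [
            config.lattice_nx * config.lattice_spacing_nm,
            config.lattice_ny * config.lattice_spacing_nm,
            box_z,
        ]
    )
    up = _leaflet_atoms(config, template, labels, z_mid + d_phos, -1.0, rng, 1)
    coords_u, rid_u, sp_u, nm_u, next_rid = up
    low = _leaflet_atoms(config, template, labels, z_mid - d_phos, +1.0, rng, next_rid)
    coords_l, rid_l, sp_l, nm_l, _ = low
    return BilayerFrame(
        coords=np.concatenate([coords_u, coords_l]),
        box=box,
        residue_id=np.array(rid_u + rid_l),
        species=np.array(sp_u + sp_l, dtype=object),
        atom_name=np.array(nm_u + nm_l, dtype=object),
        time=time_ns,
    )


def generate_frame(
    config: SynthConfig,
    template: ChainTemplate | None = None,
    rng: np.random.Generator | None = None,
) -> BilayerFrame:
    """One mirror-symmetric two-leaflet frame under the given configuration.

    Both leaflets share the lateral species assignment (leaflets in registry)
    but draw chain jitter independently.  Deterministic under ``config.seed``.
    """
    template = template or ChainTemplate()
    rng = rng or np.random.default_rng(config.seed)
    labels = _assign_species(config, rng)
    return _frame_from_labels(config, template, labels, rng, time_ns=0.0)


# ---------------------------------------------------------------------------
# trajectories


def _transposition_count(config: SynthConfig, n_sites: int) -> int:
    """Swaps per frame so the neighbor-fraction lag-1 autocorrelation ~ rho.

    A site survives m uniformly random transpositions untouched with
    probability (1 - 2/n)^m.  The DPPC-neighbor fraction is a pair statistic;
    with member fraction p among phospholipids, single-site survival a gives a
    pair autocorrelation of (a^2 (1-p) + 2 a p) / (1 + p), which is inverted
    for a at the requested rho.
    """
    rho = config.frame_corr_rho
    comp = config.composition
    pl_total = sum(f for sp, f in comp.items() if sp not in STEROL_SPECIES)
    p = comp.get("DPPC", 0.0) / pl_total if pl_total > 0 else 0.5
    if p >= 1.0 or pl_total == 0:
        p = 0.5
    a = (-p + math.sqrt(p * p + rho * (1 - p * p))) / (1 - p)
    a = min(max(a, 1e-12), 1 - 1e-12)
    m = math.log(a) / math.log(1.0 - 2.0 / n_sites)
    return max(1, int(round(m)))


def generate_trajectory(
    config: SynthConfig,
    template: ChainTemplate | None = None,
) -> Trajectory:
    """``config.n_frames`` frames with correlated lateral fluctuations.

    Random mixing evolves by a cumulative random-transposition Markov chain
    whose stationary distribution is the uniform random assignment; the number
    of transpositions per frame is chosen so the lag-1 autocorrelation of the
    neighbor-fraction statistic is approximately ``frame_corr_rho``
    (``frame_corr_rho = 0`` reshuffles every frame independently).  Patch and
    checkerboard modes keep the base configuration as an anchor and maintain a
    pool of transient transpositions, each retained per frame with probability
    ``frame_corr_rho``, giving mean-reverting fluctuations around the ordered
    arrangement.  Chain, sterol and headgroup jitter are redrawn every frame.
    """
    template = template or ChainTemplate()
    rng = np.random.default_rng(config.seed)
    base = _assign_species(config, rng)
    n_sites = config.n_sites
    frames: list[BilayerFrame] = []

    if config.mixing_mode == "random":
        labels = base.copy()
        m = _transposition_count(config, n_sites)
        for t in range(config.n_frames):
            if t > 0:
                if config.frame_corr_rho == 0.0:
                    rng.shuffle(labels)
                else:
                    for _ in range(m):
                        i, j = rng.choice(n_sites, size=2, replace=False)
                        labels[i], labels[j] = labels[j], labels[i]
            frames.append(
                _frame_from_labels(config, template, labels, rng, time_ns=t * FRAME_DT_NS)
            )
    else:
        k_pool = max(2, int(round(0.04 * n_sites)))
        pool = [tuple(rng.choice(n_sites, size=2, replace=False)) for _ in range(k_pool)]
        for t in range(config.n_frames):
            if t > 0:
                keep = rng.random(k_pool) < config.frame_corr_rho
                pool = [
                    pair if k else tuple(rng.choice(n_sites, size=2, replace=False))
                    for pair, k in zip(pool, keep)
                ]
            labels = base.copy()
            for i, j in pool:
                labels[i], labels[j] = labels[j], labels[i]
            frames.append(
                _frame_from_labels(config, template, labels, rng, time_ns=t * FRAME_DT_NS)
            )
    return Trajectory(frames)


def single_frame_config(config: SynthConfig) -> SynthConfig:
    """The same configuration reduced to one frame."""
    return replace(config, n_frames=1)
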