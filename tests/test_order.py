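"""Order parameter: kernel identities, brute-force equivalence, invariances."""

import math

import numpy as np
import pytest

from conftest import make_frame

from memblens import (
    SynthConfig,
    assign_leaflets,
    classify_phase,
    compute_order,
    generate_frame,
    leaflet_tilt,
    synthetic_topology,
)
from memblens.order import second_legendre, segment_order


# ---------------------------------------------------------------------------
# kernel identities: S = 1 / -0.5 / 0


def test_parallel_segments_have_unit_order():
    axis = np.array([0.0, 0.0, 1.0])
    segs = np.tile(axis, (100, 1)) * np.linspace(0.5, 2.0, 100)[:, None]
    assert np.allclose(segment_order(segs, axis), 1.0, atol=1e-15)
    # and antiparallel too: the sign of the segment cannot matter
    assert np.allclose(segment_order(-segs, axis), 1.0, atol=1e-15)


def test_perpendicular_segments_have_order_minus_half():
    axis = np.array([0.0, 0.0, 1.0])
    phi = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    segs = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
    assert np.allclose(segment_order(segs, axis), -0.5, atol=1e-15)


def test_isotropic_segments_average_to_zero():
    """<P2> over the sphere is 0; 1e5 random segments land within 0.01."""
    rng = np.random.default_rng(2024)
    v = rng.normal(size=(100_000, 3))
    s = segment_order(v, np.array([0.0, 0.0, 1.0]))
    assert abs(s.mean()) <= 0.01
    assert s.min() >= -0.5 - 1e-12 and s.max() <= 1.0 + 1e-12


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)
        ).filter(lambda v: sum(x * x for x in v) > 1e-6),
        min_size=1,
        max_size=50,
    ),
    st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)).filter(
        lambda v: sum(x * x for x in v) > 1e-3
    ),
)
def test_order_parameter_bounded_for_any_segments(segs, axis):
    s = segment_order(np.array(segs), np.array(axis))
    assert np.all(s >= -0.5 - 1e-9) and np.all(s <= 1.0 + 1e-9)


def test_p2_bounds_hold_for_any_cosine():
    c = np.linspace(-1, 1, 1001)
    p = second_legendre(c)
    assert p.min() >= -0.5 and p.max() <= 1.0


# ---------------------------------------------------------------------------
# phase classification (strict threshold)


@pytest.mark.parametrize(
    "S, expected",
    [(0.75, "ordered"), (0.70, "disordered"), (0.7000000001, "ordered"), (-0.2, "disordered")],
)
def test_phase_threshold_is_strict(S, expected):
    assert classify_phase(S) == expected


def test_out_of_range_order_parameter_rejected():
    with pytest.raises(ValueError):
        classify_phase(1.2)


# ---------------------------------------------------------------------------
# leaflet tilt


def _two_leaflet_chains(chain_dirs_up, n_carbons=4, step=0.25):
    """Hand-built frame: straight chains along the given directions (stated in
    upper-leaflet convention, z < 0 = descending) plus a z-mirrored lower
    leaflet; P atoms sit just outside each chain top."""
    atoms = []
    rid = 1
    for z0, mirror in ((6.0, 1.0), (2.0, -1.0)):
        outward = np.array([0.0, 0.0, mirror * 0.05])
        for d in chain_dirs_up:
            d = np.asarray(d, float)
            d = d / np.linalg.norm(d)
            d = np.array([d[0], d[1], mirror * d[2]])
            x0 = np.array([5.0, 5.0, z0])
            atoms.append((rid, "DPPC", "P", tuple(x0 + outward)))
            for k in range(n_carbons):
                atoms.append((rid, "DPPC", f"C2{k + 1}", tuple(x0 + k * step * d)))
            rid += 1
    return make_frame(atoms, box=(10.0, 10.0, 10.0))


@pytest.fixture
def chain_topology(minimal_topology):
    return minimal_topology


def test_chains_along_normal_have_zero_tilt(chain_topology):
    frame = _two_leaflet_chains([(0, 0, -1)] * 4)
    lm = assign_leaflets(frame, chain_topology)
    tilts = leaflet_tilt(frame, lm, chain_topology)
    for _, ang in tilts.values():
        assert ang == pytest.approx(0.0, abs=1e-9)


def test_uniform_30_degree_tilt_recovered(chain_topology):
    t = math.radians(30.0)
    frame = _two_leaflet_chains([(math.sin(t), 0, -math.cos(t))] * 4)
    lm = assign_leaflets(frame, chain_topology)
    tilts = leaflet_tilt(frame, lm, chain_topology)
    for vec, ang in tilts.values():
        assert ang == pytest.approx(30.0, abs=1e-6)
        assert abs(vec[1]) < 1e-9  # in the xz-plane


def test_azimuthally_uniform_tilt_cancels(chain_topology):
    """10^4 chains tilted 30 deg with evenly spaced azimuths: average ~ normal."""
    t = math.radians(30.0)
    phi = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
    dirs = [
        (math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), -math.cos(t))
        for p in phi
    ]
    frame = _two_leaflet_chains(dirs)
    lm = assign_leaflets(frame, chain_topology)
    tilts = leaflet_tilt(frame, lm, chain_topology)
    for _, ang in tilts.values():
        assert ang == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# brute-force equivalence on a small frame


def _brute_force_per_segment(frame, topology, species):
    """Independent re-computation with explicit loops over chains/segments."""
    lm = assign_leaflets(frame, topology)
    # leaflet tilt: average normalized first->last carbon vector
    tilt_vec = {}
    for leaf in ("upper", "lower"):
        inward = np.array([0, 0, -1.0]) if leaf == "upper" else np.array([0, 0, 1.0])
        acc = np.zeros(3)
        count = 0
        for sp in topology.phospholipids():
            entry = topology[sp]
            rids = sorted(
                set(frame.residue_id[frame.select(species=sp)].tolist())
            )
            for rid in rids:
                if lm[rid] != leaf:
                    continue
                sel = frame.residue_id == rid
                names = {n: i for i, n in enumerate(frame.atom_name[sel])}
                xyz = frame.coords[sel]
                for chain in entry.chain_atoms:
                    v = xyz[names[chain[-1]]] - xyz[names[chain[0]]]
                    v = v / np.linalg.norm(v)
                    if np.dot(v, inward) < 0:
                        v = -v
                    acc += v
                    count += 1
        acc /= count
        tilt_vec[leaf] = acc / np.linalg.norm(acc)
    entry = topology[species]
    out = {}
    for rid in sorted(set(frame.residue_id[frame.select(species=species)].tolist())):
        sel = frame.residue_id == rid
        names = {n: i for i, n in enumerate(frame.atom_name[sel])}
        xyz = frame.coords[sel]
        axis = tilt_vec[lm[rid]]
        vals = []
        for chain in entry.chain_atoms:
            for i in range(len(chain) - 2):
                seg = xyz[names[chain[i + 2]]] - xyz[names[chain[i]]]
                cos_a = np.dot(seg, axis) / np.linalg.norm(seg)
                vals.append(0.5 * (3 * cos_a**2 - 1))
        out[rid] = np.array(vals)
    return out


def test_matches_brute_force_to_1e12():
    cfg = SynthConfig(
        lattice_nx=3,
        lattice_ny=3,
        composition={"DPPC": 2 / 3, "DLiPC": 1 / 3},
        order_noise_sigma=0.5,
        seed=17,
    )
    top = synthetic_topology(cfg)
    frame = generate_frame(cfg)
    res = compute_order(frame, top, "DPPC")
    brute = _brute_force_per_segment(frame, top, "DPPC")
    for row, rid in zip(res.per_segment_S, res.lipid_ids):
        assert np.abs(row - brute[int(rid)]).max() < 1e-12


def test_rotation_about_z_leaves_order_unchanged():
    cfg = SynthConfig(
        lattice_nx=3, lattice_ny=3, composition={"DPPC": 1.0}, order_noise_sigma=0.4, seed=5
    )
    top = synthetic_topology(cfg)
    frame = generate_frame(cfg)
    res0 = compute_order(frame, top, "DPPC")
    a = math.radians(33.0)
    R = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])
    center = np.array([*(frame.box[:2] / 2), 0.0])
    rotated = make_frame_like(frame, (frame.coords - center) @ R.T + center)
    res1 = compute_order(rotated, top, "DPPC")
    assert np.abs(res1.per_segment_S - res0.per_segment_S).max() < 1e-10


def make_frame_like(frame, coords):
    from memblens import BilayerFrame

    return BilayerFrame(
        coords=coords,
        box=frame.box,
        residue_id=frame.residue_id,
        species=frame.species,
        atom_name=frame.atom_name,
    )


def test_generator_matches_monte_carlo_expectation():
    """Aggregate S vs the closed sampling oracle E[P2(cos th)], th~N(0, sigma)."""

    def oracle(sigma, n=1_000_000):
        th = np.random.default_rng(99).normal(0, sigma, n)
        vals = 0.5 * (3 * np.cos(th) ** 2 - 1)
        return vals.mean(), vals.std() / np.sqrt(n)

    for sigma in (0.2, 0.4, 0.8):
        vals = []
        for seed in range(20):
            cfg = SynthConfig(
                lattice_nx=8,
                lattice_ny=8,
                composition={"DPPC": 1.0},
                order_noise_sigma=sigma,
                seed=seed,
            )
            top = synthetic_topology(cfg)
            vals.append(
                compute_order(generate_frame(cfg), top, "DPPC", statistic="mean").S
            )
        mean, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals))
        exp, ose = oracle(sigma)
        assert abs(mean - exp) < 3 * math.hypot(se, ose), f"sigma={sigma}"


def test_median_and_mean_both_reported(ordered_config):
    top = synthetic_topology(ordered_config)
    res = compute_order(generate_frame(ordered_config), top, "DPPC", statistic="mean")
    assert set(res.aggregate_S) == {"median", "mean"}
    assert res.S == res.aggregate_S["mean"]


def test_stride2_segments_are_subset(ordered_config):
    cfg = ordered_config
    top = synthetic_topology(cfg)
    frame = generate_frame(cfg)
    full = compute_order(frame, top, "DPPC")
    half = compute_order(frame, top, "DPPC", stride2_only=True)
    assert half.per_segment_S.shape[1] == full.per_segment_S.shape[1] // 2
    assert np.allclose(half.per_segment_S, full.per_segment_S[:, ::2])


def test_absent_species_raises(ordered_config):
    from memblens.order import SelectionError
    from memblens.topology import builtin_topology

    top = builtin_topology()
    frame = generate_frame(ordered_config)
    with pytest.raises(SelectionError):
        compute_order(frame, top, "POPS")
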