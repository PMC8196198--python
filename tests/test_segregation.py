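"""Neighbor-fraction statistics and the blocking error estimator."""

import numpy as np
import pytest

from memblens import (
    ChainTemplate,
    NeighborParams,
    SynthConfig,
    assign_leaflets,
    blocking_se,
    generate_frame,
    generate_trajectory,
    naive_se,
    neighbor_fraction,
    segregation_series,
    synthetic_topology,
)

SHORT = ChainTemplate(n_carbons=4)


def _frame_and_top(**kwargs):
    cfg = SynthConfig(**kwargs)
    top = synthetic_topology(cfg, SHORT)
    frame = generate_frame(cfg, SHORT)
    return cfg, frame, top


def test_pure_dppc_leaflet_has_fraction_one():
    _, frame, top = _frame_and_top(
        lattice_nx=6, lattice_ny=6, composition={"DPPC": 1.0}, head_jitter_nm=0.0
    )
    ff = neighbor_fraction(frame, assign_leaflets(frame, top), top, "DPPC")
    assert ff.fraction == 1.0
    assert ff.excluded_centers == 0


def test_segregated_patch_reaches_complete_segregation_level():
    """20x20 DPPC patch in DLiPC, nearest-neighbor criterion: exactly 0.95."""
    _, frame, top = _frame_and_top(
        lattice_nx=30,
        lattice_ny=30,
        composition={"DPPC": 400 / 900, "DLiPC": 500 / 900},
        mixing_mode="patch",
        head_jitter_nm=0.0,
        seed=1,
    )
    ff = neighbor_fraction(
        frame,
        assign_leaflets(frame, top),
        top,
        "DPPC",
        NeighborParams(cutoff_nm=1.0),  # 0.8 nm lattice: 4-connected shell
    )
    # exact lattice count: (324*1 + 72*0.75 + 4*0.5) / 400
    assert ff.fraction == pytest.approx(0.95, abs=1e-12)
    assert ff.fraction >= 0.9


def test_sterols_excluded_from_denominator():
    """Sterol-rich random system: fraction still tracks the PL-only share."""
    vals = []
    for seed in range(30):
        _, frame, top = _frame_and_top(
            lattice_nx=12,
            lattice_ny=12,
            composition={"DPPC": 0.336, "DLiPC": 0.504, "CHOL": 0.16},
            seed=seed,
        )
        ff = neighbor_fraction(frame, assign_leaflets(frame, top), top, "DPPC")
        vals.append(ff.fraction)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    n_pl = round(0.336 * 144) + round(0.504 * 144)
    expected = (round(0.336 * 144) - 1) / (n_pl - 1)
    assert abs(np.mean(vals) - expected) < 3 * se


@pytest.mark.parametrize("cutoff", [0.9, 1.2, 1.7])
def test_random_mixing_expectation_is_cutoff_robust(cutoff):
    vals = []
    for seed in range(30):
        _, frame, top = _frame_and_top(
            lattice_nx=14,
            lattice_ny=14,
            composition={"DPPC": 0.4, "DLiPC": 0.6},
            seed=seed,
        )
        ff = neighbor_fraction(
            frame, assign_leaflets(frame, top), top, "DPPC", NeighborParams(cutoff)
        )
        vals.append(ff.fraction)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    n = 196
    expected = (round(0.4 * n) - 1) / (n - 1)
    assert abs(np.mean(vals) - expected) < 3 * se + 0.005


def test_fractions_match_brute_force_neighbor_search():
    """KDTree result equals an explicit min-image double loop (and the
    underlying relation is symmetric by construction of that loop)."""
    _, frame, top = _frame_and_top(
        lattice_nx=8, lattice_ny=8, composition={"DPPC": 0.4, "DLiPC": 0.6}, seed=3
    )
    lm = assign_leaflets(frame, top)
    params = NeighborParams(cutoff_nm=1.2)
    got = neighbor_fraction(frame, lm, top, "DPPC", params)

    mask = frame.select(atom_name="P")
    xy = frame.coords[mask, :2]
    rid = frame.residue_id[mask]
    sp = frame.species[mask]
    box = frame.box[:2]
    expected = {}
    for i in range(len(xy)):
        if sp[i] != "DPPC":
            continue
        n_pl = n_dppc = 0
        for j in range(len(xy)):
            if i == j or lm[int(rid[i])] != lm[int(rid[j])]:
                continue
            d = xy[i] - xy[j]
            d -= box * np.round(d / box)
            if np.hypot(*d) <= params.cutoff_nm:
                n_pl += 1
                n_dppc += sp[j] == "DPPC"
        if n_pl:
            expected[int(rid[i])] = n_dppc / n_pl
    assert got.per_center == pytest.approx(expected)


def test_cutoff_at_half_box_rejected():
    _, frame, top = _frame_and_top(lattice_nx=4, lattice_ny=4)
    with pytest.raises(ValueError, match="cutoff"):
        neighbor_fraction(
            frame, assign_leaflets(frame, top), top, "DPPC", NeighborParams(1.6)
        )


def test_absent_center_species_raises():
    _, frame, top = _frame_and_top(
        lattice_nx=4, lattice_ny=4, composition={"DPPC": 0.5, "DLiPC": 0.5}
    )
    with pytest.raises(ValueError, match="CHIM"):
        neighbor_fraction(frame, assign_leaflets(frame, top), top, "CHIM")


# ---------------------------------------------------------------------------
# time series


def test_random_trajectory_tail_matches_random_mixing_level():
    cfg = SynthConfig(
        lattice_nx=12,
        lattice_ny=12,
        composition={"DPPC": 0.4, "DLiPC": 0.6},
        n_frames=64,
        frame_corr_rho=0.3,
        seed=8,
    )
    top = synthetic_topology(cfg, SHORT)
    series = segregation_series(generate_trajectory(cfg, SHORT), top, "DPPC")
    assert np.all((series.f_t >= 0) & (series.f_t <= 1))
    assert series.tail_mean == pytest.approx(0.40, abs=max(3 * series.tail_se, 0.02))
    assert series.ref_random == 0.4 and series.ref_segregated == 0.9


def test_patch_trajectory_stays_segregated():
    cfg = SynthConfig(
        lattice_nx=20,
        lattice_ny=20,
        composition={"DPPC": 0.4, "DLiPC": 0.6},
        mixing_mode="patch",
        n_frames=16,
        frame_corr_rho=0.5,
        seed=8,
    )
    top = synthetic_topology(cfg, SHORT)
    series = segregation_series(generate_trajectory(cfg, SHORT), top, "DPPC")
    assert series.tail_mean > 0.75  # well above the random-mixing level


def test_constant_series_has_zero_tail_se():
    cfg = SynthConfig(
        lattice_nx=6,
        lattice_ny=6,
        composition={"DPPC": 1.0},
        n_frames=12,
        head_jitter_nm=0.0,
        seed=2,
    )
    top = synthetic_topology(cfg, SHORT)
    series = segregation_series(generate_trajectory(cfg, SHORT), top, "DPPC")
    assert np.all(series.f_t == 1.0)
    assert series.tail_se == 0.0


def test_tail_window_respects_fraction():
    cfg = SynthConfig(lattice_nx=6, lattice_ny=6, n_frames=16, seed=2)
    top = synthetic_topology(cfg, SHORT)
    traj = generate_trajectory(cfg, SHORT)
    series = segregation_series(traj, top, "DPPC", tail_fraction=0.25)
    assert series.tail_mean == pytest.approx(np.mean(series.f_t[-4:]))
    assert min(series.f_t) - 1e-12 <= series.tail_mean <= max(series.f_t) + 1e-12
    with pytest.raises(ValueError):
        segregation_series(traj, top, "DPPC", tail_fraction=0.0)


def test_too_short_trajectory_rejected():
    cfg = SynthConfig(lattice_nx=4, lattice_ny=4, n_frames=2, seed=2)
    top = synthetic_topology(cfg, SHORT)
    with pytest.raises(ValueError, match="4 frames"):
        segregation_series(generate_trajectory(cfg, SHORT), top, "DPPC")


# ---------------------------------------------------------------------------
# blocking method


def test_blocking_matches_root_n_for_iid_series():
    rng = np.random.default_rng(1)
    x = rng.normal(0.0, 1.0, 1024)
    res = blocking_se(x)
    assert res.se == pytest.approx(1.0 / 32.0, rel=0.2)
    assert res.converged


def test_blocking_recovers_ar1_inflation():
    rho, N = 0.9, 2**14
    rng = np.random.default_rng(3)
    x = np.empty(N)
    x[0] = rng.normal()
    eps = rng.normal(size=N) * np.sqrt(1 - rho**2)
    for i in range(1, N):
        x[i] = rho * x[i - 1] + eps[i]
    expected = np.sqrt((1 + rho) / (1 - rho)) / np.sqrt(N)
    assert blocking_se(x).se == pytest.approx(expected, rel=0.25)


def test_blocking_exceeds_naive_for_correlated_series():
    rho, N = 0.8, 4096
    rng = np.random.default_rng(5)
    x = np.empty(N)
    x[0] = rng.normal()
    for i in range(1, N):
        x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.normal()
    assert blocking_se(x).se > naive_se(x)


def test_constant_series_blocking_is_zero():
    res = blocking_se(np.full(64, 3.14))
    assert res.se == 0.0


def test_short_series_rejected():
    with pytest.raises(ValueError, match=">= 8"):
        blocking_se(np.arange(5.0))


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    arrays(
        float,
        st.integers(8, 200),
        elements=st.floats(-1e6, 1e6, allow_nan=False),
    )
)
def test_blocking_se_nonnegative_and_bounded_by_spread(x):
    res = blocking_se(x)
    assert res.se >= 0.0
    assert res.se <= np.ptp(x) + 1e-9
    assert len(res.se_curve) >= 1


def test_blocking_curve_shapes():
    rng = np.random.default_rng(7)
    res = blocking_se(rng.normal(size=512))
    assert len(res.block_sizes) == len(res.se_curve) == len(res.se_uncertainty)
    assert res.block_sizes[0] == 1 and np.all(np.diff(res.block_sizes) > 0)
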