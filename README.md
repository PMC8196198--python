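# memblens

Structural statistics for planar lipid bilayers: leaflet-referenced acyl-chain
order parameters with ordered/disordered phase classification, sterol
insertion depth and ring-axis tilt, lateral segregation (DPPC-neighbor
fraction) statistics with blocking-method errors, and cooperative (Hill)
binding-isotherm fitting. A synthetic bilayer generator with *known, imposed*
structure serves as the validation substrate for every analysis.

The package targets membrane biophysicists characterizing how sterols — e.g.
cholesterol and its imidazolium-based analogs (CHIMs) — integrate into and
reorganize phospholipid bilayers of DPPC, DLiPC and POPS, whether from
atomistic MD trajectories (GRO/PDB coordinates, XTC/DCD trajectories) or from
synthetic test systems.

## The statistics

**Chain order parameter.** For each acyl chain, segments connect every second
carbon (Cᵢ → Cᵢ₊₂). With α the angle between a segment and the *average
leaflet tilt* — the normalized mean over the leaflet's chains of the
first-to-last-carbon vector — the order parameter is the second Legendre
polynomial

    S = ⟨ (3 cos²α − 1) / 2 ⟩         S ∈ [−0.5, 1]

S = 1 for chains frozen parallel to the tilt, 0 for isotropic disorder,
−0.5 for perpendicular segments. Per-lipid values are aggregated (median by
default) and a bilayer with aggregate S > 0.7 (strict) is classified as
*ordered* (Lo-like), otherwise *disordered*.

**Sterol insertion depth.** Δz = mean z of the sterol reference carbon (the
carbon bearing cholesterol's hydroxyl group, C3) minus the mean phosphate z of
the same leaflet, lower-leaflet values mirrored so negative always means
buried toward the bilayer center. Sterol tilt is the angle between the
headward ring axis (C3 → C17, reported head − tail) and the outward leaflet
normal, folded into [0°, 90°].

**Lateral segregation.** Around each lipid of a center species, neighbors are
same-leaflet phospholipids whose reference atoms lie within a lateral cutoff
(default 1.0 nm, 2D minimum image); the statistic is the fraction of DPPC
among those phospholipid neighbors. At a 2:3 DPPC/DLiPC composition, 0.4 is
the random-mixing level and ~0.9 marks complete segregation. Time series are
summarized by the mean over the last 25% of frames, with a standard error
from the Flyvbjerg–Petersen blocking method (successive pair averaging until
the error estimate plateaus).

**Cooperative binding.** Isotherms y(c) = B_max·cⁿ / (Kⁿ + cⁿ) are fitted by
nonlinear least squares; n > 1 indicates positive cooperativity, as in the
binding of annexin A2 to sterol-containing membranes.

## Worked example

```python
import numpy as np
from memblens import (SynthConfig, generate_trajectory, synthetic_topology,
                      compute_order, sterol_depth, segregation_series,
                      fit_hill, simulate_isotherm)

cfg = SynthConfig(
    lattice_nx=10, lattice_ny=10,
    composition={"DPPC": 0.56, "DLiPC": 0.28, "CHOL": 0.16},
    order_noise_sigma=0.25, sterol_depth_nm=-0.45, sterol_tilt_deg=15.0,
    n_frames=20, frame_corr_rho=0.5, seed=7,
)
top = synthetic_topology(cfg)
traj = generate_trajectory(cfg)

order = compute_order(traj, top, "DPPC")
print(f"aggregate S (median over DPPC) = {order.S:.3f} -> phase {order.phase}")
depth = sterol_depth(traj, top, "CHOL")
print(f"CHOL insertion depth = {depth.delta_z_nm:.3f} +/- {depth.se_nm:.3f} nm")
seg = segregation_series(traj, top, "DPPC")
print(f"DPPC-neighbor fraction (tail) = {seg.tail_mean:.3f} +/- {seg.tail_se:.3f}")
fit = fit_hill(simulate_isotherm(1.88, 0.35, 22.0, noise_sd=1.2,
                                 rng=np.random.default_rng(0)))
print(fit.summary())
```

prints

```
aggregate S (median over DPPC) = 0.912 -> phase ordered
CHOL insertion depth = -0.448 +/- 0.001 nm
DPPC-neighbor fraction (tail) = 0.663 +/- 0.012
n_Hill = 1.65 ± 0.09, K = 0.393 ± 0.018, B_max = 23.9 ± 0.47, R² = 0.999 — positive cooperativity (n > 1)
```

The bilayer is classified ordered (moderate chain jitter leaves S ≈ 0.91);
the imposed −0.45 nm cholesterol depth is recovered to within the headgroup
jitter; the DPPC-neighbor fraction ≈ 0.66 equals the DPPC share among
phospholipids (0.56/0.84), i.e. random mixing at this composition; and the
simulated isotherm recovers a cooperative Hill coefficient with its
asymptotic uncertainty.

The same analyses are available from the shell:

```bash
memblens synth --config synth.yaml --out bilayer        # GRO + XTC + topology
memblens order --coords bilayer.gro --traj bilayer.xtc \
    --topology bilayer.topology.yaml --species DPPC
memblens run --config run.yaml                           # full pipeline
```

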