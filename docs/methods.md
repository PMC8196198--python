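# Methods

This note documents the models, conventions and numerical choices behind
memblens, what the synthetic bilayer generator does and does not emulate, and
the design decisions taken where more than one defensible convention exists.

## Coordinate model and leaflet assignment

All geometry lives in nm with the z-axis as the bilayer normal and an
orthorhombic box; coordinates are wrapped into [0, box) on file load, and all
intra-chain and neighbor displacements use the minimum-image convention.
Triclinic cells are rejected rather than silently mishandled: the lateral
neighbor search assumes a rectangular periodic cell, and planar bilayers
simulated under semi-isotropic pressure coupling satisfy that.

Leaflets are assigned *per frame* from reference-atom positions: the midplane
is the mean phosphate z over all phospholipids; phospholipids are split by
their phosphate z, sterols by their reference carbon (C3) z. A reference atom
exactly on the midplane goes to the upper leaflet — a deterministic,
measure-zero tie-break. This global-midplane criterion is correct for planar
bilayers only; curved membranes and vesicles are out of scope. How to assign
a sterol sitting deep between the leaflets is genuinely ambiguous; the
ref-atom-vs-midplane rule is our choice and is applied uniformly.

## Chain order parameter

Segments connect carbon i to carbon i+2 for *all* i ("every second carbon"
read as the i → i+2 span). The alternative reading — only non-overlapping
stride-2 segments C1→C3, C3→C5, … — is available via `stride2_only`; the
all-i default maximizes samples per chain. The reference direction is the
per-leaflet, per-frame average tilt: each phospholipid chain's normalized
first-to-last-carbon vector, oriented to point along the leaflet's inward
normal, averaged and re-normalized. The angle α between segment and tilt
enters S = ⟨P₂(cos α)⟩; P₂ depends on cos²α, so segment orientation signs
cannot matter.

Aggregation: per-segment values are averaged over frames first, a lipid's
pooled segments (both acyl chains) are averaged next, and the across-lipid
statistic (median by default, mean also reported) is taken last. Whether the
median should run across lipids, segments, or both is underdetermined; the
across-lipid default matches how a per-lipid order distribution is usually
summarized, and the axis is a parameter. Phase classification is strict:
aggregate S > 0.7 is ordered, S = 0.7 is disordered. Sterols never enter
tilt or order computations (they have no acyl-chain template here).

## Sterol depth, tilt and density profiles

Insertion depth Δz uses per-leaflet phosphate references (not the global
midplane), mirroring lower-leaflet values so that negative Δz always means
buried toward the bilayer center — the sign convention is ours and is stated
on every output. Sterol tilt uses a topology-declared ordered atom pair
(head, tail) for the ring axis — C3/C17 by default — because no single atom
pair is canonical; the headward orientation fixes the hemisphere and angles
are folded into [0°, 90°] as a guard against mis-oriented inputs. Density
profiles are plain number densities of named reference atoms, accumulated on
z-bins relative to the per-frame phosphate midplane and normalized by
box area × bin width × frame count; the default 0.1 nm bin resolves phosphate
peaks without starving counts. Electron/mass densities are not computed.

## Lateral segregation statistic

The neighbor criterion is nowhere given in the source analyses, so it is
explicit and tunable here: two lipids are neighbors when their reference
atoms (phosphate; sterol C3) lie within a 2D minimum-image distance of
1.0 nm in the same leaflet — a cutoff at the first coordination shell for
typical lipid areas. The per-lipid statistic divides DPPC neighbors by
*phospholipid* neighbors; sterols are never counted in the denominator.
Centers with zero phospholipid neighbors have an undefined ratio; they are
excluded from the frame mean and reported in a diagnostics counter. Both
leaflets are pooled. The key robustness property, verified in the tests, is
that under uniformly random placement the expected fraction equals the DPPC
share among phospholipids *for any cutoff*, so the 0.4 random-mixing
calibration does not depend on the criterion; the 0.95 complete-segregation
value of a 20×20 patch, by contrast, is a lattice-geometry number (interior
18² sites see 4/4 DPPC, 72 edge sites 3/4, 4 corners 2/4) and the 0.9
reference level should be read as geometry-dependent.

Time series report the mean over the last ⌈25%⌉ of frames with a blocking
standard error (below); shorter-than-8-frame tails fall back to the naive
SE, and a constant tail reports SE = 0.

## Blocking errors

`blocking_se` implements successive pair averaging: at each level the series
is replaced by means of consecutive pairs and the naive SE of the blocked
series recorded, together with its own uncertainty SE/√(2(n−1)). The
reported error is the plateau value — the first level whose successor's SE
stops increasing by more than that uncertainty (the larger of the two level
values is returned); if no plateau appears before fewer than 4 blocks
remain, the maximum over levels is returned and the result flagged
unconverged. On iid Gaussian series of length 1024 this lands within a few
percent of σ/√N; on AR(1) series at ρ = 0.9 and N = 2¹⁴ it recovers the
closed-form inflation √((1+ρ)/(1−ρ)) to well within 25%.

## Hill fitting

y(c) = B_max·cⁿ/(Kⁿ+cⁿ) is fitted by unweighted least squares (per-point
SDs switch on weighting) in linear response space, since no transform is
prescribed for the data this reproduces. Initialization: B_max⁰ = max
response, K⁰ = interpolated half-max concentration, n⁰ = 1; bounds keep all
three parameters positive. The problem is solved in normalized coordinates
(concentrations over their geometric mean, responses over their maximum)
with tight solver tolerances, which makes the fit equivariant under axis
rescaling to ~1e-8: scaling c by λ scales K by λ only, scaling y by μ scales
B_max (and its SE) by μ only, with n and R² invariant. Parameter SEs are
asymptotic (Jacobian-based covariance), matching the "value ± SE" reporting
convention; non-convergence sets a flag with diagnostics instead of raising.
`matched_noise_sd` inverts E[R²] ≈ 1 − (m−3)σ²/(SS_tot + (m−1)σ²) to find
the Gaussian noise level at which a design's expected R² equals a target —
used to run parameter-recovery studies at a reported goodness of fit.

## The synthetic bilayer generator

The generator produces *geometric constructions*, not sampled thermodynamic
states: no force field, no dynamics. It exists so that every analysis can be
validated against known imposed values.

* **Chains** are ideal zigzags whose i → i+2 segment directions are drawn
  independently: the leaflet chain axis rotated by a polar angle
  θ ~ N(0, `order_noise_sigma`) about a uniform azimuth. Carbon positions
  are built from two interleaved sub-chains so that *every* second-carbon
  segment realizes exactly one draw; the zigzag amplitude displaces odd
  carbons laterally (random azimuth per chain) and cancels out of all
  segment vectors. The expected order parameter is therefore
  E[P₂(cos θ)] — a closed sampling oracle the tests compare against.
  σ = 0 gives S = 1 up to the ~0.1° residual from measuring tilt with
  first-to-last-carbon vectors.
* **Lattice placement**: one lipid per square-lattice site (0.8 nm spacing,
  roughly the square root of a typical lipid area), which makes neighbor
  counts exactly enumerable for test oracles; the analysis-side neighbor
  criterion remains distance-based and lattice-agnostic. Mixing modes:
  uniformly random, checkerboard (two species 1:1), or a pre-formed square
  or disc patch. Species counts follow largest-remainder rounding of the
  mole fractions (exact to within one lipid per species). Both leaflets
  share the lateral assignment (leaflets in registry) but draw all geometry
  noise independently; phosphate planes are mirror-symmetric about the box
  midplane. The default composition is the 2:3 DPPC/DLiPC phospholipid mix
  of the patched segregation systems; the stated patch compositions are
  internally inconsistent between a 2:3 and a 3:2 reading, and 2:3
  (DPPC = 40% of phospholipids) is the only one consistent with the 0.4
  random-mixing level, so it is the default.
* **Sterols** are minimal three-atom bodies — C3 reference carbon placed at
  the phosphate plane plus the signed `sterol_depth_nm`, a C17 axis tail
  0.9 nm along the ring axis tilted by `sterol_tilt_deg` from the inward
  normal at uniform azimuth, and an R1 ring-centroid proxy — because every
  in-scope statistic touches only reference atoms. Default depth −0.45 nm
  and tilt 15° are typical cholesterol values in fluid PC bilayers.
  A small Gaussian z-jitter (`head_jitter_nm`, default 0.02 nm) on
  phosphates and sterol bodies gives profiles finite width and depth series
  nonzero variance; set it to 0 for exact-arithmetic tests.
* **Trajectories**: chain/sterol jitter is redrawn independently every
  frame; lateral correlation is carried by the species field. An exact
  AR(1) law cannot be imposed on a statistic of a discrete lattice, so two
  Markov schemes approximate it. Random mixing uses a cumulative
  random-transposition chain — the uniform assignment is its stationary
  distribution, so the neighbor-fraction series is stationary and ergodic
  with mean at the composition fraction; the number of transpositions per
  frame is solved from the requested lag-1 autocorrelation ρ via the
  single-site survival probability and the pair-statistic correction
  (a²(1−p) + 2ap)/(1+p). ρ = 0 reshuffles every frame. Patch and
  checkerboard modes instead keep the base configuration as an anchor and
  maintain a small pool (4% of sites) of transient transpositions, each
  retained per frame with probability ρ — mean-reverting fluctuations that
  preserve the ordered arrangement indefinitely. The measured lag-1
  autocorrelation tracks ρ to within a few percent, which places the
  blocking-SE inflation within the tested 25% of the AR(1) closed form.

What passing tests on this substrate show: that the estimators recover
imposed order, depth, tilt, mixing state and temporal correlation, with
correct error bars, units and conventions. What they do not show: anything
about force-field accuracy, sampling convergence, chain isomerization,
headgroup chemistry, membrane undulations or electrostatics — none of which
the generator models. Analyses of real MD data stand on the estimator
definitions above, not on the generator.

## Problem sizes in the test suite

The suite validates on deliberately small systems — lattices of 3×3 to
40×40 sites per leaflet, trajectories of 3–64 frames, blocking series up to
2¹⁴ points, 200 isotherm replicates — sizes at which the oracle computations
(brute-force loops, exact lattice counts, Monte-Carlo expectations) are exact
or tightly convergent. Statistical assertions use 3σ bands around the
oracle value with fixed seeds throughout; seeds enter every stochastic
component through `numpy.random.default_rng`.

## Known limitations

* Planar bilayers only; leaflet assignment by global midplane fails for
  curved or porated membranes.
* Wrapping on load assumes molecules are whole in the input files; chains
  split across the z boundary would corrupt tilt vectors (lateral splits are
  handled by minimum image).
* The segregation statistic's "complete segregation" level depends on patch
  geometry and neighbor criterion; only the random-mixing level is
  criterion-free.
* Blocking SEs need series much longer than the correlation time; the
  unconverged flag should be checked on short tails.
* No S_CD (C–H deuterium) order parameters: the segment definition here is a
  carbon-backbone angle, which is related but not identical.
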