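# Methods

This note documents the models, numerical choices and limitations behind
`protonspot`. It describes what the code computes; every number quoted here
is produced by the test suite or the worked example, not asserted from
elsewhere.

## Delivery-error model of the generator

A delivered spot is modelled as

    delivered_xy = planned_xy + systematic(gantry, E) + N(0, σ_xy)  [+ layer offset]
    delivered_MU = planned_MU · (1 + ε),   ε ~ N(0, f_MU), clipped at −0.9

with the spot split into `P` pulses: pulse target values equal the plan,
pulse actual positions scatter zero-mean (σ_jitter) about the delivered
position, and the delivered MU is divided equally over pulses so that the
pulse actual MUs sum to the delivered MU exactly (the generator applies MU
noise at spot level and distributes it proportionally, because pulse-level
MU statistics are not an observable we model). Zero-mean jitter makes the
MU-weighted aggregation unbiased, so the aggregation tests are exact for
zero-jitter truths.

Defaults (one-time choices, in units of mm unless noted): systematic
x = 0.6, y = −0.8 — order 1 mm or below, larger inplane than crossplane, as
delivery records from compact PBS systems show; random σ_x = 0.30,
σ_y = 0.35; MU noise 2 %; pulse jitter 0.05. The systematic terms may be
callables of (gantry angle, energy) for angle-dependent studies. An
optional layer-level shared offset exists but defaults to zero: whether
delivery errors correlate within an energy layer is not observable in the
data we emulate, so independence is the default and the knob makes the
assumption testable.

QA grids: 11 × 11 nominal positions at 20 mm pitch; the "recorded" (log)
position carries the truth's error; the "measured" position adds isotropic
detector noise (default SD 0.15 mm, chosen well under the millimetre-scale
disagreements QA reports) and is quantized to the 0.5 mm detector
resolution. Note an implication tested in the suite: because the simulated
log records the true delivered position, recorded-minus-measured Δ has
near-zero mean — the QA statistic measures log/detector agreement, not the
delivery error itself.

## Synthetic plans

Plans are generated on voxel phantoms (default 44³ voxels at 2.5 mm,
water-equivalent background, spherical CTV of radius 20 mm, a spherical
OAR, and a bone-like slab of RSP 1.8 and 24 mm thickness upstream of the
target). The slab matters: with parallel beams and a flat, homogeneous
phantom, a rigid setup shift along the beam axis cannot change any
structure's radiological depth (translation invariance), so range
sensitivity enters only through the ±3.5 % stopping-power scenarios — and
the slab amplifies the absolute range error they produce, as real
heterogeneity does.

Per beam, spots sit on a regular lattice (9 mm pitch) covering the CTV's
beam's-eye-view outline dilated by the lateral margin; energy layers step
in water-equivalent path length (WEPL, 5 mm pitch) *downward from the
distal edge*, so a zero distal margin places the deepest Bragg peak exactly
on the distal target boundary; the aperture polygon is the outline dilated
by the aperture margin (static, or per-layer for the dynamic mode). Spot
weights are then set by bounded least squares (non-negative, lightly
ridge-regularized, `scipy.optimize.lsq_linear`) toward a uniform unit dose
over the CTV dilated by the coverage margin and clipped in depth by the
range margins — a deliberately simple stand-in for the treatment-planning
system's intensity optimization that shapes real input plans. Near-zero
weights are pruned (keeping at least one spot per layer); the hottest spot
is scaled to 2 MU so plan features stay inside the training corpus's MU
range.

Presets:

* `two_beam` — two near-anterior beams (gantry 345°/15°), static aperture,
  15 mm coverage/lateral/range margins, 5 mm robustness shift;
* `six_beam` — six beams on the RAO/LAO/LPO/RPO/LL/RL pattern, dynamic
  aperture, 3 mm shift, 5040 cGy(RBE) prescription;
* `zero_margin` — a single-beam plan with every margin zero: energy layers
  stop at the distal CTV edge (sharp distal gradient) and the spot lattice
  stops at the CTV outline. This is the deliberately non-robust member of
  the discriminating pair.

The margins are geometry, not tuning: a corner scenario displaces the
target by |(±5, ±5, ±5)| = 8.7 mm and ±3.5 % density moves the Bragg peaks
by ~3 mm at the phantom's distal WEPL (~90 mm), so a 15 mm margin covers
the perturbations with slack while a 0 mm margin cannot.

## Log dialect and aggregation

One UTF-8 CSV per beam: `# key=value` header lines (dialect version, date,
plan/beam ids, gantry angle, snout extension, total prescribed MU) followed
by nine columns per pulse (indices, energy, target/actual x, y, target/actual
MU). Parsing is strict: missing columns, negative MUs, non-finite
coordinates and non-contiguous spot blocks are rejected with the offending
line number. Floats are parsed with `float_precision="round_trip"` so
writer→parser is bit-exact.

Aggregation: delivered MU = Σ pulse actual MU; delivered position =
actual-MU-weighted mean (weights are *actual* MU — the quantity actually
delivered — not target). Spots with zero delivered MU have an undefined
position; they are flagged and excluded from model training but retained
for QA counts. Single-pulse spots take the pulse position verbatim, which
makes PLF round-trips (write predictions → parse → aggregate) exactly the
identity. Pseudo log files use one pulse per spot with target = planned and
actual = predicted.

## Error model (network and training)

Architecture 6→5→3: tanh hidden layer, linear output — the classic shallow
toolbox configuration for a smooth low-dimensional regression; 53 free
parameters. Inputs and outputs are standardized by training-split mean/SD.
The data are split 70/15/15 (seeded permutation; sizes round to 700/150/150
at n = 1000). Training is full-batch Levenberg–Marquardt on the
least-squares objective: solve (JᵀJ + λ diag JᵀJ) δ = −Jᵀr with adaptive λ
(÷5 on accepted steps, ×4 on rejections), validation loss checked after
every accepted step, early stopping after 20 non-improving checks (the
best-validation weights are restored), at most 200 accepted steps by
default. LM is the natural optimizer at this parameter count — the normal
system is a 53 × 53 solve — and converges in seconds on 5 × 10⁴ samples. A
quasi-Newton fallback (L-BFGS-B with analytic gradients and the same
validation-based stopping) is provided under the contract that all recovery
properties hold with either solver; the tests exercise both.

Reported metrics come from the held-out test split only: MSE on
standardized targets, overall R² on both standardized and raw scales, and
per-output raw R². Raw-position R² is dominated by the large dynamic range
of spot positions (±100 mm) relative to millimetre errors and is therefore
very close to 1 whenever the fit is sane; the standardized metrics are the
informative ones, and both are reported for that reason. Models serialize
to JSON (architecture, normalization, weights, metrics); JSON floats
round-trip exactly, so a reloaded model predicts bit-identically.

One global model covers all gantry angles and energies (they are features),
and MU is predicted jointly with position — three standardized outputs with
equal weight, since no per-output weighting is better motivated.

## Dose engine

Per spot: dose = c · MU · DD(wepl) · G(lateral; σ), with

* range-energy law R(E) = α E^p, α = 0.0022 cm/MeV^p, p = 1.77 (the
  standard power-law fit to proton range in water);
* depth dose DD: a rising plateau shaped by a sigmoid cut at R, plus a
  Gaussian Bragg peak at R with width max(3 mm, 0.02 R) (straggling grows
  with range) and peak-to-plateau ratio 3;
* lateral term G: normalized 2-D Gaussian, σ²(E, d) = σ_air²(E) + (0.04 d)²,
  σ_air(E) = 10 mm · (150/E)^0.5 — anchored at σ ≈ 10 mm for 150 MeV in air
  at isocenter, growing toward lower energies;
* radiological depth from a single central ray per spot (1 mm sampling,
  trapezoidal WEPL accumulation) — adequate because the phantoms are
  piecewise-uniform with interfaces normal to the dominant beam directions;
* calibration c = 1.1 cGy(RBE)·mm²/MU: a constant RBE of 1.1 folded into an
  otherwise arbitrary scale, since plan normalization (below) removes the
  absolute calibration.

Because G is a normalized density, the lateral integral at fixed depth
equals c·MU·DD — a quadrature identity the tests check to 1e−3 (the
accumulation truncates at 6σ, losing < 1e−7 of the mass). Doubling MU
doubles every voxel dose bit-exactly (linearity). The Bragg-peak depth is
monotone in energy and scales as 1/(1+f) under a density scale 1+f, exactly
in WEPL and to interpolation tolerance in geometry.

Scenarios displace the beam isocenters (structures fixed — equivalent to a
rigid setup error for lateral components; see the slab discussion above for
the along-axis subtlety) and scale all voxel RSPs before ray tracing.

Aperture: a spot is kept iff its centroid is inside or on the polygon
boundary (shapely `covers`; boundary-inclusive). Deleted spots deposit no
dose — mirroring TPS behaviour for centroids outside the aperture — and
their MU is reported as unmodelled underdose; the real patient would
receive part of that dose through the aperture edge, which this engine does
not model.

Normalization: all spot MUs are scaled by one global factor so D99 % of the
CTV equals the prescription; the engine's linearity makes the factor exact
(prescription / current D99), verified to 0.1 cGy and cross-checked against
a bisection oracle in the tests. The predicted-spot plan reuses the
clinical plan's frozen factor — no re-normalization — so delivery errors
show up as coverage changes rather than being normalized away.

## DVH and indices

Cumulative DVHs count voxels at or above each dose edge (default bin 1 cGy
in the library, 2 cGy in the pipeline — interpolation error well under the
printed index precision). D_p% and D_vcc read the sorted-descending dose
profile at the requested cumulative volume with fractional-voxel linear
interpolation; a request within the hottest single voxel returns that
voxel's dose (so "dose to the hottest 1 cc" with 1-cc voxels is the maximum
voxel dose, and D99 % of a uniform dose is that dose). V_d counts voxels
directly. When an absolute-volume index spans fewer than 3 voxels
(e.g. D0.03 cc at 2.5 mm spacing, voxel = 0.0156 cc),
`index_resolution_limited` flags it as resolution-limited rather than
pretending sub-voxel accuracy.

Banded DVHs are pointwise min/max envelopes over the scenario curves on a
shared dose axis; nominal curves are carried alongside and may fall outside
the band, since the nominal scenario is not part of the perturbed set.
Worst-case tables take min/max per (structure, index) pair independently —
the scenario achieving one extremum need not achieve another — and record
the achieving scenario labels. Plan comparison is a signed per-cell
difference (b − a). The 95/95 verdict passes iff min over scenarios of
V(95 % Rx) ≥ 95 % with a boundary-inclusive threshold.

The default 16-scenario set interprets "isotropic ± shifts on three axes ×
± density" as the 8 simultaneous-corner shifts × 2 density scales; this is
one of two defensible readings, so an `axis_aligned` mode (6 single-axis
shifts × 2 densities = 12) is exposed and the corner composition should not
be assumed when comparing worst-case tables against external ones. Whether
shifts should combine with density errors or be evaluated separately is
likewise configuration, not doctrine.

## Pipeline

Stages synth → qa → train → predict → dose → robust → report, each writing
a manifest (seed, SHA-256 of inputs, outputs) so reruns are byte-for-byte
reproducible; all randomness derives from one global seed through named
substreams (`synth-plan`, `synth-corpus`, `split-train`, …). Default
problem sizes — 6 000 corpus spots, a ~1 100-spot two-beam plan on a 44³
grid, 16 + nominal scenarios for two plans — were chosen so a full
`run-all` completes in minutes on one core; the structure of the outputs
does not depend on these sizes, and the acceptance tests use 5 × 10⁴ spots
where the recovery tolerances require it.

## What the synthetic data does and does not show

The generator emulates the *structure* of the problem — pulse→spot
bookkeeping, a learnable low-dimensional error map, aperture trimming,
scenario dosimetry — with known ground truth, so passing tests demonstrate
the machinery is correct and the statistics are implemented as defined.
It does not emulate: real log dialects (hundreds of vendor columns), beam
current/timing, angle-dependent detector sag, anatomical heterogeneity
beyond a slab, nuclear halo or aperture-edge scatter dose, Monte Carlo
transport, fractionation or motion interplay. Dose conclusions are
therefore *relative* statements about plan robustness under the stated
error and uncertainty models, not absolute clinical dosimetry, and
agreement with any published clinical table can only be qualitative.

Other known limitations: the conformal weighting is a convex least-squares
surrogate, so synthetic plans are smoother and less degenerate than MFO
plans from a commercial optimizer; the QA Δ statistic cannot separate
random from systematic error sources; and the D0.03 cc analogue on the
default grids is resolution-limited as flagged.
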