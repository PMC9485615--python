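# Methods

This note documents the models, numerical choices and limitations of
`vmhsim`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## The virtual-helmet idea

MEG sensors are not fixed to the scalp. If the same class of activity
(e.g. averaged interictal spikes) is recorded at several head positions and
all recordings are expressed in one head frame, the data behave as if one
static head had been observed by the union of the sensor arrays — a
*virtual MEG helmet* with `248·n` channels for `n` head positions. The
richer sampling can help source estimation, but each position gets `1/n` of
the recording time, so the averaged noise floor rises by `√n`. The package
quantifies this trade-off in controlled simulations where the ground-truth
sources are known.

## Geometry

**Head model.** A homogeneous conducting sphere of radius 95.5 mm centred
at the head-frame origin. All rotations are about axes through this origin
and are applied before translations.

**Base array.** The physical 248-channel magnetometer helmet the study
design references has no published sensor coordinates, so the package ships
a synthetic stand-in: 248 point magnetometers on a Fibonacci lattice
covering a spherical cap of radius 120 mm from the +z vertex down to
z = −15 mm, oriented radially inward. This reproduces whole-head coverage
and a realistic vertex standoff (24.5 mm) while being fully deterministic.
Consequences: quantities tied to the real layout — per-helmet effective
ranks, best-helmet percentages, exact improvement figures — differ from the
original study's printed values and are treated as reference points, not
test targets. User-supplied layouts can be loaded from a TSV file
(label, x, y, z, ox, oy, oz).

**Transforms and catalog.** A rigid transform is parameterized by three
rotation angles (degrees, composed as `R = Rz·Ry·Rx`, extrinsic head axes —
the composition order is a convention the package fixes and documents, and
`counter_transform` converts a head movement into the equivalent sensor
counter-movement) plus a translation in mm. The catalog holds the standard
helmet and 13 VMHs built from ±20°/±15 mm movements (serials 1–14; serial
11 = VMHa with arrays at identity and (20,20,20)°/(15,15,15) mm; serial
14 = VMHb adding (−20,−20,−20)°/(−15,−15,0) mm). A helmet is excluded if
any sensor comes within `radius + margin` of the origin (margin defaults to
0 mm — touching the sphere counts as a clash). None of the 14 shipped
entries clashes with the default head.

## Source space

Three concentric icosphere layers (icosahedron subdivided 3 times, 642
vertices each, projected to radii 65/75/85 mm — 10 mm apart, mean in-layer
nearest-neighbor spacing ≈ 9.2/10.6/12.0 mm). Points below the ears are
removed by a cut plane at z = −10 mm (the original exclusion used subject
ear landmarks that are not recoverable; the plane height is configurable).
The default grid retains 1093 of 1926 points.

Each point carries two orthonormal tangent vectors
(`e1 = normalize(ẑ×r̂)`, pole fallback `x̂×r̂`; `e2 = r̂×e1`); no radial
component is ever defined because a spherical conductor is magnetically
silent to radial currents. Random dipole sets draw k distinct grid indices
uniformly and coefficients `(q1, q2) ~ U(0.5, 1)` (non-negative as
specified; orientation diversity comes from the basis geometry).

**Neighbors.** Per point: first-ring tessellation neighbors, those
neighbors' first rings, and the nearest point on each other layer (4–20
neighbors on the default grid). Robustness cases move each placed dipole to
one of its neighbors (Cartesian product across dipoles, deduplicated,
optionally subsampled — default cap 16 cases — with a seeded draw) and
scale each coefficient by an independent factor in [0.8, 1.2].

## Forward model

The closed-form field of a current dipole in a homogeneous sphere centred
at the origin (Sarvas' formula), projected on each sensor's orientation.
Sensors are ideal point magnetometers (no coil integration). The `μ0/4π`
prefactor is folded into a global scale: every downstream quantity
(correlations, ratios, ranks, distances) is scale-invariant, so units are
arbitrary-but-consistent. Gain matrices are `(248·n) × 2P` with array-major
rows and point-major `(e1, e2)` columns. The implementation is verified in
the tests against an independent literal transcription of the closed form
(1e-10 relative) and against the model identities: radial-moment silence,
linearity, and joint-rotation equivariance.

**Effective rank.** Number of singular values above 0.1 % of the largest,
computed on the raw gain. On the synthetic geometry the standard helmet
gives 242 and every 2-array VMH exceeds it (e.g. serial 2 gives 279);
the original study's 214 / 285–352 depend on the real layout.

## Noise model

Let `f` be the target noise fraction (0.1 or 0.3 by default).

- Technical noise: `TN ~ k·N(0,1)` i.i.d. per channel, with
  `k = f · (1/3) · 0.75 · mean std(signal)`. The 1/3 is an additive-std
  bookkeeping share (`std(TN) = std(ON)/3`), and 0.75 is the analytic mean
  of the U(0.5, 1) amplitude range. The signal reference is the Monte-Carlo
  mean (1,000 draws) of the per-draw std of the standard-helmet field of
  three simultaneously active unit dipoles (unit coefficients on both
  tangent vectors; the 0.75 weight is applied analytically in `k` rather
  than drawn).
- Brain noise: `BN = Gain · (c·N(0,1) over source components)` with
  `c = 2·std(TN) / mean std(BN | standard helmet)` (1,000 Monte-Carlo
  draws), which enforces `std(BN) = 2·std(TN)` on the standard helmet.
  Both constants are always calibrated on the standard helmet and reused
  unchanged for every VMH, so helmets differ only through their gains.
- Overall noise: `ON = √n · (TN + BN)` — the √n models the reduced
  per-position averaging time. This identity holds bit-exactly per
  realization.

Because TN and BN are independent, the realized sum has
`std(TN+BN) = √5·std(TN)`; the 1/3 share is a convention inside `k`, not an
emergent property, and the tests assert both facts separately. For VMHs the
brain-noise source vector is drawn independently per constituent array by
default (separate recording sessions see independent background activity);
a single-draw mode (one source vector through the full VMH gain, as the
scaling formula literally reads) is available via `bn_mode` and yields the
same calibration target. The acceptance script reports the realized
`std(BN)/std(TN)` ratio (≈ 1.97 at 500 realizations, target 2 ± 5 %).

Calibration draws scale linearly in `f`, so the experiment drivers
calibrate once and rescale per level; calibrations serialize to JSON for
replay.

## Inverse model

Sequential dipole fit (SDF): for every grid location solve the
overdetermined `channels × 2` least-squares problem for `(q1, q2)`, form
the estimated field, and select the location with the highest squared
Pearson correlation (mean-removed; computed over the whole array — no
a-priori channel selection; ties break to the lowest grid index). Subtract
the selected dipole's fitted field and repeat on the residual, at most 6
times, stopping early when the residual falls below 1e-12 of the input
norm. Candidates with coefficient norm below 0.3 of the strongest are then
discarded.

Numerics: the per-location normal matrices are formed and (pseudo-)
inverted once per gain (`LeadfieldSolver`), so a scan costs one `Gᵀr`
product plus O(P) arithmetic; correlations are computed from sufficient
statistics without materializing the P estimated fields. Degenerate tangent
pairs (near-singular 2×2 normal matrix) fall back to the pseudo-inverse,
giving the minimum-norm solution. Whether correlation should be computed
mean-removed is not externally fixed; Pearson is the package's choice and
the brute-force oracle in the tests uses the same convention.

The forward and inverse solvers deliberately share one model (the "inverse
crime"): the point is to isolate helmet-geometry effects, not to benchmark
solver realism. Noiseless single dipoles are recovered exactly (200/200 in
the acceptance suite) — results for multiple dipoles and noise are not
trivial in this design.

## Evaluation

Solved dipoles are matched to placed dipoles by minimum-total-distance
optimal assignment (Hungarian algorithm; a greedy mode exists for
sensitivity checks). Exactly `min(n_placed, n_solved)` pairs form; missing
and superfluous dipoles do not enter the distance mean. A trial with no
solved dipoles has an undefined mean distance: it is excluded from distance
averages and counted separately (`n_no_solution`).

Best-helmet precedence: rank by `|n_solved − n_placed|`; at equal deviation
missing beats superfluous; within the winning class the lowest mean
distance wins; exact ties all win. This generalizes the enumerated
same/−1/+1 ladder of the original scheme to arbitrary deviations.
Robustness of a helmet for a configuration = percentage of neighbor cases
on which it is among the best.

The permutation test (difference of means, add-one correction) is the only
significance machinery shipped; ANOVA/Tukey analyses are out of scope.

## Experiments

All drivers derive every random stream from a master seed via
`SeedSequence` spawning keyed by (part, condition, trial/pair, helmet), so
the placed set of a trial is identical across compared helmets and full
runs are bit-reproducible. Default replication counts are reduced to desk
scale — Part I 200 trials/condition, Parts II–III 50–100 pairs with at most
16 neighbor cases per pair — chosen so each part completes in minutes on
one CPU; the modelled conditions (noise levels, dipole counts, helmet set)
are unchanged by this choice.

- **Part I** (standard, VMHa, VMHb × 1–5 dipoles × noise 0/0.1/0.3):
  at 200 trials, 3 dipoles, noise 0.1 the VMHb mean distance error is
  11.4 mm vs 13.7 mm for the standard helmet (one-sided permutation
  p ≈ 0.001); at noise 0.3 the advantage vanishes (p ≈ 0.25) and
  superfluous solutions appear. Noiseless single dipoles are perfect for
  every helmet.
- **Part II** (14 helmets × dipole pairs at noise 0.1): helmets that are
  best on the original pair remain best on far more neighbor cases than
  helmets that are not (at 50 pairs: mean robustness ≈ 66 % vs 28 %,
  permutation p < 1e-3) — a helmet's suitability for a source pair is a
  stable property of the pair's neighborhood, which is what makes
  personalization from a prior possible. Effective ranks are reported
  alongside (optional, `compute_rank`).
- **Part III** (personalization): stage 1 localizes each pair with the
  standard helmet; stage 2 forward-projects the stage-1 estimate (its
  solved locations and coefficients verbatim) and its jittered neighbors,
  scores every candidate VMH (standard excluded by default to avoid biasing
  toward the stage-1 helmet; includable via config), and selects the VMH
  best on the most cases — partial ties resolved by a seeded uniform draw
  (`tie_sweep` re-draws them N times for sensitivity), full ties flagged
  "no preference" with no selection; stage 3 scores the selected helmet on
  the true pair. At 50 pairs / seed 1: 13 no-preference cases; excluding
  them, the personalized VMH improves mean error by ≈ 38 % over the
  standard helmet (one-sided permutation p < 0.05), the single best VMH by
  ≈ 53 %, and the per-pair oracle ("theoretical personalized", a ceiling
  computed with knowledge of the truth) by ≈ 75 %. For all-pairs summaries
  the personalized scheme falls back to the standard helmet on
  no-preference cases, since no movement instruction would be issued.

## Degenerate inputs and edge cases

Non-finite transforms, sensors inside the head at construction of
admissible arrays, dipoles on or outside the sphere, out-of-range grid
indices, zero-variance fields, mismatched vector lengths, and invalid
tolerances/margins all raise `ValueError` early. An all-zero gain has
effective rank 0. `k = 0` (f = 0) short-circuits to noiseless simulation.

## Known limitations

- Single-sphere conductor and point magnetometers only; no BEM/multi-sphere
  heads, coil integration, or EEG.
- The synthetic base array is a stand-in: all layout-bound printed
  reference values (ranks 214–352, 1,084 retained points, 29 % standard
  best-rate, 18/100 no-preference, ≈ 24.8/36.4 % improvements) are
  reproduced in direction and structure, not digits. On this geometry one
  helmet can exceed a 50 % best-rate, which the original layout did not
  show.
- Grid-restricted dipole fitting (no off-grid nonlinear refinement) and no
  distributed inverse solvers.
- White Gaussian noise without temporal structure; no empty-room or
  physiological artifact models.
- Passing tests demonstrate correctness of the simulation machinery and the
  direction of the helmet-comparison effects under these idealized
  conditions, not performance on real MEG recordings.
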