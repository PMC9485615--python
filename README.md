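# vmhsim

Simulation framework for **virtual MEG helmets** (VMHs): composite
magnetometer arrays built by recording the same brain activity at several
head positions and mapping all recordings into a single head frame, so that
one head position is effectively observed by `248·n` sensors. The package
answers a sensor-array design question: *does the richer spatial sampling of
a VMH improve equivalent-current-dipole source localization, and can a VMH
be tailored to a specific patient's sources from a prior recording?*

Intended users: MEG methods researchers and simulation-minded
clinicians/engineers studying sensor-array optimization for source
estimation (e.g. presurgical epilepsy workups with averaged interictal
spikes).

## What it implements

- **Geometry** — a synthetic 248-channel whole-head magnetometer cap
  (Fibonacci lattice, 120 mm shell, radially inward sensors), rigid
  counter-movements (`Rz·Ry·Rx` rotations about the head origin, then
  translations), VMH assembly, head-clash exclusion against the spherical
  head model (r = 95.5 mm), and a catalog of 14 helmets (standard, twelve
  2-array VMHs, one 3-array VMHb) built from ±20° / ±15 mm movements.
- **Source space** — a three-layer icosphere grid (radii 65/75/85 mm, 642
  points per layer before a below-the-ears cut at z < −10 mm), per-point
  orthonormal *tangential* dipole bases (a homogeneous sphere is silent to
  radial currents), uniform dipole draws with amplitudes in U(0.5, 1), and a
  neighbor graph (first + second tessellation ring in-layer, nearest point
  per other layer).
- **Forward model** — the closed-form magnetic field of a current dipole in
  a homogeneous conducting sphere,

  `B(r) = (F·(Q×r₀) − ((Q×r₀)·r)∇F) / F²`,  `F = a(ra + r² − r₀·r)`,

  projected on each sensor orientation; gain matrices `(248·n) × 2P`; SVD
  effective rank at a 0.1 % singular-value tolerance.
- **Noise model** — technical noise `TN ~ k·N(0,1)` per sensor and brain
  noise `BN ~ Gain·(c·N(0,1))` over grid sources, with k and c Monte-Carlo
  calibrated on the standard helmet so that `std(BN) = 2·std(TN)` and the
  overall noise `ON = √n·(TN + BN)` is a chosen fraction f of a reference
  signal.
- **Inverse model** — sequential single equivalent-current-dipole fitting:
  per-location 2-column least squares, selection by highest squared Pearson
  spatial correlation, residual subtraction, at most 6 iterations, pruning
  below 0.3 of the strongest magnitude.
- **Evaluation** — optimal one-to-one placed/solved matching (unmatched
  dipoles excluded from the distance mean), a best-helmet precedence scheme
  (dipole count over distance; missing over superfluous), neighbor
  robustness, and a permutation test utility.
- **Experiments** — Part I (standard vs VMHa/VMHb over 1–5 dipoles × noise
  levels), Part II (catalog-wide robustness on dipole pairs), Part III
  (three-stage prior-based personalized VMH selection).

## Worked example

```python
import numpy as np
from vmhsim import (HeadModel, build_grid, calibrate, gain_matrix,
                    helmet_catalog, synthetic_helmet, random_dipoles,
                    simulate_measurement, sequential_dipole_fit, match_dipoles,
                    effective_rank)

head = HeadModel()                       # r = 95.5 mm sphere at the origin
grid = build_grid(head)                  # 1093 grid points, 3 layers
helmets = {h.serial: h for h in helmet_catalog(synthetic_helmet(), head)}

g_std = gain_matrix(helmets[1], grid, head)    # (248, 2186)
g_vmhb = gain_matrix(helmets[14], grid, head)  # (744, 2186)
print(effective_rank(g_std), effective_rank(g_vmhb))

rng = np.random.default_rng(1)
cal = calibrate(g_std, f=0.1, n_iter=1000, rng=rng)
placed = random_dipoles(grid, 3, rng)
meas = simulate_measurement(g_vmhb, placed, cal, rng)
fit = sequential_dipole_fit(g_vmhb, meas)
res = match_dipoles(placed, fit, grid)
print(res.n_solved, round(res.mean_distance_mm, 1))
```

prints

```
242 297
3 0.0
```

i.e. the three-array VMHb offers 297 effectively independent leadfields
versus 242 for the standard helmet; in this noisy three-dipole trial it
recovers all three sources at their exact grid locations (0.0 mm mean
error).

The same comparison at scale (`run_part1`, 200 trials, 3 dipoles, noise
0.1) gives mean distance errors of 11.4 mm (VMHb) versus 13.7 mm
(standard); at noise 0.3 the advantage disappears and superfluous dipoles
appear. The personalization pipeline (`run_part3`, 50 pairs) improves the
mean error of preference cases by ≈ 38 % over the standard helmet.

Command line:

```bash
vmhsim catalog                 # list the 14 helmets
vmhsim rank --helmet 3         # effective rank of one helmet
vmhsim part1 --seed 7 --out results/   # CSV tables + run manifest
```

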