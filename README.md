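# rcspt

Quantitative single-molecule and spatial analyses for membraneless nuclear
compartments, built around the question of **how RNA Polymerase II (and other
DNA-binding proteins) become enriched in herpesvirus replication compartments
(RCs)** — by liquid–liquid phase separation, or by transient nonspecific
binding to an unusually accessible viral genome.

The package provides, as a tested, reusable library with a CLI:

- **Two-state jump-length kinetics** (`rcspt.kinetics`) — the core model.
  Single-particle-tracking (SPT) jump-length CDFs at lags of 1–7 frames are
  fitted to a mixture of an immobile ("bound", diffusion coefficient
  `D_bound`) and a freely diffusing population (`D_free`), with localization
  error σ and defocalization through an axial detection slab of depth `dZ`:

  ```
  P(r' ≤ r | lag n) ∝ Σ_X  w_X(n) · [1 − exp(−r² / 4(D_X·nΔt + σ²))],
  X ∈ {bound, free},  w_X(n) = F_X · Σ_{s<cap} Z_{n+s}(D_X, dZ)
  ```

  where `Z_k` is the absorbing-slab survival eigenseries and `cap` the
  per-trajectory jump cap. `TwoStateJumpModel(...).fit()` returns a results
  object with the estimates, SSE, per-lag jump counts and a `summary()`
  table; `subsample_fit` adds the 100×15-cell resampling uncertainty.
- **Trajectory plumbing** (`rcspt.tracking`) — greedy nearest-neighbour
  linking with gap closing, linear drift interpolation of hand-drawn
  nucleus/compartment polygons, inside/outside sorting (a single localization
  inside a compartment labels the whole trajectory "inside"), randomized
  mock-compartment placement for null controls, and boundary-crossing
  jump-length CDFs.
- **Diffusion anisotropy** (`rcspt.anisotropy`) — folded angles between
  consecutive displacements, mobility filtering (both jumps ≥ 150 nm,
  optional HMM bound-state removal) and the backward/forward fold statistic
  f(180°±30° / 0°±30°) with bootstrap errors.
- **Edge-corrected Ripley statistics** (`rcspt.spatial`) — the isotropic
  edge-corrected neighbourhood density N(r), K(r) = N(r)/λ and
  L(r) − r = √(K/π) − r for localization patterns inside polygons, with CSR
  envelopes and 25,000-detection subsampling.
- **FRAP / FLIP photokinetics** (`rcspt.photokinetics`) — double
  normalization of recovery traces and exponential photobleach correction
  (default rate 0.09 per frame) for loss curves.
- **Disorder segmentation** (`rcspt.disorder`) — 8-residue rolling-mean
  smoothing of per-residue disorder scores, segmentation at score > 0.55,
  and fraction-IDR from runs longer than 10 residues.
- **Genome-budget bookkeeping** (`rcspt.quantify`) — FISH copy numbers
  calibrated to a replication-blocked (PAA) single-genome condition, viral
  vs host DNA percentages and concentrations, ATAC accessibility enrichment,
  Poisson MOI estimation, and Feret aspect ratios of compartment outlines.
- **Synthetic data** (`rcspt.simulate`) — generators with the statistical
  structure the analyses assume (two-state Brownian motion in a polygonal
  nucleus observed through a 0.7 µm slab at 7.447 ms/frame with 45 nm
  localization error; CSR and Thomas-cluster point patterns; particle-based
  FRAP/FLIP traces; lognormal FISH intensities; piecewise disorder
  profiles), so every stage is testable without downloads.

## Worked example

Simulate SPT data for a Pol II-like protein (50% bound, D_free = 3.5 µm²/s)
and recover its kinetics:

```python
from rcspt import SpaSptSimConfig, simulate_spaspt, TwoStateJumpModel

cfg = SpaSptSimConfig(n_trajectories=5000, F_bound=0.5, D_free=3.5,
                      D_bound=0.005, seed=12)
trajs, truth = simulate_spaspt(cfg)
result = TwoStateJumpModel.from_trajectories(trajs).fit(seed=0)
print(result.summary())
```

```
Two-state jump-length model fit
===============================
trajectories: 5000
jumps per lag: {1: 12139, 2: 11031, 3: 10372, 4: 9975, 5: 9712, 6: 9559, 7: 9460}
restarts: 4   converged: True
SSE: 9.08282e-06

  F_bound  =   0.5008
  D_free   =   3.5684 um^2/s
  D_bound  =   0.0053 um^2/s
  sigma    =   0.0450 um (fixed)
  dZ       =   0.7000 um (fixed)
  dt       =   7.4470 ms (fixed)
```

The fitted bound fraction (0.501) and free diffusion coefficient
(3.57 µm²/s) recover the generating truth (0.5 and 3.5); `D_bound` ≈
0.005 µm²/s is the residual chromatin-like motion given to "immobile"
molecules.

The same pipeline runs end to end from the shell:

```bash
rcspt run --outdir demo --seed 7        # simulate → sort → fit → spatial stats
rcspt simulate --n 2000 --out trajs.csv
rcspt fit-kinetics trajs.csv --out fit.json
```

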