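# Methods

This note documents the models implemented in `rcspt`, their assumptions,
the choices made where the design was genuinely open, and what the synthetic
data generators do and do not emulate.

## Coordinate and file conventions

All internal coordinates are micrometres, 2-D, origin at the image top-left
with y increasing downward. Frames are 0-based; frame intervals are half-open
in time. Localization tables arrive in camera pixels and are converted on
read with a mandatory `pixel_size` (µm/px) — there is no safe default for the
camera scale, so it is a required configuration item. Polygon containment is
edge-inclusive everywhere: a point exactly on an edge counts as inside. This
tie-break is applied consistently by the sorting, anisotropy, spatial and
simulation code.

## Two-state jump-length model

**Model.** Each molecule is either immobile ("bound"; `D_bound` absorbs
residual chromatin motion) or freely diffusing (`D_free`), and does not
switch state within a trajectory. For a lag of n frames (t = nΔt) the jump
length r of a population with diffusivity D, observed with localization
error σ per coordinate, has CDF `1 − exp(−r²/(4(Dt + σ²)))`. Fits use
CDFs, not histograms, jointly over lags 1–7, each lag weighted by its jump
count; the empirical support is subsampled to ≤ 500 grid points per lag.
Bounded least squares (`scipy.optimize.least_squares`, trf) runs from three
stratified starts plus seeded random restarts; the lowest-SSE solution wins.
Bounds: `F_bound ∈ [0, 1]`, `D_free ∈ [0.5, 25] µm²/s`,
`D_bound ∈ [10⁻⁴, 0.08] µm²/s`; σ = 45 nm and dZ = 0.7 µm are fixed, not
fitted. Fits refuse < 100 trajectories and warn below 1000, the regime where
two-state fits become reliable.

**Defocalization.** Fast molecules leave the axial detection slab (depth
dZ), thinning the free population at longer lags. `defocalization_fraction`
computes the survival of a molecule diffusing axially in an absorbing slab,
starting from a uniform axial position, by the eigenfunction series
`Z(t) = Σ_{k odd} 8/(k²π²)·exp(−k²π²Dt/dZ²)`, truncated when terms fall
below 10⁻¹⁰. The series agrees with a Brownian-bridge-corrected Monte-Carlo
simulation to < 5×10⁻⁴ at the default parameters.

**Mixture weights.** Jump statistics retain at most the first `cap = 4`
jumps of each trajectory at each lag. The jump starting at frame s is
observed only if the molecule is still detectable at frame s + n, so the
expected number of observed lag-n jumps per molecule of diffusivity D is
`Σ_{s<cap} Z_{(n+s)Δt}(D)`, and this capped sum — applied to both
components and renormalized per lag — is the mixture weight used by
`two_state_cdf`. With cap = 1 it reduces to the single-window survival
`Z_n`. Using `Z_n` alone with capped multi-jump counting systematically
overestimates the bound fraction (by ≈ +0.16 at a true 0.5 under the default
simulation conditions), because immobile molecules contribute `cap` jumps
per lag while free molecules contribute roughly `Σ Z` — the capped sum is
the self-consistent correction and needs no empirical constants.

**Uncertainty.** `subsample_fit` draws 15 cells without replacement, pools
their trajectories, fits, and repeats 100 times (seeded); the median and SD
per parameter are reported. This mirrors how sparse per-cell data are
handled when single cells fall below the 1000-trajectory threshold.

**Identifiability limit.** At `D_free = 10 µm²/s` with `F_bound ≥ 0.5`, the
free population contributes < 5% of the capped jumps (Z₁ ≈ 0.18 and the
bound population holds 4 jumps per lag), and (F_bound, D_free) trade off
along a ridge: fits at 5,000 — and even 20,000 — trajectories can return
parameter pairs with *lower* SSE than the truth. Recovery to ±0.05 on
F_bound and 15% on D_free holds on the rest of the
{0.2, 0.5, 0.7} × {1, 3.5, 10} grid and is tested there. Users fitting
fast-diffusing, mostly-bound proteins should expect this degeneracy.

## Trajectory linking and compartment sorting

Linking is deterministic greedy nearest-neighbour: for a k-frame gap
(k ≤ 1 + gaps, default 1 gap) the search radius is
`r_max(k) = sqrt(4·D_max·k·Δt)` with `D_max = 10 µm²/s`. Candidate pairs are
linked smallest-distance-first with ties broken by detection row order, and
a trajectory whose search disc holds more than 3 candidates is terminated
rather than ambiguously linked. This replaces probabilistic multi-hypothesis
scoring with an auditable rule that honours the same radius, gap and
competitor limits; linking quality is not the scientific contribution here.

Annotations are drawn on the first and last frames of a movie; cell motion
over the acquisition is assumed linear, so each polygon vertex is
interpolated at fraction `frame/(n_frames − 1)`. Localizations outside the
interpolated nucleus are discarded; a trajectory is labeled "inside" if at
least one remaining localization falls inside any interpolated compartment
at its own frame.

**Mock compartments.** Library polygons are translated (rotation optional,
off by default) to uniform random interior positions and accepted when fully
inside the nucleus and disjoint from nucleoli, already-placed mocks and,
optionally, the real compartments; placement is seeded and fails loudly
after a configurable attempt budget.

**A caveat the mock control exposes.** The "touch" labeling rule is not
neutral with respect to mobility: a moving molecule sweeps more area than an
immobile one, so it is more likely to touch a compartment at least once.
On homogeneous synthetic data (50% bound, D_free = 3.5 µm²/s) with a 2.5 µm
mock in a 6 µm nucleus, P(labeled inside) is 0.171 for bound molecules
(exactly the area fraction) but 0.187 for free ones, and inside-labeled free
tracks are additionally length-biased. The fitted bound fraction inside
mocks is therefore depressed by ≈ 0.05 relative to outside — a real property
of the sorting rule, visible here because the resampling SD of clean
synthetic data (~0.01–0.02) is far smaller than the uncertainty of real
experiments. The relative touch excess scales like `2·d_eff/r_mock`
(d_eff ≈ 0.12 µm at these parameters), so it shrinks for large compartments
but never vanishes. The corresponding acceptance test is deliberately left
asserting the idealized equality and currently fails, documenting the
artifact rather than hiding it; interpretation of small inside-vs-outside
differences in bound fraction should keep this selection effect in mind.

## Angular anisotropy

For each trajectory, every gap-free three-point set defines a folded angle
θ = arccos(v₁·v₂/‖v₁‖‖v₂‖) ∈ [0°, 180°]. Only mobile segments are used —
both displacements must be ≥ 150 nm — because localization noise makes
immobile molecules look strongly anisotropic (their apparent steps are noise
vectors that reverse by construction). An optional 2-state Gaussian HMM on
log squared displacements (hmmlearn) removes bound-dominated trajectories
before the hard threshold, mirroring the two-criterion cascade used in
practice; on mixed data the cascade takes the fold from ≈ 4.3 (unfiltered)
to ≈ 1.2. The fold statistic is
`f = #{θ ≥ 150°}/#{θ ≤ 30°}` with a seeded 1000-draw bootstrap SD.
Angles are histogrammed in 5° bins by default.

Even for freely diffusing molecules the shared middle localization induces a
noise anti-correlation between consecutive displacement vectors, which
biases the fold upward (to ≈ 1.16 at D = 3.5 µm²/s, σ = 45 nm, Δt =
7.447 ms, after the 150 nm filter). The isotropy *null* is therefore stated
for ideal Brownian motion (σ = 0), where the fold is 1 within error; noisy
free motion retains this small, reproducible excess, as real SPT data do.

**Trap model.** For robustness tests, immobile trap points are scattered
(Poisson, configurable density); a free molecule whose step lands within the
capture radius (default 0.15 µm, about one free jump) snaps to the trap and
stays for a geometric number of frames (escape probability 0.8 per frame,
i.e. transient binding). Recapture after a one-frame excursion records a
near-reversal, so the fold grows with trap density — the signature of
repeated revisits to accessible DNA.

## Edge-corrected Ripley statistics

For detections P in a polygonal region, each ordered pair (i, j) with
d(i,j) ≤ r contributes weight `2π·d/C_in`, where C_in is the arclength of
the circle of radius d(i,j) centred on i lying inside the region; pairs
whose circle lies entirely outside are excluded with a warning. C_in is
computed analytically from circle–polygon edge intersections (angles sorted,
arc midpoints classified by containment); an angular-scan oracle with
bisection-refined crossings confirms the analytic values to ≤ 10⁻⁶ relative.
Then `N(r) = (1/N_p) Σ_i Σ_{j≠i} f(i,j,r)`, `K(r) = N(r)/λ` with
λ = N_p/area, and `L(r) − r = sqrt(K/π) − r`: 0 under complete spatial
randomness, positive for clustering, negative for regularity. CSR envelopes
are pointwise 2.5/97.5% quantiles over seeded conditional-CSR simulations
with the observed point count. Large patterns are summarized by 100 seeded
subsamples of 25,000 detections (mean ± SD per radius). Pair weights are
independent of r, so a full curve costs one weight computation. Radii below
~20 nm are dominated by fluorophore re-blinking in real data and should not
be interpreted; the radius grid is caller-controlled.

## FRAP and FLIP

Spot extraction from movies is an upstream contract; the module consumes
per-frame spot and reference intensities. FRAP traces are divided by the
whole-nucleus reference (cancelling acquisition photobleaching) and then by
the mean of the first 15 pre-bleach frames, so the pre-bleach level is 1 by
construction; the bleach is applied between frames 15 and 16 (0.956 µm
circle, 250 ms frames in the reference geometry). FLIP traces have no
internal reference; the global photobleaching is divided out as
`exp(−0.09·frame)` (rate configurable per frame) and the trace normalized to
its initial value, so a pure-photobleaching trace flattens exactly to 1.
Aggregation reports the pointwise mean flanked by SEM. No reaction–diffusion
model is fitted to FRAP curves — the curves themselves are the readout.

## Disorder segmentation

Per-residue disorder likelihoods (IUPred-compatible two-column TSV; the
predictor itself is not reimplemented) are smoothed by a centered rolling
mean of 8 residues. Even windows are centered left-heavy (position i
averages residues i−4 … i+3); edges shrink the window to the available
residues. Maximal runs with smoothed score strictly > 0.55 are reported as
disordered regions; runs *longer than* 10 residues (length ≥ 11 — the strict
reading, which shifts boundary proteins by one residue and is flagged here
deliberately) count toward fraction-IDR. Segmentation runs strictly after
smoothing, with no post-hoc merging.

## Genome budget, MOI, shape

Copy numbers divide each compartment's integrated FISH intensity by the
median intensity of the replication-blocked (PAA) condition, in which each
punctum holds exactly one genome; estimates are invariant to global
intensity rescaling. Budget arithmetic uses a diploid host genome
(2 × 3.2×10⁹ bp) — an upper bound for hypertriploid U2OS cells — and a
1.5×10⁵ bp viral genome; concentrations divide base pairs by measured
volumes (volumes are inputs; 3-D segmentation is out of scope). Accessibility
enrichment is the viral ATAC-seq read percentage over the viral percentage
of total DNA. Internally everything is full precision; `summary()` rounds to
2 significant figures for presentation. MOI is estimated from the uninfected
fraction under a Poisson infection model, `MOI = −ln(f_uninfected)`, with
the pmf exposed for checks; a sample with zero uninfected cells is rejected
with guidance rather than returning infinity. Compartment aspect ratios are
max/min Feret diameters via rotating calipers on the convex hull.

## Synthetic data: what it does and does not emulate

The spaSPT generator draws each molecule bound with probability `F_bound`,
evolves lateral positions by isotropic Gaussian steps (variance 2DΔt per
axis, Δt = 7.447 ms) inside the nucleus polygon, adds independent N(0, σ²)
localization noise per coordinate (σ = 45 nm), and truncates trajectories
when a hidden z-coordinate leaves the 0.7 µm slab. Axial absorption uses
Brownian-bridge crossing probabilities between frames so that it is
continuous in time and consistent with the eigenseries used in fitting;
checking |z| only at frame boundaries would overestimate survival by ≈ 0.03
per frame window at D = 3.5 µm²/s. Boundary handling mirrors an
out-of-bounds step across the nearest boundary point (clamping to the
boundary if the mirror also lands outside) — adequate for the tested
statistics, though not exact specular reflection. Trajectories last at most
`n_frames = 12` observations so that every lag 1–7 can host the full
4-jump cap. State switching is off by default (matching the fitting model's
assumption) but available via `p_switch`.

Not emulated: photoactivation sparsity, fluorophore blinking and bleaching,
camera noise, detection/linking errors, 3-D astigmatic PSFs, and cell-to-cell
biological variability (synthetic "cells" differ only by seed). Passing
recovery tests on these data therefore validates the estimators under the
model's own assumptions — they say nothing about detection artifacts, and
the resampling SDs on synthetic data are smaller than real-data
uncertainties (see the mock-control caveat above).

The point-pattern generator provides conditional CSR (exactly n uniform
points) and a Thomas cluster process (Poisson or fixed-count parents,
Gaussian offspring, offspring outside the region dropped). The recovery
simulator diffuses molecules in an idealized 2-D nucleus — one geometry
serves both the confocal FRAP/FLIP and the HiLo SPT contracts, a deliberate
simplification — darkening molecules in the bleach circle once (FRAP) or
every frame (FLIP), and reports fluorescent counts in the measurement circle
and whole nucleus, both multiplied by `exp(−bleach_rate·frame)`. FISH
intensities are copy_number × lognormal(mean, CV) with a PAA condition at
copy number exactly 1; disorder profiles are piecewise-constant with
truncated Gaussian noise.

## Reproducibility

Every stochastic routine takes an explicit seed and is a pure function of
(config, seed); the pipeline derives per-stage substreams from one global
seed via `numpy.random.SeedSequence`, echoes the full configuration into the
run log, and reproduces its text outputs bit for bit when re-run. Problem
sizes in the tests (e.g. 5,000 trajectories for recovery checks, 60–200 CSR
replicates for spatial nulls, 10⁶ jumps and walkers for Monte-Carlo oracles)
were chosen so the statistical assertions have comfortable margins on a
single CPU.
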