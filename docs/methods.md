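# Methods

This note records what the package computes, the assumptions behind each
stage, the defaults and why they are set where they are, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Trajectory simulation

A foraging agent moves in a square arena (side 2.2 box units, centered at
the origin) with Euler integration at τ = 0.02 s per step. Per step the
speed is drawn from Rayleigh(b = 2·0.13π units/s) and the heading from a
normal distribution centered on the previous heading; the stated rotation
rate σ = 2·5.76 is treated as a per-second quantity in radians, so the
per-step heading increment has sd σ·τ. Radians (not degrees) are adopted
because a ~6.6°/step jitter would produce nearly ballistic walks unlike
foraging paths; the choice is configurable (`MotionParams.heading_sd`).

Soft walls: within 0.03 of a wall, a heading within 90° of the outward
normal is reflected about the wall plane and the speed is damped by 0.25
for that step; a final hard clamp guarantees containment. The rule keeps
the "speed and heading statistics in free space" exactly Rayleigh/normal
(tested by KS at α = 0.01) while making the containment invariant hard.

Trajectories have T = 20 steps after the uniformly drawn initial position
and heading. `generate_batch` gives each trajectory its own seeded
substream (trajectory i is invariant to batch size); the training loop uses
the lockstep-vectorised `generate_batch_fast`, statistically identical.

## Place code

Position encoding follows the difference-of-softmax form with s1 = 0.12,
s2 = 2·s1, Np = 512 at paper scale (64 at desk scale). The raw difference
sums to zero across cells, so per location the activity is shifted by the
magnitude of its minimum entry and renormalised to sum to one — the only
location-wise rule that makes the vector a probability distribution while
preserving the stated functional form. Decoding is the unweighted mean of
the centers of the three most active cells; rank-3 ties resolve to the
lowest index. The empirical round-trip error ‖decode(encode(x)) − x‖ with
512 cells is ≈ 0.04 box units (the "baseline decoding error"); with 64
cells ≈ 0.11. Global remapping redraws all centers uniformly; per-cell
spatial correlation across environments is ≈ 0 by construction.

## Network and training

The ReLU RNN (no biases) is initialised Xavier-uniform with unity gain.
The initial state g₀ = W_e p₀ is linear (no ReLU), matching the model
definition; a flag can apply ReLU. The loss is time-averaged cross-entropy
**plus** λ‖W_g‖²_F — written with a minus sign in some statements of the
model, but a subtracted penalty would reward large recurrent weights,
contradicting its stated regularising role, so it is added here. Softmax
and logs use log-sum-exp stabilisation with an ε = 1e−12 clamp.

Gradients are hand-derived full BPTT through all 20 steps (T is small) and
verified against central finite differences to 1e−5 on small instances.
The optimiser is Adam with default moments. Two schedules exist:
`multi_env` (each minibatch split equally across environments) and
`continual` (environments presented in blocks).

Scale presets:

| parameter | paper | desk |
| --- | --- | --- |
| recurrent units Ng | 4096 | 256 |
| place cells Np | 512 | 64 |
| minibatches | 1e5 × n_envs | ~2000 total |
| learning rate | 1e−4 | 3e−3 |
| batch, T | 200, 20 | 200, 20 |

The desk preset is the configuration the test suite trains. Its learning
rate was chosen by a short sweep (1e−3 / 3e−3 / 1e−2 over 600 steps) for
best KL progress under the fixed desk step budget: with ~150× fewer
gradient steps than the full schedule, a proportionally larger rate is the
standard scaled-down-training adjustment. At desk scale the network
reliably shows the qualitative training signatures — KL divergence falls,
familiar-environment decoding error drops below the untrained level, novel
environments stay at the untrained level — but it remains far from
convergence: decoding error improves by ~10%, not to the baseline floor.
Consequences for downstream analyses are noted below.

## Synthetic grid modules

Ideal cells are the ReLU of three cosines with unit wave vectors at 0°,
60°, 120°, rotated by the module orientation. The real-space peak lattice
has spacing a = 2/(√3 f); "spacing = 1/f" is a loose convention — the
package reports the geometric lattice constant and the estimators are
validated against it. Phases are sampled uniformly in the Wigner–Seitz
cell of the peak lattice (regular hexagon, inradius a/2, vertices on the
0° + 60k° axes for θ = 0). Defaults: f = 1/0.838 (so a ≈ 0.968), 50 cells
per module at desk scale (604 available by config).

Remapping scenarios: identity; coherent phase shift (default (−0.2, −0.2));
coherent reorientation (default −5°); incoherent per-cell phase resampling;
incoherent per-cell rotation (uniform in (−π, π]). Coherent scenarios
yield unimodal shift histograms; incoherent ones near-uniform histograms
(circular-variance separation ≥ 0.5 in the tests).

## Spatial statistics

Ratemaps are per-bin means over trajectory visits (64×64 default, 32×32
for clustering inputs, which also drop the first 10 timesteps to avoid
initial-state transients); unvisited bins are missing (NaN), never zero.
Correlograms are per-lag Pearson correlations computed by FFT with
missing bins excluded pairwise and lags with < 20 overlapping bins masked.

* **Grid score** — annulus-masked autocorrelogram correlated with its
  rotations; score = min(60°, 120°) − max(30°, 90°, 150°), maximised over
  ten annulus outer radii (inner radius 20% of the half-size). Ideal grids
  score > 1, single plane waves < 0.3. Degenerate maps give NaN and are
  excluded from rankings.
* **Phase shift** — cross-correlogram local peak nearest the center (3×3
  local maxima after 1-bin Gaussian smoothing used for detection only),
  reported in box units. Sign convention: `phase_shift(a, b) = δ` when
  `b(x) = a(x − δ)`.
* **Orientation shift** — both autocorrelograms normalised by the absolute
  value of their sum (Pearson is scale-invariant; the absolute value
  guards against a sign flip when an autocorrelogram sums negative), then
  one is rotated in 1° increments over the largest common disk; the argmax
  rotation is the shift, ties resolving to the smallest magnitude. The
  30°-wrapped version is ((shift + 15) mod 30) − 15.
* **Spacing** — autocorrelogram peak distances sorted; the first difference
  exceeding mean + 2 sd marks the end of the innermost isodistant ring;
  the spacing is the median distance before the jump (all peaks when no
  jump). Matches 2/(√3 f) within one bin for f ∈ [0.8, 2.0].
* **Shift densities** — 2-d Gaussian KDE with Scott's-rule bandwidth.

Rotations of raster images use bilinear interpolation with precomputed
per-angle coordinate tables (shared by the grid score, orientation shift
and rotational fingerprints).

## Unit-type discovery

Each unit's rotational fingerprint is the vector of 360 Pearson
correlations between the central radius-16 disk of its **spatial
autocorrelogram** (z-scored) and rotated copies at 1° steps. The
autocorrelogram, not the raw ratemap, is rotated: it is centered by
construction, so the fingerprint is phase-invariant and shows the expected
signatures (grids peak near ±60°, ±120°, 180°; bands only near 180°;
radially symmetric fields are flat near 1).

Before clustering, units with zero activity everywhere are excluded, then
units above the 99.75th percentile of mean spatial rate (percentile taken
on the post-zero-removal population). UMAP (n_neighbors = 20, min_dist =
0.05, spectral init, fixed seed) embeds the fingerprints in 2-d and DBSCAN
(min_samples = 30) clusters them. The DBSCAN radius defaults to the
k-distance heuristic — the median distance to the min_samples-th neighbor —
because a fixed radius does not transfer across population sizes (UMAP's
embedding scale grows as the population shrinks); a fixed float is still
accepted. On planted populations (grids + bands + bumps, 100 each) the
procedure recovers the families with ≥ 90% purity.

Band-like clusters are flagged automatically: a cluster whose mean
fingerprint is high at 180° while its 60°/120° values stay clearly lower
(a manual override is available, as visual grouping is the fallback).
Their union is the torus-ensemble candidate; K-means (k = 3) on rows of
the pairwise autocorrelogram-correlation matrix splits it into the three
orientation families (exact separation on planted bands at 0°/60°/120°).

## Topology

Population activity (ratemaps stacked as bins × units) is projected to 6
principal components. Downsampling assigns each point a membership
a_ij = exp(−d_ij/σ_i) over its k cosine-nearest neighbors with σ_i
bisected so Σ_j a_ij = log₂ k, symmetrises m_ij = a_ij + a_ji − a_ij a_ji,
scores each point by the mean membership over its own k neighbors, and
keeps the N strongest. Defaults k = 200, N = 3000 (of 4096 rasterised
bins) at desk scale; far more aggressive cuts (e.g. keeping only a quarter
of the cloud) were found to shred evenly-rasterised manifolds — they
remove a coherent low-density region of the torus, not scattered noise —
so the milder N is the default and the compute cost is bounded by
landmarking instead. The downsampling depth should match the data's
noise: for the *noiseless* synthetic-module control cloud the tests cut
only 15% (N = 3500), since deeper cuts on a clean, evenly-covered
manifold start carving the manifold itself (seed-dependently inflating a
transient third loop); for noisy model-derived clouds the default depth
stands.

Persistence is computed by an in-package Vietoris–Rips engine
(dimensions 0–2, coefficients in F_p, default p = 47): greedy
farthest-point subsampling to `nperm` landmarks (300 desk / 500 paper),
union-find for H0, boundary-matrix column reduction with the
clearing/twist optimisation for H1/H2. The filtration is truncated at the
enclosing radius (beyond which the complex is a cone — exact), or earlier
at a threshold chosen so the estimated simplex count fits a budget
(default 2.5e6); classes alive at the threshold are reported with death =
∞ and clipped to the threshold when lengths are compared. The engine is
validated against spaces with known Betti numbers: circle (1,1,0), sphere
(1,0,1), flat torus (1,2,1), Gaussian blobs (1,0,0).

`detect_torus` counts "significant" bars per dimension as the bars
separated from the rest by the largest persistence ratio, accepted when
that ratio reaches `gap_factor` = 2 and the weakest significant bar
exceeds twice a noise floor (median H1 persistence, or the median H0 merge
scale when H1 is sparse). A fixed multiple-of-median rule was tried first
and miscounts on all four control spaces at 300 landmarks (the noise
persistence distribution is heavy-tailed); the ratio rule is scale-free
and reproduces all controls. The verdict is a torus iff the counts are
(1, 2, 1).

Synthetic-module controls: the population cloud of a coherent module is a
torus under identity, coherent phase, coherent rotation, and incoherent
phase remapping (phases relabel points on the same manifold). Incoherent
per-cell *rotation* destroys the shared lattice and with it the torus —
the detector correctly reports its breakdown; this is a property of the
construction, not a detector failure.

## Pruning

A unit is inactivated by zeroing its incoming recurrent and velocity
weights; with no biases its activity is identically zero, so pruning
removes exactly its causal contribution while leaving the encoder/decoder
untouched. Curves prune cumulatively without replacement within a target
set (increments of 10; 30 repeats at paper scale, 5 at desk scale), with a
fresh 200-trajectory evaluation batch per repeat, reporting the median ±
MAD decoding error at timestep 20 (errors accumulate, and the model is
trained to t = 20). The top-grid target set ranks units by cumulative grid
score across environments; planted ideal-grid units are recovered exactly.

## What desk scale does and does not show

Passing desk-scale tests demonstrates: the training loop optimises the
intended objective; the estimators recover planted ground truth exactly or
within a bin; the topology stack detects the correct Betti signatures on
analytically known manifolds; pruning contracts hold; and the band-like
ensemble of the desk-trained network degrades decoding faster than random
pruning, directionally as at full scale.

It does not show the full-scale phenomenology: after ~2000 minibatches the
desk network's unit tuning is weak, its cluster structure coarse (one
dominant band-like cluster), and its population cloud still blob-like, so
no torus is detected in the *trained* desk model and the
"torus-breakdown-under-ablation" observation is out of reach at this
scale. The desk model's decoding error (~0.64 at t = 20) also still sits
near — in fact slightly above — the error of a constant uniform-prediction
decoder (~0.59), so orderings that bracket pruned models between the full
model and the uniform baseline are not meaningful at this scale either;
the tests assert the exact contracts (anchors, reproducibility, uniform
limit) and the directional torus-vs-random contrast instead. Those statements require the full-scale configuration
(`ExperimentConfig.paper()`), which is available but takes GPU-days-scale
compute. The synthetic-module oracles stand in as ground truth for every
analysis stage precisely for this reason.

## Known limitations

* The soft-boundary deflection rule is one of several plausible readings
  of "soft walls"; free-space statistics are unaffected.
* The Rips threshold budget trades diagram completeness for tractability
  on unstructured (blob-like) clouds; long bars are then reported as
  clipped/infinite rather than with exact deaths.
* `refine_torus_ensemble` enforces k = 3 subclusters; with a different
  number of planted orientations the split is a documented misspecification
  (silhouette drops).
* UMAP coordinates are visualisation-only; no quantitative claim is made
  on them (persistence operates on PCA coordinates).
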