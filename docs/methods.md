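# Methods

This note records the models, conventions and parameter choices behind
`kvflow`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish about real data.

## Multinomial permutation test

Phenotype scoring assigns each embryo to exactly one of m ≥ 2 categories;
a condition is modelled as a single multinomial sample. The two-sample
statistic is δ = Σ_c |k_{α,c}/N_α − k_{β,c}/N_β| — twice the total-variation
distance between the empirical distributions, so δ ∈ [0, 2] and δ is
symmetric. The null (both conditions share one outcome distribution) is
tested by pooling the N_α + N_β labelled observations and re-splitting them
uniformly at random, without replacement, into groups of the original
sizes; p is the fraction of K re-splits with δ′ ≥ δ.

Implementation notes:

* Re-splitting is executed as a multivariate hypergeometric draw of the
  pooled category counts, which has exactly the distribution of re-split
  group-α counts; K = 100,000 draws take well under a second.
* δ′ ≥ δ is decided on the integer statistic Σ_c |k_{α,c}N_β − k_{β,c}N_α|
  (equal to δ·N_αN_β), so ties — which must count as exceedances — are
  exact rather than float-dependent.
* With zero exceedances the test has hit its resolution; the API keeps
  p_value = 0 but flags `is_lower_bound` and reports the bound 1/K, which
  is how such results should be printed.
* Only permutation without replacement is offered; a bootstrap alternative
  would test a different null.
* The test is conservative by construction (ties counted, discrete
  statistic): calibration at m = 3, N = 100 per group, K = 2,000 gives a
  type-I rate of ≈ 0.038 at nominal 0.05 (null frequencies 0.5/0.3/0.2;
  other choices differ little).

## Count reconstruction from printed percentages

Published tables print per-category percentages to two decimals plus a
total N. `reconstruct_counts` searches for the smallest total (or
validates a known one) whose nearest-integer counts reproduce every printed
value to within half a unit in the last decimal (0.005) — agnostic to the
rounding rule used upstream, deterministic, and failing loudly with the
nearest misses when no consistent total exists.

Published summary rows are not always internally consistent, so
`kvflow.datasets` applies a fixed policy per row: (1) validate the stated
N; (2) if that fails, take the smallest consistent total ≤ 300 (one
heart-looping row prints N = 134 while its percentages are consistent only
with N = 131); (3) if no consistent total exists at printed precision,
trust the stated sample size and take the nearest-integer composition
(`nearest_counts`), flagged as inexact. Case (3) occurs for exactly one
row — the *metrnlb*⁻ᐟ⁻ heart-looping distribution (74.21/21.38/4.41 with
stated N = 104; no total below 725 is consistent, and a neighbouring row
of the same table sums to 98.5%, so the percentages are evidently garbled
at source). Reconstruction at the stated N = 104 gives (77, 22, 5). With
these counts the permutation p for the triple-heterozygote comparison
reproduces the published 0.034 almost exactly, while the p for the
wild-type comparison computes to ≈ 0.007 rather than the published 0.003;
no count vector anywhere near the printed row yields both published values
simultaneously, so the 0.003 appears uncomputable from the published
summary and the discrepancy is reported rather than hidden.

## Malformation probability and Fisher test

A binary malformation outcome with probability q over n embryos is
binomial; under a uniform prior the posterior is Beta(k+1, n−k+1). The
point estimate is the empirical frequency k/n (the maximum-likelihood
value) and the posterior standard deviation
√(αβ/((α+β)²(α+β+1))) is the error bar; the interval mean ± sd is clipped
to [0, 1]. The two-sided Fisher exact test uses the point-probability
convention (sum of hypergeometric probabilities of all equally-margined
tables no more probable than the observed one); `scipy.stats.fisher_exact`
implements exactly this and is verified in the test suite against a full
exact-fraction enumeration for every table with total ≤ 12.

## Bead detection, linking and MSD

Acquisition assumptions: single Z-plane, 4 Hz (frame interval 0.25 s),
0.25 µm pixels. Detection is multi-scale Laplacian-of-Gaussian after
subtracting the stack median as background:

* the image is pre-smoothed with a σ = 0.75 px Gaussian so that
  single-pixel noise spikes cannot capture the scale-space maximum at the
  smallest searched scale; spot sizes are recovered by subtracting the
  pre-smoothing in quadrature;
* scales span 0.5–2.5× the physical size gate so oversized blobs are
  detected with a truthful size estimate and then rejected by the
  0.75–1.25 µm diameter gate (apparent diameter 2√2·σ);
* the response threshold is 0.5 × 5 × the stack's robust noise level
  (MAD), since a peak of amplitude A gives a normalized-LoG maximum ≈ A/2;
  on pure-noise stacks this yields ≲ 1 false positive per 100 frames;
* the brightness gate keeps peaks above a whole-stack intensity quantile.
  The default 0.99 (top 1% of intensities) is one reading of a "0.01
  percentile" brightness cut whose literal reading (the 0.0001 quantile)
  excludes almost nothing; both are available via `brightness_quantile`
  and neither is asserted as the original intent;
* centres are refined by a background-subtracted intensity centroid
  (≈ 0.2 px accuracy at SNR 10).

Linking is frame-to-frame greedy one-to-one assignment in increasing
distance order (ties by lower index), gated strictly below 2.5 µm; objects
travelling farther are treated as new trajectories. No gap closing,
merging or splitting, and no 3D — matching the single-plane acquisition.

MSD is time-averaged over overlapping pairs: MSD(nΔ) = ⟨|r(t+nΔ) − r(t)|²⟩.
For a noise-free constant-velocity track this equals v²Δt² exactly at
every lag — used as a machine-precision identity test. Ensemble curves
average per-track MSDs unweighted over tracks with duration in [1, 8] s:
shorter tracks do not constrain displacement statistics and longer ones
are rare enough to over-weight single particles; the fitted lag range
defaults to the same 8 s window. Per-track speed is the mean
frame-to-frame displacement over the frame interval, averaged unweighted
across tracks (the per-track-then-across-tracks convention). This
estimator is biased upward by diffusion and localization noise —
E|step|² = v²Δt² + 4DΔt + 4σ_loc² — which is why measured bead speeds
should be compared between conditions acquired identically rather than
read as absolute advection speeds.

Motion classification fits three nested-ish models with non-negative
parameters — directed 4DΔt + v²Δt², confined L²(1 − e^{−4DΔt/L²}) (τ =
L²/4D), free 4DΔt — and selects the lowest small-sample corrected Akaike
score computed from the residual sum of squares. The log-log slope α of
the curve is reported alongside (α ≈ 2 directed, ≈ 1 free, → 0 at confined
lags beyond τ). On simulated ensembles of 200 beads (vortex at 1 µm/s with
D = 0.02 µm²/s versus diffusion with D = 1 µm²/s confined to a 5 µm disc)
the verdict is correct in ≥ 19/20 seeded replicates for both regimes.

## DFC kinematics

The convergence ratio divides the group's y-extent (max − min over cells)
at the first common frame by the extent at the last common frame; the
initial/final orientation is a convention chosen so convergence scores
above 1, and max − min is the plainest reading of how far a cell group
"stretches" along an axis. Cells lacking a sample at either common frame
(ragged manual tracks) are excluded. Migration speed is the per-cell mean
step speed averaged across cells (µm/min; positional noise biases it
upward, vanishing noise recovers the drift exactly). The migration index
is 100 × position/embryo-length along the animal-to-vegetal axis.

## Synthetic data: what it emulates and what it does not

* Beads: a rigid counter-clockwise rotation (tangential speed 1 µm/s at a
  25 µm ring — organizer-scale geometry) plus Brownian noise stands in for
  the cilia-driven vortex; the rotation step is integrated exactly (a
  forward-Euler tangential step would spiral outward). Confined motion is
  Brownian displacement reflected at a 5 µm disc boundary — the simplest
  stationary confinement; its long-lag ensemble MSD approaches E|r₁−r₂|² =
  R² for a uniform disc, verified within 20%. Diffusivities: 0.02 µm²/s in
  the advected regime (flow-dominated transport), 1.0 µm²/s for free beads
  (Stokes–Einstein scale for a 0.5 µm bead in water at 28 °C).
* Rendering: isotropic Gaussian spots (σ = 0.354 µm → apparent diameter
  1.0 µm, mid-gate), constant background, Gaussian and optional Poisson
  noise, default SNR (peak/noise-sd) 10. Not emulated: optical
  aberrations, bead z-excursions and defocus, photobleaching, motion blur,
  autofluorescence structure. Passing recovery tests therefore shows the
  detector/linker logic is correct at nominal conditions, not that it is
  robust to every microscopy artefact.
* DFC tracks: cell offsets from a centroid drifting vegetally at 1 µm/min
  relax as e^{−ct} (applied exactly per 6-min sample over 3 h, ~20 cells),
  with optional additive observation noise. The extent ratio of the
  generated group equals e^{cT} exactly at zero noise, giving the
  convergence estimator a closed-form target. Real DFC clusters
  additionally exhibit neighbour exchanges, contact dynamics and
  nonstationary drift that this generator does not model.
* Phenotype tables are true multinomial draws, matching the statistical
  model of the test exactly.

All generators take explicit integer seeds and are bit-reproducible.

## Numerical choices and degenerate inputs

* Percent-matching tolerance: strictly half a unit in the last printed
  decimal; `nearest_counts` uses largest-remainder apportionment.
* Permutation resamples are drawn in chunks of 200,000 to bound memory.
* Confined-model fitting uses bounded Levenberg–Marquardt (trust-region)
  with L₀ = √max(MSD) and D₀ from the first lag; a failed fit scores +∞
  and can never win model selection. RSS is floored at 10⁻³⁰ inside the
  Akaike score so exact fits remain comparable.
* Zero final extent in the convergence ratio returns an infinite result
  carrying an explicit flag instead of raising.
* Empty stacks, single-frame stacks, single-point tracks, zero margins and
  category mismatches raise typed errors (`kvflow.errors`).

## Problem sizes used in the test suite

Simulation-backed checks run at: 200 beads × 8 s for classification
(20 replicates per regime), 200 beads × 5 s rendered at 320×320 px for the
end-to-end speed recovery, 500 beads for diffusive-slope checks, 1,000
table pairs at K = 2,000 for type-I calibration, and K = 100,000 for every
published-comparison p-value. These sizes keep each check's Monte-Carlo
error well inside its asserted tolerance.

## Known limitations

* The permutation test assumes independent embryos pooled across batches;
  batch effects are not modelled (the published per-batch Fisher p-values
  are accordingly not reproducible from pooled tables and are not
  attempted).
* Bead speeds are upward-biased as described; published absolute speeds
  (0.96 / 0.48 µm/s) cannot be re-derived without the raw imaging data.
* Linking is greedy rather than globally optimal; at bead densities where
  neighbour distances approach the 2.5 µm gate, identity swaps are
  possible (speed and MSD statistics are insensitive to rare swaps, track
  identities are not).
* The size gate interacts with overlapping spots: merged pairs can be
  rejected as oversized, which fragments tracks in dense fields.
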