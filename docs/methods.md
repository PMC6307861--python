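# Methods

This note documents the models, the observation model behind the
synthetic-data generator, the numerical choices, and the limitations of
each analysis stage. Units are µm, seconds, and µm²/s throughout; pixel
centres sit at `(i + 0.5) · pixel_size`, and the default pixel pitch is
0.1 µm (a choice — the analyses take the pitch per movie).

## Two-state displacement kinetics

The fast-frame-rate (10 ms) analysis treats each molecule as either bound
(slow, apparent diffusion D_b) or free (fast, D_f) under steady state,
with no state transitions within a single displacement. The radial
displacement density over a lag Δτ is Rayleigh with per-axis variance
`2(D Δτ + σ²)`; σ is the static localization error, counted once per
localization and hence twice per displacement. σ is fitted, bounded to
[0.01, 0.08] µm.

**Defocalization.** A free molecule leaves the axial detection slice
(depth Δz, default 0.8 µm) before contributing long-lag displacements.
`defocalization_survival` gives the survival probability of a molecule
starting uniform in an absorbing slab,

    P(t) = Σ_{n odd} 8/(nπ)² · exp(−D n²π² t / Δz²),

truncated when terms fall below 1e−8.

**Jump-pool depletion.** Displacements are compiled per lag k from
trajectories, keeping at most J = 4 jumps per trajectory per lag. A
molecule contributing the jump that starts at frame i must have remained
detectable for (i + k) frames, so the correct per-lag weight of each
component is the slab survival averaged over jump-start indices,
`A_c(k) = (1/J) Σ_{i<J} S_c((i+k)δ)`, applied to the bound component too
(with its fitted D_b). Weighting by the single-jump survival `S(kδ)`
alone over-weights the free component and inflates the fitted bound
fraction by ~10 percentage points at these parameters. A small residual
underestimate (~2 points) remains because photobleaching tilts the
jump-start distribution toward early indices; the bleach rate is not a
model parameter, so this is left uncorrected and is well inside the
benchmark tolerance.

**Fitting.** Histograms use 10-nm bins to 3 µm (resolves σ ≈ 25–50 nm
structure without empty-bin noise at the benchmark sample sizes), each
lag normalized to unit mass; the loss is the plain sum of squared
per-bin residuals jointly over lags 1–7 (PDF fitting). The optimizer is
bounded trust-region least squares from 5 random initializations (the
best loss is kept), matching the convention of treating "fit iterations"
as re-initializations.

## Residence times

Track durations at 500 ms frames yield a survival curve SP(t) = 1 − CDF
on the grid of integer frame counts. The double-exponential model is fit
by bounded least squares on the linear-scale curve, restricted to
SP ≥ 10⁻³ (tails are data-poor) and to durations of at least n frames,
with the curve renormalized to 1 at the first kept point and the time
origin shifted there (rates are origin-invariant; amplitudes become
conditional weights). Renormalization can be disabled with a flag.

The minimum-duration threshold n is chosen by a convergence scan: the
smallest n whose slow rate changes by < 5% when moving to n + 1; if the
scan never converges the maximum candidate is returned with a warning.

Bias correction subtracts the slow rate of the identical fit on a His2B
control: photobleaching, chromatin/nuclear motion, and defocalization
are treated as independent Poisson losses shared by target and control,
so `k_s,true = k_s − k_bias` and `τ_res = 1/k_s,true`. `k_s ≤ k_bias`
raises an error ("bias exceeds signal"). Note the axial loss of a slowly
diffusing bound molecule is not exactly exponential (its hazard rises
over ~Δz²/π²D_b before settling); the non-exponential transient is
common to target and control and largely cancels in the subtraction —
the end-to-end benchmark recovers 5.56 s and 2.33 s within a few
percent on average, with seed-to-seed spread of ~5–10% at 10⁴
trajectories.

## TAMSD and the anomalous exponent

Per trajectory, the time-averaged MSD at lag kδ uses all overlapping
pairs with that frame separation; the ensemble curve weights
trajectories by pair counts. Lags are limited to 25% of the longest
trajectory (estimator variance grows at long lags), and the default fit
range additionally drops the first lag (localization-error dominated) —
standard TAMSD practice. The anomalous fit is ordinary least squares of
`log(MSD/τ)` on `log(τ)`; α = 1 + slope, Γ = exp(intercept). α = 1 is
free diffusion; confined motion drives α < 1. Localization error adds a
`4σ²` intercept to the MSD, which is why the first lag is excluded
rather than modelled.

## Hubs and enrichment

Segmentation is a fixed pipeline: Gaussian blur (σ = 5 px) → adaptive
local-mean threshold (window ≈ 1/8 of the image; foreground where
intensity > local mean × (1.6 − sensitivity), sensitivity 0.6, with a
1e−6-of-dynamic-range epsilon so that flat regions, where the comparison
is a float-rounding coin flip, stay background) → disk-3 binary dilation
→ optional ROI mask → hole filling → 8-connected labelling → area
(default [1000, 20000] px) and eccentricity (≤ 0.9) filters. The area
and eccentricity defaults are package choices, config-exposed.

The relative density map ranks each nucleus's pixels into integer
percentiles 1–100 against that nucleus's own intensities (ties take the
maximum rank of the tied block — documented because it decides hub
membership in degenerate, flat nuclei). This per-nucleus normalization
makes everything downstream invariant to per-nucleus affine intensity
rescaling. A trajectory's density is the mean percentile of the pixels
it visited (out-of-nucleus localizations excluded); it is "in hub" if
that mean exceeds the threshold (default 85). Enrichment accumulates
trajectory counts and pixel areas across all nucleus images before
forming the ratio of densities, and counts trajectories, not
localizations.

The segmentation necessarily includes a few pixels of dim rim around
each nucleus (threshold contour ~1 px outside the edge plus the 3-px
dilation). At realistic blastoderm packing the adaptive local mean is
high everywhere, the contour pulls inward, and the benchmark recovers
generator folds 2 and 4 within a few percent; at sparse layouts the rim
fraction grows and the recovered fold inflates by up to ~10% — a
property of the benchmark geometry, not of the estimator.

## MS2 locus analysis

Detection: 3-D difference of Gaussians (lateral sigmas 1.3/3.9 voxels,
axial scaled by voxel anisotropy), global threshold at median + k·MAD
(k = 10), connected components, voxel-count size filter,
intensity-weighted centroids. The contrast filter takes ±1 µm line
profiles along x and y at the centroid plane and keeps detections whose
mean max/min ratio is ≥ 2 (default; in-nucleus loci sit in dark
nucleoplasm, extranuclear detections in bright cytoplasm), refining the
centroid to the profile maxima. Tracking is gated nearest-neighbour
with no gap closing.

Windows: 2.18 µm squares around each tracked locus, cut from the TF
channel max-projected over 5 µm (≈ a nuclear diameter, configurable) of
z around the locus; a window must lie entirely inside its nucleus. The
control window sits 2.6 µm away, at the first angle (10° steps from 0°)
whose window is fully in-nucleus; loci with no valid control are
discarded. The fixed-offset control rule is the implemented default; a
random-control mode would be a straightforward variant but the fixed
rule is the fully specified one. Radial profiles average 1-px annuli
about the window centre, normalized so the outermost annulus is exactly
1, with standard errors taken across windows.

## FRAP

Correction: per frame, the dark-spot mean is subtracted from each
bleach trace and the result divided by the (equally dark-subtracted)
control mean — dark subtraction of the control before ratioing is the
default, togglable, since either reading of the correction order is
defensible; each spot is then normalized to its own pre-bleach mean.
Spots whose deviation from the mean curve has a standard deviation above
3× the median are discarded — an algorithmic stand-in for manual culling
of drifting spots, not a reconstruction of it. Time zero is the first
post-bleach frame; the bleach interval itself is excluded.

The reaction-dominant model `1 − A e^(−k_a t) − B e^(−k_b t)` is fit by
bounded curve fitting from several rate initializations; components are
ordered so k_a is the faster rate, rates within 5% of each other are
flagged degenerate, and if one amplitude vanishes the slow rate is taken
from the surviving component (the other rate is unidentifiable). The
slow half-recovery time is ln 2 / k_slow.

## Synthetic-data generator

The generator encodes the observation model the analyses assume, with
presets `zld_like` (F_bound 0.5, τ_res 5.56 s, FRAP t½ 5 s), `bcd_like`
(0.5, 2.33 s, 1 s) and `his2b_like` (0.88, no specific unbinding) so
benchmarks reference presets rather than magic numbers. Diffusion
coefficients (D_b = 0.01, D_f = 3.0 µm²/s), the non-specific off-rate
(2/s), the specific fraction of bound molecules (0.5), localization
error (30 nm), and bleach rates (5/s at 10-ms high-power imaging,
0.15/s at 500 ms) are package defaults chosen as realistic for nuclear
factors; they are stated in `presets.yaml` and flagged there as
defaults.

Trajectories: each molecule is bound (specific/non-specific split) or
free at steady state; 2-D lateral Brownian motion at its state's D plus
1-D axial Brownian motion in the detection slab. The track ends at the
first of unbinding, bleaching, axial exit, or movie end. Axial exit is
first passage out of an absorbing slab: sub-stepped (8 per frame) with a
Brownian-bridge crossing test between sub-steps, so exit statistics
match the continuous process the eigenfunction series describes rather
than the discretely sampled one (naive frame-time checking overestimates
survival by several percent here). Motion blur at exposures ≥ 100 ms is
a detectability gate — a molecule renders only if bound for ≥ 60% of the
exposure — rather than rendered PSF streaks, because the analyses
consume localizations, not raw movies, and long-exposure imaging loses
fast molecules rather than recording them. Ground truth records every
molecule's state and true event times. `simulate_trajectories_until`
accumulates batches until a requested number of *observed* trajectories,
since short-lived or blurred molecules render in fewer than two frames.

Nucleus images place disc nuclei (radius 3 µm) on a jittered grid at
blastoderm-like packing spanning the field, with intra-nuclear Gaussian
hubs; the ground-truth hub mask thresholds the noiseless per-nucleus
percentile map at the same 85th-percentile rule the analysis uses,
restricted to pixels genuinely above the nuclear background (a hub-free
flat nucleus has all pixels tied at percentile 100 but no hubs). Bound
molecules are placed so the expected per-pixel density in hub pixels is
exactly `fold` times the non-hub density. MS2 volumes render dark
nucleoplasm/bright cytoplasm in the MCP channel with one confined-
random-walk locus per nucleus, and a nucleoplasmic TF channel with
optional Gaussian enrichment co-centred on the locus. FRAP traces are
the model curve times a multiplicative per-frame control drift plus dark
offset and Gaussian noise, with matching control and dark spots.

What the generator does **not** emulate: photophysics (blinking,
photoswitching duty cycles), nuclear-cycle choreography and mitosis,
chromatin elasticity (bound-state motion is free Brownian at small D,
not confined), anisotropic PSFs, detection/linking errors in the
long-exposure data (residence-time benchmarks consume simulated
localizations directly), and spatial heterogeneity of binding within
nuclei. Passing recovery tests therefore demonstrate estimator
correctness under the stated observation model, not robustness to every
failure mode of real microscopy data.

## Benchmark problem sizes

The recovery benchmarks use 50,000 molecules (fast-imaging bound
fraction), 10,000 observed trajectories for target and control
(residence times), 20 nucleus images with 500 trajectories each (hub
enrichment, folds 2 and 4), and 50 FRAP spots at 1% noise — sizes at
which the stochastic spread of each estimate sits well inside the
stated tolerances (±3 percentage points, ±20%, ±10%, ±10%
respectively).

## Known limitations

- The two-state model excludes state transitions within displacements
  and three-state behaviour; anomalous sub-populations are absorbed
  into the two apparent states.
- The bias-correction subtraction assumes loss processes are shared and
  Poisson; slow non-exponential defocalization transients cancel only
  approximately.
- The greedy mutual-NN tracker is intended for the controlled low
  densities of photoactivated SPT; it has no merge/split or blinking
  handling.
- The segmentation rim bias described above; hand-drawn embryo-edge
  masks are replaced by an optional ROI argument with no automatic
  equivalent.
- FRAP fitting is reaction-dominant only; diffusion-coupled recovery is
  out of scope.
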