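# smtf

Single-molecule and bulk-imaging analysis of transcription-factor dynamics
in live embryos: two-state diffusion kinetics, DNA residence times with
photobleaching/defocalization bias correction, anomalous-diffusion (TAMSD)
analysis, subnuclear "hub" segmentation and binding enrichment, nascent-
transcription (MS2) locus radial profiling, and reaction-dominant FRAP
fitting — plus a synthetic-data generator with known ground truth so every
stage is verifiable end to end without raw microscopy data.

The package is aimed at people analysing single-particle-tracking (SPT)
and light-sheet imaging of nuclear proteins — e.g. Zelda- and Bicoid-class
transcription factors in syncytial-blastoderm *Drosophila* embryos — and
at people who want a tested, scriptable reference implementation of these
standard SPT analyses.

## The models

**Bound fraction (fast frames, ~10 ms).** Displacements r at frameshifts
Δτ = kδ (k = 1..7) are pooled (at most 4 jumps per trajectory per lag, one
tracking gap allowed) and jointly fit to a two-state Brownian mixture

    P_k(r) ∝ F·A_b(kδ)·Ray(r; 2(D_b kδ + σ²)) + (1−F)·A_f(kδ)·Ray(r; 2(D_f kδ + σ²))

where Ray(r; v) is the 2-D displacement (Rayleigh) density with per-axis
variance v, σ is the localization error, and A_c are defocalization
weights: the survival probability of a molecule diffusing axially in an
absorbing slab of depth Δz = 0.8 µm, averaged over the jump-start indices
imposed by the compilation. F is the bound (immobile) fraction.

**Residence time (slow frames, ~500 ms).** Fast molecules blur away; the
survival probability of bound-track durations is fit (for SP ≥ 10⁻³,
above a convergence-selected minimum duration) to

    SP(t) = F·exp(−k_ns t) + (1−F)·exp(−k_s t),

and the slow rate is bias-corrected with a stably bound His2B control:
k_s,true = k_s − k_bias, τ_res = 1/k_s,true, where k_bias is the slow rate
of the same fit to the His2B survival curve (photobleaching + chromatin
motion + defocalization).

**Hubs.** Nuclei are segmented (Gaussian blur σ = 5 px, adaptive
local-mean threshold at sensitivity 0.6, disk-3 dilation, hole filling,
area/eccentricity filters); each nucleus's pixels are ranked into integer
intensity percentiles; pixels above the 85th percentile are hub pixels;
enrichment is the ratio of trajectory densities (counts per pixel) inside
versus outside hubs.

**MS2 locus profiles.** Loci are DoG-detected in 3-D, contrast-filtered
(max/min of ±1 µm line profiles — nucleoplasm is dark in the MCP channel,
cytoplasm bright), NN-tracked, and a 2.18 µm window (plus an in-nucleus
control window offset by 2.6 µm) is cropped from the TF channel; windows
are averaged into radial profiles normalized to 1 at the largest radius.

**FRAP.** Traces are dark-subtracted, control-divided, pre-bleach
normalized, and fit to FRAP(t) = 1 − A·e^(−k_a t) − B·e^(−k_b t); the
slower rate gives the bound-population half-recovery time ln 2 / k_slow.

## Worked example

```python
from smtf import simulate, kinetics

# 10-ms imaging of a Zelda-like factor (50% bound, D_free = 3 um^2/s)
params = simulate.preset_params("zld_like", imaging="fast",
                                n_molecules=20000, seed=7)
trajs, truth = simulate.simulate_trajectories(params)
ds = kinetics.compile_displacements(trajs, timepoints=8,
                                    jumps_per_traj=4, gaps_allowed=1)
fit = kinetics.fit_two_state(ds, slice_depth=0.8, n_init=5, seed=7)
print(fit.summary())
```

```
Two-state displacement-distribution fit
===============================================
bound fraction F_bound                0.4672
D_bound (um^2/s)                      0.0103
D_free (um^2/s)                       2.9711
localization error sigma (um)         0.0298
detection slice (um)                   0.800
sum of squared residuals           1.945e-04
displacements used                    215228
initializations                            5
```

The fit recovers the generator's bound fraction (0.50), diffusion
coefficients (0.01 / 3.0 µm²/s) and localization error (0.03 µm). The
residence-time pipeline on 500-ms data with a His2B control:

```python
p = simulate.preset_params("zld_like", imaging="residence",
                           n_molecules=10000, seed=7)
trajs, _ = simulate.simulate_trajectories_until(p, 10000)
ph = simulate.preset_params("his2b_like", imaging="residence",
                            n_molecules=10000, seed=1007)
control, _ = simulate.simulate_trajectories_until(ph, 10000)
print(kinetics.ResidenceTimeModel(trajs, control).fit().estimate.summary())
```

```
Bias-corrected residence time
===============================================
apparent slow rate k_s (1/s)          0.4841
bias rate k_bias (1/s)                0.3082
corrected k_s_true (1/s)              0.1759
residence time tau_res (s)             5.685
```

The apparent slow rate mixes specific unbinding (1/5.56 s ≈ 0.18/s) with
bleaching and defocalization (~0.31/s, measured on the control); the
corrected residence time recovers the generator's 5.56 s.

There is also a thin CLI that chains the stages from a YAML config:
`smtf simulate --config cfg.yaml --out out/`, with stages `simulate`,
`track`, `kinetics`, `residence`, `msd`, `hubs`, `locus`, `frap`.

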