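# Methods

`locusdyn` analyses the mobility of fluorescently labelled chromatin loci
(e.g. dCas9-tagged telomeres imaged at 10 frames/s for 2 minutes) from 2D
single-particle tracks, and ships a generative model of the same data for
validation. This note records the models, the estimators, the parameter
choices and their rationale, and what the synthetic validation does and
does not demonstrate.

## Motion models

Trajectories are treated as realizations of one of three phenomenological
motion classes, in µm and seconds throughout:

- **fBm** (`model="fbm"`): each coordinate is an independent fractional
  Brownian motion with Hurst index H = α/2, scaled so the 2D ensemble law
  is MSD(t) = 4·D·t^α with D in µm²/s^α. Increments are sampled exactly by
  Cholesky factorization of the fractional-Gaussian-noise covariance
  γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); the closed-form covariance
  doubles as the oracle in the test suite. The factor is cached per
  (n_steps, H), so large populations cost one O(n³) factorization plus
  matrix products. α = 1 short-circuits to independent Gaussian steps.
- **Confined** (`model="confined"`): Brownian stepping with per-step
  standard deviation √(2·D·Δt) per coordinate inside a reflecting square of
  side L, implemented by folding the free path with period 2L (exact for
  Markovian steps). Start positions are uniform in the square. The long-lag
  TA-MSD plateau is E|r₁−r₂|² for two independent uniform points, L²/3 —
  the closed form the tests check.
- **Immobile** (`model="immobile"`): the true position never moves;
  observed positions are truth plus i.i.d. Gaussian localization noise of
  s.d. σ_loc per coordinate, giving a flat observed TA-MSD of 4σ² at all
  lags ≥ 1. This emulates chemically fixed cells.

Observed coordinates are truth plus localization noise for every model;
truth is kept on the track (`x_true`, `y_true`) so detection and MSD stages
can be scored against it.

Population heterogeneity: real per-trajectory diffusivity peaks are much
wider than the sampling error of a 1200-frame TA-MSD, because loci and
cells differ. Each component therefore draws per-track D from a log-normal
centred on its nominal D with dispersion `d_log10_sd` (default 0.25 decades
for the moving presets; 0 disables it). Without this the simulated D_app
peaks would be implausibly narrow (≈0.03 decades).

## TA-MSD and the anomalous-diffusion fit

The per-track time-averaged MSD at lag nΔt is the average of
[x(i+n)−x(i)]² + [y(i+n)−y(i)]² over all i, i+n present in the track
(gapped tracks average only over index pairs both present — unbiased under
missingness-at-random blinking). The ensemble curve is the unweighted mean
of per-track TA-MSD values over all tracks long enough to contribute each
lag. Tracks spanning less than 20 s are discarded first (inclusive
boundary: a 201-frame track at Δt = 0.1 s is kept).

MSD = 4·D·t^α is fitted by ordinary least squares of log MSD on log t over
the first 25% of lags (configurable; at least 4 points): α is the slope,
D = exp(intercept)/4. The log-log form is standard for power laws and gives
closed-form standard errors. Two caveats and their remedies:

- **Static noise floor.** Localization noise adds a constant 4σ² to every
  observed MSD value, which flattens the short-lag slope and biases α low
  (for the subdiffusive validation preset, by ≈0.03). `fit_anomalous`
  accepts a `static_offset` to subtract; `static_offset_from_tracks`
  measures it from an immobile (fixed-cell style) ensemble acquired with
  the same noise level. Condition reports in the pipeline use the raw
  (uncorrected) fit, since the perturbation comparisons are relative.
- **Correlated residuals.** Neighbouring ensemble-MSD lags share
  displacement pairs, so regression standard errors understate the
  trajectory-sampling uncertainty severalfold. `fit_ensemble(n_boot=...)`
  resamples tracks with replacement and reports bootstrap standard
  deviations instead; per-track curves are cached so each resample is a
  weighted mean.

## Per-trajectory apparent diffusion constant

D_app is the slope/4 of an OLS line with free intercept through TA-MSD at
lags 1–4. The intercept absorbs the 4σ² noise offset, so D_app estimates
short-lag diffusivity without a noise-calibration step. The price is sign
noise: for effectively static loci the slope is symmetric around zero and
roughly half the values are negative. Non-positive values are excluded from
the log-axis analysis and counted (`n_excluded_nonpositive`); reported
population fractions are therefore fractions of the positive-D_app subset,
and validation compares them with truth-label counts within that subset.

## Fixed-cell calibration and the anchored mixture

log10(D_app) from a mixed population is multimodal. The density histogram
(Freedman–Diaconis bins, floored at 30 bins — rule-based widths are far too
coarse on multimodal log-scale data whose IQR spans decades) is fitted with
a sum of up to three Gaussians by weighted nonlinear least squares (weights
from per-bin Poisson counting error):

- **fixed**: mean anchored at log10(D_fix) from `calibrate_dfix`, the
  back-transformed peak of a single-Gaussian fit to a fixed-cell D_app
  histogram acquired under the same imaging configuration. Its width is
  bounded to [0.5, 2]× the calibration width; its weight is free. Only the
  location is anchored.
- **slow**, **fast**: free means, widths and weights, floored in width at
  one bin (a narrower feature cannot be a resolved population peak).

Initialization is deterministic: peaks of the lightly smoothed histogram,
greedily by height with a 0.4-decade minimum separation, quantile-filled on
shortfall — no random restarts, so fits are exactly reproducible.

A component is considered unsupported when any of: the fit does not
converge; its weight is below 2%; its weight's standard error exceeds the
weight; it overlaps a neighbour (means closer than 1.25× the sum of their
s.d.s describe one population — the lighter peak is flagged); or a partial
F-test (α = 0.05) finds the richer model no better than the best reduced
one. On failure the model falls back 3 → 2 → 1: the two-peak shape is
anchored fixed+slow or free slow+fast, chosen by identity — if the
unanchored fit's lower peak lies within 2 of its own s.d.s of the anchor it
*is* the fixed population — not by residuals, since a free mean always fits
at least as well as an anchored one. Surviving free peaks are renamed
contiguously (a lone free peak beside a surviving fixed peak is "slow").

After selection, component weights are re-estimated by iterating the
responsibility average over the individual log10 samples with the peak
shapes held fixed (weights-only EM). This uses every sample rather than
~30 bins and brings weight variance close to the multinomial floor
(±2 points at n = 600); peak locations, widths and the selection decision
remain those of the histogram fit. Reported fractions are 100× the
normalized weights; absent components report 0%.

## Detection and tracking

- **Detection**: scale-normalized negated Laplacian-of-Gaussian filter at
  σ = r/√2 for expected spot radius r, local maxima above a quality
  threshold, duplicates within one radius suppressed (higher response
  wins). Detection count is monotonically non-increasing in the threshold.
- **Refinement**: least-squares symmetric 2D Gaussian per spot in an odd
  window (default 7 px) via unconstrained Levenberg–Marquardt, with a
  containment check and an intensity-weighted-centroid fallback on
  divergence; border-overlapping windows keep the detector position with a
  warning. On rendered spots at SNR ≥ 10 the per-coordinate RMSE is
  ≈0.03 px.
- **Linking**: per frame pair, an optimal linear assignment (Jaqaman-style
  LAP with birth/death slots) on squared displacement among candidates
  within max_disp, bridging up to max_gap = 2 missed frames with the radius
  scaled by √(gap+1). Tracks never contain two detections from one frame;
  singleton tracks are dropped.

Coordinates use the pixel-center convention — pixel (i, j) center at
((j+0.5)·pixel_size, (i+0.5)·pixel_size) — 0-based frames, µm everywhere
outside image buffers.

Movie rendering integrates the Gaussian PSF over pixel areas (erf
differences), adds constant background, Poisson photon noise and Gaussian
read noise, and stores ground truth as a registry; identical seeds give
bit-identical uint16 stacks.

## Presets and their calibration

The condition presets re-weight three motion classes
(Δt = 0.1 s, 1200 frames, 600 tracks per condition by default):

| class | model | nominal parameters | D_app scale |
|---|---|---|---|
| fast | fBm | D = 0.05 µm²/s^α, α = 0.8, σ_loc = 0.02 µm | ≈10^−1.3 µm²/s |
| slow | confined | D = 8×10⁻³ µm²/s, L = 0.35 µm, σ_loc = 0.02 µm | ≈10^−2.3 µm²/s |
| fixed | immobile | σ_loc = 0.10 µm | mode ≈ 0.7×10⁻³ µm²/s |

The fixed class's σ_loc = 0.10 µm is a calibration, not a measurement: it
is the effective fluctuation amplitude (residual thermal jiggle plus
localization error of dim fixed-cell loci) chosen so that the immobile
D_app mode lands at the ~10⁻³ µm²/s scale characteristic of fixed-cell
thermal fluctuation; the moving classes carry a 0.02 µm localization noise
typical of live tracking. Condition weights:

| condition | fast | slow | fixed | emulates |
|---|---|---|---|---|
| fixed-cells | – | – | 1.00 | fixed-cell calibration |
| baseline | 0.25 | 0.45 | 0.30 | untreated cells |
| released | 0.45 | 0.55 | – | transcription-factor inhibition |
| rigid | – | 0.40 | 0.60 | DNA intercalation |
| osmotic | – | 0.30 | 0.70 | hyperosmotic confinement |
| compacted | 0.40 | 0.40 | 0.20 | cohesin-driven compaction |

Directions mirror the studied biology (release raises the fast fraction and
removes the fixed peak; rigidity removes fast and raises fixed; osmotic
pressure makes fixed dominant; compaction raises fast); the magnitudes are
constructed, so cross-condition comparisons on synthetic runs validate the
pipeline's ability to rank conditions, not any biological effect size.
Per-condition seeds derive deterministically from the global seed and the
condition label, and reports contain nothing time-dependent, so a (config,
seed) pair reproduces byte-identical reports.

## Problem sizes used in validation

The test suite and the acceptance script run at the sizes the analysis is
designed for: 500–1000 trajectories of 1200 frames for ensemble recovery,
confinement and static-noise laws; 600 trajectories per condition and 20
replicates per weight vector for mixture recovery; a 36-locus, 250-frame
rendered movie for tracking fidelity. Covariance-oracle checks use short
tracks (9 steps) at 20 000 replicates where the comparison is elementwise.

## What the synthetic validation does not show

The generator emulates trajectory statistics — not microscopy realism.
It omits photobleaching, nucleus boundaries and drift, per-cell random
effects (trajectory counts stand in for the cells × trajectories reporting
unit), 3D motion and defocus, and any polymer-physics coupling between
loci; population identity is fixed per track (no state switching). Passing
tests therefore demonstrate correctness of the estimators and the
pipeline's discrimination between motion regimes under its own model
assumptions, not performance on any particular microscope's data.

## Known limitations

- The log-log ensemble fit reports the raw α in pipeline outputs; users
  comparing against a fixed-cell control should pass the measured
  `static_offset` explicitly.
- The fallback's identity rule assumes the fixed peak, when present, is the
  lowest; a population with sub-anchor mobility peaks would be misread.
- `estimate_dapp`'s sign noise makes per-population fractions conditional
  on D_app > 0; with a mostly-immobile sample the excluded share is large
  and is reported alongside the fractions.
- Histogram-least-squares peak fitting is a shape approximation: the
  immobile population's log10 density is left-skewed, and its Gaussian
  approximation absorbs some tail weight into neighbouring components at
  the few-percent level.
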