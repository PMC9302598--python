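# locusdyn

Analysis of chromatin-locus mobility from live-cell single-particle
tracking: spot detection and linking in fluorescence movies, time-averaged
mean-squared-displacement (TA-MSD) computation, anomalous-diffusion
fitting, and decomposition of per-trajectory apparent diffusion constants
into fast / slow / fixed populations anchored to a fixed-cell calibration.
A seeded synthetic-data generator produces trajectory mixtures and rendered
movies with known ground truth, so every stage of the pipeline is
validated end to end.

It is written for quantitative cell biologists and microscopists who track
punctate nuclear loci (telomeres or other dCas9/FROS-tagged sites imaged at
~10 frames/s for minutes) and want a reproducible route from a TIFF stack
or a track table to diffusion constants, anomalous exponents and
population fractions.

## The model

For a 2D trajectory of N positions at frame interval Δt, the time-averaged
MSD at lag nΔt is

    MSD(nΔt) = 1/(N−n) · Σᵢ [x(i+n)−x(i)]² + [y(i+n)−y(i)]²,

averaged over all start points i. Tracks spanning at least 20 s are kept;
per-track curves are averaged (unweighted) into an ensemble curve, which is
fitted with the 2D anomalous-diffusion law

    MSD(t) = 4 D t^α

by log-log linear regression over the first quarter of lags: α is the
anomalous exponent (α < 1: subdiffusion), D the generalized diffusion
coefficient in µm²/s^α.

Per trajectory, an apparent diffusion constant D_app is the slope/4 of a
straight line (free intercept, absorbing the localization-noise offset
4σ²) through TA-MSD at lags 1–4. Across a cell population, log₁₀(D_app) is
multimodal; its histogram is decomposed into up to three Gaussian peaks —
**fast** (global chromatin movement), **slow** (local locus motion), and
**fixed** (immobilized loci showing only thermal/localization fluctuation),
the fixed peak's location anchored at D_fix measured from fixed cells under
the same imaging configuration. If a peak is unsupported by the data the
fit falls back to two, then one component, mirroring how perturbations
(transcription inhibition, DNA intercalation, osmotic confinement,
chromatin compaction) add or remove populations. Reported fractions are
the component weights in percent.

Details, parameter defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Run the preset condition suite (600 synthetic trajectories per condition,
1200 frames at Δt = 0.1 s), which calibrates D_fix on an immobile
"fixed-cells" population and then analyses each perturbation regime:

```python
import locusdyn as ld

cfg = ld.RunConfig(conditions=ld.preset_conditions(), seed=1, n_tracks=600)
reports = ld.run_pipeline(cfg)
for label, r in reports.items():
    fr = r.fractions
    print(f"{label:12s} n={r.n_tracks}  alpha={r.ensemble_alpha:6.3f}  "
          f"fast={fr['fast']:5.1f}%  slow={fr['slow']:5.1f}%  fixed={fr['fixed']:5.1f}%")
```

prints

```
fixed-cells  n=600  alpha= 0.000  fast=  0.0%  slow=  0.0%  fixed=100.0%
baseline     n=600  alpha= 0.625  fast= 28.2%  slow= 47.0%  fixed= 24.7%
released     n=600  alpha= 0.756  fast= 45.7%  slow= 54.3%  fixed=  0.0%
rigid        n=600  alpha= 0.119  fast=  0.0%  slow= 53.6%  fixed= 46.4%
osmotic      n=600  alpha= 0.082  fast=  0.0%  slow= 42.1%  fixed= 57.9%
compacted    n=600  alpha= 0.714  fast= 42.5%  slow= 48.1%  fixed=  9.4%
```

Reading the numbers: fixed cells show no time dependence (α ≈ 0 — pure
localization noise) and define the D_fix anchor (0.64 × 10⁻³ µm²/s in this
run). The baseline population is subdiffusive (α ≈ 0.6 from a mixture of
motion classes) with all three peaks present. "Released" (emulating
transcription-factor inhibition) raises the fast fraction and loses the
fixed peak — the triple fit fails for it and the fallback reports two
components. "Rigid" (intercalation) and "osmotic" lose the fast peak and
inflate the fixed fraction, with correspondingly small α; "compacted"
(cohesin overexpression) raises the fast fraction. The reported fractions
refer to trajectories with positive D_app; the per-condition reports also
record how many non-positive values were excluded.

The same pipeline is available from the shell:

```
locusdyn run --seed 1 --n-tracks 600 --out results/run1
locusdyn simulate --condition baseline --n-tracks 200 --seed 2 --out sim/
locusdyn track --movie movie.tif --radius-um 0.3 --quality 30 --out tracks.csv
locusdyn msd --tracks tracks.csv --dt 0.1 --out msd/
locusdyn mixture --dapp msd/dapp.csv --calib calib.json --out mix/
```

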