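# enhancerdose

Quantitative analysis of enhancer reporter dose-response assays in *Ciona*
embryos.

Many developmental genes are controlled by several "shadow" enhancers that
drive near-identical expression patterns. Whether such enhancers are truly
redundant can be asked quantitatively: titrate an upstream signal (here,
MAPK/FGF activity via graded doses of the MEK inhibitor U0126), measure
reporter output per embryo and per notochord cell, and compare the
dose-response curves of each enhancer construct (a promoter-proximal
enhancer, a distal enhancer, and a full-length construct carrying both).
This package implements that analysis chain end to end:

- **Image quantification** — background subtraction, light median
  filtering, z sum-projection, automatic embryo masking, and the summed
  enhancer value (SEV) per embryo.
- **Batch normalization** — SEVs divided by each electroporation batch's
  DMSO-control mean, rescaled to a normalized scaled SEV (NSSEV) and
  expressed as a fraction of the full-length construct's DMSO mean, plus
  batch-stratified bootstrap comparisons of DMSO expression.
- **Dose-response modelling** — the core of the package. On a log10-dose
  axis `x` (DMSO vehicle coded two log units below the lowest dose), three
  models are fit by bounded nonlinear least squares:

  - linear: `y = m·x + b`
  - monophasic (4-parameter logistic): `y = (A−D)/(1 + 10^((C−x)·B)) + D`
  - biphasic (double logistic): `y = (A−D)/(1 + 10^((C−x)·B)) + (D−G)/(1 + 10^((F−x)·E)) + G`

  with top/middle/bottom plateaus `A, D, G`, Hill coefficients `B, E`
  (negative for falling responses), and log10-EC50s `C, F`. Parameter
  uncertainty comes from a residual bootstrap (resample fit residuals,
  refit, drop-and-count failures; EC50s summarized in log space); model
  classes are compared via least-squares AIC and relative likelihood
  `exp((AIC_min − AIC)/2)`.
- **Single-cell analysis** — ON/OFF classification from the bimodal
  modal-gray-value distribution (OFF iff ROI mode ≤ 10), matched-control
  stratified bootstrap of the ON-fraction ratio against DMSO, and
  stratified bootstraps of mean and 90th-percentile cell expression for
  ALL and ON-only cells (the "switch vs fade" question).
- **In situ score analysis** — semi-quantitative 0–3 scores per notochord
  founder blastomere: DMSO rescaling, medial/lateral/secondary grouping,
  ANOVA + Tukey HSD across cell pairs, and ordered/shuffled expression
  heatmaps.
- **Synthetic data** — a generator with known ground truth emulating
  mosaic electroporation, batch efficiency variation, skewed
  heteroskedastic intensities, bimodal ROI modes, Hill-shaped dose
  responses of both ON fraction and ON intensity, and founder-specific
  sensitivity offsets. Every analysis stage is validated against it.

## Worked example

```python
import enhancerdose as ed

# simulate a full study: 3 reporters x 3 batches x 9 dose levels x 10 embryos
embryos, cells, truth = ed.simulate_experiment(ed.SynthConfig(), seed=1)
norm = ed.normalize_embryos(embryos)

distal = norm[norm.reporter == "Distal"]
model = ed.DoseResponseModel.from_dataframe(distal, kind="monophasic")
res = model.fit()
boot = res.bootstrap(n_boot=1000, seed=2)
print(res.summary())
print(boot.summary())
```

Output:

```
Dose-response fit: monophasic
  n = 270, k = 4, RSS = 0.180922, AIC = -1965
  converged = True
   A =  0.310548
   B = -1.4244
   C = -1.13492
   D =  0.0664035
  EC50 = 0.0733 uM
Residual bootstrap (monophasic): 1000 replicates, 0 failed and dropped
        median    ci_low   ci_high
A      0.31069  0.30008   0.31981
B      -1.4226  -1.6068   -1.2628
C      -1.1349  -1.1734   -1.0905
D     0.066513  0.059428  0.073304
EC50  0.073293 0.067078  0.081176
```

The fitted Hill coefficient `B ≈ −1.42` (a shallow, weakly cooperative
response) and `EC50 ≈ 0.073 µM` recover the generator's configured truth
for the distal enhancer (−1.43 and 0.0686 µM); the 95% bootstrap CI on the
EC50 covers it. Fitting the full-length construct with all three model
kinds and passing the results to `compare_models_aic` ranks the models by
AIC; on the default generator its biphasic truth wins with relative
likelihood 1.

The same chain runs from the command line:

```bash
enhancerdose simulate --seed 1 --outdir run/
enhancerdose run --outdir run/ --seed 1       # full pipeline + manifest
```

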