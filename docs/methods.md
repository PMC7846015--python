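# Methods

## The measurement model

A reporter construct is electroporated into embryos; expression is read
out as fluorescence. Two features of this assay drive the entire design
of the analysis:

1. **Mosaicism.** Electroporated transgenes are carried and expressed by
   only a fraction of cells, so even vehicle-control embryos contain
   non-expressing notochord cells. Expression loss under inhibition can
   therefore happen on two axes: fewer cells expressing at all
   ("switch"), or all expressing cells getting dimmer ("fade").
2. **Batch efficiency.** Transfection efficiency varies between
   electroporations, multiplying all of a batch's intensities by an
   unknown factor. Every batch carries DMSO vehicle controls so this
   factor can be divided out.

## Normalization

For each embryo: `norm_score = SEV / mean(SEV of same-batch,
same-reporter DMSO controls)`, then `NSSEV = norm_score × grand DMSO mean
SEV of the reporter` (restores natural scale), then `expr = NSSEV /
(grand DMSO mean NSSEV of the reference reporter)`, so the reference
(full-length) DMSO mean is exactly 1. Grand means are unweighted means
over embryos — the simplest reading of "average over all control
embryos"; a batch-weighted mean would differ only when batch sizes are
unequal. The same chain applied to per-cell ROI means yields `norm_mean`.

Exact consequences used as tests: `norm_score` is invariant to rescaling
any single batch; rescaling shifts `NSSEV`/`expr` only by one common
factor per reporter (the grand mean moves), so all within-reporter
contrasts are unchanged.

DMSO bootstrap resampling is stratified by batch and preserves each
batch's observed count; an `equal_per_batch` mode draws equal counts per
batch instead (the other reading of "sampled equally from each
electroporation"). A pseudocount of 1 precedes any log transformation of
intensity metrics.

## Dose-response models

Responses are modelled on a log10-dose axis; the vehicle has no defined
log dose and is coded **two log10 units below the lowest treated dose**,
far enough below the dose range to sit on the top plateau. Three models:
linear (k=2), monophasic 4-parameter logistic (k=4), and biphasic double
logistic (k=7, plateaus A ≥ D ≥ G chained across two transitions). Hill
coefficients are negative for falling responses; at `x = C` the
monophasic curve passes exactly through `(A+D)/2`. Evaluation goes
through `scipy.special.expit`, so arbitrarily steep slopes never
overflow.

**Fitting.** Bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with minimally
restrictive bounds: plateaus in `[0, 2·max(y)]`, Hill coefficients in
`[−30, 0)`, log-EC50s within one log unit of the observed range. Crude
data-driven starts: top plateau from the mean response at the lowest
dose, bottom from the highest, EC50 at the x nearest the half-range
crossing, slope −1. The biphasic fit is internally parameterized as
`F = C + δ, δ ≥ 0`, which enforces the phase order `C ≤ F` and prevents
phase-label switching between bootstrap replicates (medians of mislabeled
phases would be meaningless). Fits to plateau-degenerate data (A ≈ D)
are flagged as slope-unidentifiable rather than rejected.

**Residual bootstrap.** Residuals of the initial fit are resampled with
replacement, added back to the fitted curve, and each pseudo-dataset is
refit (warm-started from the initial estimates). Replicates that fail —
non-convergence, non-finite parameters, or a shape parameter pinned at a
bound — are dropped and counted, never silently kept. Per-parameter
medians and 2.5th/97.5th percentile CIs summarize the distribution; EC50
is summarized on the log scale and back-transformed.

The i.i.d. residual resampling is the default deliberately, matching the
classical recipe, although the data are skewed and heteroskedastic.
Monte-Carlo study at the default design shows the consequence precisely:
under homoskedastic Gaussian noise the percentile CIs cover the true
log10-EC50 at ~94%, but under the generator's multiplicative noise the
bootstrap underestimates the sampling sd of the EC50 by roughly a
quarter, and coverage drops to ~85%. A `method="wild"` option (Rademacher
sign-flipped residuals kept at their own observations) is provided as the
heteroskedasticity-robust alternative; both coverages are reported by
`scripts/acceptance.py`. Point estimates (medians) are unaffected.

**Model selection.** Least-squares AIC, `n·ln(RSS/n) + 2k`, with
relative likelihood `exp((AIC_min − AIC)/2)`; only differences between
models on identical data are meaningful, and the shared additive constant
cancels there. A zero RSS yields a −inf sentinel with a warning. AICc is
not used by default: at n ≈ 270 and k ≤ 7 the small-sample correction is
below 0.5 AIC units.

## Single-cell analysis

Cells are OFF iff the modal gray value of their nuclear ROI is ≤ 10,
exploiting the bimodal mode distribution; the integer histogram mode with
ties broken toward the smaller value keeps OFF calls deterministic and
conservative. Only embryos with all 40 notochord cells measured enter
cell-level analyses (excluded embryos are counted).

The ON-fraction effect of a dose is expressed as a ratio against matched
DMSO controls: each bootstrap replicate resamples treated cells within
each batch and an equally sized DMSO sample from the same batches, so
batch efficiency cancels inside every replicate. Replicates with a zero
DMSO ON fraction leave the ratio undefined and are dropped with a count.
The distribution is tested against 1 by a one-sample t-test. Mean and
90th-percentile expression are bootstrapped stratified by batch,
separately for ALL and ON-only cells; pairwise dose comparisons use the
exceedance p-value `#{high_i > low_i}/n` on matched replicates (one-sided
as defined; a doubled two-sided variant is available), reported as
`< 1/n` when the count is zero.

## In situ scores

Ten founder blastomeres (left/right pairs of A8.5, A8.6, A8.13, A8.14,
B8.6) scored 0–3 per embryo. Per-embryo mean scores are rescaled so the
DMSO group mean is 1, making the curve overlayable on normalized reporter
expression. Cell-pair tests pool left/right members (per-embryo pair
means) and run one-way ANOVA followed by Tukey HSD within each dose;
score-mean CIs use the normal approximation. Heatmaps order embryos by
descending mean score with uniform rows (including all-zero) removed —
they carry no spatial information — with ties kept in input order; the
randomized control permutes each embryo's ten scores uniformly without
replacement, which preserves row multisets exactly and destroys any
column gradient.

## Image quantification

Order is fixed: background subtraction (a constant level; per-stack 1st
percentile of the reporter channel when not supplied), per-slice median
filter (default radius 1, "light"), z sum-projection with int64
accumulation, masking, in-mask summation (SEV). The embryo mask comes
from Otsu thresholding the **log1p** of the projected phalloidin channel
— summed intensity is proportional to tissue thickness, so a raw-scale
Otsu cut amputates the thin rim while the log-scale histogram stays
cleanly bimodal — followed by binary closing (disk radius 3), hole
filling, and retention of the largest connected component. Masks covering
<1% or >90% of the field are flagged for QC instead of the original
hand-editing step. Coordinates are (z, y, x), 0-based; values are 12-bit
in 16-bit containers.

## The synthetic generator

What it emulates: per-cell Bernoulli transgene expression
(`p_on_baseline = 0.7`, optionally Hill-modulated in log-dose with its
own EC50/slope — the switch axis), log-normal ON intensities whose median
tracks the reporter's true curve with constant log-sd 0.6 (skewed and
heteroskedastic — the fade axis), one log-normal efficiency factor per
batch (ln-sd 0.25) multiplying all its ON intensities, OFF-cell
background whose ROI mode never exceeds 10 while ON modes always exceed
it, embryo SEV as the sum of cell ROI totals plus an optional ectopic
(non-notochord) term excluded from the cell table, and founder-specific
log-EC50 offsets for the in situ scores (medial pairs +0.10 to +0.15 —
more resistant). Default design: 3 batches × 10 embryos per batch per
dose × 9 dose levels (DMSO + 0.029–4 µM) × 3 reporters × 40 cells.

Default true curves: distal enhancer EC50 0.0686 µM with Hill −1.43
(sensitive, shallow); proximal 0.5 µM with Hill −5.0 (resistant, steep);
full-length biphasic with phases near the two single-enhancer EC50s
(0.05 and 0.63 µM), middle plateau 0.63, and a top plateau of 1 slightly
above the sum of the single-enhancer tops (0.62 + 0.30) — weak synergy.
These place the DMSO-relative expression at the intermediate doses near
the regimes the assay is designed to resolve (distal ~50% at 0.1 µM,
full-length ~60–67% across 0.1–0.34 µM, proximal mildly reduced at
0.34 µM).

By default the ON-fraction Hill is disabled (mosaicism dose-independent),
so the expected embryo-level expression equals the configured reporter
curve exactly and fitted parameters have well-defined truth; switch-type
behavior is enabled explicitly per reporter. The intensity log-normal is
median-parameterized: the dose-independent mean/median factor
`exp(σ²/2)` cancels in normalization.

What it does **not** emulate: embryo morphology and its degradation at
high doses, manual ROI placement error, optical effects (depth
attenuation, bleed-through), cell-volume differences along the notochord,
and any dependence between a cell's ON state and its neighbors. Passing
tests therefore validate the statistical machinery (estimators,
bootstraps, selection rules) under the assumed noise structure, not the
imaging itself. The magnitude of ectopic (mesenchyme) signal is a free
knob with default 0 — it exists so tests can probe whole-embryo vs
cell-based disagreement, not because its real size is known.

Synthetic image stacks are deliberately small (12×96×128 voxels): one
bright ellipsoid body in the phalloidin channel, Gaussian reporter blobs
with exactly known integrated signals (kernels normalized over their
rendered support), flat background, optional Gaussian noise, rounded and
clipped to 12 bits.

## Simulation scales and numerical choices

Monte-Carlo studies use 200 repetitions with 250 bootstrap replicates
(tests) or 100–150 repetitions (acceptance script); single-analysis
bootstraps default to 1000 replicates. Percentile CIs use linear
interpolation (`numpy.percentile` default). Stratified percentile
bootstrap of a mean is slightly anticonservative at ~10 values per
stratum (per-stratum variance shrinkage); its nominal behavior is
verified at 30 per stratum. Welch's correction is the t-test default.
Random number streams are `numpy.random.default_rng` seeded explicitly
everywhere; identical (config, seed) runs are byte-identical.

## Known limitations

- The i.i.d. residual bootstrap undercovers under strong
  heteroskedasticity (see above); the wild option is the remedy but is
  not the default, by design fidelity to the classical chain.
- The biphasic model at this dose resolution has broad CIs on its Hill
  coefficients; phase EC50s are the robustly interpretable parameters.
- Whole-embryo SEV includes any ectopic signal inside the mask;
  agreement with notochord-restricted cell-level measurements must be
  checked, not assumed (the generator's ectopic knob exists for exactly
  this).
- In situ scores are ordinal; ANOVA/Tukey on 0–3 scores is an
  approximation that mirrors standard practice for such semi-quantitative
  scales.
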