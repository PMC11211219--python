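# Methods

## The marker and the measurement protocol

The Ao:LV ratio divides the mean bSSFP blood signal in a ~1 cm² circular
ROI in the ascending aorta by that in a matching ROI in the LV cavity, both
on the end-systolic frame of a 3-chamber cine. End-systole maximises the
aorto-ventricular pressure difference and avoids systolic jet turbulence
contaminating the LV sample. The package operationalises the protocol with
explicit, oracle-checkable rules:

- **Frame selection.** End-systole is the frame whose LV cavity mask has
  the smallest area (pixel count × pixel area); ties go to the earliest
  frame. The clinical protocol identifies this frame visually ("smallest LV
  cavity after aortic valve closure"); the mask-argmin rule is our
  deterministic operationalisation, since valve-closure timing is not
  represented in the landmark data.
- **ROI placement.** The aortic ROI centre is the valve point displaced
  exactly 10 mm along the (unit) aortic direction — a fixed reading of
  "approximately 1 cm above the leaflets". The LV ROI centre is the LV
  cavity centre landmark. Both ROIs are discs of nominal area 1 cm²
  (radius √(100/π) ≈ 5.64 mm).
- **Pixel inclusion.** A pixel belongs to an ROI iff its centre lies
  strictly inside the disc. The realised pixel area must be within ±10% of
  1 cm² on the given grid, otherwise placement fails loudly. On coarse
  grids the discretised area depends on where the centre falls relative to
  the grid; at 2 mm spacing a perfectly grid-aligned centre realises
  0.84 cm² (a placement error), while generic off-grid centres realise
  1.00 cm². Landmarks in physical mm are generically off-grid, so this is
  the behaviour we want: the check catches degenerate alignments rather
  than silently measuring a mis-sized ROI.
- **Coordinates.** (row, col) order, 0-based, physical position =
  index × pixel spacing (mm). The landmark JSON schema documents this.
- **Severity calls.** `ratio < 0.58` → severe stenosis; `0.58 ≤ ratio <
  0.86` → non-severe stenosis; `ratio ≥ 0.86` → no stenosis. The published
  operators are strict "<", so boundary values fall to the less-diseased
  class.

## The cine phantom

The phantom is a single-slice 2D+time scene matching the single-slice
3-chamber acquisition: an elliptical LV blood pool whose semi-axes scale as
`1 − f·w(t)` with `w(t) = (1 + cos 2π(t − t_es)/T)/2`, so cavity area has
its unique minimum exactly at the configured end-systolic frame; a
myocardial ring of constant thickness; and a constant-width aortic band
running ≥ 4 cm from the valve point along the aortic direction, so the
10 mm ROI offset always lands inside the lumen.

The flow void is modelled **phenomenologically**: the aortic lumen is
painted at `blood_signal × true_ratio`, a uniform multiplicative
attenuation. No intravoxel dephasing, off-resonance banding, through-plane
motion or papillary muscles are simulated — the marker uses the void only
as an observed intensity effect, and the phantom's job is to give the
measurement pipeline a known ground truth, not to emulate MR physics.

Noise is Rician (magnitude of a complex signal with i.i.d. Gaussian noise
per channel), the correct model for magnitude MR images; at SNR ≫ 1 it
coincides with Gaussian noise. The Rician mean has the closed form
`σ√(π/2)·L_{1/2}(−ν²/2σ²)`, which the tests use as an analytic oracle for
the expected measured ratio under noise: at 5% noise the expected measured
ratio for a true ratio of 0.45 is 0.4522 rather than 0.45, because the
Rician mean lifts low signals more than high ones, and the measured mean
matches this value to Monte-Carlo precision.

Default phantom geometry (192×192 pixels at 1.46 mm — the typical 1.5 T
pixel spacing — 30 frames, blood signal 186.2, myocardium 70) is one
plausible scan; tests also run a compact ~188 mm field-of-view variant for
speed. Phantoms serialise to NIfTI (frames on the 4th axis) or a minimal
per-frame DICOM series (PixelSpacing, InstanceNumber, TriggerTime,
RescaleSlope populated; intensities quantised to uint16, which bounds
round-trip ratio error at ~1e-4).

## The synthetic cohort generator

The generator defines the study conditions under which every cohort-level
statistic is evaluated. Per severity group (control / mild / moderate /
severe) it draws:

- **Ao:LV ratio and TTE peak velocity** from normal marginals truncated
  below at `truncation_floor` (default 0.05, forbidding non-physical
  values), coupled by a Gaussian copula with within-group correlation
  `within_group_coupling` (default −0.5). Group means/SDs default to the
  published severity-conditional values — ratio 1.01±0.19 (control),
  0.83±0.14 (mild), 0.67±0.13 (moderate), 0.45±0.12 (severe); velocity
  1.59±0.61 / 2.34±0.63 / 3.14±0.68 / 4.08±0.89 m/s — at group sizes
  86/66/78/84. The truncation floor sits > 5 SD below every group mean, so
  its effect on means is negligible (< 1e-4).
- **Gradients** via the simplified Bernoulli relation: peak gradient =
  4v² + ε, mean gradient = c·peak + ε′, with c the ratio of configured
  group means and residual SDs solved (delta method, clipped at zero) so
  the marginal SDs match the configured values. This keeps velocity and
  gradients mutually consistent within a patient.
- **Dimensionless index, valve area, stroke volume index** from
  independent truncated normals at their group parameters.
- **Flags.** Bicuspid morphology and root dilation are Bernoulli draws at
  the group prevalences (printed counts over group sizes). The low-flow
  flag is *derived*, not drawn: `low_flow ⇔ SVi ≤ 35 ml/m²`, preserving
  the defining invariant exactly.

The within-group coupling default is a calibration choice: only the
overall (between-group-driven) ratio–velocity correlation is published,
and −0.5 reproduces an overall correlation near the published −0.8. With
coupling set to 0 the generator still reproduces every acceptance target,
since those depend only on the ratio marginals.

Optional per-severity `(tricuspid, bicuspid)` ratio-mean overrides emulate
morphology-dependent means for subgroup analyses; the mechanism (a mean
shift conditional on the flag) is the simplest generative reading of
stratified cell-mean tables and is off by default.

The **3 T preset** is a declared stand-in: group ratio means are pulled
toward the control mean by a configurable shrink factor (default 0.5),
emulating the weaker severity separation reported at 3 T; no 3 T group
distributions are published, so this preset supports qualitative tests
only (separation weakens) and no numeric targets.

What the generator does **not** emulate: echo measurement error, the
CMR–TTE time interval, scanner/vendor batch effects, non-Gaussian tails,
or any outcome process. Passing tests therefore show that the statistics
recover the configured generative structure — not that the marker performs
identically on real patients.

## Statistics

- **Pearson correlation** with the two-sided p from `t = r√((n−2)/(1−r²))`
  on n−2 df; constant inputs are rejected by name.
- **ROC** with the diseased class at *lower* ratios, implemented by
  thresholding with "<" (matching the published cut-off operators) rather
  than by negating scores. AUC uses the Mann–Whitney midrank identity
  (ties count ½) and equals the trapezoidal integral of the empirical
  curve to 1e-12. The 95% CI is a seeded percentile bootstrap over
  patients (2000 replicates by default; single-class resamples are
  redrawn as missing). The CI method is a package choice — the original
  analysis does not state one. The Youden cut-off maximises
  sens + spec − 1 with ties resolved toward the lower threshold (higher
  specificity).
- **Group comparison**: one-way ANOVA F/p plus Tukey HSD adjusted
  pairwise p-values via the studentized-range distribution (scipy). With
  two groups Tukey collapses to the pooled-variance t-test (q = √2·|t|),
  which the tests verify to 1e-10. Tukey HSD is the only multiplicity
  correction used, matching the published analysis.
- **Stratified comparison**: within each severity class, a pooled-variance
  two-sample t-test between the two strata of a binary factor (morphology,
  flow state, root dilation) plus the cell-mean table; empty cells are
  flagged absent, never an error.
- **Agreement**: ICC(2,1) — two-way random effects, absolute agreement,
  single measure — from the mean-squares decomposition (the published
  analysis says only "ICC"; ICC(2,1) is the standard choice for two fixed
  readers sampled from a population of readers, and is the conservative
  one because it penalises systematic offsets). When the layout has zero
  variance everywhere (identical constant readings) the estimator's 0/0 is
  defined as 1. Bland–Altman reports bias ± 1.96·SD of reader differences.
  The dual-reader simulator adds independent Gaussian reading error to the
  true ratio on a 15% subset; its default error SDs (0.08 inter-reader,
  0.058 intra-reader) are calibrated so that, at the default cohort's
  between-subject spread (SD ≈ 0.26), the paired correlations land near
  the reported inter-/intra-observer values (0.914 / 0.953). These are
  calibration aids, not validated error magnitudes.

## Replicated runs and problem sizes

`run_study` replicates cohort generation and the full fit over child seeds
spawned from one master seed (`numpy.random.SeedSequence`), reporting the
Monte-Carlo mean and standard error of each statistic; the report JSON
carries a schema version and a provenance block (seed, config digest,
package version) and serialises with sorted keys, so fixed-seed runs are
byte-identical. Bootstrap CIs are computed on the first replicate only;
the per-replicate AUC is the exact Mann–Whitney value and needs no
bootstrap.

Default problem sizes: 200 replicates of the 314-patient cohort for the
simulation targets (Monte-Carlo SE of the mean AUC ≈ 0.001, an order of
magnitude below the ±0.03 assessment band); 100 seeds for the noisy-
phantom and null-stratification checks; 10,000 patients per group for
marginal-convergence checks. The compact phantom variant keeps the full
multi-spacing recovery grid fast without changing any geometry rule.

## Known limitations

- The phantom is geometric, not physical: no dephasing model, no banding,
  no motion artefacts; it validates the measurement *rules*, not
  robustness to real image degradation.
- The cohort model is parametric (truncated Gaussians + copula); real
  ratio distributions may be skewed or heavy-tailed.
- Automated landmark detection is out of scope: the measurement module
  consumes human (or phantom-provided) landmarks, mirroring the manual
  protocol.
- The 3 T preset is qualitative only.
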