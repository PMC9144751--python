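# Methods

This note documents the models, defaults and numerical choices behind
`phenoprime`, and what the synthetic benchmarks do and do not show
about real plate assays.

## Growth model and simulation defaults

Rosettes in wells saturate, so the generator uses logistic growth

    A(t) = K' / (1 + ((K' − A0)/A0) · e^(−r′ t)),

with `A0` the area at transfer (default 40 px), `K` the unprimed
optimal-condition carrying capacity (default 1000 px), and `r` the
intrinsic rate (default 1.4 day⁻¹, which saturates the curve within the
7-day window). The exponential regime is the `K → ∞` limit, which makes
RGR recovery exactly testable.

Stress acts multiplicatively on the carrying capacity:
`K' = K · stress_K_multiplier · effect.K`. The default multipliers
(0.30 for 100 mM mannitol, 0.22 for 100 mM NaCl) produce the ~70% and
~78% final-size reductions characteristic of these two stresses in this
assay. Treatment effects multiply `r`, `K` and greenness independently
so the PBCI components (slope vs final size vs colour) can be perturbed
separately. The shipped `DEFAULT_TREATMENT_EFFECTS` emulate the
qualitative outcome of a polyamine priming screen — little effect under
optimal growth, broad alleviation under salt with 1 mM DAP strongest,
mixed effects under osmotic stress, growth inhibition by 1 mM Orn — and
are plain data that callers can replace.

Measurement noise is multiplicative lognormal with unit mean,
parameterised by its coefficient of variation (`noise_cv`, default
0.15). Multiplicative noise keeps areas positive and makes the CV
scale-free; within-group variance in real screens is rarely reported,
so 0.15 is a package choice, exposed in the scenario config. Each
plant's greenness (mean GLI) is drawn once per plant
(s.d. `gli_sd` = 0.02) around the treatment×condition greenness
parameter (base 0.40, reduced to 0.90×/0.85× under osmotic/salt
stress).

The default time grid is 14 points at 0.0, 0.25, 1.0, 1.25, …, 6.25
days, mimicking twice-daily imaging at 10:00 and 16:00 for seven days.

## Plate rendering

The renderer exists to give segmentation a pixel-exact ground truth,
not to be photorealistic. Each plant is a star-shaped blob: well-disc
pixels are ranked by `r/f(θ)` where `f` superimposes 4–8 random cosine
lobes (plus a half-amplitude second harmonic) on a circle, and exactly
`round(area)` lowest-ranked pixels are taken. Because sublevel sets of
a star-shaped radial function are connected and the prefix is cut
inside the (convex) well disc, the blob is connected, inside its well,
and has an exact pixel count — stronger than the ±1% contract the
tests assert. Plant colour is chosen so the blob's GLI equals the
requested greenness (G = 150, R = B = G(1−g)/(1+g)), with small
per-pixel jitter (s.d. 2 intensity levels); the plate/agar background
(205, 205, 200) has GLI ≈ 0.006 < 0.05, so excess-green segmentation is
well posed. Lobe shapes, centre jitter and pixel noise are drawn from
the scene seed; everything is deterministic given (entries, layout,
seed).

## Segmentation

Foreground is `ExG = 2G − R − B > threshold` (default 40, Otsu not
needed for the synthetic scenes but the threshold is a parameter).
A binary opening (disc radius 1) is applied as a *speck filter by
reconstruction*: connected components with no pixel surviving the
opening are discarded, survivors keep their raw thresholded extent.
Measuring on the raw extent rather than the opened mask avoids the
systematic area erosion (and Dice loss) that opening inflicts on small
lobed rosettes. Each well takes its largest surviving component
(≥ `min_object_px`, default 20) whose centroid lies inside the well
disc; components spanning wells are assigned by centroid with a logged
warning. Channel means and GLI are averaged per pixel over the final
component mask; pure-black pixels (GLI denominator 0) are excluded from
the GLI mean and counted.

## Traits

* AUC defaults to the trapezoidal rule over real time in days. A
  `literal` mode computes ∑(sᵢ − sᵢ₋₁)/2 instead, which telescopes to
  (sₙ − s₀)/2; it is retained only for comparability with reports that
  print that difference form, since it discards the trajectory and
  cannot distinguish curves with equal endpoints.
* RGR uses the first and last observations and day units; it is
  invariant to area rescaling.
* GC-slope is OLS on raw areas (closed form, no fitting options).
* Per-plant GLI is the final timepoint's pixel-averaged GLI (pooling
  over the mask, not GLI of pre-averaged channels, except for simulated
  trajectories where the two coincide by construction).
* Degenerate inputs: series need ≥ 2 timepoints; a nonpositive endpoint
  area makes RGR undefined — the trait is set to NaN and the plant is
  flagged, never silently dropped.

## PBCI

Ratios are of group means (plants are unpaired across groups, so
per-plant ratios do not exist). A nonpositive group mean (possible for
GC-slope under severe stress, or GLI) has no principled log₂; the
component is excluded from the sum, counted and flagged rather than
clamped. PBCI = 0 — which occurs exactly when a control is scored
against itself — is labelled `neutral`; the sign rule otherwise maps
positive to promoter/alleviator (by condition) and negative to
inductor. The bootstrap CI (percentile, resampling plants within
groups) is an addition of this package; when the point estimate is
exactly 0 the sign-stability is reported as the larger of the positive
and negative replicate fractions (≈0.5 under the null).

## Statistics

* **Kruskal–Wallis on AUC**: two-group rank tests of each treatment vs
  its condition's control, flagged at p < 0.05, no multiplicity
  correction by default (matching common practice for the AUC bar
  chart); correction can be layered on the returned p-values.
* **Metabolite ANOVA**: one-way per metabolite on ln concentrations
  across the seven treatment groups within each condition. Tukey HSD vs
  control is the default post hoc (family-wise error control); Duncan's
  multiple range test is available behind a flag (stepwise studentized
  range at 1 − (1−α)^(p−1)), and a two-way treatment×condition ANOVA
  (type II) behind another. The Tukey p-values are computed directly
  from the studentized-range distribution batched per condition; they
  match `scipy.stats.tukey_hsd` to full precision (asserted in tests)
  at ~7× less cost. Metabolites with zero within-group variance
  everywhere are flagged undefined, not significant.
* **PCA**: columns are centred and (default) scaled to unit sample
  variance; the SVD gives scores U·S, orthonormal loadings V and
  variance fractions σ²ₖ/∑σ². Signs are fixed (largest-magnitude
  loading positive) for determinism. Constant columns are dropped with
  a warning under scaling. The biplot-ready `pca_metabolites` runs on
  ln-transformed group means by default (one symbol per
  treatment×condition mean of n = 4 replicates), with a per-sample mode
  and optional growth columns (final size, biomass) appended.
* **Pearson matrix**: exact t-transform p-values, NaN (never 0) for
  zero-variance variables.
* **Heatmap matrix**: ln of group means, rows in class blocks (free
  amino acids, total polyamines, free polyamines), columns
  condition-major; significance dots taken from the post hoc vs
  control.

## Pipeline and determinism

One global seed fans out through `numpy.random.SeedSequence` into
per-stage child seeds (growth, metabolites, bootstrap, render), so
stages are independently reproducible and two runs with the same
config+seed are byte-identical (the manifest deliberately contains no
timestamps). In simulate mode the pipeline computes traits directly
from simulated trajectories; the renderer/segmentation pair is
exercised by the `segment` CLI subcommand and by the benchmark suite,
keeping the default end-to-end run fast. Stage failures abort with the
stage name and leave a `FAILED` marker beside any partial outputs.

## Benchmark problem sizes

The shipped checks use 100 rendered wells for segmentation recovery,
48 plants/group and 200 simulated experiments for PBCI sign recovery,
2000 null replicates for test calibration, and the full default design
(1008 plants, 84 metabolite samples) for the end-to-end run — sizes at
which the asserted properties are statistically stable while the whole
suite stays fast.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes: logistic saturation, multiplicative noise, group-mean shifts
on metabolites, lognormal replicates. It does not emulate leaf-level
morphology, overlapping rosettes, lighting gradients, condensation
artefacts, or metabolite covariance structure; segmentation accuracy on
rendered scenes is therefore an upper bound on real-image performance,
and the type-I/power calibrations certify the statistical machinery,
not any biological claim. Equivalence with any particular lab's
segmentation software cannot be claimed — only recovery of this
package's own rendered ground truth.

## Known limitations

* No tracking of plants across wells or occlusion handling.
* Duncan's test is implemented for vs-control comparisons only.
* The bootstrap treats traits as exchangeable across plants within a
  group; it does not model plate or position effects.
* `literal` AUC is deliberately not the default; analyses mixing both
  modes are not comparable.
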