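# Methods

## Generative model

The synthetic study reproduces the structure of a chronic-jet-lag liver
transcriptome experiment. The sampling design is full-factorial over stage
× protocol × Zeitgeber time × replicate: 4 animals per time point at
baseline (protocol `none`) and 2 per time point per rotation (CW = 8-h
phase delays, CCW = 8-h phase advances) at 1 shift, 6 shifts, 5 days and
14 days recovery — 120 arrays over six ZTs (0, 4, …, 20 h).

Gene expression is modelled on the natural-log scale. For gene *g* and
sample *s*:

    ln level = mesor
             + amplitude · cos(2π(ZT − (acrophase + offset(stage, protocol)))/24)
             + log_fc_per_shift · shifts(stage) · scale(protocol) · persistence(stage)
             + ε,   ε ~ N(0, noise_sd²)

* **Circadian genes** have amplitude > 0 and acrophases drawn uniformly on
  [0, 24) h. The default re-entrainment offsets move the peak ±8 h after a
  single shift (delay vs advance); after six 8-h shifts the cumulative
  displacement is 48 h ≡ 0 (mod 24), and recovered stages carry no offset.
* **CRD-responsive genes** accumulate ±ln(1.5)/6 per shift so the expected
  recovery-stage fold change is 1.5 (or 1/1.5; signs alternate across the
  planted genes). The persistence fraction (default 1.0) scales the effect
  at the recovery stages; 1.0 models fully non-reversible deregulation.
* **Null genes** carry the mesor only.

The array-technical layer mimics the two-color common-reference design:
each probe receives a fixed affinity offset (sd 0.3, drawn once, shared by
all samples so replicate-spot averaging is meaningful), each of the 3 spots
per probe adds technical noise (sd 0.1), and the reference channel carries
the across-sample mean ln level of its probe — an equimolar pool of the
experimental samples — with its own spot noise. Intensities are
exponentiated to the raw scale.

Serum analytes follow `mesor·(1 + stage_shift) + amplitude·cos(2π(ZT − φ)/τ) + ε`.
The corticosterone-like analyte uses τ = 12 h with acrophase 0 h, giving the
characteristic double peak at lights-on and lights-off; five outliers of
+5 noise-sd are injected at random rows and recorded in a ground-truth
sidecar. The CD36-like analyte is non-rhythmic with planted 14-d-recovery
increases of +18% (CCW) and +11% (CW).

### What the generator does and does not emulate

It reproduces the blocking structure, the two-channel/3-spot probe layout,
multiplicative (ln-additive Gaussian) noise, dose-dependent persistent
deregulation and condition-dependent phase. It does **not** model probe
sequence effects, intensity-dependent dye bias, spatial artifacts,
heavy-tailed biological variation, correlated gene modules, or partial
re-entrainment dynamics between shifts. Passing the planted-recovery tests
therefore demonstrates the pipeline's correctness under its own statistical
assumptions, not its performance on real arrays, where effect attenuation
and correlated noise would lower power.

## Normalization

The four steps run in fixed order: (1) ln transform (non-positive
intensities are an error naming the offending spot), (2) quantile
normalization jointly over *all* scans — every sample-channel and
reference-channel vector of every array shares one target distribution,
because the ratio correction in step 3 only makes sense if both channels
are on a common scale, (3) per-spot subtraction of the reference ln signal,
(4) arithmetic mean over replicate spots (probes with missing spots are
averaged over what is present, with a logged warning). Ties in quantile
normalization receive the mean of the per-rank means they jointly occupy —
deterministic and exactly matched by a brute-force oracle in the tests.

A property worth knowing: because the pooled reference channel has a
narrower cross-probe spread than any individual sample, forcing both
channels onto the common quantile distribution shrinks sample-channel
contrasts by roughly 13% at the default parameters. This attenuation is a
faithful consequence of the normalization scheme (the real pooled reference
is likewise an average), and the power analyses below account for it.

## Rhythmicity

The rhythmicity test is the single-harmonic cosinor: least squares for
`y = M + A·cos(2πt/τ) + B·sin(2πt/τ)`, amplitude √(A² + B²), acrophase
`atan2(B, A)·τ/2π` reduced to [0, τ), and the F-test of the two harmonic
terms against the intercept-only model. Higher harmonics are available via
`harmonics > 1` (acrophase then found on an 8192-point grid), but defaults
report the fundamental only, since the analysis uses τ = 24 h for genes and
τ = 12 h for baseline corticosterone. A series whose total variation is
numerically indistinguishable from zero (relative tolerance 1e-10 on the
mean's scale) is reported flat: amplitude 0, F = 0, p = 1; a perfect fit
reports p = 0.

Batch screens fit one condition per stage (protocols pooled) and correct
p-values per condition with Benjamini–Hochberg (delegated to statsmodels);
q < 0.05 flags a probe rhythmic. Per-condition rather than global
correction was chosen because each stage asks a separate scientific
question; the docs flag this for sensitivity analysis. Note that after one
shift the two protocols are phase-shifted in opposite directions, so the
pooled screen deliberately finds few coherent rhythms at that stage;
planted circadian genes are still excluded through the baseline and
recovery screens.

The Grubbs screen is the classical iterative two-sided test: flag the
single most extreme studentized deviation if it exceeds the t-based
critical value at α, remove, repeat, never below three retained points; a
zero-variance sample flags nothing. In the serum analysis the screen runs
per stage × protocol group on rhythm-adjusted residuals (value minus its
time-point cell mean) — screening raw values pooled across the clock would
let the circadian waveform mask genuine outliers. Group comparisons use the
equal-variance two-sample t-test (not Welch), matching the analysis this
package mirrors; two zero-variance groups with equal means return p = 1 by
convention.

## Classification

CRD = 14-d-recovery samples with both rotations pooled; ND = baseline. The
pooling is configurable but default, since the analysis treats disruption
as one class. Cross-validation is leave-one-ZT-out: folds partition the
samples, and no ZT ever appears on both sides of a split (asserted
structurally in the tests).

Feature inclusion per family:

* **Random forest** (1,000 trees, seeded): top-k probes by impurity
  importance, k = 50. Impurity importance was chosen over permutation
  importance because permutation importance at 2,000 probes × 6 folds is
  orders of magnitude more expensive while ranking essentially identically
  in this uncorrelated-feature setting; the importance rule is a
  configurable spec field.
* **Linear SVM** (C = 1): top-k probes by absolute weight. The linear
  kernel is required — selection needs interpretable weights.
* **Nearest shrunken centroids**: implemented in-package (standardized
  centroid deviations with pooled within-class sd, fudge factor s₀ =
  median(s), m_k = √(1/n_k − 1/n), soft thresholding); features with all
  components shrunk to zero drop out. The shrinkage is chosen by stratified
  5-fold inner CV over a 30-point grid from 0 to the largest deviation,
  ties broken toward the **largest** shrinkage (the sparsest model, as in
  standard shrunken-centroid practice). Degenerate all-zero within-class
  variance is guarded with a 1e-12 floor.

Per-classifier consensus = probes kept in strictly more than half of the
folds ("majority" read literally; exactly half is excluded). The
cross-classifier consensus is the plain intersection, annotated to genes by
the many-probes-to-one-gene collapse. Accuracy is pooled over all test-set
predictions across folds. External-stage prediction retrains each family on
the consensus panel (baseline + 14 d recovery) and reports the fraction of
each held-out stage × protocol group classified CRD.

## Sequential selection

Differential expression is the two-group one-way ANOVA of 14-d recovery vs
baseline per protocol, pooled across ZT (time of day treated as noise —
the goal is time-independent markers, and rhythmic genes are removed by the
next filter); with two groups F = t² exactly, which the tests assert to
1e-10. Gene aggregation: a gene is significant if any of its probes is, and
carries the fold change of its most significant probe. The gates follow in
order — p < 0.001 in both protocols, fold change > 1.2 or < 0.8 with
**concordant direction** in both protocols, no rhythmic flag in any of the
five stage screens, no ageing-list membership (case-insensitive), then the
blood-detectability flag (union of the secreted/extracellular and
plasma-detected lists). Every stage is a subset of its predecessor, and
the set-difference filters commute; both are property-tested.

The ageing/secretome/plasma lists are plain text inputs. For synthetic runs
the secreted list is exactly the planted secreted genes and the ageing list
marks 50 null genes, so the age filter is exercised without touching
planted markers. The shipped 19-gene reference panel (TSV with per-route
flags) reproduces the published marker-table counts 15 / 9 / 5
(consensus / blood-detectable / overlap) through `build_marker_report`.

## Study conditions and calibration regimes

The generator's biological noise default is **sd 0.1** (ln scale, ≈10% CV —
typical replicate variability for liver arrays). At this level the
differential-expression gate has its specified power: noncentrality ≈ 9
for n = 12 vs 24 after normalization attenuation, so p < 0.001 is reached
essentially always, and exact recovery of the five planted blood candidates
is limited only by the ~2% per-gene chance of a false rhythmic flag across
the four informative screens.

The classifier-consensus calibration runs at **sd 0.2**, where each planted
probe separates the classes by ≈2 within-class sd. The two regimes are
deliberate: at sd 0.2 the DE gate's per-test power (~0.98) is too low for
all ten gene × protocol tests to pass simultaneously, while at sd 0.1 the
NSC inner-CV accuracy saturates with 3–5 probes and its sparsest-optimal
selection under-fills the consensus (a denser tie-break instead admits
chance-correlated null probes shared by all three families). Each
planted-recovery check therefore runs at the noise level at which its
behaviour is specified; both are fixed study conditions, not tuning knobs.

Problem sizes: planted-recovery checks use the full 120-array design with
2,000 genes over 20 seeds; calibration checks use 10,000 null genes
(cosinor and ANOVA type-I error, binomial 99% bands), 2,000 Grubbs
simulations at n = 50, and exhaustive/randomized oracle comparisons for
quantile normalization, shrunken centroids and Benjamini–Hochberg.

## Known limitations

* One probe per gene is the default; multi-probe layouts are supported but
  the consensus/recovery calibrations are stated at one probe per gene.
* The generator's reference channel is the exact mean ln level; a real
  pooled reference would add pipetting and labelling variation.
* The external-stage dose response (1 shift = 1/6 of the full effect,
  linear) is an explicit modelling convention; the underlying biology is
  only qualitatively monotone.
* CircWave-style forward harmonic selection is not implemented; the
  fundamental-harmonic cosinor with an optional fixed harmonic count is the
  extension point.
* The pipeline is calibrated for the two-class CRD/ND contrast; multi-class
  stage prediction is out of scope.
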