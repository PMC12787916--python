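# Methods

This note documents the models, defaults and numerical choices behind
`stancestrength`, and what the synthetic-data generator does and does
not establish.

## Measurement model

A standing subject exerts maximal isometric force against a platform
instrumented with a triaxial force sensor. Six directions are tested:
frontal-plane adduction (A) and abduction (B) on the mediolateral axis
*Fx* with both feet level, and four sagittal tests on the
anteroposterior axis *Fy* in a staggered stance — forward push / backward
pull with the right (D1/D2) or left (K1/K2) leg in front. Each direction
gets three maximal efforts with one minute of rest; the protocol's score
is the best of three.

Sign conventions are fixed in `protocol.DIRECTIONS` because the source
protocol describes directions only verbally: outward push (+) vs inward
pull (−) on *Fx*, forward push (+) vs backward pull (−) on *Fy*. The
windowed mean is computed on the direction-signed component, never the
absolute value, so push and pull remain distinct tests. A/B are treated
as the platform's resultant mediolateral force (not per-foot sums).

## MVC extraction

* Sampling: 1400 Hz (config knob `SensorChainSpec.fs`).
* Filter: Butterworth low-pass, cutoff 15 Hz, order 4, applied
  zero-phase (forward–backward, `sosfiltfilt`), so the effective
  magnitude response is the squared one-way response and the timing of
  the best window is not phase-shifted. The order is a knob; 4 is the
  common biomechanics choice. Whether the original device filtered
  causally in real time is unknown; offline zero-phase is this package's
  documented choice.
* Window: 1.5 s sliding mean, stride 1 sample ("any continuous
  segment"), computed with a prefix sum in O(n). Ties are broken to the
  earliest window for determinism. Traces shorter than one window are
  errors: the protocol demands the effort be sustained at least 1.5 s.
* Best-of-three is taken over windowed means (not raw peaks).

Numerical notes: the prefix-sum means agree with direct slice averaging
to ~1e-12 relative; the invariant mean(x) ≤ MVC ≤ max(x) is exact when
the window length divides the trace length (disjoint tiling), and holds
to sampling fluctuations otherwise.

## Acquisition-chain emulation

The electronics are modelled at their settled operating points: the
closed-loop supply trimming and the PWM-formed reference are reduced to
static constants, because the analysis consumes only settled values.
Per-axis calibration is independent (three independent bridges); the
zero offset is the unloaded mean and the gain factor comes from a known
reference load. ADC quantisation rounds to the nearest grid point, so
force round trips are exact to `gain_factor · LSB / 2`. Rail saturation
(amplifier or inverse-calibration output beyond [0, supply]) is flagged
metadata, not an exception — a genuine maximal effort may clip and the
pipeline must carry that fact.

Two stated figures of the source electronics are internally
inconsistent and are *not* asserted anywhere: the reference-trim
resolution (2.32 V / 50 000 counts = 46.4 µV, not 5 µV) and the sensing
principle (the formulas describe strain-gauge bridges; a piezoelectric
mention elsewhere is ignored). The module always computes resolution
from range/counts.

## Synthetic traces

`generate_trace` builds: zero baseline (0.5 s) → C³-smoothstep ramp
(1 s) → plateau at the target MVC (3 s) → release (0.5 s), plus

* tremor: band-limited Gaussian noise at 8–12 Hz — below the 15 Hz
  cutoff, so the filter is exercised by signal it must *keep* — scaled
  by the effort envelope, SD defaulting to 2% of the target;
* wideband sensor noise, SD 1% of the target;
* sparse single-sample spike artifacts (0.2 events/s, ±50% of target),
  which the 1.5-s window must suppress.

The C³ ramp is deliberate: with a ramp whose first three derivatives
vanish at its ends, the zero-phase filter adds no visible ringing and a
noiseless trace round-trips through the full pipeline to ~1e-7 relative.
Quick-ramp/plateau timing is configurable; plateaus shorter than the
1.5-s window are rejected at construction.

## Synthetic cohort

The cohort emulates the study population: 2 sexes × 3 age groups
(20–30, 40–50, 60–70 years), default sizes 19/17/15 men and 18/17/15
women (101 participants; the source's stated analysed total of 99 is
slightly inconsistent with its per-group counts, so n is a config knob).
Anthropometrics are drawn per stratum from the published means/SDs,
truncated to the published ranges; the untruncated location is
moment-matched so the *truncated* draw reproduces the published mean
(naive truncation would shift, e.g., the older men's mass mean by
~1 kg). Ages are uniform in the decade; BMI is recomputed.

Relative strength per direction is Normal(cell mean, SD) truncated at
zero. Cell means are additive — sex effect + age effect, no
interaction — matching the near-null interaction the source reports.
Anchors are the four fully printed group means (direction A in the
youngest group: 1.8504 / 1.3659 N/kg; direction D2 in the middle group:
2.3039 / 1.6909 N/kg); the remaining baselines and age offsets were
chosen once to approximate the printed male-advantage (≈16–36%) and
age-decline (≈20–46%) percentages and are assumptions, not data.
Within-stratum SDs are never printed directly; they are back-computed
from the published two-way-ANOVA error mean squares as
`sd_d = sqrt(SS_error,d / 93)` (0.30–0.49 N/kg by direction).

Because the cell means are additive in absolute N/kg, the *percentage*
male advantage grows as means decline with age; the printed group-wise
percentages cannot all be reproduced simultaneously under additivity,
and no attempt is made to do so.

What a green test establishes: that the extraction and statistics
recover a known, Normal, additively structured world at realistic noise
levels. What it does not: biomechanical realism (no fatigue across
trials, no balance coupling between axes, no skewness or heteroscedastic
age effects), and none of the source's unpublished raw-data quantities.

## Statistics

* t-tests: pooled-variance Student's by default (a reported df of 30
  where the group sizes imply 32 was judged a typo in the source, not a
  method signal), Welch behind a flag.
* One-way ANOVA from the between/within decomposition; zero within-group
  variance with equal means is an error, with unequal means F = ∞.
* Games–Howell: pairwise SE `sqrt(s_i²/n_i + s_j²/n_j)`,
  Welch–Satterthwaite df, `q = |Δ|·√2/SE` referred to the
  studentized-range distribution with k groups. Zero-variance pairs are
  errors rather than silently pooled. Cross-checked against pingouin.
* Two-way ANOVA: Type II sums of squares by nested OLS model
  comparisons (reduces to the classical decomposition when balanced;
  cross-checked against statsmodels `anova_lm(typ=2)`);
  `ηp² = SS/(SS + SS_error)`.
* α = 0.05 throughout; no multiple-testing correction across the six
  directions by default (matching the source analysis); a Bonferroni
  adjustment can be applied by the caller.
* Normative tables omit strata with n < 2 (no SD) with a warning;
  deficit reports give z-scores, percent-of-norm and the same
  percent-difference formula per direction, and fail with a
  nearest-stratum hint when the patient's stratum is missing.

## Known limitations

* The generator's stratum SDs and non-anchored means are assumptions;
  absolute agreement with unpublished cohort values is out of reach by
  construction.
* The voltage-dialect writer clips the vertical channel at the ADC rail
  for heavy subjects (body weight exceeds the ±720 N span of the default
  calibration); extraction does not use Fz, but `mass_from_fz` should
  not be used on voltage-dialect sessions with default gain.
* Sessions are processed in memory one trace at a time; nothing is
  streamed or parallelised — desk-scale reproducibility over throughput.
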