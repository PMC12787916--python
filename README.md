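# stancestrength

Multi-directional **standing lower-limb strength assessment**: a tested
re-implementation of the analysis chain behind a force-platform test in
which a standing subject pushes or pulls maximally in six directions —
adduction/abduction in the frontal plane (mediolateral axis *Fx*) and
forward-push/backward-pull with either leg in front in the sagittal
plane (anteroposterior axis *Fy*) — while the vertical axis *Fz* carries
body weight.

It is aimed at biomechanics and rehabilitation researchers who want to
(1) score maximal voluntary contraction (MVC) from noisy force traces
the way the device does, (2) normalise to relative strength, and
(3) build age- and sex-stratified normative benchmarks with the
accompanying inferential battery. No raw study recordings are public, so
the package ships a first-class synthetic-data generator that emulates
the acquisition chain and the cohort's statistical structure.

## The score and the statistics

The strength score of one trial is not the raw peak but the highest
sustained effort: after a zero-phase 4th-order Butterworth low-pass at
15 Hz (sampling rate 1.4 kHz), the MVC is

```
MVC = max over window starts t of  mean( F[t .. t + 1.5 s] )
```

i.e. the largest mean over any continuous 1.5-s segment. Each direction
is attempted three times; the best of the three is the definitive score,
and relative strength is `MVC / body mass` in N/kg.

Benchmarking follows the standard battery: group means *M* and SDs,
percent differences `100·(M1 − M2)/M2`, independent-samples t-tests
(pooled-variance by default, Welch by flag), one-way ANOVA across age
groups followed by the Games–Howell post hoc test (pairwise Welch
standard errors, Welch–Satterthwaite df, studentized-range p-values),
and a sex × age-group two-way ANOVA with Type II sums of squares and
partial eta squared, `ηp² = SS_effect / (SS_effect + SS_error)`.

The electronics emulation covers the settled acquisition chain:
regulator output `V_OUT = V_REF (1 + R2/R1)`, instrumentation-amplifier
output `V = G (V+ − V−) + V_REF` with mid-rail offset and rail
saturation flags, ADC quantisation (`LSB = supply / 2^bits`), and the
per-axis linear calibration `F = (ADC_mV − ZeroOffset) · GainFactor`.

## Worked example

```python
from stancestrength import CohortGenConfig, generate_cohort
from stancestrength.pipeline import cohort_to_dataframe, run_benchmark

cohort = generate_cohort(CohortGenConfig(seed=7))   # 101 participants
bench = run_benchmark(cohort_to_dataframe(cohort))
print(bench["sex_ttests"].query("age_group == 'all'")
      [["direction", "mean_male", "mean_female", "pct_diff", "p"]].round(4))
```

prints (seed 7):

```
direction  mean_male  mean_female  pct_diff      p
        A     1.7152       1.2478   37.4536 0.0000
        B     1.6946       1.3597   24.6322 0.0012
       D1     2.7203       2.0973   29.7083 0.0000
       D2     2.2684       1.6616   36.5177 0.0000
       K1     2.4201       2.0513   17.9819 0.0022
       K2     1.8862       1.4150   33.3024 0.0000
```

— the pooled male advantage in relative strength per direction
(`pct_diff`, percent of the female mean) with its t-test p-value. The
`examples/` directory holds one short narrative script per capability:
electronics arithmetic, MVC extraction, a single assessment, cohort
benchmarking, deficit reports, and the file-based session workflow.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch — simulates the stratified
cohort at the published group sizes, materialises every trial's force
trace, extracts and normalises the scores, and computes the normative
and inferential tables — printing the key tables and writing the results
manifest to `--out`.
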