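# gaitspm

Gait-cycle kinematics with 1D statistical (non-)parametric mapping for
paired running conditions.

## The problem

When a runner's joint-angle curves are compared between two conditions —
here, the start of a *transition run* (TR, running immediately after a
long cycling bout, the situation triathletes describe as "brick running")
against a *warm-up run* (WR, an isolated control run) — the interesting
differences are small (0.5–4°), windowed (confined to parts of the gait
cycle), and spread over many joints and planes. Comparing single
time-points throws information away and invites cherry-picking; the
appropriate tool is inference over the whole curve with familywise error
control across the 100 nodes of the normalized gait cycle — statistical
parametric mapping (SPM) and its permutation-based counterpart (SnPM).

`gaitspm` implements that analysis end to end for anyone working with
multi-joint inertial-capture running data: reading joint-angle streams
(mvnx-style XML or long CSV), detecting foot contacts and toe-offs,
segmenting steps, selecting the analysis window once the target speed is
reached, mirroring left-side data into one convention, splitting
active-leg (AL) and passive-leg (PL) phases, time-normalizing to 100
nodes, and testing condition differences per channel and phase — plus a
fully seeded synthetic gait generator with ground truth for closed-loop
validation.

## The statistics

For each channel/phase field, let d_i(q) be subject i's TR-median minus
WR-median curve at node q (i = 1..n, q = 1..100). The node-wise paired
statistic is

    t(q) = mean_i d_i(q) / ( sd_i d_i(q) / sqrt(n) )

Under the null, each subject's whole curve may flip sign. The critical
threshold t* is the (1 − α) quantile of the permutation distribution of
max_q |t(q)| — all 2^n sign vectors when they fit the permutation budget,
otherwise seeded random vectors. **Clusters** are maximal runs of nodes
with |t| ≥ t*; each receives a p-value from the permutation distribution
of maximal suprathreshold run length, floored at 1/n_permutations. A
parametric branch thresholds the same t-curve with 1D random field
theory (Euler-characteristic expectation at the residual field's
estimated FWHM). Scalar spatiotemporal metrics (velocity, stride length,
stride frequency, analyzed distance) are compared with a paired t-test
or Wilcoxon matched-pairs test dispatched by a Kolmogorov–Smirnov
normality screen.

Conventions: gravity-aligned frame, z up, metres; ISB angle signs;
flexion and internal rotation positive. A *step* is one foot's contact to
the contralateral contact; toe-off falls at ≈60.4% of the active-leg
phase. See `docs/methods.md` for the full model description.

## Worked example

Generate a 16-subject paired cohort at the default study conditions
(stride 2.52 m at 84.63 strides/min → 12.79 km/h, toe-off 60.4%, 2°
step-to-step noise, reported condition effects injected into TR trials)
and run the full analysis on a few fields:

```python
from gaitspm import PipelineConfig, run_study, report_table1
from gaitspm.synth import default_study_model, generate_cohort

model, effects = default_study_model()
cohort = generate_cohort(model, effects, n_subjects=16, seed=42)
report = run_study(PipelineConfig(seed=7, fields=[
    "hip/flexion_extension/PL",
    "knee/flexion_extension/AL",
    "ankle/flexion_extension/AL",
]), cohort)

for label, fr in sorted(report.fields.items()):
    for c in fr.spm.clusters:
        print(f"{label}: nodes {c.start_node}-{c.end_node} "
              f"sign {c.sign:+d} p={c.p_value:.4f}")
print(report_table1(report)["markdown"])
```

prints

```
hip/flexion_extension/PL: nodes 0-57 sign +1 p=0.0008
knee/flexion_extension/AL: nodes 17-33 sign +1 p=0.0038
knee/flexion_extension/AL: nodes 61-87 sign -1 p=0.0004
|  | Mean Velocity (km/h) | Mean Stride Length (m) | Mean Frequency (Strides Per Minute) | Analyzed Running Distance (m) |
|---|---|---|---|---|
| Warm-Up Run | 12.57 +/- 1.10 | 2.51 +/- 0.11 | 83.25 +/- 5.18 | 25.14 +/- 1.11 |
| Transition Run | 12.43 +/- 1.06 | 2.49 +/- 0.11 | 83.01 +/- 5.32 | 24.95 +/- 1.11 |
| p-value | 0.022 | 0.02 | 0.44 | 0.02 |
```

Reading this: the injected +3° hip-flexion effect (toe-off to mid-swing)
is recovered as a significant positive cluster over the first ~55% of the
passive-leg phase; the knee shows the injected biphasic pattern (more
flexion around mid-stance, more extension in initial swing); the ankle
sagittal field, which carries no injected effect, reports no clusters
(and is therefore not printed). The table summarizes the spatiotemporal
metrics per condition with paired-test p-values.

The same pipeline runs from the shell:

```sh
gaitspm synth --subjects 16 --seed 42 --out cohort/   # trials + truth manifest
gaitspm run --config cfg.yaml                          # full study from files
gaitspm report --study out/report.json                 # table + clusters
```

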