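# Methods

`gaitspm` implements a complete kinematic comparison of two paired running
conditions — in the motivating setting, a *transition run* (TR, the run
immediately after a cycling bout) against a *warm-up run* (WR, an isolated
control run) — from raw multi-joint angle streams to cluster-level 1D
inference. This note documents the models, conventions, numerical choices
and limitations.

## Data model

A trial is a `Recording`: 30 joint-angle channels sampled at 240 Hz (four
trunk joints L5S1/L4L3/L1T12/T9T8 and hip/knee/ankle of both legs, each in
flexion/extension, abduction/adduction and internal/external rotation, ISB
sign conventions), plus pelvis and foot position tracks in a
gravity-aligned frame (metres, z up). Loaders (an mvnx-style XML subset and
a long-format CSV) never resample, reorder or impute; NaNs are rejected at
load.

## Gait events and segmentation

A **step** runs from one foot's first ground contact to the first contact
of the contralateral foot. Events come either from per-sample contact
flags (trusted when present) or from foot kinematics:

* **contact** — the first minimum of vertical foot position inside a
  sustained low-speed region (foot speed < `v_contact_ms`, default
  1.5 m/s, for at least 2 samples);
* **toe-off** — the subsequent sample at which foot speed exceeds
  `v_toeoff_ms` (default 2.0 m/s).

The thresholds are configuration keys; the defaults were chosen against
the synthetic generator's ground truth, where they recover contacts
exactly and toe-offs within one sample on clean data. Two successive
contacts on the same side signal a missed event; the interval is skipped
and logged, never silently dropped.

The **analysis window** is the first `n_steps` (default 20) consecutive
steps once the per-step speed — horizontal pelvis displacement over step
duration — falls within `target ± k_sd·σ`. σ is the SD of per-step speeds
over the whole trial (the emulated protocol states "target speed ± two
standard deviations" without defining the SD; this self-contained reading
is the default, and an absolute band in km/h can be configured instead).

**Spatiotemporal summaries** over the window: stride length = horizontal
pelvis displacement between successive ipsilateral contacts; frequency =
60 / stride duration (strides/min); velocity = net horizontal pelvis
displacement over the window duration; relative toe-off = (toe-off −
start)/(end − start) per step, in %. These satisfy
`velocity ≈ stride_length × frequency × 0.06` (km/h) to within 2% by
construction of the definitions, which is asserted on every synthetic
cohort.

## Mirroring, phases, normalization

Left-lead steps are mapped into right-lead convention by a **full-body
reflection**: left/right channels are swapped and every frontal
(abduction/adduction) and transverse (internal/external rotation) channel
— trunk included — is sign-flipped; sagittal channels are untouched. The
reflection is an involution and leaves right-lead steps unchanged, so
after mirroring no left/right distinction remains and left- and
right-lead steps pool into one convention. Whether the trunk's
frontal/transverse channels should be flipped when pooling is genuinely
open in the emulated protocol; flipping is the default because pooled
trunk-rotation effects are reported with one consistent sign for both
body sides, and it is what keeps the trunk channels zero-mean-consistent
across lead sides.

Each step contributes, per collapsed channel:

* an **active-leg (AL)** curve — the lead leg over the step itself
  (touchdown to contralateral touchdown: stance plus initial swing;
  toe-off at 60.4% of this phase on average);
* a **passive-leg (PL)** curve — the same leg over the *following* step's
  interval (the remaining swing);
* **trunk** curves over the plain step window (an active/passive
  distinction is not meaningful for the trunk).

Curves are resampled onto 100 nodes by linear interpolation spanning the
first to last sample inclusive (endpoints exact). Linear interpolation is
monotonicity-preserving and the vendor-typical choice; no amplitude
normalization or time-warping beyond this is applied. Node-wise
per-subject medians and IQRs (Q3 − Q1, linear interpolation between order
statistics) summarize the 20-step stack; the per-subject median curve per
condition is the default unit entering the paired tests (a per-step
pairing mode exists but is non-default).

## Statistical mapping

Per channel/phase field, the paired sample is the n_subjects × 100 matrix
of TR-median minus WR-median curves.

**Normality screen.** A one-sample Kolmogorov–Smirnov test per node: the
sample is z-scored and compared with the standard normal CDF (asymptotic
p). Because the null parameters are estimated from the same sample, this
screen is conservative; the estimated-parameter (Lilliefors) correction is
available via `lilliefors=True` and is the calibrated variant (≈5%
rejections on normal data). Zero-variance nodes are non-testable and
counted as non-normal.

**Non-parametric branch (default).** Sign-permutation ("SnPM") inference:
under the null of exchangeable condition labels within subject, each
subject's whole difference curve may flip sign. The permutation
distribution of the maximum of |t| over the 100 nodes gives the critical
threshold t* at the (1 − α) quantile ("higher" interpolation, hence never
anti-conservative). All 2^n sign vectors are enumerated when 2^n fits the
permutation budget (n ≤ 13 at the default 10 000); otherwise seeded
uniform sign vectors, always including the identity. Clusters are maximal
runs with |t| ≥ t*; each cluster's p-value is the fraction of permutations
whose maximal suprathreshold run length (at the same t*) reaches the
observed extent, floored at 1/n_permutations. Inference is two-tailed;
cluster signs record direction. The test is invariant to subject order
and symmetric under global sign flip; its familywise type-I error is
≈0.05 on null simulations (acceptance-tested at 200 replicates).

**Parametric branch.** The same t-curve thresholded by 1D random field
theory: the smoothness (FWHM in nodes) of the residual field is estimated
from the mean squared gradient of the node-wise-normalized residuals
(FWHM = sqrt(4 ln 2 / ⟨grad²⟩)), and t* solves E[EC](t*) = α with the
expected Euler characteristic of the excursion set over (Q − 1)/FWHM
resels (two-tailed inference uses α/2). As FWHM → ∞ the threshold
reduces exactly to the pointwise critical t; Monte-Carlo simulation of
smooth t-fields reproduces the threshold within ~2% at the smoothness
levels relevant here.

AL and PL are tested as separate 100-node fields with separate
thresholds. All 30 fields are tested without cross-channel multiplicity
correction by default (each joint/DOF is reported on its own, as is
conventional in this literature); a Bonferroni-across-fields option
exists and the report records the policy. Scalar spatiotemporal metrics
are compared with a paired t-test or a Wilcoxon matched-pairs test
(exact null for small n, zeros dropped), dispatched by the same KS rule.

The pipeline's `test_method` defaults to `"nonparametric"` — the analysis
actually applied in the emulated study, whose data were non-normal at most
nodes. The KS-dispatched `"auto"` mode is available but on near-normal
synthetic data it selects the parametric branch, which would not mirror
that study.

## Synthetic gait generator

The generator is the ground-truth test bed; it emulates the statistical
structure of the study's inputs, not validated biomechanics.

* **Templates.** Per-channel stride-periodic Fourier curves (order ≤ 8,
  low-passed periodic interpolants of fixed knot tables) resembling
  running kinematics. The left leg evaluates the same template half a
  stride out of phase, with handed DOFs sign-flipped, making the
  noise-free gait perfectly bilaterally symmetric. Trunk
  frontal/transverse templates contain odd stride harmonics only
  (antisymmetric under a half-stride shift), which is exactly the property
  that makes left- and right-lead trunk curves poolable after mirroring;
  trunk flexion uses even harmonics (one oscillation per step).
* **Spatiotemporal scale.** Stride 2.52 m at 84.63 strides/min (implied
  speed 12.79 km/h), toe-off at 60.4% of the AL phase, 240 Hz — the
  warm-up-run scale of the emulated study. Per-subject stride parameters
  vary with CV 5%, per-trial with CV 1%, per-step plateau speeds with CV
  0.8%, and the toe-off fraction jitters with SD 0.02 per step.
* **Speed ramp.** Each trial opens with two steps at 60% and 80% of
  target speed before the plateau, so the window-selection rule has a real
  criterion to find; 28 steps per trial leave 20 analyzable steps plus
  margin.
* **Foot kinematics.** Feet are exactly stationary (z = 0) during stance
  and follow a smooth swing (sin² vertical bump, asymmetric forward-speed
  profile: fast leave-off at 5 m/s, slow approach at 2.8 m/s) so that the
  event-detection rules are exercised realistically and recover the
  scheduled contacts to ±2 samples. Position tracks are generated
  noise-free; the documented default noise level applies to the angle
  channels.
* **Noise.** Step-to-step smooth angular noise (SD 2°, six control points
  per step, linearly interpolated), constant per-subject channel offsets
  (SD 3°, shared across conditions, zero for trunk handed DOFs to preserve
  antisymmetry), and a smooth per-(subject, condition) response curve
  (SD 0.2°, three stride harmonics) that keeps the paired differences from
  collapsing to pure step noise. All draws are seeded; a subject's two
  conditions share the subject-level draws.
* **Effects.** TR trials add windowed offsets per the reported condition
  differences: trunk extension (−1° L5S1, −0.5° cranial joints) and
  external rotation (−0.5°/−0.2°) over the whole cycle; hip flexion +3°
  from 65% AL to 55% PL; hip internal rotation +2.5° over AL and 0–30%
  PL; knee adduction +1° at 80–95% AL; knee flexion +2° (20–30% AL), −3°
  (65–85% AL), +4° (50–80% PL). Effects hold full magnitude across their
  stated window with 5%-wide raised-cosine shoulders *outside* it (the
  windows are approximate by nature; boxcar edges are available). Leg
  effects are applied to both legs in their own conventions; trunk
  frontal/transverse effects alternate sign with lead side so that the
  pooled (mirrored) curves carry one consistent sign.

What the generator does **not** emulate: soft-tissue and sensor-fusion
artifacts, drift, curve-registration (timing) differences between
conditions, asymmetric pathologies, and any kinetic quantity. Passing
closed-loop tests therefore demonstrates that the pipeline recovers what
it is defined to recover under realistic noise magnitudes — not that it
is robust to every artifact of field recordings.

## Numerical choices and degenerate inputs

* Quantile rule everywhere: linear interpolation between order statistics.
* Permutation threshold quantile: "higher" interpolation (size ≤ α).
* Zero-SD nodes in the t-curve yield signed-infinity sentinels and are
  logged; an all-zero difference field has t* = 0 and reports no clusters.
* `time_normalize` requires ≥ 2 samples; it is linear
  (normalize(a·x + b) = a·normalize(x) + b) and exact on constants and on
  already-100-node inputs.
* The noiseless template-recovery check (≤ 0.1° at every node) uses a
  grid-aligned model variant whose step duration is an exact number of
  samples; at the default 84.63 strides/min, contact-time quantization on
  the 240 Hz grid alone causes up to ~1° of apparent error, which is a
  property of sampling rather than of the normalization chain.
* Test problem sizes: the type-I check uses 200 null cohorts of directly
  simulated smooth difference curves; effect recovery uses 50 (test) / 20
  (acceptance script) full synthetic cohorts of 16 subjects, which keeps
  the complete suite within a few minutes on one core.

## Known limitations

* Cluster p-values use suprathreshold *extent*; mass-based or TFCE-style
  inference is not implemented.
* The parametric branch reports clusters at the RFT height threshold
  without set-level cluster p-values.
* The speed criterion's σ is a per-trial quantity; a cross-subject
  targeted-speed SD is only expressible through the absolute-band option.
* The mvnx reader targets the documented schema subset (jointAngle +
  position + optional footContacts) and fails loudly on anything else; it
  is not a general mvnx parser.
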