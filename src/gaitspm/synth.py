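"""Synthetic two-condition running kinematics with known ground truth.

The generator emulates the inputs of an overground paired-condition running
study: per-trial joint-angle streams (30 channels at 240 Hz), pelvis and
foot trajectories, a short speed ramp-up followed by a plateau at the target
speed, and condition effects injected into defined windows of the gait
cycle.  Every stochastic element is seeded, and each trial is returned
together with a :class:`TrialTruth` manifest (contact/toe-off samples,
per-step speeds, actual stride parameters) so downstream modules can be
tested closed-loop.

Geometry conventions: gravity-aligned frame, z vertical up, metres; the
runner advances along +x.  A *step* runs from one foot's contact to the
contralateral contact; the stride (one full gait cycle of a leg) covers two
steps.  Toe-off happens at ``toe_off_fraction`` of the active-leg (AL)
phase, 0.604 by default.

Angle templates are periodic Fourier curves (order <= 8) over the stride
resembling running kinematics; their exact coefficients are fixture
constants of this package, not claimed physiological truth — only the
statistical structure (smoothness, amplitudes, symmetry) matters for
testing the pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .channels import (
    ANGLE_CHANNELS,
    HANDED_DOFS,
    LEG_JOINTS,
    TRUNK_JOINTS,
    ChannelKey,
    Dof,
    Joint,
    Side,
)
from .recording import Recording

# --------------------------------------------------------------------------
# Effect specification
# --------------------------------------------------------------------------

PHASES = ("AL", "PL", "TRUNK")


@dataclass(frozen=True)
class EffectSpec:
    """A windowed condition effect on one collapsed angle channel.

    ``magnitude`` degrees are added to the affected channel of transition-run
    (TR) trials inside ``window`` (percent of the named phase), with either
    hard (``boxcar``) or raised-cosine edges.  Raised-cosine roll-offs extend
    *outside* the nominal window so that the full magnitude is reached
    throughout it (the windows are approximate by nature).  Leg-channel
    effects are applied to both legs, each in its own convention, so the
    mirrored/pooled curves carry the effect with the stated sign.
    """

    joint: Joint
    dof: Dof
    phase: str  # "AL" | "PL" | "TRUNK"
    window: tuple[float, float]  # percent of the phase
    magnitude: float  # degrees, signed
    shape: str = "raised_cosine"  # or "boxcar"

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"effect window must satisfy 0 <= start < end <= 100, got {self.window}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase == "TRUNK" and self.joint not in TRUNK_JOINTS:
            raise ValueError("TRUNK-phase effects must target a trunk joint")
        if self.phase != "TRUNK" and self.joint not in LEG_JOINTS:
            raise ValueError("AL/PL-phase effects must target a leg joint")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.shape not in ("raised_cosine", "boxcar"):
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def field_key(self) -> tuple[Joint, Dof, str]:
        return (self.joint, self.dof, self.phase)

    def node_window(self, n_nodes: int = 100) -> np.ndarray:
        """Indices of the normalized-curve nodes inside the nominal window."""
        lo, hi = self.window
        nodes = np.arange(n_nodes)
        return nodes[(nodes >= lo * n_nodes / 100.0) & (nodes < hi * n_nodes / 100.0)]

    def to_dict(self) -> dict:
        return {
            "joint": self.joint.value,
            "dof": self.dof.value,
            "phase": self.phase,
            "window": list(self.window),
            "magnitude": self.magnitude,
            "shape": self.shape,
        }


# --------------------------------------------------------------------------
# Gait model
# --------------------------------------------------------------------------


@dataclass
class GaitModel:
    """Parameters of the synthetic running model.

    Spatiotemporal defaults follow the warm-up-run scale of the emulated
    study: stride 2.52 m at 84.63 strides/min (implied speed
    2.52 * 84.63 * 0.06 = 12.79 km/h) and toe-off at 60.4 % of the
    active-leg phase.
    """

    stride_length_m: float = 2.52
    stride_frequency_per_min: float = 84.63
    toe_off_fraction: float = 0.604
    sample_rate: float = 240.0

    #: total number of steps per trial (two steps per stride)
    n_steps: int = 28
    #: per-step speed multipliers for the initial ramp-up before the plateau
    ramp_step_fractions: tuple[float, ...] = (0.6, 0.8)

    # noise / variability (degrees unless noted)
    step_noise_deg: float = 2.0  # step-to-step smooth angular noise SD
    noise_ctrl_points: int = 6  # control points per step of the noise process
    subject_offset_sd_deg: float = 3.0  # constant per-subject channel offsets
    condition_response_sd_deg: float = 0.2  # smooth per-(subject,condition) curve SD
    subject_param_cv: float = 0.05  # between-subject CV of stride length/frequency
    trial_param_cv: float = 0.01  # within-subject, between-trial CV
    step_speed_jitter_cv: float = 0.008  # per-step speed jitter on the plateau
    toe_off_fraction_sd: float = 0.02  # per-step jitter of the toe-off fraction

    # kinematic shape parameters
    swing_start_speed_ms: float = 5.0  # foot speed just after toe-off
    swing_end_speed_ms: float = 2.8  # foot speed just before touchdown
    swing_height_m: float = 0.12
    pelvis_height_m: float = 0.95
    pelvis_bounce_m: float = 0.03
    pelvis_sway_m: float = 0.02
    foot_lead_m: float = 0.25  # foot plant ahead of the pelvis at contact

    fourier_order: int = 6
    effect_ramp_pct: float = 5.0  # raised-cosine roll-off width, % of phase
    lead_in_s: float = 0.05  # recorded time before the first contact

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.4 < self.toe_off_fraction < 0.8:
            raise ValueError("toe_off_fraction must lie in (0.4, 0.8)")
        for name in ("stride_length_m", "stride_frequency_per_min", "sample_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_steps < 4:
            raise ValueError("n_steps must be at least 4")
        if any(not 0 < f <= 1 for f in self.ramp_step_fractions):
            raise ValueError("ramp fractions must lie in (0, 1]")
        if self.fourier_order > 8:
            raise ValueError("fourier_order must be <= 8")

    @property
    def stride_duration_s(self) -> float:
        return 60.0 / self.stride_frequency_per_min

    @property
    def step_duration_s(self) -> float:
        return self.stride_duration_s / 2.0

    @property
    def implied_velocity_kmh(self) -> float:
        return self.stride_length_m * self.stride_frequency_per_min * 0.06

    def grid_aligned(self) -> "GaitModel":
        """A copy whose step duration is an exact number of samples.

        With contacts on the sample grid, pipeline output differs from the
        underlying template only by interpolation error — useful for
        testing normalization fidelity without sampling quantization.
        """
        n = max(2, round(self.step_duration_s * self.sample_rate))
        return dataclasses.replace(self, stride_frequency_per_min=30.0 * self.sample_rate / n)

    def noiseless(self) -> "GaitModel":
        """A copy with every stochastic component switched off."""
        return dataclasses.replace(
            self,
            step_noise_deg=0.0,
            subject_offset_sd_deg=0.0,
            condition_response_sd_deg=0.0,
            subject_param_cv=0.0,
            trial_param_cv=0.0,
            step_speed_jitter_cv=0.0,
            toe_off_fraction_sd=0.0,
        )


def default_study_model() -> tuple[GaitModel, list[EffectSpec]]:
    """The study-conditions model: Table-1 scale plus the reported effects.

    The effect list transcribes the reported condition differences: trunk
    extension (1 deg at L5S1, 0.5 deg at the cranial joints, whole cycle),
    trunk external rotation (0.5 / 0.2 deg), more hip flexion (+3 deg from
    ~65 % AL to ~55 % PL), internal hip rotation (+2.5 deg over the AL phase
    and 0-30 % PL), knee adduction (+1 deg at 80-95 % AL) and the triphasic
    knee flexion pattern (+2 deg at 20-30 % AL, -3 deg at 65-85 % AL,
    +4 deg at 50-80 % PL).  Flexion and internal rotation are positive, so
    extension/external-rotation effects carry negative magnitudes.
    """
    model = GaitModel()
    F, A, R = Dof.FLEXION_EXTENSION, Dof.ABDUCTION_ADDUCTION, Dof.INTERNAL_EXTERNAL_ROTATION
    effects = [
        EffectSpec(Joint.L5S1, F, "TRUNK", (0, 100), -1.0),
        EffectSpec(Joint.L4L3, F, "TRUNK", (0, 100), -0.5),
        EffectSpec(Joint.L1T12, F, "TRUNK", (0, 100), -0.5),
        EffectSpec(Joint.T9T8, F, "TRUNK", (0, 100), -0.5),
        EffectSpec(Joint.L5S1, R, "TRUNK", (0, 100), -0.5),
        EffectSpec(Joint.L4L3, R, "TRUNK", (0, 100), -0.2),
        EffectSpec(Joint.L1T12, R, "TRUNK", (0, 100), -0.2),
        EffectSpec(Joint.T9T8, R, "TRUNK", (0, 100), -0.2),
        EffectSpec(Joint.HIP, F, "AL", (65, 100), 3.0),
        EffectSpec(Joint.HIP, F, "PL", (0, 55), 3.0),
        EffectSpec(Joint.HIP, R, "AL", (0, 100), 2.5),
        EffectSpec(Joint.HIP, R, "PL", (0, 30), 2.5),
        EffectSpec(Joint.KNEE, A, "AL", (80, 95), 1.0),
        EffectSpec(Joint.KNEE, F, "AL", (20, 30), 2.0),
        EffectSpec(Joint.KNEE, F, "AL", (65, 85), -3.0),
        EffectSpec(Joint.KNEE, F, "PL", (50, 80), 4.0),
    ]
    return model, effects


# --------------------------------------------------------------------------
# Angle templates
# --------------------------------------------------------------------------

# Knots (stride phase, degrees) for the leg channels, right-side convention,
# phase 0 = own foot contact, toe-off near 0.302 of the stride.
_LEG_KNOTS: dict[tuple[Joint, Dof], list[tuple[float, float]]] = {
    (Joint.HIP, Dof.FLEXION_EXTENSION): [
        (0.0, 33), (0.1, 28), (0.2, 6), (0.302, -8), (0.4, 5),
        (0.55, 30), (0.7, 52), (0.85, 44), (0.95, 36),
    ],
    (Joint.HIP, Dof.ABDUCTION_ADDUCTION): [
        (0.0, 6), (0.1, 9), (0.2, 7), (0.302, 1), (0.45, -4),
        (0.6, -5), (0.8, -1), (0.9, 3),
    ],
    (Joint.HIP, Dof.INTERNAL_EXTERNAL_ROTATION): [
        (0.0, 1), (0.1, 5), (0.2, 3), (0.302, -4), (0.5, -7),
        (0.7, -4), (0.9, -1),
    ],
    (Joint.KNEE, Dof.FLEXION_EXTENSION): [
        (0.0, 16), (0.1, 38), (0.2, 33), (0.302, 24), (0.45, 75),
        (0.55, 96), (0.65, 88), (0.8, 45), (0.9, 24),
    ],
    (Joint.KNEE, Dof.ABDUCTION_ADDUCTION): [
        (0.0, 1), (0.1, 4), (0.2, 3), (0.302, 0), (0.5, -4),
        (0.7, -3), (0.85, -1),
    ],
    (Joint.KNEE, Dof.INTERNAL_EXTERNAL_ROTATION): [
        (0.0, -2), (0.1, 3), (0.2, 1), (0.302, -3), (0.5, 5),
        (0.7, 3), (0.85, 0),
    ],
    (Joint.ANKLE, Dof.FLEXION_EXTENSION): [
        (0.0, 3), (0.08, 14), (0.18, 11), (0.25, -2), (0.302, -17),
        (0.4, -2), (0.55, 6), (0.75, 9), (0.9, 5),
    ],
    (Joint.ANKLE, Dof.ABDUCTION_ADDUCTION): [
        (0.0, -2), (0.15, 2), (0.302, -4), (0.55, 1), (0.8, -1),
    ],
    (Joint.ANKLE, Dof.INTERNAL_EXTERNAL_ROTATION): [
        (0.0, 2), (0.15, -3), (0.302, 4), (0.55, -2), (0.8, 1),
    ],
}

# Trunk templates: flexion oscillates once per *step* (even stride
# harmonics); frontal/transverse channels are stride-antisymmetric (odd
# harmonics only), so a half-stride shift flips their sign — this is what
# makes left- and right-lead steps poolable after mirroring.
_TRUNK_FLEX = {Joint.L5S1: (8.0, 1.5), Joint.L4L3: (6.0, 1.2), Joint.L1T12: (4.0, 1.0), Joint.T9T8: (2.0, 0.8)}
_TRUNK_ABD_AMP = {Joint.L5S1: 3.0, Joint.L4L3: 2.0, Joint.L1T12: 1.5, Joint.T9T8: 1.2}
_TRUNK_ROT_AMP = {Joint.L5S1: 5.0, Joint.L4L3: 3.0, Joint.L1T12: 2.5, Joint.T9T8: 2.0}


def _fourier_coeffs_from_knots(knots: list[tuple[float, float]], order: int) -> np.ndarray:
    """Low-pass Fourier coefficients of the periodic linear interpolant."""
    phi, val = zip(*sorted(knots))
    grid = np.linspace(0.0, 1.0, 512, endpoint=False)
    dense = np.interp(grid, phi, val, period=1.0)
    spec = np.fft.rfft(dense) / len(dense)
    return spec[: order + 1]


def _eval_fourier(coeffs: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.full_like(phi, coeffs[0].real, dtype=float)
    for m in range(1, len(coeffs)):
        out += 2.0 * (coeffs[m].real * np.cos(2 * np.pi * m * phi) - coeffs[m].imag * np.sin(2 * np.pi * m * phi))
    return out


class TemplateSet:
    """Per-channel stride-periodic angle templates for one model."""

    def __init__(self, model: GaitModel):
        self.order = model.fourier_order
        self._leg = {
            key: _fourier_coeffs_from_knots(knots, self.order) for key, knots in _LEG_KNOTS.items()
        }

    def leg(self, joint: Joint, dof: Dof, phi: np.ndarray) -> np.ndarray:
        """Leg-channel template at stride phase ``phi`` (0 = own contact)."""
        return _eval_fourier(self._leg[(joint, dof)], np.asarray(phi, dtype=float))

    def trunk(self, joint: Joint, dof: Dof, phi: np.ndarray) -> np.ndarray:
        """Trunk-channel template at stride phase ``phi`` (0 = right contact)."""
        phi = np.asarray(phi, dtype=float)
        if dof is Dof.FLEXION_EXTENSION:
            mean, amp = _TRUNK_FLEX[joint]
            return mean + amp * np.cos(4 * np.pi * phi - 0.6)
        if dof is Dof.ABDUCTION_ADDUCTION:
            return _TRUNK_ABD_AMP[joint] * np.sin(2 * np.pi * phi + 0.4)
        return _TRUNK_ROT_AMP[joint] * np.sin(2 * np.pi * phi + 1.0)

    def collapsed(self, joint: Joint, dof: Dof, phi: np.ndarray) -> np.ndarray:
        if joint in TRUNK_JOINTS:
            return self.trunk(joint, dof, phi)
        return self.leg(joint, dof, phi)


# --------------------------------------------------------------------------
# Effect profiles in phase space
# --------------------------------------------------------------------------


def _window_profile(x: np.ndarray, lo: float, hi: float, ramp: float, shape: str, period: float = 1.0) -> np.ndarray:
    """Unit profile: 1 on [lo, hi], roll-offs of width ``ramp`` outside.

    ``x`` is a periodic coordinate with the given period; roll-offs wrap.
    """
    x = np.mod(x, period)
    prof = np.zeros_like(x, dtype=float)
    inside = (x >= lo) & (x <= hi)
    prof[inside] = 1.0
    if shape == "raised_cosine" and ramp > 0:
        for edge, sgn in ((lo, -1.0), (hi, +1.0)):
            d = np.mod(sgn * (x - edge), period)  # distance beyond the edge
            on_ramp = (d > 0) & (d < ramp) & ~inside
            prof[on_ramp] = np.maximum(prof[on_ramp], 0.5 * (1 + np.cos(np.pi * d[on_ramp] / ramp)))
    return prof


def effect_profile_leg(effect: EffectSpec, model: GaitModel, phi: np.ndarray) -> np.ndarray:
    """Signed effect (degrees) on a collapsed leg channel at stride phase phi.

    AL occupies stride phase [0, 0.5), PL [0.5, 1.0).
    """
    lo, hi = effect.window
    base = 0.0 if effect.phase == "AL" else 0.5
    ramp = model.effect_ramp_pct / 200.0  # percent of a phase -> stride units
    return effect.magnitude * _window_profile(
        np.asarray(phi, float), base + lo / 200.0, base + hi / 200.0, ramp, effect.shape
    )


def effect_profile_trunk(effect: EffectSpec, model: GaitModel, phi: np.ndarray) -> np.ndarray:
    """Signed effect on a trunk channel at stride phase phi (0 = right contact).

    The window is a fraction of the *step*; frontal/transverse effects
    alternate sign between right- and left-lead steps so that pooled
    (mirrored) curves carry a consistent sign.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.mod(2.0 * phi, 1.0)  # step phase
    lo, hi = effect.window
    ramp = model.effect_ramp_pct / 100.0
    prof = effect.magnitude * _window_profile(psi, lo / 100.0, hi / 100.0, ramp, effect.shape)
    if effect.dof in HANDED_DOFS:
        prof = prof * np.where(np.mod(phi, 1.0) < 0.5, 1.0, -1.0)
    return prof


# --------------------------------------------------------------------------
# Trial generation
# --------------------------------------------------------------------------


@dataclass
class StepTruth:
    index: int
    lead_side: Side
    start_sample: int
    end_sample: int
    toe_off_sample: int
    speed_kmh: float
    toe_off_fraction: float


@dataclass
class TrialTruth:
    """Ground truth emitted alongside a generated trial."""

    condition: str
    contacts: list[tuple[int, Side]]
    toe_offs: list[tuple[int, Side]]
    steps: list[StepTruth]
    stride_length_m: float
    stride_frequency_per_min: float
    velocity_kmh: float
    toe_off_fraction: float
    window_start_step: int  # first step on the speed plateau
    effects: list[EffectSpec]

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "contacts": [[int(i), s.value] for i, s in self.contacts],
            "toe_offs": [[int(i), s.value] for i, s in self.toe_offs],
            "stride_length_m": self.stride_length_m,
            "stride_frequency_per_min": self.stride_frequency_per_min,
            "velocity_kmh": self.velocity_kmh,
            "toe_off_fraction": self.toe_off_fraction,
            "window_start_step": self.window_start_step,
            "step_speeds_kmh": [s.speed_kmh for s in self.steps],
            "effects": [e.to_dict() for e in self.effects],
        }


def _subject_rng(subject_seed: int) -> np.random.Generator:
    return np.random.default_rng([0x5A17, int(subject_seed)])


def _condition_rng(subject_seed: int, condition: str) -> np.random.Generator:
    return np.random.default_rng([0x5A17, int(subject_seed), 0 if condition == "WR" else 1])


def _trial_rng(subject_seed: int, condition: str, trial_seed: int) -> np.random.Generator:
    return np.random.default_rng([0x5A17, int(subject_seed), 0 if condition == "WR" else 1, int(trial_seed)])


_COLLAPSED_CHANNELS: list[tuple[Joint, Dof]] = [(j, d) for j in TRUNK_JOINTS for d in Dof] + [
    (j, d) for j in LEG_JOINTS for d in Dof
]


def _draw_subject_offsets(rng: np.random.Generator, model: GaitModel) -> dict[tuple[Joint, Dof], float]:
    offsets = {}
    for joint, dof in _COLLAPSED_CHANNELS:
        if joint in TRUNK_JOINTS and dof in HANDED_DOFS:
            offsets[(joint, dof)] = 0.0  # keep trunk frontal/transverse antisymmetric
        else:
            offsets[(joint, dof)] = rng.normal(0.0, model.subject_offset_sd_deg)
    return offsets


def _draw_response_coeffs(rng: np.random.Generator, model: GaitModel) -> dict[tuple[Joint, Dof], np.ndarray]:
    """Smooth per-(subject, condition) response curves as stride harmonics.

    Three harmonics per channel, scaled so the pointwise SD equals
    ``condition_response_sd_deg``.  Trunk frontal/transverse channels use odd
    harmonics only, preserving their antisymmetry.
    """
    out = {}
    sd = model.condition_response_sd_deg
    for joint, dof in _COLLAPSED_CHANNELS:
        harmonics = (1, 3, 5) if (joint in TRUNK_JOINTS and dof in HANDED_DOFS) else (1, 2, 3)
        coeffs = rng.normal(0.0, sd / np.sqrt(len(harmonics)), size=(len(harmonics), 2))
        out[(joint, dof)] = np.column_stack([np.asarray(harmonics, float), coeffs])
    return out


def _eval_response(coeffs: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.zeros_like(phi, dtype=float)
    for m, a, b in coeffs:
        out += a * np.cos(2 * np.pi * m * phi) + b * np.sin(2 * np.pi * m * phi)
    return out


def generate_trial(
    model: GaitModel,
    condition: str,
    subject_seed: int,
    trial_seed: int,
    effects: tuple[EffectSpec, ...] | list[EffectSpec] = (),
    with_event_flags: bool = False,
    templates: TemplateSet | None = None,
) -> tuple[Recording, TrialTruth]:
    """Generate one trial and its ground truth.

    Subject-level draws (channel offsets, stride parameters, condition
    response curves) depend only on ``subject_seed`` (and the condition for
    the response curves), so a subject's WR and TR trials share them; the
    step-to-step noise stream additionally depends on ``trial_seed``.
    Effects are applied to TR trials only.
    """
    if condition not in ("WR", "TR"):
        raise ValueError("condition must be WR or TR")
    if subject_seed is None or trial_seed is None:
        raise ValueError("subject_seed and trial_seed are required for reproducibility")
    model.validate()
    templates = templates or TemplateSet(model)

    rng_subj = _subject_rng(subject_seed)
    rng_cond = _condition_rng(subject_seed, condition)
    rng_trial = _trial_rng(subject_seed, condition, trial_seed)

    # --- stride parameters for this trial -------------------------------
    z_sub = rng_subj.normal(size=2)
    offsets = _draw_subject_offsets(rng_subj, model)
    response = _draw_response_coeffs(rng_cond, model)
    z_tri = rng_trial.normal(size=2)
    stride_len = model.stride_length_m * (1 + model.subject_param_cv * z_sub[0]) * (1 + model.trial_param_cv * z_tri[0])
    stride_freq = model.stride_frequency_per_min * (1 + model.subject_param_cv * z_sub[1]) * (
        1 + model.trial_param_cv * z_tri[1]
    )
    T_stride = 60.0 / stride_freq
    Ts = T_stride / 2.0
    step_len = stride_len / 2.0
    fs = model.sample_rate

    # --- per-step schedule ----------------------------------------------
    n_steps = model.n_steps
    factors = np.ones(n_steps)
    ramp = np.asarray(model.ramp_step_fractions)
    factors[: len(ramp)] = ramp
    factors[len(ramp):] *= 1.0 + model.step_speed_jitter_cv * rng_trial.normal(size=n_steps - len(ramp))
    step_lengths = step_len * factors
    t0 = model.lead_in_s
    boundaries_t = t0 + Ts * np.arange(n_steps + 1)  # contact times
    total_T = boundaries_t[-1] + model.lead_in_s
    n_samples = int(np.floor(total_T * fs)) + 1
    t = np.arange(n_samples) / fs

    toe_fracs = np.clip(
        model.toe_off_fraction + model.toe_off_fraction_sd * rng_trial.normal(size=n_steps + 1),
        0.45, 0.75,
    )

    # --- pelvis -----------------------------------------------------------
    boundary_x = np.concatenate([[0.0], np.cumsum(step_lengths)])
    # linear within steps, extrapolated at the constant adjacent-step speed
    pelvis_x = np.interp(t, boundaries_t, boundary_x)
    pre = t < boundaries_t[0]
    post = t > boundaries_t[-1]
    pelvis_x[pre] = boundary_x[0] - (boundaries_t[0] - t[pre]) * step_lengths[0] / Ts
    pelvis_x[post] = boundary_x[-1] + (t[post] - boundaries_t[-1]) * step_lengths[-1] / Ts
    phi = (t - t0) / T_stride  # stride phase of the right leg (unwrapped)
    pelvis = np.column_stack(
        [
            pelvis_x,
            model.pelvis_sway_m * np.sin(2 * np.pi * phi),
            model.pelvis_height_m + model.pelvis_bounce_m * np.cos(4 * np.pi * phi),
        ]
    )

    # --- feet -------------------------------------------------------------
    def pelvis_x_at(time: float) -> float:
        # linear extrapolation keeps virtual (out-of-record) stances moving
        # at the adjacent step speed
        if time < boundaries_t[0]:
            return float(boundary_x[0] - (boundaries_t[0] - time) * step_lengths[0] / Ts)
        if time > boundaries_t[-1]:
            return float(boundary_x[-1] + (time - boundaries_t[-1]) * step_lengths[-1] / Ts)
        return float(np.interp(time, boundaries_t, boundary_x))

    def foot_track(first_contact_idx: int) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
        """Piecewise stance/swing track for the foot whose contacts are at
        boundary indices ``first_contact_idx, first_contact_idx+2, ...``
        (including virtual contacts outside the record)."""
        x = np.empty(n_samples)
        z = np.empty(n_samples)
        stance_windows: list[tuple[int, int]] = []  # sample ranges, truth
        idxs = list(range(first_contact_idx - 2, n_steps + 3, 2))
        contact_t = {k: t0 + Ts * k for k in idxs}
        stance_x = {k: pelvis_x_at(contact_t[k]) + model.foot_lead_m for k in idxs}
        toe_t = {}
        for k in idxs:
            frac = toe_fracs[k] if 0 <= k <= n_steps else model.toe_off_fraction
            toe_t[k] = contact_t[k] + frac * Ts
        v0, v1 = model.swing_start_speed_ms, model.swing_end_speed_ms
        eps = 1e-7  # guards against float jitter at exact sample-grid boundaries
        for k in idxs:
            # stance [contact, toe-off]
            m_st = (t >= contact_t[k] - eps) & (t <= toe_t[k] + eps)
            x[m_st] = stance_x[k]
            z[m_st] = 0.0
            # swing (toe-off, next contact)
            nk = k + 2
            if nk not in contact_t:
                continue
            T_sw = contact_t[nk] - toe_t[k]
            dX = stance_x[nk] - stance_x[k]
            A = (dX / T_sw - 0.5 * (v0 + v1)) * np.pi / 2.0
            m_sw = (t > toe_t[k] + eps) & (t < contact_t[nk] - eps)
            s = (t[m_sw] - toe_t[k]) / T_sw
            x[m_sw] = stance_x[k] + T_sw * (v0 * s + 0.5 * (v1 - v0) * s**2 + A * (1 - np.cos(np.pi * s)) / np.pi)
            z[m_sw] = model.swing_height_m * np.sin(np.pi * s) ** 2
            if 0 <= k <= n_steps:
                i0 = int(np.ceil(contact_t[k] * fs - 1e-5))
                i1 = int(np.floor(toe_t[k] * fs + 1e-5))
                if 0 <= i0 < n_samples:
                    stance_windows.append((i0, min(i1, n_samples - 1)))
        return x, z, stance_windows

    rx, rz, r_stance = foot_track(0)
    lx, lz, l_stance = foot_track(1)
    sway_foot = 0.0  # feet run parallel to x; lateral offset irrelevant to events
    right_foot = np.column_stack([rx, np.full(n_samples, -0.1 + sway_foot), rz])
    left_foot = np.column_stack([lx, np.full(n_samples, 0.1 + sway_foot), lz])

    # --- angles -----------------------------------------------------------
    apply_effects = tuple(effects) if condition == "TR" else ()
    leg_eff = [e for e in apply_effects if e.phase != "TRUNK"]
    trunk_eff = [e for e in apply_effects if e.phase == "TRUNK"]

    angles: dict[ChannelKey, np.ndarray] = {}
    phi_r = np.mod(phi, 1.0)
    phi_l = np.mod(phi - 0.5, 1.0)

    def collapsed_curve(joint: Joint, dof: Dof, ph: np.ndarray) -> np.ndarray:
        cur = templates.collapsed(joint, dof, ph) + offsets[(joint, dof)] + _eval_response(response[(joint, dof)], ph)
        if joint in TRUNK_JOINTS:
            for e in trunk_eff:
                if e.joint is joint and e.dof is dof:
                    cur = cur + effect_profile_trunk(e, model, ph)
        else:
            for e in leg_eff:
                if e.joint is joint and e.dof is dof:
                    cur = cur + effect_profile_leg(e, model, ph)
        return cur

    for joint in TRUNK_JOINTS:
        for dof in Dof:
            angles[ChannelKey(joint, Side.NONE, dof)] = collapsed_curve(joint, dof, phi_r)
    for joint in LEG_JOINTS:
        for dof in Dof:
            sgn = -1.0 if dof in HANDED_DOFS else 1.0
            angles[ChannelKey(joint, Side.RIGHT, dof)] = collapsed_curve(joint, dof, phi_r)
            angles[ChannelKey(joint, Side.LEFT, dof)] = sgn * collapsed_curve(joint, dof, phi_l)

    # --- step-to-step smooth noise ---------------------------------------
    if model.step_noise_deg > 0:
        nc = model.noise_ctrl_points
        n_chan = len(ANGLE_CHANNELS)
        step_idx = np.clip(np.floor((t - t0) / Ts).astype(int) + 1, 0, n_steps + 1)
        ctrl = rng_trial.normal(0.0, model.step_noise_deg, size=(n_steps + 2, n_chan, nc))
        u = np.clip((t - t0) / Ts - (step_idx - 1), 0.0, 1.0) * (nc - 1)
        i0 = np.minimum(u.astype(int), nc - 2)
        w = u - i0
        chans = np.arange(n_chan)
        lo = ctrl[step_idx[:, None], chans[None, :], i0[:, None]]
        hi = ctrl[step_idx[:, None], chans[None, :], (i0 + 1)[:, None]]
        noise = lo * (1 - w[:, None]) + hi * w[:, None]
        for j, key in enumerate(ANGLE_CHANNELS):
            angles[key] = angles[key] + noise[:, j]

    # --- truth and flags ---------------------------------------------------
    contacts: list[tuple[int, Side]] = []
    toe_offs: list[tuple[int, Side]] = []
    for k in range(n_steps + 1):
        side = Side.RIGHT if k % 2 == 0 else Side.LEFT
        c = int(np.ceil((t0 + Ts * k) * fs - 1e-5))
        to = int(np.floor((t0 + Ts * (k + toe_fracs[k])) * fs + 1e-5))
        if c < n_samples:
            contacts.append((c, side))
        if to < n_samples:
            toe_offs.append((to, side))

    steps_truth: list[StepTruth] = []
    speeds = step_lengths / Ts * 3.6
    for k in range(n_steps):
        c0, s0 = contacts[k]
        c1, _ = contacts[k + 1]
        to = toe_offs[k][0]
        steps_truth.append(
            StepTruth(
                index=k, lead_side=s0, start_sample=c0, end_sample=c1, toe_off_sample=to,
                speed_kmh=float(speeds[k]), toe_off_fraction=float(toe_fracs[k]),
            )
        )

    flags = None
    if with_event_flags:
        flags = {Side.RIGHT: np.zeros(n_samples, dtype=bool), Side.LEFT: np.zeros(n_samples, dtype=bool)}
        for side, windows in ((Side.RIGHT, r_stance), (Side.LEFT, l_stance)):
            for i0_, i1_ in windows:
                flags[side][i0_: i1_ + 1] = True

    rec = Recording(
        trial_id=f"synth-s{subject_seed}-{condition}-t{trial_seed}",
        condition=condition,
        sample_rate=fs,
        angles=angles,
        positions={"pelvis": pelvis, "right_foot": right_foot, "left_foot": left_foot},
        event_flags=flags,
    )
    truth = TrialTruth(
        condition=condition,
        contacts=contacts,
        toe_offs=toe_offs,
        steps=steps_truth,
        stride_length_m=float(stride_len),
        stride_frequency_per_min=float(stride_freq),
        velocity_kmh=float(stride_len * stride_freq * 0.06),
        toe_off_fraction=model.toe_off_fraction,
        window_start_step=len(model.ramp_step_fractions),
        effects=list(apply_effects),
    )
    return rec, truth


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass
class SubjectData:
    subject_id: str
    subject_seed: int
    recordings: dict[str, Recording]
    truths: dict[str, TrialTruth]


@dataclass
class Cohort:
    model: GaitModel
    effects: list[EffectSpec]
    subjects: list[SubjectData]
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": len(self.subjects),
            "effects": [e.to_dict() for e in self.effects],
            "subjects": {
                s.subject_id: {cond: tr.to_dict() for cond, tr in s.truths.items()} for s in self.subjects
            },
        }


def generate_cohort(
    model: GaitModel,
    effects: list[EffectSpec] | tuple[EffectSpec, ...] = (),
    n_subjects: int = 16,
    seed: int = 0,
    with_event_flags: bool = False,
) -> Cohort:
    """Paired WR/TR recordings for ``n_subjects`` subjects.

    Subject random effects (offsets, stride parameters) are shared across a
    subject's two conditions; effects are injected into TR trials only.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    templates = TemplateSet(model)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    trial_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 2))
    subjects = []
    for i in range(n_subjects):
        recs, truths = {}, {}
        for j, cond in enumerate(("WR", "TR")):
            rec, truth = generate_trial(
                model, cond, int(subject_seeds[i]), int(trial_seeds[i, j]),
                effects=effects, with_event_flags=with_event_flags, templates=templates,
            )
            recs[cond], truths[cond] = rec, truth
        subjects.append(SubjectData(f"S{i:02d}", int(subject_seeds[i]), recs, truths))
    return Cohort(model=model, effects=list(effects), subjects=subjects, seed=seed)
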