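"""Mirroring, phase splitting, time normalization and curve ensembles.

After mirroring, a left-lead step looks exactly like a right-lead step:
left- and right-lead steps can be pooled and no left/right distinction
remains.  Each step contributes, per collapsed channel, an active-leg (AL)
curve over its own interval, a passive-leg (PL) curve of its lead leg over
the subsequent step's interval, and whole-step trunk curves.  All curves
are linearly resampled onto 100 nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .channels import HANDED_DOFS, LEG_JOINTS, TRUNK_JOINTS, ChannelKey, Dof, Joint, Side
from .events import StepCycle

logger = logging.getLogger(__name__)

PHASE_AL = "AL"
PHASE_PL = "PL"
PHASE_TRUNK = "TRUNK"

#: (joint, dof, phase) keys of the 30 analyzed fields, fixed order.
FIELD_KEYS: list[tuple[Joint, Dof, str]] = (
    [(j, d, PHASE_TRUNK) for j in TRUNK_JOINTS for d in Dof]
    + [(j, d, PHASE_AL) for j in LEG_JOINTS for d in Dof]
    + [(j, d, PHASE_PL) for j in LEG_JOINTS for d in Dof]
)


def field_label(key: tuple[Joint, Dof, str]) -> str:
    joint, dof, phase = key
    return f"{joint.value}/{dof.value}/{phase}"


# --------------------------------------------------------------------------
# Mirroring
# --------------------------------------------------------------------------


def reflect_channels(channels: dict[ChannelKey, np.ndarray]) -> dict[ChannelKey, np.ndarray]:
    """Full-body left/right reflection.

    Swaps left and right channels and sign-flips the handed DOFs
    (abduction/adduction, internal/external rotation) of every joint,
    trunk included; sagittal channels are untouched.  An involution.
    """
    out: dict[ChannelKey, np.ndarray] = {}
    for key, values in channels.items():
        sgn = -1.0 if key.dof in HANDED_DOFS else 1.0
        out[key.mirrored()] = sgn * np.asarray(values, dtype=float)
    return out


def mirror_left(channels: dict[ChannelKey, np.ndarray], step: StepCycle) -> dict[ChannelKey, np.ndarray]:
    """Express a step's channels in right-lead convention.

    Right-lead steps pass through unchanged; left-lead steps are reflected,
    so the lead leg's data always sits on the right-side channels and the
    trunk frontal/transverse channels are pooled consistently across body
    sides.
    """
    if step.lead_side is Side.RIGHT:
        return dict(channels)
    return reflect_channels(channels)


# --------------------------------------------------------------------------
# Phase windows
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseWindow:
    phase: str
    start: int
    end: int  # inclusive sample bounds


def split_phases(step: StepCycle, next_step: StepCycle | None) -> tuple[PhaseWindow, PhaseWindow | None]:
    """AL and PL windows for the lead leg of ``step``.

    The AL phase is the step itself (touchdown to contralateral touchdown);
    the PL phase is the remaining swing, i.e. the following step's interval,
    attributed to this step's lead leg.  Trunk channels use the plain step
    window.  When there is no following step, the PL window is absent.
    """
    al = PhaseWindow(PHASE_AL, step.start, step.end)
    if next_step is None:
        logger.warning("step at sample %d has no successor; PL phase absent", step.start)
        return al, None
    if next_step.start != step.end:
        raise ValueError("steps are not consecutive")
    if next_step.lead_side is step.lead_side:
        raise ValueError("consecutive steps must alternate lead side")
    return al, PhaseWindow(PHASE_PL, next_step.start, next_step.end)


# --------------------------------------------------------------------------
# Time normalization
# --------------------------------------------------------------------------


def time_normalize(samples: np.ndarray, n_nodes: int = 100) -> np.ndarray:
    """Linear resampling onto ``n_nodes`` equally spaced points.

    The nodes span the first to last sample inclusive; endpoints are
    preserved exactly.
    """
    y = np.asarray(samples, dtype=float)
    if y.ndim != 1:
        raise ValueError("samples must be a 1-D vector")
    if y.size < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    src = np.linspace(0.0, y.size - 1.0, n_nodes)
    out = np.interp(src, np.arange(y.size), y)
    out[0], out[-1] = y[0], y[-1]
    return out


# --------------------------------------------------------------------------
# Per-step curve extraction
# --------------------------------------------------------------------------


def step_curves(
    angles: dict[ChannelKey, np.ndarray],
    step: StepCycle,
    next_step: StepCycle | None,
    n_nodes: int = 100,
) -> dict[tuple[Joint, Dof, str], np.ndarray]:
    """All normalized curves contributed by one step.

    Mirrors left-lead steps, splits phases and time-normalizes.  Returns a
    mapping from (joint, dof, phase) to a 100-node curve; PL entries are
    missing when the step has no successor.
    """
    mirrored = mirror_left(angles, step)
    al, pl = split_phases(step, next_step)
    out: dict[tuple[Joint, Dof, str], np.ndarray] = {}
    for joint in TRUNK_JOINTS:
        for dof in Dof:
            seg = mirrored[ChannelKey(joint, Side.NONE, dof)][al.start: al.end + 1]
            out[(joint, dof, PHASE_TRUNK)] = time_normalize(seg, n_nodes)
    for joint in LEG_JOINTS:
        for dof in Dof:
            ch = mirrored[ChannelKey(joint, Side.RIGHT, dof)]  # lead leg, post-mirroring
            out[(joint, dof, PHASE_AL)] = time_normalize(ch[al.start: al.end + 1], n_nodes)
            if pl is not None:
                out[(joint, dof, PHASE_PL)] = time_normalize(ch[pl.start: pl.end + 1], n_nodes)
    return out


# --------------------------------------------------------------------------
# Ensembles
# --------------------------------------------------------------------------

CONDITIONS = ("WR", "TR")


@dataclass
class NormalizedEnsemble:
    """Subjects x conditions x fields x steps x nodes curve stack.

    ``median`` and ``iqr`` hold the node-wise per-subject median and
    interquartile range (Q3 - Q1, linear-interpolation quantile rule); the
    per-subject median curve is the unit entering the paired tests.
    """

    steps: np.ndarray  # (S, 2, K, M, N)
    median: np.ndarray  # (S, 2, K, N)
    iqr: np.ndarray  # (S, 2, K, N)
    subjects: list[str]
    fields: list[tuple[Joint, Dof, str]]
    conditions: tuple[str, str] = CONDITIONS
    n_nodes: int = 100

    def __post_init__(self) -> None:
        S, C, K, M, N = self.steps.shape
        if S == 0 or K == 0 or M == 0:
            raise ValueError("ensemble is empty")
        if C != len(self.conditions):
            raise ValueError("condition axis mismatch")
        if K != len(self.fields) or S != len(self.subjects) or N != self.n_nodes:
            raise ValueError("ensemble axes do not match metadata")
        if not np.isfinite(self.steps).all():
            raise ValueError("ensemble contains non-finite values")

    def field_index(self, key: tuple[Joint, Dof, str]) -> int:
        return self.fields.index(key)

    def paired_differences(self, key: tuple[Joint, Dof, str]) -> np.ndarray:
        """(S, N) matrix of per-subject TR-median minus WR-median curves."""
        k = self.field_index(key)
        i_wr = self.conditions.index("WR")
        i_tr = self.conditions.index("TR")
        return self.median[:, i_tr, k] - self.median[:, i_wr, k]


def _median_iqr(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(stack, axis=0)
    q1, q3 = np.percentile(stack, [25, 75], axis=0, method="linear")
    return med, q3 - q1


def build_ensemble(
    curves: dict[str, dict[str, dict[tuple[Joint, Dof, str], list[np.ndarray]]]],
    n_nodes: int = 100,
    fields: list[tuple[Joint, Dof, str]] | None = None,
) -> NormalizedEnsemble:
    """Stack per-trial curves into an ensemble.

    ``curves[subject][condition][field]`` is the list of per-step curves.
    Subjects missing a condition are excluded with a log entry; every
    retained (subject, condition) cell must have equal step counts across
    fields.
    """
    fields = fields or FIELD_KEYS
    kept: list[str] = []
    for subject, conds in curves.items():
        if all(c in conds and conds[c] for c in CONDITIONS):
            kept.append(subject)
        else:
            logger.warning("subject %s lacks a condition; excluded from the ensemble", subject)
    if not kept:
        raise ValueError("no subject has both conditions")

    counts = {
        len(curves[s][c][f])
        for s in kept
        for c in CONDITIONS
        for f in fields
    }
    if len(counts) != 1:
        raise ValueError(f"unequal step counts across cells/fields: {sorted(counts)}")
    (M,) = counts

    S, K = len(kept), len(fields)
    steps = np.empty((S, 2, K, M, n_nodes))
    for si, subject in enumerate(kept):
        for ci, cond in enumerate(CONDITIONS):
            for ki, f in enumerate(fields):
                steps[si, ci, ki] = np.vstack(curves[subject][cond][f])
    med = np.empty((S, 2, K, n_nodes))
    iqr = np.empty((S, 2, K, n_nodes))
    for si in range(S):
        for ci in range(2):
            for ki in range(K):
                med[si, ci, ki], iqr[si, ci, ki] = _median_iqr(steps[si, ci, ki])
    return NormalizedEnsemble(
        steps=steps, median=med, iqr=iqr, subjects=list(kept), fields=list(fields), n_nodes=n_nodes
    )
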