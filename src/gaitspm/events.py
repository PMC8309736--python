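"""Foot-contact / toe-off detection, step segmentation, window selection
and spatiotemporal summaries.

A *step* runs from one foot's first ground contact to the first contact of
the contralateral foot; the lead foot's toe-off falls inside it (running
has a flight phase).  The analyzed window is the first ``n_steps``
consecutive steps once per-step running speed has settled within
``target +/- k_sd * sigma`` of the target speed, emulating the
"first 20 steps once the target speed is reached" selection rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .channels import Side
from .recording import Recording

logger = logging.getLogger(__name__)


class NoGaitError(RuntimeError):
    pass


@dataclass
class GaitEventSet:
    """Timed foot contacts and toe-offs per side (sample indices)."""

    contacts: list[tuple[int, Side]]
    toe_offs: list[tuple[int, Side]]

    def __post_init__(self) -> None:
        for events in (self.contacts, self.toe_offs):
            events.sort(key=lambda e: e[0])
        for side in (Side.LEFT, Side.RIGHT):
            idx = [i for i, s in self.contacts if s is side]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"contacts for side {side.value} are not strictly increasing")

    def contacts_of(self, side: Side) -> list[int]:
        return [i for i, s in self.contacts if s is side]

    def toe_offs_of(self, side: Side) -> list[int]:
        return [i for i, s in self.toe_offs if s is side]

    def to_rows(self, sample_rate: float) -> list[dict]:
        rows = [
            {"sample_index": i, "time_s": i / sample_rate, "side": s.value, "type": kind}
            for kind, events in (("contact", self.contacts), ("toe_off", self.toe_offs))
            for i, s in events
        ]
        return sorted(rows, key=lambda r: (r["sample_index"], r["type"]))


@dataclass
class StepCycle:
    """One step: lead-foot contact to contralateral contact."""

    lead_side: Side
    start: int
    end: int
    lead_toe_off: int | None
    duration_s: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("step must have start < end")
        if self.lead_toe_off is not None and not (self.start < self.lead_toe_off < self.end):
            raise ValueError("toe-off must fall strictly inside the step")

    @property
    def relative_toe_off_pct(self) -> float | None:
        if self.lead_toe_off is None:
            return None
        return 100.0 * (self.lead_toe_off - self.start) / (self.end - self.start)


@dataclass
class SpatiotemporalSummary:
    mean_velocity_kmh: float
    mean_stride_length_m: float
    mean_frequency_per_min: float  # strides per minute
    analyzed_distance_m: float
    relative_toe_off_mean_pct: float
    relative_toe_off_sd_pct: float

    def __post_init__(self) -> None:
        for name in ("mean_velocity_kmh", "mean_stride_length_m", "mean_frequency_per_min", "analyzed_distance_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------


def _foot_speed(pos: np.ndarray, fs: float) -> np.ndarray:
    vel = np.gradient(pos, axis=0) * fs
    return np.linalg.norm(vel, axis=1)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    rec: Recording,
    v_contact_ms: float = 1.5,
    v_toeoff_ms: float = 2.0,
    min_low_samples: int = 2,
) -> GaitEventSet:
    """Detect contacts and toe-offs per foot.

    If the recording carries per-sample contact flags they take precedence:
    events are the flag transitions.  Otherwise a contact is placed at the
    (first) local minimum of vertical foot position within each sustained
    low-speed region (foot speed < ``v_contact_ms`` for at least
    ``min_low_samples``), and the toe-off at the subsequent sample where
    foot speed rises above ``v_toeoff_ms``.
    """
    contacts: list[tuple[int, Side]] = []
    toe_offs: list[tuple[int, Side]] = []

    if rec.event_flags is not None:
        for side, flags in rec.event_flags.items():
            flags = np.asarray(flags, dtype=bool)
            d = np.diff(flags.astype(np.int8))
            contacts.extend((int(i) + 1, side) for i in np.flatnonzero(d == 1))
            toe_offs.extend((int(i), side) for i in np.flatnonzero(d == -1))
            if flags[0]:
                logger.debug("%s: %s foot already in contact at trial start", rec.trial_id, side.value)
    else:
        for side, key in ((Side.RIGHT, "right_foot"), (Side.LEFT, "left_foot")):
            if key not in rec.positions:
                raise ValueError(f"recording lacks {key} positions; cannot detect events")
            pos = np.asarray(rec.positions[key], dtype=float)
            z = pos[:, 2]
            speed = _foot_speed(pos, rec.sample_rate)
            for lo, hi in _runs(speed < v_contact_ms):
                if hi - lo + 1 < min_low_samples:
                    continue
                seg = z[lo: hi + 1]
                contact = lo + int(np.argmin(seg))  # first occurrence of the minimum
                contacts.append((contact, side))
                above = np.flatnonzero(speed[contact + 1:] > v_toeoff_ms)
                if above.size:
                    toe_offs.append((contact + 1 + int(above[0]), side))

    if not contacts:
        raise NoGaitError(f"no gait detected in trial {rec.trial_id}")
    for side in (Side.LEFT, Side.RIGHT):
        n = sum(1 for _, s in contacts if s is side)
        if n < 2:
            raise NoGaitError(
                f"no gait detected in trial {rec.trial_id}: fewer than 2 contacts on side {side.value}"
            )
    return GaitEventSet(contacts=contacts, toe_offs=toe_offs)


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------


def segment_steps(events: GaitEventSet, sample_rate: float, trial_id: str = "") -> list[StepCycle]:
    """One step per (contact, next contralateral contact) pair.

    Two successive contacts on the same side signal a missed event; the
    interval is skipped and logged.  The trailing incomplete step (no
    contralateral contact) is dropped.
    """
    steps: list[StepCycle] = []
    contacts = events.contacts
    toe_by_side = {s: np.asarray(events.toe_offs_of(s)) for s in (Side.LEFT, Side.RIGHT)}
    for (c0, s0), (c1, s1) in zip(contacts, contacts[1:]):
        if s0 is s1:
            logger.warning("%s: successive contacts on side %s at samples %d, %d; interval skipped",
                           trial_id or "trial", s0.value, c0, c1)
            continue
        toes = toe_by_side[s0]
        inside = toes[(toes > c0) & (toes < c1)]
        steps.append(
            StepCycle(
                lead_side=s0,
                start=int(c0),
                end=int(c1),
                lead_toe_off=int(inside[0]) if inside.size else None,
                duration_s=(c1 - c0) / sample_rate,
            )
        )
    return steps


# --------------------------------------------------------------------------
# Analysis window
# --------------------------------------------------------------------------


def step_speeds_kmh(steps: list[StepCycle], rec: Recording) -> np.ndarray:
    """Per-step speed from horizontal pelvis displacement, km/h."""
    if "pelvis" not in rec.positions:
        raise ValueError("recording lacks pelvis positions")
    pel = np.asarray(rec.positions["pelvis"], dtype=float)[:, :2]
    out = np.empty(len(steps))
    for i, st in enumerate(steps):
        disp = np.linalg.norm(pel[st.end] - pel[st.start])
        out[i] = disp / st.duration_s * 3.6
    return out


def select_analysis_window(
    steps: list[StepCycle],
    rec: Recording,
    target_speed_kmh: float,
    k_sd: float = 2.0,
    n_steps: int = 20,
    speed_band_kmh: float | None = None,
) -> list[StepCycle]:
    """First ``n_steps`` consecutive steps once per-step speed is on target.

    The acceptance band is ``target +/- k_sd * sigma`` with ``sigma`` the SD
    of per-step speeds over the whole trial, or ``target +/- speed_band_kmh``
    when an absolute band is given.
    """
    if not steps:
        raise ValueError("no steps to select from")
    speeds = step_speeds_kmh(steps, rec)
    if speed_band_kmh is not None:
        band = float(speed_band_kmh)
    else:
        band = k_sd * float(np.std(speeds, ddof=1))
    dev = np.abs(speeds - target_speed_kmh)
    ok = np.flatnonzero(dev <= band)
    if ok.size == 0:
        raise ValueError(
            f"speed criterion never met: target {target_speed_kmh:.2f} km/h +/- {band:.2f}, "
            f"closest approach {dev.min():.2f} km/h at step {int(dev.argmin())}"
        )
    start = int(ok[0])
    if start + n_steps > len(steps):
        raise ValueError(
            f"insufficient steps after speed criterion: need {n_steps}, have {len(steps) - start}"
        )
    window = steps[start: start + n_steps]
    n_right = sum(1 for s in window if s.lead_side is Side.RIGHT)
    if n_right != n_steps // 2 or n_steps - n_right != n_steps // 2:
        logger.warning("analysis window is lead-imbalanced: %d right-lead vs %d left-lead",
                       n_right, n_steps - n_right)
    return window


# --------------------------------------------------------------------------
# Spatiotemporal summary
# --------------------------------------------------------------------------


def spatiotemporal(steps: list[StepCycle], rec: Recording) -> SpatiotemporalSummary:
    """Stride length / frequency / velocity / distance over a step window.

    Stride length is the horizontal pelvis displacement between successive
    ipsilateral contacts; frequency is 60 / stride duration (strides per
    minute); velocity is the total horizontal pelvis displacement over the
    window duration; the relative toe-off is expressed in % of each step
    (active-leg phase).
    """
    if "pelvis" not in rec.positions:
        raise ValueError("recording lacks pelvis positions")
    if len(steps) < 3:
        raise ValueError("need at least 3 steps (2 same-side contacts) for stride metrics")
    pel = np.asarray(rec.positions["pelvis"], dtype=float)[:, :2]
    fs = rec.sample_rate

    stride_lengths, stride_durations = [], []
    for a, b in zip(steps, steps[2:]):
        if a.lead_side is not b.lead_side:
            continue  # interleaving broken by a skipped interval
        stride_lengths.append(np.linalg.norm(pel[b.start] - pel[a.start]))
        stride_durations.append((b.start - a.start) / fs)
    if not stride_lengths:
        raise ValueError("no ipsilateral contact pairs in the window")

    span = np.linalg.norm(pel[steps[-1].end] - pel[steps[0].start])
    duration = (steps[-1].end - steps[0].start) / fs
    rel_to = np.asarray([s.relative_toe_off_pct for s in steps if s.relative_toe_off_pct is not None])

    return SpatiotemporalSummary(
        mean_velocity_kmh=span / duration * 3.6,
        mean_stride_length_m=float(np.mean(stride_lengths)),
        mean_frequency_per_min=float(np.mean(60.0 / np.asarray(stride_durations))),
        analyzed_distance_m=float(span),
        relative_toe_off_mean_pct=float(np.mean(rel_to)) if rel_to.size else float("nan"),
        relative_toe_off_sd_pct=float(np.std(rel_to, ddof=1)) if rel_to.size > 1 else 0.0,
    )
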