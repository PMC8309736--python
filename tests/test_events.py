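"""Event detection, step segmentation, window selection, spatiotemporal ops."""

import logging

import numpy as np
import pytest

from gaitspm.channels import ANGLE_CHANNELS, Side
from gaitspm.events import (
    GaitEventSet,
    NoGaitError,
    StepCycle,
    detect_events,
    segment_steps,
    select_analysis_window,
    spatiotemporal,
    step_speeds_kmh,
)
from gaitspm.recording import Recording
from gaitspm.synth import TemplateSet, generate_trial


def _match_errors(detected, truth):
    return [min(abs(i - j) for j, s2 in truth if s2 is s) for i, s in detected]


def test_detection_matches_truth_noise_free(noiseless_trial):
    """Contacts within +/-2 samples and toe-offs near truth on clean data."""
    _, rec, truth = noiseless_trial
    ev = detect_events(rec)
    assert len(ev.contacts) == len(truth.contacts)
    assert max(_match_errors(ev.contacts, truth.contacts)) <= 2
    assert max(_match_errors(ev.toe_offs, truth.toe_offs)) <= 2


def test_detection_matches_truth_default_noise(noisy_trial):
    _, rec, truth = noisy_trial
    ev = detect_events(rec)
    assert max(_match_errors(ev.contacts, truth.contacts)) <= 5
    assert max(_match_errors(ev.toe_offs, truth.toe_offs)) <= 5


def test_standing_still_raises_no_gait():
    T = 1000
    angles = {k: np.zeros(T) for k in ANGLE_CHANNELS}
    positions = {
        "pelvis": np.tile([0.0, 0.0, 0.95], (T, 1)),
        "left_foot": np.tile([0.0, 0.1, 0.0], (T, 1)),
        "right_foot": np.tile([0.0, -0.1, 0.0], (T, 1)),
    }
    rec = Recording("standing", "WR", 240.0, angles, positions)
    with pytest.raises(NoGaitError, match="no gait detected"):
        detect_events(rec)


def test_event_flags_take_precedence(study_model, templates):
    """With contact flags present, events equal the flag transitions exactly."""
    rec, _ = generate_trial(study_model, "WR", 9, 10, with_event_flags=True, templates=templates)
    ev = detect_events(rec)
    for side in (Side.LEFT, Side.RIGHT):
        flags = rec.event_flags[side].astype(np.int8)
        expected_contacts = (np.flatnonzero(np.diff(flags) == 1) + 1).tolist()
        expected_toes = np.flatnonzero(np.diff(flags) == -1).tolist()
        assert ev.contacts_of(side) == expected_contacts
        assert ev.toe_offs_of(side) == expected_toes


# ----------------------------------------------------------------- segment


def test_segment_constructed_example():
    """Contacts R@0, L@100, R@210 with toe-offs R@60, L@160 -> two steps."""
    ev = GaitEventSet(
        contacts=[(0, Side.RIGHT), (100, Side.LEFT), (210, Side.RIGHT)],
        toe_offs=[(60, Side.RIGHT), (160, Side.LEFT)],
    )
    steps = segment_steps(ev, sample_rate=240.0)
    assert len(steps) == 2
    assert (steps[0].lead_side, steps[0].start, steps[0].end, steps[0].lead_toe_off) == (Side.RIGHT, 0, 100, 60)
    assert (steps[1].lead_side, steps[1].start, steps[1].end, steps[1].lead_toe_off) == (Side.LEFT, 100, 210, 160)
    assert steps[0].duration_s == pytest.approx(100 / 240.0)


def test_segment_counts_on_generator(noiseless_trial):
    _, rec, _ = noiseless_trial
    ev = detect_events(rec)
    steps = segment_steps(ev, rec.sample_rate)
    assert len(steps) == len(ev.contacts) - 1


def test_segment_skips_same_side_interval(caplog):
    ev = GaitEventSet(
        contacts=[(0, Side.RIGHT), (100, Side.RIGHT), (200, Side.LEFT)],
        toe_offs=[(150, Side.RIGHT)],
    )
    with caplog.at_level(logging.WARNING, logger="gaitspm.events"):
        steps = segment_steps(ev, 240.0)
    assert len(steps) == 1
    assert steps[0].start == 100
    assert any("skipped" in r.message for r in caplog.records)


def test_segmentation_exhaustive_non_overlapping(noiseless_trial):
    """Steps tile [first contact, last contact] without gaps or overlap."""
    _, rec, _ = noiseless_trial
    ev = detect_events(rec)
    steps = segment_steps(ev, rec.sample_rate)
    for a, b in zip(steps, steps[1:]):
        assert a.end == b.start
    assert steps[0].start == ev.contacts[0][0]
    assert steps[-1].end == ev.contacts[-1][0]


# ------------------------------------------------------------------ window


def test_window_starts_at_plateau(noiseless_trial):
    _, rec, truth = noiseless_trial
    steps = segment_steps(detect_events(rec), rec.sample_rate)
    win = select_analysis_window(steps, rec, truth.velocity_kmh)
    assert win[0].start == truth.steps[truth.window_start_step].start_sample
    assert len(win) == 20
    assert sum(1 for s in win if s.lead_side is Side.RIGHT) == 10


def test_window_all_at_target_takes_first_steps(study_model):
    import dataclasses

    model = dataclasses.replace(study_model.noiseless(), ramp_step_fractions=())
    rec, truth = generate_trial(model, "WR", 1, 1, templates=TemplateSet(model))
    steps = segment_steps(detect_events(rec), rec.sample_rate)
    win = select_analysis_window(steps, rec, truth.velocity_kmh)
    assert win == steps[:20]


def test_window_insufficient_steps(study_model):
    import dataclasses

    model = dataclasses.replace(study_model.noiseless(), n_steps=10, ramp_step_fractions=())
    rec, truth = generate_trial(model, "WR", 1, 1, templates=TemplateSet(model))
    steps = segment_steps(detect_events(rec), rec.sample_rate)
    with pytest.raises(ValueError, match="insufficient steps"):
        select_analysis_window(steps, rec, truth.velocity_kmh, n_steps=20)


def test_window_criterion_never_met(noiseless_trial):
    _, rec, truth = noiseless_trial
    steps = segment_steps(detect_events(rec), rec.sample_rate)
    with pytest.raises(ValueError, match="closest approach"):
        select_analysis_window(steps, rec, truth.velocity_kmh + 30.0, speed_band_kmh=0.5)


# ------------------------------------------------------------ spatiotemporal


def test_spatiotemporal_matches_generator(noiseless_trial):
    """Stride length, frequency, velocity within 2% of the generator; toe-off
    within one percentage point of the configured 60.4%."""
    model, rec, truth = noiseless_trial
    steps = segment_steps(detect_events(rec), rec.sample_rate)
    win = select_analysis_window(steps, rec, truth.velocity_kmh)
    st = spatiotemporal(win, rec)
    assert st.mean_stride_length_m == pytest.approx(truth.stride_length_m, rel=0.02)
    assert st.mean_frequency_per_min == pytest.approx(truth.stride_frequency_per_min, rel=0.02)
    assert st.mean_velocity_kmh == pytest.approx(truth.velocity_kmh, rel=0.02)
    assert abs(st.relative_toe_off_mean_pct - 60.4) < 1.0


def test_velocity_consistency_invariant(noisy_trial):
    """v = stride length x frequency x 0.06 within 2% on noisy data too."""
    _, rec, truth = noisy_trial
    steps = segment_steps(detect_events(rec), rec.sample_rate)
    win = select_analysis_window(steps, rec, truth.velocity_kmh)
    st = spatiotemporal(win, rec)
    implied = st.mean_stride_length_m * st.mean_frequency_per_min * 0.06
    assert st.mean_velocity_kmh == pytest.approx(implied, rel=0.02)


def test_analyzed_distance_constructed():
    """10 strides of exactly 2.5 m give 25.0 m analyzed distance."""
    fs = 100.0
    n_steps, step_samples = 20, 50
    T = n_steps * step_samples + 1
    x = np.linspace(0.0, 25.0, T)  # 1.25 m per step
    pelvis = np.column_stack([x, np.zeros(T), np.full(T, 0.95)])
    angles = {k: np.zeros(T) for k in ANGLE_CHANNELS}
    rec = Recording("const", "WR", fs, angles, {"pelvis": pelvis})
    steps = [
        StepCycle(
            lead_side=Side.RIGHT if k % 2 == 0 else Side.LEFT,
            start=k * step_samples, end=(k + 1) * step_samples,
            lead_toe_off=k * step_samples + 30, duration_s=step_samples / fs,
        )
        for k in range(n_steps)
    ]
    st = spatiotemporal(steps, rec)
    assert st.analyzed_distance_m == pytest.approx(25.0)
    assert st.mean_stride_length_m == pytest.approx(2.5)
    assert st.relative_toe_off_mean_pct == pytest.approx(60.0)


def test_spatiotemporal_requires_pelvis():
    angles = {k: np.zeros(300) for k in ANGLE_CHANNELS}
    rec = Recording("nopelvis", "WR", 240.0, angles, {})
    steps = [
        StepCycle(Side.RIGHT, 0, 100, 60, 100 / 240.0),
        StepCycle(Side.LEFT, 100, 200, 160, 100 / 240.0),
        StepCycle(Side.RIGHT, 200, 299, 260, 99 / 240.0),
    ]
    with pytest.raises(ValueError, match="pelvis"):
        spatiotemporal(steps, rec)
    with pytest.raises(ValueError, match="pelvis"):
        step_speeds_kmh(steps, rec)
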