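"""Gaze-contingent controller: trigger rule, bias correction, trial timeline."""

import itertools

import numpy as np
import pytest

from lwl.config import (
    AOI_ATTENTION,
    AOI_LEFT,
    AOI_OFF,
    AOI_RIGHT,
    EXCLAMATION_DURATIONS_MS,
    GAZE_TRIGGERED,
)
from lwl.controller import (
    PairHistory,
    SessionState,
    detect_trigger_fixation,
    manual_trigger_target,
    run_trial,
    select_target_gaze,
    session_stop_rule,
)
from lwl.preprocess import Fixation
from lwl.schedule import build_schedule


def fx(onset, offset, aoi, trial=0):
    return Fixation(float(onset), float(offset), aoi, trial)


# ---------------------------------------------------------------------------
# Trigger detection


def test_trigger_fires_after_100ms_continuous_look():
    stream = [fx(1000, 1120, AOI_LEFT)]
    assert detect_trigger_fixation(stream, window_start=1000) == (AOI_LEFT, 1100)


def test_trigger_counts_ongoing_fixation_from_window_start():
    stream = [fx(500, 1500, AOI_RIGHT)]
    assert detect_trigger_fixation(stream, window_start=1000) == (AOI_RIGHT, 1100)


def test_two_short_looks_with_gap_do_not_trigger():
    stream = [fx(1000, 1080, AOI_LEFT), fx(1200, 1280, AOI_LEFT)]
    assert detect_trigger_fixation(stream, window_start=1000) is None


def test_abutting_same_aoi_fixations_merge_into_one_run():
    stream = [fx(1000, 1060, AOI_LEFT), fx(1060, 1150, AOI_LEFT)]
    assert detect_trigger_fixation(stream, window_start=1000) == (AOI_LEFT, 1100)


def test_empty_stream_times_out():
    assert detect_trigger_fixation([], window_start=0) is None


def _oracle_trigger(stream, window_start, config):
    """Integer-millisecond brute force: first instant t such that one picture
    AOI was occupied continuously over [t-100, t) within the window."""
    w0 = int(window_start)
    w1 = w0 + config.trigger_window_ms
    horizon = w1 + 1
    occupancy = [None] * horizon
    for f in sorted(stream, key=lambda f: f.onset_ms):
        if f.aoi not in (AOI_LEFT, AOI_RIGHT):
            continue
        for t in range(max(0, int(f.onset_ms)), min(horizon, int(f.offset_ms))):
            occupancy[t] = f.aoi
    for t in range(w0 + config.trigger_fix_ms, w1 + 1):
        span = occupancy[t - config.trigger_fix_ms : t]
        if span[0] is not None and all(a == span[0] for a in span):
            return (span[0], float(t))
    return None


def test_trigger_matches_brute_force_on_random_streams(config):
    rng = np.random.default_rng(7)
    mismatches = 0
    for _ in range(300):
        t, stream = 0, []
        while t < 10_000:
            dur = int(rng.integers(20, 400))
            aoi = rng.choice([AOI_LEFT, AOI_RIGHT, AOI_OFF, None])
            if aoi is not None:
                stream.append(fx(t, t + dur, aoi))
            t += dur + int(rng.integers(0, 3)) * int(rng.integers(0, 50))
        ws = float(rng.integers(0, 3000))
        got = detect_trigger_fixation(stream, ws, config)
        expected = _oracle_trigger(stream, ws, config)
        if got != expected:
            mismatches += 1
    assert mismatches == 0


# ---------------------------------------------------------------------------
# Target selection and bias correction


def make_history(fixated_seq, items=("A", "B")):
    h = PairHistory(pair_id="A_B", items=items)
    for f in fixated_seq:
        # replay the default/bias rules to populate label counts
        target, _ = select_target_gaze(h, f, trial_ordinal=h.n_completed + 1)
        h.record(f, target)
    return h


def test_default_rule_names_the_other_item():
    h = PairHistory(pair_id="A_B", items=("A", "B"))
    assert select_target_gaze(h, "A", 1) == ("B", False)


def test_third_in_a_row_names_the_fixated_item():
    h = make_history(["A", "A"])
    assert select_target_gaze(h, "A", 3) == ("A", True)


def test_fixated_item_outside_pair_raises():
    h = PairHistory(pair_id="A_B", items=("A", "B"))
    with pytest.raises(ValueError):
        select_target_gaze(h, "C", 1)


@pytest.mark.parametrize(
    "seq", list(itertools.product("AB", repeat=4)), ids="".join
)
def test_every_fixation_sequence_ends_with_equal_labels(seq):
    """Brute-force enumeration: all 16 length-4 fixation sequences leave each
    item of the pair labeled exactly twice."""
    h = PairHistory(pair_id="A_B", items=("A", "B"))
    for f in seq:
        target, flag = select_target_gaze(h, f, trial_ordinal=h.n_completed + 1)
        h.record(f, target)
    assert h.label_counts == {"A": 2, "B": 2}
    # bias corrections are capped at two per pair
    n_bias = sum(
        1
        for i, f in enumerate(seq)
        if _was_bias_corrected(seq[:i], f)
    )
    assert n_bias <= 2


def _was_bias_corrected(prefix, fixated):
    h = PairHistory(pair_id="A_B", items=("A", "B"))
    for f in prefix:
        t, _ = select_target_gaze(h, f, trial_ordinal=h.n_completed + 1)
        h.record(f, t)
    _, flag = select_target_gaze(h, fixated, trial_ordinal=h.n_completed + 1)
    return flag


def test_manual_trigger_prefers_least_labeled_then_backup():
    h = PairHistory(pair_id="A_B", items=("A", "B"))
    h.record("A", "B")
    assert manual_trigger_target(h, backup="B") == "A"
    h2 = PairHistory(pair_id="A_B", items=("A", "B"))
    assert manual_trigger_target(h2, backup="B") == "B"


# ---------------------------------------------------------------------------
# Whole-trial and whole-session behavior


def _attentive_stream(spec, side_item, config):
    """Attention-getter fixation, then an unbroken look at one item."""
    side = AOI_LEFT if spec.left_item == side_item else AOI_RIGHT
    end = config.preview_ms + EXCLAMATION_DURATIONS_MS[spec.exclamation_id] + 8000
    return [
        fx(-600, 0, AOI_ATTENTION, spec.trial_index),
        fx(0, end, side, spec.trial_index),
    ]


def test_original_trial_label_onset_is_exclamation_offset_plus_100(config):
    sched = build_schedule(config, 0, 5)
    spec = next(t for t in sched.trials if t.trial_type == "original")
    stream = _attentive_stream(spec, spec.left_item, config)
    record, _ = run_trial(spec, stream, SessionState(), config)
    excl_offset = config.preview_ms + EXCLAMATION_DURATIONS_MS[spec.exclamation_id]
    assert record.label_onset_ms == excl_offset + 100
    assert record.target_item == spec.predetermined_target
    assert record.completed


def test_gaze_trial_labels_at_trigger_and_names_other_item(config):
    sched = build_schedule(config, 0, 5)
    spec = next(t for t in sched.trials if t.trial_type == GAZE_TRIGGERED)
    stream = _attentive_stream(spec, spec.left_item, config)
    record, _ = run_trial(spec, stream, SessionState(), config)
    excl_offset = config.preview_ms + EXCLAMATION_DURATIONS_MS[spec.exclamation_id]
    assert record.label_onset_ms == excl_offset + config.trigger_fix_ms
    assert record.target_item == spec.right_item
    assert record.distractor_item == spec.left_item
    assert not record.manual_trigger


def test_never_on_screen_trial_yields_manual_trigger_record(config):
    sched = build_schedule(config, 0, 5)
    spec = next(t for t in sched.trials if t.trial_type == GAZE_TRIGGERED)
    record, state = run_trial(spec, [], SessionState(), config)
    assert record.manual_trigger
    assert not record.completed
    assert state.consecutive_failed_trials == 1


def test_stream_for_wrong_trial_raises(config):
    sched = build_schedule(config, 0, 5)
    spec = sched.trials[0]
    bad = [fx(0, 500, AOI_LEFT, trial=spec.trial_index + 1)]
    with pytest.raises(ValueError):
        run_trial(spec, bad, SessionState(), config)


def test_stop_rule_thresholds(config):
    state = SessionState()
    assert not session_stop_rule(state, config)
    state.consecutive_failed_trials = 4
    assert not session_stop_rule(state, config)
    state.consecutive_failed_trials = 5
    assert session_stop_rule(state, config)


def _run_full_session(config, policy):
    """Run all gaze-triggered trials of a session under a fixation policy
    mapping a TrialSpec to the item the infant stares at pre-naming."""
    sched = build_schedule(config, 0, 11)
    state = SessionState()
    records = []
    for spec in sched.trials:
        if spec.trial_type != GAZE_TRIGGERED:
            item = spec.left_item  # attentive; target is predetermined anyway
        else:
            item = policy(spec)
        record, state = run_trial(
            spec, _attentive_stream(spec, item, config), state, config
        )
        records.append(record)
    return records


def test_adversarial_one_sided_policy_forces_exactly_16_bias_corrections(config):
    """Always fixating the same item of every pair hits the printed maximum
    of bias-corrected trials: half the gaze-triggered trials."""
    records = _run_full_session(
        config, policy=lambda spec: min(spec.left_item, spec.right_item)
    )
    gaze = [r for r in records if r.trial_type == GAZE_TRIGGERED]
    assert sum(r.bias_corrected for r in gaze) == 16


def test_completed_session_names_every_item_twice_per_condition(config):
    rng = np.random.default_rng(3)
    records = _run_full_session(
        config,
        policy=lambda spec: spec.left_item if rng.random() < 0.5 else spec.right_item,
    )
    for cond in (GAZE_TRIGGERED, "original"):
        counts: dict[str, int] = {}
        for r in records:
            if r.trial_type == cond:
                counts[r.target_item] = counts.get(r.target_item, 0) + 1
        assert all(n == 2 for n in counts.values())
        assert len(counts) == 16
    # no pair exceeds two bias corrections
    per_pair: dict[str, int] = {}
    for r in records:
        if r.trial_type == GAZE_TRIGGERED and r.bias_corrected:
            per_pair[r.pair_id] = per_pair.get(r.pair_id, 0) + 1
    assert all(n <= 2 for n in per_pair.values())


def test_repeat_previous_fourth_trial_variant():
    h = PairHistory(pair_id="A_B", items=("A", "B"))
    for f, expect_target in (("A", "B"), ("B", "A"), ("A", "B")):
        t, _ = select_target_gaze(h, f, h.n_completed + 1, rule="repeat_previous")
        assert t == expect_target
        h.record(f, t)
    # 4th trial repeats previous fixation -> fixated item is named
    t, flag = select_target_gaze(h, "A", 4, rule="repeat_previous")
    assert (t, flag) == ("A", True)
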