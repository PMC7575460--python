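"""Trial validity and RT extraction rules."""

import numpy as np
import pytest

from lwl.config import AOI_LEFT, AOI_OFF, AOI_RIGHT
from lwl.preprocess import Fixation
from lwl.rt import (
    apply_inclusion,
    attention_valid,
    extract_rt,
    summarize_cohort,
    summarize_participant,
)

LABEL = 3000.0


def fx(onset, offset, aoi):
    return Fixation(float(onset), float(offset), aoi, 0)


def score(stream, target_side=AOI_RIGHT, **kw):
    defaults = dict(
        participant_id="p0",
        trial_index=0,
        condition="original",
        pair_id="A_B",
        target_item="B",
        target_side=target_side,
        label_onset_ms=LABEL,
        completed=True,
        bias_corrected=False,
        manual_trigger=False,
    )
    defaults.update(kw)
    return extract_rt(stream, **defaults)


# ---------------------------------------------------------------------------
# Attention criterion


def test_single_99ms_fixation_fails_attention():
    stream = [fx(LABEL + 100, LABEL + 199, AOI_LEFT)]
    assert not attention_valid(stream, LABEL)


def test_two_short_fixations_accumulate_to_pass():
    stream = [fx(LABEL + 100, LABEL + 160, AOI_LEFT), fx(LABEL + 500, LABEL + 560, AOI_RIGHT)]
    assert attention_valid(stream, LABEL)


def test_looking_outside_the_window_does_not_count():
    stream = [fx(0, LABEL, AOI_LEFT), fx(LABEL + 2100, LABEL + 4000, AOI_LEFT)]
    assert not attention_valid(stream, LABEL)


def test_attention_matches_brute_force_overlap_sums(config):
    rng = np.random.default_rng(21)
    lo, hi = config.attention_window
    for _ in range(1000):
        stream = [
            fx(on, on + dur, rng.choice([AOI_LEFT, AOI_RIGHT, AOI_OFF]))
            for on, dur in zip(
                rng.uniform(0, 6000, size=6), rng.uniform(10, 500, size=6)
            )
        ]
        label = float(rng.uniform(2000, 4000))
        expected = (
            sum(
                max(0.0, min(f.offset_ms, label + hi) - max(f.onset_ms, label + lo))
                for f in stream
                if f.aoi in (AOI_LEFT, AOI_RIGHT)
            )
            >= config.attention_min_ms
        )
        assert attention_valid(stream, label, config) == expected


# ---------------------------------------------------------------------------
# RT rule


def test_distractor_initial_shift_at_650ms_is_valid():
    stream = [fx(LABEL - 400, LABEL + 620, AOI_LEFT), fx(LABEL + 650, LABEL + 1400, AOI_RIGHT)]
    out = score(stream)
    assert out.initial_aoi_at_onset == "distractor"
    assert out.rt_ms == 650
    assert out.rt_valid


def test_shift_at_250ms_is_too_early():
    stream = [fx(LABEL - 400, LABEL + 220, AOI_LEFT), fx(LABEL + 250, LABEL + 1400, AOI_RIGHT)]
    out = score(stream)
    assert not out.rt_valid
    assert out.invalid_reason == "too_early"
    assert out.rt_ms == 250


def test_shift_after_1800ms_is_too_late():
    stream = [fx(LABEL - 400, LABEL + 1820, AOI_LEFT), fx(LABEL + 1900, LABEL + 2000, AOI_RIGHT)]
    out = score(stream)
    assert out.invalid_reason == "too_late"


def test_target_initial_trial_yields_no_rt():
    stream = [fx(LABEL - 400, LABEL + 500, AOI_RIGHT), fx(LABEL + 600, LABEL + 900, AOI_LEFT)]
    out = score(stream)
    assert out.initial_aoi_at_onset == "target"
    assert not out.rt_valid
    assert out.invalid_reason == "target_initial"


def test_no_fixation_covering_onset_yields_none_initial():
    stream = [fx(LABEL + 400, LABEL + 900, AOI_RIGHT)]
    out = score(stream)
    assert out.initial_aoi_at_onset == "none"
    assert out.invalid_reason == "no_fixation_at_onset"


def test_off_aoi_gap_between_distractor_and_target_does_not_invalidate():
    stream = [
        fx(LABEL - 400, LABEL + 300, AOI_LEFT),
        fx(LABEL + 350, LABEL + 500, AOI_OFF),
        fx(LABEL + 700, LABEL + 1200, AOI_RIGHT),
    ]
    out = score(stream)
    assert out.rt_valid and out.rt_ms == 700


def test_bias_corrected_and_manual_trials_never_valid():
    stream = [fx(LABEL - 400, LABEL + 620, AOI_LEFT), fx(LABEL + 650, LABEL + 1400, AOI_RIGHT)]
    assert score(stream, bias_corrected=True).invalid_reason == "bias_corrected"
    assert score(stream, manual_trigger=True).invalid_reason == "manual_trigger"
    assert score(stream, completed=False).invalid_reason == "not_completed"


def _oracle_extract(stream, target_side, label, config):
    """Exhaustive scan, written independently of extract_rt."""
    distractor_side = AOI_LEFT if target_side == AOI_RIGHT else AOI_RIGHT
    initial = "none"
    for f in stream:
        if f.onset_ms <= label < f.offset_ms:
            initial = (
                "target"
                if f.aoi == target_side
                else "distractor"
                if f.aoi == distractor_side
                else "none"
            )
            break
    candidates = sorted(
        (f.onset_ms - label for f in stream if f.aoi == target_side and f.onset_ms > label),
    )
    rt = candidates[0] if candidates else None
    valid = (
        initial == "distractor"
        and rt is not None
        and config.rt_window[0] <= rt <= config.rt_window[1]
    )
    return initial, rt, valid


def test_extraction_matches_exhaustive_scan_on_random_trials(config):
    rng = np.random.default_rng(99)
    for i in range(2000):
        n = int(rng.integers(0, 8))
        onsets = np.sort(rng.uniform(0, 6000, size=n))
        stream = []
        for on in onsets:
            dur = float(rng.uniform(20, 800))
            stream.append(fx(on, on + dur, rng.choice([AOI_LEFT, AOI_RIGHT, AOI_OFF])))
        label = float(rng.uniform(2000, 4000))
        target_side = AOI_LEFT if rng.random() < 0.5 else AOI_RIGHT
        out = score(stream, target_side=target_side, label_onset_ms=label)
        initial, rt, valid = _oracle_extract(stream, target_side, label, config)
        attended = attention_valid(stream, label, config)
        assert out.initial_aoi_at_onset == initial
        assert out.rt_ms == rt
        assert out.rt_valid == (valid and attended)


# ---------------------------------------------------------------------------
# Summaries and inclusion


def _make_outcomes(spec):
    """spec: {pid: {cond: [(rt_or_None, valid, completed)]}} -> outcomes frame."""
    rows = []
    for pid, conds in spec.items():
        i = 0
        for cond, trials in conds.items():
            for rt, valid, completed in trials:
                rows.append(
                    dict(
                        participant_id=pid,
                        trial_index=i,
                        condition=cond,
                        pair_id="A_B",
                        target_item="B",
                        completed=completed,
                        attended=completed,
                        initial_aoi_at_onset="distractor",
                        rt_ms=rt,
                        rt_valid=valid,
                        invalid_reason=None if valid else "x",
                        bias_corrected=False,
                        manual_trigger=False,
                    )
                )
                i += 1
    import pandas as pd

    return pd.DataFrame(rows)


def test_pct_valid_and_mean_rt_arithmetic():
    trials = [(None, False, True)] * 10 + [(600.0, True, True), (800.0, True, True)]
    trials += [(None, False, True)] * 8
    outcomes = _make_outcomes({"p0": {"original": trials, "gaze_triggered": trials}})
    s = summarize_participant(outcomes, "p0", ["original", "gaze_triggered"])
    st = s.per_condition["original"]
    assert st.completed_trials == 20
    assert st.rt_valid_trials == 2
    assert st.pct_valid == 10.0
    assert st.mean_rt_ms == 700.0


def test_summaries_match_brute_force_on_simulated_cohort(cohort43):
    _, _, _, _, outcomes, summaries = cohort43
    for s in summaries[:10]:
        sub = outcomes[outcomes.participant_id == s.participant_id]
        for cond, st in s.per_condition.items():
            c = sub[sub.condition == cond]
            assert st.completed_trials == int(c.completed.sum())
            assert st.rt_valid_trials == int(c.rt_valid.sum())
            if st.completed_trials:
                assert st.pct_valid == pytest.approx(
                    100.0 * c.rt_valid.sum() / c.completed.sum()
                )
            rts = c.loc[c.rt_valid, "rt_ms"]
            if len(rts):
                assert st.mean_rt_ms == pytest.approx(rts.mean())


def test_inclusion_requires_a_valid_rt_in_both_conditions():
    outcomes = _make_outcomes(
        {
            "p0": {
                "original": [(700.0, True, True)],
                "gaze_triggered": [(650.0, True, True)],
            },
            "p1": {
                "original": [(None, False, True)],
                "gaze_triggered": [(650.0, True, True)],
            },
        }
    )
    summaries = summarize_cohort(outcomes)
    included, log = apply_inclusion(summaries)
    assert [s.participant_id for s in included] == ["p0"]
    assert log[0][0] == "p1" and "original" in log[0][1]


def test_inclusion_with_min_two_trials_matches_brute_force(cohort43):
    _, _, _, _, outcomes, summaries = cohort43
    included, _ = apply_inclusion(summaries, min_rt_trials=2)
    expected = {
        s.participant_id
        for s in summaries
        if all(st.rt_valid_trials >= 2 for st in s.per_condition.values())
    }
    assert {s.participant_id for s in included} == expected


def test_bias_and_manual_trials_counted_completed_but_never_valid(cohort43):
    _, _, _, _, outcomes, _ = cohort43
    flagged = outcomes[outcomes.bias_corrected | outcomes.manual_trigger]
    assert not flagged.rt_valid.any()
    assert flagged.completed.sum() > 0  # they do contribute to the denominator
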