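"""Gaze-contingent trial control (offline replay).

One trial unfolds as: attention getter (negative time, ends at picture onset
= 0 once fixated for 500 ms or overridden) -> 2 s silent preview ->
exclamation -> naming. In the original condition the predetermined target is
named 100 ms after the exclamation ends. In the gaze-triggered condition the
first picture the infant fixates continuously for 100 ms (inside a trigger
window after the exclamation) becomes the *distractor* and the other picture
is named — guaranteeing a distractor-initial trial — unless bias correction
intervenes so that both items of a pair are named equally often:

* third-in-a-row: if the infant fixated the same item of a pair on the two
  preceding gaze-triggered trials and does so again, the fixated item itself
  is named;
* fourth trial of a pair: the target is chosen to force an exact 2/2 label
  split for the pair.

If the infant never produces a trigger fixation the label is triggered
manually (here: at the end of the trigger window) and the pair's
least-labeled item is named. The trial ends 2 s after label onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import (
    AOI_ATTENTION,
    AOI_LEFT,
    AOI_RIGHT,
    DesignConfig,
    EXCLAMATION_DURATIONS_MS,
    FILLER,
    GAZE_TRIGGERED,
    ORIGINAL,
)
from .preprocess import Fixation
from .schedule import SessionSchedule, TrialSpec

EVENTS_CSV_COLUMNS = [
    "participant_id",
    "trial_index",
    "block_index",
    "trial_type",
    "pair_id",
    "target_item",
    "distractor_item",
    "target_side",
    "exclamation_onset_ms",
    "label_onset_ms",
    "bias_corrected",
    "manual_trigger",
    "completed",
]


@dataclass
class PairHistory:
    """Per-pair bookkeeping across a session's gaze-triggered trials."""

    pair_id: str
    items: tuple[str, str]
    #: pre-naming fixated item on each completed gaze-triggered trial of this
    #: pair (None when the label was triggered manually)
    fixated_sequence: list[Optional[str]] = field(default_factory=list)
    label_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for it in self.items:
            self.label_counts.setdefault(it, 0)

    @property
    def n_completed(self) -> int:
        return sum(self.label_counts.values())

    def least_labeled(self) -> Optional[str]:
        a, b = self.items
        if self.label_counts[a] < self.label_counts[b]:
            return a
        if self.label_counts[b] < self.label_counts[a]:
            return b
        return None  # tie

    def record(self, fixated: Optional[str], target: str) -> None:
        self.fixated_sequence.append(fixated)
        self.label_counts[target] += 1


@dataclass
class SessionState:
    """Mutable session-level state the controller threads across trials."""

    consecutive_failed_trials: int = 0
    trials_run: int = 0
    pair_history: dict[str, PairHistory] = field(default_factory=dict)

    def history_for(self, pair_id: str, items: tuple[str, str]) -> PairHistory:
        if pair_id not in self.pair_history:
            self.pair_history[pair_id] = PairHistory(pair_id=pair_id, items=items)
        return self.pair_history[pair_id]


@dataclass(frozen=True)
class TrialRecord:
    """What actually happened on one trial."""

    trial_index: int
    block_index: int
    trial_type: str
    pair_id: str
    target_item: str
    distractor_item: str
    target_side: str  # left | right
    exclamation_onset_ms: float
    label_onset_ms: float
    bias_corrected: bool
    manual_trigger: bool
    completed: bool
    participant_id: str = ""
    picture_onset_ms: float = 0.0
    ag_manual: bool = False


# ---------------------------------------------------------------------------
# Trigger detection


def _merged_runs(
    stream: Sequence[Fixation],
) -> list[tuple[float, float, str]]:
    """Contiguous same-AOI picture-fixation runs: abutting fixations on the
    same picture AOI (no gap) merge into one continuous run."""
    runs: list[list] = []
    for f in sorted(stream, key=lambda f: f.onset_ms):
        if f.aoi not in (AOI_LEFT, AOI_RIGHT):
            continue
        if runs and runs[-1][2] == f.aoi and abs(runs[-1][1] - f.onset_ms) < 1e-9:
            runs[-1][1] = f.offset_ms
        else:
            runs.append([f.onset_ms, f.offset_ms, f.aoi])
    return [tuple(r) for r in runs]


def detect_trigger_fixation(
    stream: Sequence[Fixation],
    window_start: float,
    config: DesignConfig | None = None,
) -> Optional[tuple[str, float]]:
    """First picture AOI fixated continuously for >= ``trigger_fix_ms``
    within ``[window_start, window_start + trigger_window_ms]``.

    Returns (aoi, trigger_time) where trigger_time marks the end of the
    qualifying 100 ms run (a fixation already ongoing when the window opens
    counts only from window_start), or None on timeout. An empty stream is a
    timeout, not an error.
    """
    config = config or DesignConfig()
    window_end = window_start + config.trigger_window_ms
    best: Optional[tuple[str, float]] = None
    for onset, offset, aoi in _merged_runs(stream):
        start = max(onset, window_start)
        trigger_time = start + config.trigger_fix_ms
        if trigger_time <= min(offset, window_end):
            if best is None or trigger_time < best[1]:
                best = (aoi, trigger_time)
    return best


# ---------------------------------------------------------------------------
# Target selection


def select_target_gaze(
    history: PairHistory,
    fixated: str,
    trial_ordinal: int,
    rule: str = "balance",
    appearances_per_condition: int = 4,
) -> tuple[str, bool]:
    """Choose the named target on a gaze-triggered trial.

    Default: the fixated item becomes the distractor and the other item is
    named. Bias correction (flag True iff the fixated item itself is named):
    third-in-a-row fixations name the fixated item; on the pair's last
    gaze-triggered trial the "balance" rule names whichever item restores an
    exact label split, while the "repeat_previous" variant names the fixated
    item only if it repeats the immediately preceding trial's fixation.
    """
    if fixated not in history.items:
        raise ValueError(f"fixated item {fixated!r} not in pair {history.pair_id}")
    if not 1 <= trial_ordinal <= appearances_per_condition:
        raise ValueError(f"trial_ordinal {trial_ordinal} out of range")
    other = history.items[0] if fixated == history.items[1] else history.items[1]

    if trial_ordinal == appearances_per_condition and rule == "balance":
        target = history.least_labeled()
        if target is None:  # tie cannot occur after an odd number of labels
            target = other
        return target, target == fixated

    last_two = history.fixated_sequence[-2:]
    if len(last_two) == 2 and last_two[0] == fixated and last_two[1] == fixated:
        return fixated, True
    if (
        trial_ordinal == appearances_per_condition
        and rule == "repeat_previous"
        and history.fixated_sequence
        and history.fixated_sequence[-1] == fixated
    ):
        return fixated, True
    return other, False


def manual_trigger_target(history: PairHistory, backup: Optional[str]) -> str:
    """Target when the label is triggered without a gaze fixation: the pair's
    least-labeled item, falling back to the scheduled backup on a tie."""
    least = history.least_labeled()
    if least is not None:
        return least
    return backup if backup is not None else history.items[0]


# ---------------------------------------------------------------------------
# Running trials


def exclamation_offset_ms(config: DesignConfig, spec: TrialSpec) -> float:
    return config.preview_ms + EXCLAMATION_DURATIONS_MS[spec.exclamation_id]


def _onscreen_ms(stream: Sequence[Fixation], t0: float, t1: float) -> float:
    total = 0.0
    for f in stream:
        if f.aoi in (AOI_LEFT, AOI_RIGHT):
            total += max(0.0, min(f.offset_ms, t1) - max(f.onset_ms, t0))
    return total


def run_trial(
    spec: TrialSpec,
    stream: Sequence[Fixation],
    state: SessionState,
    config: DesignConfig | None = None,
    participant_id: str = "",
) -> tuple[TrialRecord, SessionState]:
    """Replay one trial's gaze stream through the controller.

    The stream is trial-relative (picture onset 0; attention-getter fixations
    at negative times). Deterministic given (spec, stream, state). Updates
    and returns ``state``: pair history advances on completed gaze-triggered
    trials, and the consecutive-failure counter resets on any completed trial.
    """
    config = config or DesignConfig()
    for f in stream:
        if f.trial_index is not None and f.trial_index != spec.trial_index:
            raise ValueError(
                f"stream fixation for trial {f.trial_index} fed to trial "
                f"{spec.trial_index}"
            )

    # attention-getter phase: a 500 ms fixation on the getter ends the phase;
    # otherwise the experimenter advanced manually
    ag_manual = not any(
        f.aoi == AOI_ATTENTION
        and f.offset_ms <= 0
        and f.duration_ms >= config.attention_getter_fix_ms
        for f in stream
    )

    excl_onset = float(config.preview_ms)
    excl_offset = exclamation_offset_ms(config, spec)

    bias_corrected = False
    manual = False
    fixated_item: Optional[str] = None

    if spec.trial_type in (ORIGINAL, FILLER):
        label_onset = excl_offset + config.original_silence_ms
        target = spec.predetermined_target
        if target is None:
            raise ValueError(f"trial {spec.trial_index}: no predetermined target")
    else:
        items = (spec.left_item, spec.right_item)
        history = state.history_for(spec.pair_id, _pair_items(spec))
        hit = detect_trigger_fixation(stream, excl_offset, config)
        appearances = config.n_gaze_trials // len(config.pairs)
        if hit is None:
            manual = True
            label_onset = excl_offset + config.trigger_window_ms
            target = manual_trigger_target(history, spec.backup_target)
        else:
            aoi, label_onset = hit
            fixated_item = spec.left_item if aoi == AOI_LEFT else spec.right_item
            target, bias_corrected = select_target_gaze(
                history,
                fixated_item,
                trial_ordinal=history.n_completed + 1,
                rule=config.fourth_trial_rule,
                appearances_per_condition=appearances,
            )

    trial_end = label_onset + config.post_label_ms
    completed = _onscreen_ms(stream, 0.0, trial_end) >= config.attention_min_ms

    distractor = spec.right_item if target == spec.left_item else spec.left_item
    target_side = AOI_LEFT if target == spec.left_item else AOI_RIGHT

    if completed:
        state.consecutive_failed_trials = 0
        if spec.trial_type == GAZE_TRIGGERED:
            state.history_for(spec.pair_id, _pair_items(spec)).record(
                fixated_item, target
            )
    else:
        state.consecutive_failed_trials += 1
    state.trials_run += 1

    record = TrialRecord(
        trial_index=spec.trial_index,
        block_index=spec.block_index,
        trial_type=spec.trial_type,
        pair_id=spec.pair_id,
        target_item=target,
        distractor_item=distractor,
        target_side=target_side,
        exclamation_onset_ms=excl_onset,
        label_onset_ms=label_onset,
        bias_corrected=bias_corrected,
        manual_trigger=manual,
        completed=completed,
        participant_id=participant_id,
        ag_manual=ag_manual,
    )
    return record, state


def _pair_items(spec: TrialSpec) -> tuple[str, str]:
    # canonical item order for pair history, independent of display side
    return tuple(sorted((spec.left_item, spec.right_item)))  # type: ignore[return-value]


def session_stop_rule(state: SessionState, config: DesignConfig | None = None) -> bool:
    """True (stop the session) once the infant has failed to complete
    ``stop_after_failed`` trials in a row."""
    config = config or DesignConfig()
    return state.consecutive_failed_trials >= config.stop_after_failed


def replay_session(
    schedule: SessionSchedule,
    fixations: Sequence[Fixation],
    config: DesignConfig | None = None,
    participant_id: str = "",
) -> list[TrialRecord]:
    """Replay a whole recorded/simulated session trial by trial, applying the
    stop rule. Trials without any fixation data are still run (as inattentive
    trials) until the stop rule fires."""
    config = config or DesignConfig()
    by_trial: dict[int, list[Fixation]] = {}
    for f in fixations:
        by_trial.setdefault(int(f.trial_index), []).append(f)
    state = SessionState()
    records: list[TrialRecord] = []
    for spec in schedule.trials:
        if session_stop_rule(state, config):
            break
        rec, state = run_trial(
            spec, by_trial.get(spec.trial_index, []), state, config, participant_id
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Events IO


def events_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [
        {col: getattr(r, col) for col in EVENTS_CSV_COLUMNS} for r in records
    ]
    return pd.DataFrame(rows, columns=EVENTS_CSV_COLUMNS)


def write_events_csv(records: Sequence[TrialRecord], path: str | Path) -> None:
    events_to_frame(records).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("bias_corrected", "manual_trigger", "completed"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
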