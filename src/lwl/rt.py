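"""Trial validity and visual reaction-time (RT) extraction.

A trial yields a valid RT only when the infant (a) looked at the screen for
at least 100 ms in the 0-2000 ms window after label onset, (b) was fixating
the *distractor* at the instant the label began, and (c) first fixated the
target between 300 and 1800 ms after label onset. The RT is the onset of
that first target fixation, label-relative. Bias-corrected and
manually-triggered trials count as completed but can never yield an RT
(the required distractor-to-target shift is not defined for them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .config import AOI_LEFT, AOI_RIGHT, DesignConfig, FILLER
from .preprocess import Fixation, filter_short_fixations

OUTCOME_COLUMNS = [
    "participant_id",
    "trial_index",
    "condition",
    "pair_id",
    "target_item",
    "completed",
    "attended",
    "initial_aoi_at_onset",
    "rt_ms",
    "rt_valid",
    "invalid_reason",
    "bias_corrected",
    "manual_trigger",
]


@dataclass(frozen=True)
class TrialOutcome:
    participant_id: str
    trial_index: int
    condition: str
    pair_id: str
    target_item: str
    completed: bool
    attended: bool
    initial_aoi_at_onset: str  # target | distractor | none
    rt_ms: Optional[float]
    rt_valid: bool
    invalid_reason: Optional[str]
    bias_corrected: bool
    manual_trigger: bool


@dataclass
class ConditionStats:
    completed_trials: int = 0
    attended_trials: int = 0
    rt_valid_trials: int = 0
    pct_valid: Optional[float] = None  # 100 * valid / completed
    mean_rt_ms: Optional[float] = None
    sd_rt_ms: Optional[float] = None


@dataclass
class ParticipantSummary:
    participant_id: str
    per_condition: dict[str, ConditionStats] = field(default_factory=dict)
    included: bool = False


def attention_valid(
    stream: Sequence[Fixation],
    label_onset_ms: float,
    config: DesignConfig | None = None,
) -> bool:
    """Cumulative on-screen (picture-AOI) looking within the critical window
    after label onset must reach ``attention_min_ms``."""
    config = config or DesignConfig()
    lo = label_onset_ms + config.attention_window[0]
    hi = label_onset_ms + config.attention_window[1]
    total = 0.0
    for f in stream:
        if f.aoi in (AOI_LEFT, AOI_RIGHT):
            total += max(0.0, min(f.offset_ms, hi) - max(f.onset_ms, lo))
    return total >= config.attention_min_ms


def extract_rt(
    stream: Sequence[Fixation],
    *,
    participant_id: str,
    trial_index: int,
    condition: str,
    pair_id: str,
    target_item: str,
    target_side: str,
    label_onset_ms: float,
    completed: bool,
    bias_corrected: bool,
    manual_trigger: bool,
    config: DesignConfig | None = None,
) -> TrialOutcome:
    """Score one experimental trial.

    The initial AOI is that of the fixation whose half-open interval covers
    the label-onset instant (none if no fixation covers it). The RT is the
    onset of the first target-AOI fixation after label onset; shifts outside
    the 300-1800 ms window are recorded but invalid.
    """
    config = config or DesignConfig()
    distractor_side = AOI_RIGHT if target_side == AOI_LEFT else AOI_LEFT
    attended = attention_valid(stream, label_onset_ms, config)

    covering = [f for f in stream if f.covers(label_onset_ms)]
    if not covering:
        initial = "none"
    else:
        aoi = covering[0].aoi
        initial = (
            "target"
            if aoi == target_side
            else "distractor"
            if aoi == distractor_side
            else "none"
        )

    rt_ms: Optional[float] = None
    first_target = None
    for f in sorted(stream, key=lambda f: f.onset_ms):
        if f.aoi == target_side and f.onset_ms > label_onset_ms:
            first_target = f
            break
    if first_target is not None:
        rt_ms = first_target.onset_ms - label_onset_ms

    reason: Optional[str] = None
    if not completed:
        reason = "not_completed"
    elif bias_corrected:
        reason = "bias_corrected"
    elif manual_trigger:
        reason = "manual_trigger"
    elif not attended:
        reason = "not_attended"
    elif initial == "target":
        reason = "target_initial"
    elif initial == "none":
        reason = "no_fixation_at_onset"
    elif rt_ms is None:
        reason = "no_shift"
    elif rt_ms < config.rt_window[0]:
        reason = "too_early"
    elif rt_ms > config.rt_window[1]:
        reason = "too_late"

    rt_valid = reason is None
    return TrialOutcome(
        participant_id=participant_id,
        trial_index=trial_index,
        condition=condition,
        pair_id=pair_id,
        target_item=target_item,
        completed=completed,
        attended=attended,
        initial_aoi_at_onset=initial,
        rt_ms=rt_ms,
        rt_valid=rt_valid,
        invalid_reason=reason,
        bias_corrected=bias_corrected,
        manual_trigger=manual_trigger,
    )


def extract_outcomes(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    config: DesignConfig | None = None,
    min_fixation_ms: Optional[float] = None,
) -> pd.DataFrame:
    """Score every experimental trial in an events table.

    ``trials`` is the segmented fixation table (one row per fixation, as
    produced by :func:`lwl.preprocess.segment_trials`); ``events`` is the
    controller's per-trial table. Trials with no surviving fixations are
    scored from an empty stream. Fixations shorter than ``min_fixation_ms``
    (default: the config's 100 ms) are dropped before scoring.
    """
    config = config or DesignConfig()
    if min_fixation_ms is None:
        min_fixation_ms = config.min_fixation_ms

    grouped: dict[tuple[str, int], list[Fixation]] = {}
    if len(trials):
        for row in trials.itertuples(index=False):
            fix = Fixation(
                onset_ms=float(row.fix_onset_ms),
                offset_ms=float(row.fix_offset_ms),
                aoi=row.aoi,
                trial_index=int(row.trial_index),
                participant_id=str(row.participant_id),
            )
            grouped.setdefault((fix.participant_id, fix.trial_index), []).append(fix)

    outcomes: list[TrialOutcome] = []
    for ev in events.itertuples(index=False):
        if ev.trial_type == FILLER:
            continue
        key = (str(ev.participant_id), int(ev.trial_index))
        stream = filter_short_fixations(grouped.get(key, []), min_fixation_ms)
        outcomes.append(
            extract_rt(
                stream,
                participant_id=key[0],
                trial_index=key[1],
                condition=ev.trial_type,
                pair_id=str(ev.pair_id),
                target_item=str(ev.target_item),
                target_side=str(ev.target_side),
                label_onset_ms=float(ev.label_onset_ms),
                completed=bool(ev.completed),
                bias_corrected=bool(ev.bias_corrected),
                manual_trigger=bool(ev.manual_trigger),
                config=config,
            )
        )
    return outcomes_to_frame(outcomes)


def outcomes_to_frame(outcomes: Sequence[TrialOutcome]) -> pd.DataFrame:
    rows = [{c: getattr(o, c) for c in OUTCOME_COLUMNS} for o in outcomes]
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def summarize_participant(
    outcomes: pd.DataFrame, participant_id: str, conditions: Sequence[str]
) -> ParticipantSummary:
    """Per-condition counts, percentage of completed trials yielding a valid
    RT, and mean/SD of valid RTs for one participant."""
    sub = outcomes[outcomes["participant_id"] == participant_id]
    summary = ParticipantSummary(participant_id=participant_id)
    for cond in conditions:
        c = sub[sub["condition"] == cond]
        stats = ConditionStats(
            completed_trials=int(c["completed"].sum()),
            attended_trials=int((c["completed"] & c["attended"]).sum()),
            rt_valid_trials=int(c["rt_valid"].sum()),
        )
        if stats.completed_trials > 0:
            stats.pct_valid = 100.0 * stats.rt_valid_trials / stats.completed_trials
        valid_rts = c.loc[c["rt_valid"], "rt_ms"].astype(float)
        if len(valid_rts) > 0:
            stats.mean_rt_ms = float(valid_rts.mean())
            stats.sd_rt_ms = (
                float(valid_rts.std(ddof=1)) if len(valid_rts) > 1 else None
            )
        summary.per_condition[cond] = stats
    return summary


def summarize_cohort(
    outcomes: pd.DataFrame, conditions: Sequence[str] = ("gaze_triggered", "original")
) -> list[ParticipantSummary]:
    return [
        summarize_participant(outcomes, pid, conditions)
        for pid in sorted(outcomes["participant_id"].unique())
    ]


def apply_inclusion(
    summaries: Sequence[ParticipantSummary], min_rt_trials: int = 1
) -> tuple[list[ParticipantSummary], list[tuple[str, str]]]:
    """Keep participants with at least ``min_rt_trials`` valid RTs in *every*
    condition; log the rest with a reason. Returns (included, exclusion_log).
    """
    included: list[ParticipantSummary] = []
    log: list[tuple[str, str]] = []
    for s in summaries:
        lacking = [
            cond
            for cond, st in s.per_condition.items()
            if st.rt_valid_trials < min_rt_trials
        ]
        if lacking:
            s.included = False
            log.append(
                (
                    s.participant_id,
                    f"fewer than {min_rt_trials} valid RT trial(s) in: "
                    + ", ".join(lacking),
                )
            )
        else:
            s.included = True
            included.append(s)
    return included, log


def summaries_to_frame(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for cond, st in s.per_condition.items():
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "condition": cond,
                    "completed_trials": st.completed_trials,
                    "attended_trials": st.attended_trials,
                    "rt_valid_trials": st.rt_valid_trials,
                    "pct_valid": st.pct_valid if st.pct_valid is not None else math.nan,
                    "mean_rt_ms": st.mean_rt_ms if st.mean_rt_ms is not None else math.nan,
                    "sd_rt_ms": st.sd_rt_ms if st.sd_rt_ms is not None else math.nan,
                    "included": s.included,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "completed_trials",
            "attended_trials",
            "rt_valid_trials",
            "pct_valid",
            "mean_rt_ms",
            "sd_rt_ms",
            "included",
        ],
    )
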