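"""Synthetic infant gaze for the looking-while-listening paradigm.

Each simulated infant carries a latent speed-of-processing parameter (the
mean distractor-to-target shift latency), attention and gaze-dynamics
parameters, and a parent-report vocabulary correlated with latency. Trials
are generated interactively against the gaze-contingent controller: the
pre-naming fixation bouts are produced first, the controller's trigger rule
determines the label onset and target, and the post-naming behavior then
depends on where the infant is looking and whether the named word is known.

What the generator emulates: alternating left/right fixation bouts with
saccade gaps, off-screen excursions, whole-trial inattention, a roughly 50%
chance of fixating the (predetermined) target at label onset in the original
condition, label-locked distractor-to-target shifts for known words, and
weaker/unreliable shifts for unknown words. It does not emulate raw 1000 Hz
samples, pupil dynamics, saccade kinematics, or drift.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    AOI_ATTENTION,
    AOI_LEFT,
    AOI_RIGHT,
    DesignConfig,
    GAZE_TRIGGERED,
)
from .controller import (
    SessionState,
    TrialRecord,
    detect_trigger_fixation,
    events_to_frame,
    exclamation_offset_ms,
    manual_trigger_target,
    run_trial,
    select_target_gaze,
    session_stop_rule,
)
from .preprocess import Fixation, fixations_to_frame
from .schedule import SessionSchedule, TrialSpec, build_schedule

# generative defaults (population level)
MU_LATENCY_MEAN = 950.0  # ms
MU_LATENCY_SD = 130.0
MU_LATENCY_FLOOR = 400.0
SIGMA_LOG = 0.3
ATTEND_BETA = (8.0, 2.0)
DWELL_SHAPE = 2.0
DWELL_SCALE = 300.0  # ms
OBJECT_PREF_BETA = (2.0, 2.0)
P_SHIFT_UNKNOWN = 0.3
P_OFF_BOUT = 0.12
OFF_SHAPE, OFF_SCALE = 1.5, 200.0
SACCADE_MIN, SACCADE_MAX = 20.0, 40.0
RT_FLOOR = 300.0  # physiological minimum shift latency, ms


@dataclass
class InfantParams:
    """Ground-truth generative parameters for one simulated infant."""

    participant_id: str
    mu_latency_ms: float
    sigma_log: float = SIGMA_LOG
    p_attend_trial: float = 0.8
    dwell_shape: float = DWELL_SHAPE
    dwell_scale: float = DWELL_SCALE
    side_bias: float = 0.5
    object_pref: dict[str, float] = field(default_factory=dict)
    p_shift_unknown: float = P_SHIFT_UNKNOWN
    expressive_vocab: int = 200
    cdi_comprehended: int = 280
    known_words: dict[str, bool] = field(default_factory=dict)

    def knows(self, item: str) -> bool:
        return self.known_words.get(item, True)


@dataclass
class CohortTruth:
    """Everything needed to reproduce a simulated cohort."""

    master_seed: int
    n_participants: int
    infants: list[InfantParams]
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "master_seed": self.master_seed,
            "n_participants": self.n_participants,
            "config": self.config,
            "infants": [asdict(p) for p in self.infants],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            master_seed=d["master_seed"],
            n_participants=d["n_participants"],
            infants=[InfantParams(**p) for p in d["infants"]],
            config=d["config"],
        )


def _rng(seed: int, participant_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, participant_index, stream])
    )


def sample_infant(
    cohort_seed: int,
    participant_index: int,
    config: DesignConfig | None = None,
) -> InfantParams:
    """Draw one infant's ground-truth parameters (deterministic per
    (seed, index)).

    The latent mean shift latency is Normal(950, 130) truncated at 400 ms,
    spanning the 600-1300 ms range of published infant visual RTs at this
    age. Expressive vocabulary decreases weakly with latency (plus noise) so
    the latency-vocabulary rank correlation is modest and negative.
    """
    config = config or DesignConfig()
    rng = _rng(cohort_seed, participant_index, 101)
    mu = float(rng.normal(MU_LATENCY_MEAN, MU_LATENCY_SD))
    while mu < MU_LATENCY_FLOOR:
        mu = float(rng.normal(MU_LATENCY_MEAN, MU_LATENCY_SD))
    p_attend = float(rng.beta(*ATTEND_BETA))
    object_pref = {p.pair_id: float(rng.beta(*OBJECT_PREF_BETA)) for p in config.pairs}
    vocab = int(round(max(0.0, 200.0 - 0.15 * (mu - 950.0) + rng.normal(0.0, 40.0))))
    comprehended = vocab + max(0, int(round(rng.normal(80.0, 40.0))))
    p_known = 1.0 / (1.0 + np.exp(-(vocab - 80.0) / 60.0))
    known = {item: bool(rng.random() < p_known) for item in config.item_names}
    return InfantParams(
        participant_id=f"p{participant_index:03d}",
        mu_latency_ms=mu,
        p_attend_trial=p_attend,
        object_pref=object_pref,
        expressive_vocab=vocab,
        cdi_comprehended=comprehended,
        known_words=known,
    )


def shift_latency_ms(params: InfantParams, rng: np.random.Generator) -> float:
    """One distractor-to-target shift latency for a known word: a 300 ms
    floor plus a lognormal whose mean is calibrated so that
    E[latency] = mu_latency_ms exactly."""
    scale = params.mu_latency_ms - RT_FLOOR
    mu_log = np.log(scale) - params.sigma_log**2 / 2.0
    return RT_FLOOR + float(rng.lognormal(mu_log, params.sigma_log))


# ---------------------------------------------------------------------------
# Bout-level gaze generation


def _p_left_first(params: InfantParams, spec: TrialSpec) -> float:
    pref_a = params.object_pref.get(spec.pair_id, 0.5)
    # preference is expressed for the pair's alphabetically-first item
    first_item = min(spec.left_item, spec.right_item)
    pref_left = pref_a if spec.left_item == first_item else 1.0 - pref_a
    return 0.5 * params.side_bias + 0.5 * pref_left


def _prenaming_bouts(
    params: InfantParams,
    spec: TrialSpec,
    rng: np.random.Generator,
    t_end: float,
) -> list[list]:
    """Alternating picture-fixation bouts with saccade gaps and occasional
    off-screen excursions, from picture onset until past ``t_end``.
    Each bout is a mutable [onset, offset, aoi] triple."""
    bouts: list[list] = []
    t = float(rng.uniform(0.0, 150.0))  # first orienting saccade
    side = AOI_LEFT if rng.random() < _p_left_first(params, spec) else AOI_RIGHT
    while t <= t_end:
        if rng.random() < P_OFF_BOUT:
            t += float(rng.gamma(OFF_SHAPE, OFF_SCALE))
            continue
        dwell = max(50.0, float(rng.gamma(params.dwell_shape, params.dwell_scale)))
        bouts.append([t, t + dwell, side])
        t += dwell + float(rng.uniform(SACCADE_MIN, SACCADE_MAX))
        side = AOI_RIGHT if side == AOI_LEFT else AOI_LEFT
    return bouts


def _inattentive_stream(
    spec: TrialSpec, rng: np.random.Generator, t_end: float
) -> list[Fixation]:
    """A trial the infant ignores: under 100 ms of on-screen looking."""
    stream: list[Fixation] = []
    if rng.random() < 0.5:
        onset = float(rng.uniform(0.0, max(1.0, t_end - 100.0)))
        dur = float(rng.uniform(30.0, 90.0))
        side = AOI_LEFT if rng.random() < 0.5 else AOI_RIGHT
        stream.append(
            Fixation(onset, onset + dur, side, spec.trial_index)
        )
    return stream


def simulate_trial_gaze(
    params: InfantParams,
    spec: TrialSpec,
    rng: np.random.Generator,
    config: DesignConfig | None = None,
    state: Optional[SessionState] = None,
) -> list[Fixation]:
    """Generate one trial's fixation stream.

    For original and filler trials the label onset is fixed by the schedule;
    for gaze-triggered trials the trigger rule is evaluated against the
    generated pre-naming bouts (peeking at — not mutating — the session
    state) so the post-naming behavior can be locked to the actual label
    onset. Replaying the returned stream through the controller reproduces
    the same label onset and target.
    """
    config = config or DesignConfig()
    excl_offset = exclamation_offset_ms(config, spec)
    attentive = rng.random() < params.p_attend_trial
    window_end = excl_offset + config.trigger_window_ms

    if spec.trial_type == GAZE_TRIGGERED:
        horizon = window_end + 200.0
    else:
        horizon = excl_offset + config.original_silence_ms + config.post_label_ms

    if not attentive:
        t_end = (
            window_end + config.post_label_ms
            if spec.trial_type == GAZE_TRIGGERED
            else horizon
        )
        return _inattentive_stream(spec, rng, t_end)

    # attention-getter fixation ending at picture onset
    ag = Fixation(-600.0, 0.0, AOI_ATTENTION, spec.trial_index)
    bouts = _prenaming_bouts(params, spec, rng, horizon)

    # resolve label onset and target
    if spec.trial_type == GAZE_TRIGGERED:
        probe = [Fixation(b[0], b[1], b[2], spec.trial_index) for b in bouts]
        hit = detect_trigger_fixation(probe, excl_offset, config)
        history = copy.deepcopy(
            (state or SessionState()).history_for(
                spec.pair_id, tuple(sorted((spec.left_item, spec.right_item)))
            )
        )
        if hit is None:
            label_onset = window_end
            target = manual_trigger_target(history, spec.backup_target)
        else:
            aoi, label_onset = hit
            fixated = spec.left_item if aoi == AOI_LEFT else spec.right_item
            appearances = config.n_gaze_trials // len(config.pairs)
            target, _ = select_target_gaze(
                history,
                fixated,
                trial_ordinal=history.n_completed + 1,
                rule=config.fourth_trial_rule,
                appearances_per_condition=appearances,
            )
    else:
        label_onset = excl_offset + config.original_silence_ms
        target = spec.predetermined_target

    trial_end = label_onset + config.post_label_ms
    target_side = AOI_LEFT if target == spec.left_item else AOI_RIGHT
    distractor_side = AOI_RIGHT if target_side == AOI_LEFT else AOI_LEFT

    # split bouts at label onset
    pre: list[list] = []
    current: Optional[list] = None
    for b in bouts:
        if b[1] <= label_onset:
            pre.append(list(b))
        elif b[0] <= label_onset < b[1]:
            current = list(b)
        elif b[0] > label_onset:
            break

    post: list[list] = []
    known = params.knows(target)
    if current is not None and current[2] == distractor_side and (
        known or rng.random() < params.p_shift_unknown
    ):
        latency = (
            shift_latency_ms(params, rng)
            if known
            else float(rng.uniform(config.rt_window[0], config.rt_window[1]))
        )
        shift_at = label_onset + latency
        gap = float(rng.uniform(SACCADE_MIN, SACCADE_MAX))
        current[1] = max(current[0] + 1.0, shift_at - gap)
        post.append(current)
        if shift_at < trial_end:
            dwell = max(
                200.0, float(rng.gamma(params.dwell_shape, 2.0 * params.dwell_scale))
            )
            post.append([shift_at, shift_at + dwell, target_side])
    elif current is not None and current[2] == distractor_side:
        # unknown word, no reactive shift: linger, then look away
        current[1] = max(current[1], label_onset + float(rng.gamma(2.0, 400.0)))
        post.append(current)
    elif current is not None:
        # already on the target (or bias-corrected trial): bout dynamics go on
        post.append(current)
        t = current[1] + float(rng.uniform(SACCADE_MIN, SACCADE_MAX))
        side = AOI_RIGHT if current[2] == AOI_LEFT else AOI_LEFT
        while t < trial_end:
            if rng.random() < P_OFF_BOUT:
                t += float(rng.gamma(OFF_SHAPE, OFF_SCALE))
                continue
            dwell = max(50.0, float(rng.gamma(params.dwell_shape, params.dwell_scale)))
            post.append([t, t + dwell, side])
            t += dwell + float(rng.uniform(SACCADE_MIN, SACCADE_MAX))
            side = AOI_RIGHT if side == AOI_LEFT else AOI_LEFT
    # current is None: the infant was mid-saccade/off at onset; resume bouts
    elif attentive:
        t = label_onset + float(rng.uniform(100.0, 400.0))
        side = AOI_LEFT if rng.random() < 0.5 else AOI_RIGHT
        while t < trial_end:
            dwell = max(50.0, float(rng.gamma(params.dwell_shape, params.dwell_scale)))
            post.append([t, t + dwell, side])
            t += dwell + float(rng.uniform(SACCADE_MIN, SACCADE_MAX))
            side = AOI_RIGHT if side == AOI_LEFT else AOI_LEFT

    stream = [ag]
    for onset, offset, aoi in pre + post:
        onset = float(onset)
        offset = min(float(offset), trial_end)
        if offset > onset:
            stream.append(Fixation(onset, offset, aoi, spec.trial_index))
    return stream


# ---------------------------------------------------------------------------
# Sessions and cohorts


def simulate_session(
    params: InfantParams,
    schedule: SessionSchedule,
    config: DesignConfig | None = None,
    gaze_seed: int = 0,
    participant_index: int = 0,
) -> tuple[list[Fixation], list[TrialRecord]]:
    """Run one infant through a full session against the controller,
    honoring the five-consecutive-failures stop rule."""
    config = config or DesignConfig()
    rng = _rng(gaze_seed, participant_index, 202)
    state = SessionState()
    fixations: list[Fixation] = []
    records: list[TrialRecord] = []
    for spec in schedule.trials:
        if session_stop_rule(state, config):
            break
        stream = simulate_trial_gaze(params, spec, rng, config, state)
        record, state = run_trial(
            spec, stream, state, config, participant_id=params.participant_id
        )
        records.append(record)
        fixations.extend(
            Fixation(
                f.onset_ms, f.offset_ms, f.aoi, f.trial_index, params.participant_id
            )
            for f in stream
        )
    return fixations, records


def simulate_cohort(
    n: int,
    config: DesignConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[CohortTruth, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of ``n`` infants end to end.

    Returns (truth, gaze, events, vocab) as in-memory tables; when
    ``out_dir`` is given also writes gaze.csv, events.csv, vocab.csv and
    truth.json there. Byte-identical across runs with equal (n, config,
    seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or DesignConfig()
    infants: list[InfantParams] = []
    gaze_frames: list[pd.DataFrame] = []
    event_frames: list[pd.DataFrame] = []
    vocab_rows: list[dict] = []
    for i in range(n):
        params = sample_infant(seed, i, config)
        schedule = build_schedule(config, i, seed)
        fixations, records = simulate_session(
            params, schedule, config, gaze_seed=seed, participant_index=i
        )
        infants.append(params)
        gaze_frames.append(fixations_to_frame(fixations))
        event_frames.append(events_to_frame(records))
        vocab_rows.append(
            {
                "participant_id": params.participant_id,
                "cdi_comprehended": params.cdi_comprehended,
                "cdi_produced": params.expressive_vocab,
                "known_items": ";".join(
                    sorted(k for k, v in params.known_words.items() if v)
                ),
            }
        )
    truth = CohortTruth(
        master_seed=seed,
        n_participants=n,
        infants=infants,
        config=json.loads(config.model_dump_json()),
    )
    nonempty = [g for g in gaze_frames if len(g)] or gaze_frames[:1]
    gaze = pd.concat(nonempty, ignore_index=True)
    events = pd.concat(event_frames, ignore_index=True)
    vocab = pd.DataFrame(vocab_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gaze.to_csv(out / "gaze.csv", index=False)
        events.to_csv(out / "events.csv", index=False)
        vocab.to_csv(out / "vocab.csv", index=False)
        truth.to_json(out / "truth.json")
    return truth, gaze, events, vocab
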