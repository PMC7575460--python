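"""Session-design generation: blocked, counterbalanced 80-trial schedules.

The session alternates blocks of eight gaze-triggered and eight original
trials (one trial per stimulus pair per block), with two filler trials
inserted pseudo-randomly into each block — never at the block's first or
last position and never adjacent to each other. Which condition comes first
alternates across participants by parity.

Counterbalancing guarantees, per schedule:
  * each pair is shown once per experimental block (4x per condition, 8x total);
  * each of the 16 items is the predetermined target exactly twice in the
    original condition;
  * each item of a pair appears on the left in exactly half of that pair's
    appearances per condition.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel

from .config import (
    DesignConfig,
    FILLER,
    GAZE_TRIGGERED,
    ORIGINAL,
)


class TrialSpec(BaseModel):
    """One planned trial: what is shown where, and which recordings play."""

    trial_index: int
    block_index: int
    trial_type: str  # gaze_triggered | original | filler
    pair_id: str
    left_item: str
    right_item: str
    #: Named item for original and filler trials; None on gaze-triggered
    #: trials, where the target is chosen online from the infant's gaze.
    predetermined_target: Optional[str] = None
    #: Fallback target for gaze-triggered trials when the label must be
    #: triggered manually and the pair's label counts are tied.
    backup_target: Optional[str] = None
    attention_getter_id: int = 1
    exclamation_id: int = 1
    label_token_id: int = 1


class SessionSchedule(BaseModel):
    participant_index: int
    condition_first: str
    seed: int
    trials: list[TrialSpec]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionSchedule":
        return cls.model_validate(json.loads(Path(path).read_text()))


def condition_order(participant_index: int) -> str:
    """First condition for a participant: alternates by parity (even index
    starts gaze-triggered), giving an exact balance over any even cohort."""
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    return GAZE_TRIGGERED if participant_index % 2 == 0 else ORIGINAL


def _filler_positions(rng: np.random.Generator, block_len: int, k: int) -> list[int]:
    """Positions for k fillers in a block of block_len slots: never first or
    last, never adjacent."""
    inner = range(1, block_len - 1)
    combos = [
        c
        for c in itertools.combinations(inner, k)
        if all(b - a >= 2 for a, b in zip(c, c[1:]))
    ]
    return list(combos[rng.integers(len(combos))])


def _shuffled(rng: np.random.Generator, seq: list) -> list:
    out = list(seq)
    rng.shuffle(out)
    return out


def build_schedule(
    config: DesignConfig, participant_index: int, seed: int
) -> SessionSchedule:
    """Build one participant's full session schedule.

    Deterministic given (config, participant_index, seed); raises
    ``ValueError`` (from config validation) if the counts do not divide into
    the block structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, participant_index]))
    first = condition_order(participant_index)
    second = ORIGINAL if first == GAZE_TRIGGERED else GAZE_TRIGGERED
    n_blocks_per_cond = config.n_blocks // 2

    # Per-pair counterbalancing sequences across a condition's 4 blocks.
    # targets: original-condition predetermined targets, each item twice.
    # sides: whether item_a is on the left, twice each way per condition.
    # backups: manual-trigger fallback targets for gaze trials, balanced.
    per_pair: dict[str, dict] = {}
    for pair in config.pairs:
        a, b = pair.items
        half = n_blocks_per_cond // 2
        per_pair[pair.pair_id] = {
            "orig_targets": _shuffled(rng, [a] * half + [b] * half),
            "backup_targets": _shuffled(rng, [a] * half + [b] * half),
            "sides": {
                GAZE_TRIGGERED: _shuffled(rng, [True] * half + [False] * half),
                ORIGINAL: _shuffled(rng, [True] * half + [False] * half),
            },
        }

    # Filler inventory: each filler item is named 4x; visual partners rotate
    # over the other filler items so fillers never touch experimental pairs.
    fillers: list[tuple[str, str, bool]] = []  # (target, partner, target_on_left)
    items = list(config.filler_items)
    n_per_item = config.n_filler_trials // len(items)
    for i, target in enumerate(items):
        others = [it for it in items if it != target]
        for k in range(n_per_item):
            partner = others[(i + k) % len(others)]
            fillers.append((target, partner, k % 2 == 0))
    fillers = _shuffled(rng, fillers)

    ag_cycle = itertools.cycle(range(1, 7))
    for _ in range(rng.integers(6)):
        next(ag_cycle)
    excl_cycle = itertools.cycle(range(1, 17))
    for _ in range(rng.integers(16)):
        next(excl_cycle)
    label_counters = {
        item: int(rng.integers(4)) for item in config.item_names + list(items)
    }

    def next_label_token(item: str) -> int:
        label_counters[item] = (label_counters[item] + 1) % 4
        return label_counters[item] + 1

    trials: list[TrialSpec] = []
    cond_block_counter = {GAZE_TRIGGERED: 0, ORIGINAL: 0}
    filler_iter = iter(fillers)
    for block_index in range(config.n_blocks):
        cond = first if block_index % 2 == 0 else second
        cond_block = cond_block_counter[cond]
        cond_block_counter[cond] += 1

        pair_order = _shuffled(rng, list(config.pairs))
        positions = set(
            _filler_positions(rng, config.block_len, config.fillers_per_block)
        )
        pair_it = iter(pair_order)
        for pos in range(config.block_len):
            trial_index = block_index * config.block_len + pos
            if pos in positions:
                target, partner, target_left = next(filler_iter)
                left, right = (target, partner) if target_left else (partner, target)
                trials.append(
                    TrialSpec(
                        trial_index=trial_index,
                        block_index=block_index,
                        trial_type=FILLER,
                        pair_id="filler:" + "+".join(sorted((target, partner))),
                        left_item=left,
                        right_item=right,
                        predetermined_target=target,
                        attention_getter_id=next(ag_cycle),
                        exclamation_id=next(excl_cycle),
                        label_token_id=next_label_token(target),
                    )
                )
                continue
            pair = next(pair_it)
            cb = per_pair[pair.pair_id]
            a_left = cb["sides"][cond][cond_block]
            left, right = (pair.item_a, pair.item_b) if a_left else (pair.item_b, pair.item_a)
            if cond == ORIGINAL:
                target = cb["orig_targets"][cond_block]
                trials.append(
                    TrialSpec(
                        trial_index=trial_index,
                        block_index=block_index,
                        trial_type=ORIGINAL,
                        pair_id=pair.pair_id,
                        left_item=left,
                        right_item=right,
                        predetermined_target=target,
                        attention_getter_id=next(ag_cycle),
                        exclamation_id=next(excl_cycle),
                        label_token_id=next_label_token(target),
                    )
                )
            else:
                backup = cb["backup_targets"][cond_block]
                trials.append(
                    TrialSpec(
                        trial_index=trial_index,
                        block_index=block_index,
                        trial_type=GAZE_TRIGGERED,
                        pair_id=pair.pair_id,
                        left_item=left,
                        right_item=right,
                        backup_target=backup,
                        attention_getter_id=next(ag_cycle),
                        exclamation_id=next(excl_cycle),
                        # the target is unknown at design time; the label
                        # token variant is drawn when the label plays
                        label_token_id=int(rng.integers(4)) + 1,
                    )
                )

    return SessionSchedule(
        participant_index=participant_index,
        condition_first=first,
        seed=seed,
        trials=trials,
    )


def validate_schedule(
    schedule: SessionSchedule, config: DesignConfig | None = None
) -> list[str]:
    """Check every session-design invariant; return the violations found
    (empty list = valid). Never raises on a bad schedule."""
    config = config or DesignConfig()
    errors: list[str] = []
    trials = schedule.trials

    if len(trials) != config.n_trials:
        errors.append(
            f"trial count: expected {config.n_trials}, got {len(trials)}"
        )
    counts = {GAZE_TRIGGERED: 0, ORIGINAL: 0, FILLER: 0}
    for t in trials:
        if t.trial_type in counts:
            counts[t.trial_type] += 1
    expected = {
        GAZE_TRIGGERED: config.n_gaze_trials,
        ORIGINAL: config.n_original_trials,
        FILLER: config.n_filler_trials,
    }
    for k, v in expected.items():
        if counts[k] != v:
            errors.append(f"per-type count: expected {v} {k} trials, got {counts[k]}")

    # block structure and filler placement
    blocks: dict[int, list[TrialSpec]] = {}
    for t in trials:
        blocks.setdefault(t.block_index, []).append(t)
    prev_cond = None
    for bi in sorted(blocks):
        block = sorted(blocks[bi], key=lambda t: t.trial_index)
        exp = [t for t in block if t.trial_type != FILLER]
        fil = [t for t in block if t.trial_type == FILLER]
        conds = {t.trial_type for t in exp}
        if len(conds) != 1:
            errors.append(f"block {bi}: mixed experimental conditions {sorted(conds)}")
        else:
            cond = conds.pop()
            if prev_cond is not None and cond == prev_cond:
                errors.append(f"block {bi}: condition does not alternate")
            prev_cond = cond
        if len(exp) != config.block_size_experimental:
            errors.append(
                f"block {bi}: {len(exp)} experimental trials, "
                f"expected {config.block_size_experimental}"
            )
        if len(fil) != config.fillers_per_block:
            errors.append(
                f"block {bi}: {len(fil)} fillers, expected {config.fillers_per_block}"
            )
        if block and block[0].trial_type == FILLER:
            errors.append(f"block {bi}: filler at first position of block")
        if block and block[-1].trial_type == FILLER:
            errors.append(f"block {bi}: filler at last position of block")
        for t1, t2 in zip(block, block[1:]):
            if t1.trial_type == FILLER and t2.trial_type == FILLER:
                errors.append(
                    f"block {bi}: two consecutive fillers "
                    f"(trials {t1.trial_index}, {t2.trial_index})"
                )
        pair_ids = [t.pair_id for t in exp]
        if len(set(pair_ids)) != len(pair_ids):
            errors.append(f"block {bi}: a pair appears more than once")

    # pair appearance counts: 4x per condition
    for cond in (GAZE_TRIGGERED, ORIGINAL):
        per_cond = config.n_gaze_trials // len(config.pairs)
        for pair in config.pairs:
            n = sum(
                1 for t in trials if t.trial_type == cond and t.pair_id == pair.pair_id
            )
            if n != per_cond:
                errors.append(
                    f"pair {pair.pair_id}: shown {n}x in {cond}, expected {per_cond}"
                )

    # original-condition target balance: each item exactly 2x
    per_item = config.n_original_trials // len(config.item_names)
    tgt_counts = {item: 0 for item in config.item_names}
    for t in trials:
        if t.trial_type == ORIGINAL and t.predetermined_target in tgt_counts:
            tgt_counts[t.predetermined_target] += 1
    for item, n in tgt_counts.items():
        if n != per_item:
            errors.append(
                f"item {item}: predetermined target {n}x in original condition, "
                f"expected {per_item}"
            )

    # left/right balance per item per condition
    for cond in (GAZE_TRIGGERED, ORIGINAL):
        for pair in config.pairs:
            shown = [
                t for t in trials if t.trial_type == cond and t.pair_id == pair.pair_id
            ]
            n_left_a = sum(1 for t in shown if t.left_item == pair.item_a)
            if shown and n_left_a * 2 != len(shown):
                errors.append(
                    f"pair {pair.pair_id}: {pair.item_a} on left {n_left_a}/"
                    f"{len(shown)} in {cond}, expected exact half"
                )

    # per-trial field invariants
    for t in trials:
        if t.predetermined_target is not None and t.predetermined_target not in (
            t.left_item,
            t.right_item,
        ):
            errors.append(
                f"trial {t.trial_index}: predetermined target not on screen"
            )
        if t.trial_type == GAZE_TRIGGERED and t.predetermined_target is not None:
            errors.append(
                f"trial {t.trial_index}: gaze-triggered trial has a "
                "predetermined target"
            )
    return errors
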