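"""Design configuration for the gaze-triggered looking-while-listening paradigm.

All timing constants are milliseconds. A session consists of alternating
blocks of eight gaze-triggered and eight original (predetermined-target)
trials, with two filler trials inserted into each block. Picture onset is
time 0 within a trial; the attention getter occupies negative time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, model_validator

# trial types
GAZE_TRIGGERED = "gaze_triggered"
ORIGINAL = "original"
FILLER = "filler"

# AOI labels
AOI_LEFT = "left"
AOI_RIGHT = "right"
AOI_OFF = "off"
AOI_ATTENTION = "attention_getter"

Category = Literal["food", "animals", "clothes", "toys"]


class ItemPair(BaseModel):
    """A yoked pair of picture stimuli shown together on every appearance."""

    pair_id: str
    item_a: str
    item_b: str
    category_a: Category
    category_b: Category

    @model_validator(mode="after")
    def _distinct(self) -> "ItemPair":
        if self.item_a == self.item_b:
            raise ValueError("item_a and item_b must differ")
        return self

    @property
    def items(self) -> tuple[str, str]:
        return (self.item_a, self.item_b)

    def other(self, item: str) -> str:
        if item == self.item_a:
            return self.item_b
        if item == self.item_b:
            return self.item_a
        raise ValueError(f"item {item!r} not in pair {self.pair_id}")


def _pair(a: str, ca: Category, b: str, cb: Category) -> ItemPair:
    return ItemPair(pair_id=f"{a}_{b}", item_a=a, item_b=b, category_a=ca, category_b=cb)


#: The default stimulus inventory: 16 objects from four categories (food,
#: animals, clothes, toys), four per category, in eight fixed yoked pairs.
DEFAULT_PAIRS: tuple[ItemPair, ...] = (
    _pair("apple", "food", "jacket", "clothes"),
    _pair("banana", "food", "book", "toys"),
    _pair("bottle", "food", "ball", "toys"),
    _pair("bowl", "food", "shoe", "clothes"),
    _pair("cat", "animals", "hat", "clothes"),
    _pair("cow", "animals", "sock", "clothes"),
    _pair("dog", "animals", "bike", "toys"),
    _pair("horse", "animals", "car", "toys"),
)

DEFAULT_FILLER_ITEMS: tuple[str, ...] = ("baby", "cookie", "spoon", "bear")

#: Durations (ms) of the 16 exclamation recordings (4 exclamations x 4
#: intonation variants), evenly spaced so that original-condition label
#: delays (duration + 100 ms silence) span 710-1220 ms after exclamation
#: onset, matching the natural range of the recordings.
EXCLAMATION_DURATIONS_MS: dict[int, int] = {i: 610 + 34 * (i - 1) for i in range(1, 17)}


class DesignConfig(BaseModel):
    """Every count and timing constant the paradigm uses.

    Defaults encode the published session design: 80 trials (32 gaze-triggered
    + 32 original + 16 filler), 100 ms gaze trigger, label 100 ms after the
    exclamation in the original condition, RT window 300-1800 ms post label
    onset inside the 0-2000 ms attention window.
    """

    n_gaze_trials: int = 32
    n_original_trials: int = 32
    n_filler_trials: int = 16
    block_size_experimental: int = 8
    fillers_per_block: int = 2
    attention_getter_fix_ms: int = 500
    preview_ms: int = 2000
    original_silence_ms: int = 100
    trigger_fix_ms: int = 100
    trigger_window_ms: int = 5000
    post_label_ms: int = 2000
    min_fixation_ms: int = 100
    attention_window: tuple[int, int] = (0, 2000)
    attention_min_ms: int = 100
    rt_window: tuple[int, int] = (300, 1800)
    stop_after_failed: int = 5
    filler_items: tuple[str, ...] = DEFAULT_FILLER_ITEMS
    pairs: tuple[ItemPair, ...] = DEFAULT_PAIRS
    # How the controller resolves the pair's 4th gaze-triggered trial:
    # "balance" enforces an exact 2/2 label split per pair; "repeat_previous"
    # labels the fixated item only when it repeats the previous trial's
    # fixation (sensitivity-analysis variant).
    fourth_trial_rule: Literal["balance", "repeat_previous"] = "balance"

    @model_validator(mode="after")
    def _check(self) -> "DesignConfig":
        for name in (
            "attention_getter_fix_ms",
            "preview_ms",
            "original_silence_ms",
            "trigger_fix_ms",
            "trigger_window_ms",
            "post_label_ms",
            "min_fixation_ms",
            "attention_min_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.rt_window
        alo, ahi = self.attention_window
        if not (alo <= lo < hi <= ahi):
            raise ValueError("rt_window must lie within the attention window")
        if self.n_gaze_trials != self.n_original_trials:
            raise ValueError("n_gaze_trials must equal n_original_trials")
        if self.n_gaze_trials % len(self.pairs) != 0:
            raise ValueError("n_gaze_trials must be divisible by the number of pairs")
        if self.n_gaze_trials % self.block_size_experimental != 0:
            raise ValueError(
                "n_gaze_trials must be divisible by block_size_experimental"
            )
        n_blocks = (self.n_gaze_trials + self.n_original_trials) // self.block_size_experimental
        if n_blocks * self.fillers_per_block != self.n_filler_trials:
            raise ValueError(
                "n_filler_trials must equal fillers_per_block x number of blocks"
            )
        if self.block_size_experimental != len(self.pairs):
            raise ValueError(
                "block_size_experimental must equal the number of pairs "
                "(one trial per pair per block)"
            )
        names = [p.item_a for p in self.pairs] + [p.item_b for p in self.pairs]
        if len(set(names)) != len(names):
            raise ValueError("pair items must be unique across pairs")
        return self

    @property
    def n_blocks(self) -> int:
        return (self.n_gaze_trials + self.n_original_trials) // self.block_size_experimental

    @property
    def block_len(self) -> int:
        return self.block_size_experimental + self.fillers_per_block

    @property
    def n_trials(self) -> int:
        return self.n_gaze_trials + self.n_original_trials + self.n_filler_trials

    @property
    def item_names(self) -> list[str]:
        return [it for p in self.pairs for it in p.items]

    def pair_by_id(self, pair_id: str) -> ItemPair:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(pair_id)

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


class AoiLayout(BaseModel):
    """Screen areas of interest as half-open pixel rectangles [x0,x1) x [y0,y1).

    Defaults split a 1600x900 screen into left/right halves separated by an
    80-px central gutter.
    """

    left_region: tuple[int, int, int, int] = (0, 760, 0, 900)
    right_region: tuple[int, int, int, int] = (840, 1600, 0, 900)
    screen_size: tuple[int, int] = (1600, 900)

    @model_validator(mode="after")
    def _disjoint(self) -> "AoiLayout":
        lx0, lx1, ly0, ly1 = self.left_region
        rx0, rx1, ry0, ry1 = self.right_region
        if lx0 >= lx1 or ly0 >= ly1 or rx0 >= rx1 or ry0 >= ry1:
            raise ValueError("regions must have positive extent")
        if lx1 > rx0 and rx1 > lx0 and ly1 > ry0 and ry1 > ly0:
            raise ValueError("left and right regions must be disjoint")
        return self
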