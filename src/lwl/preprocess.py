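"""Gaze-data ingestion and preparation.

Fixations are the native unit: half-open intervals ``[onset_ms, offset_ms)``
in trial-relative milliseconds with picture onset at 0 (attention-getter
fixations occupy negative time). An AOI label places each fixation on the
left picture, the right picture, the attention getter, or off-screen.

Preparation for analysis removes attention-getter and filler-trial data,
drops fixations shorter than 100 ms (the eye-tracker filter used for all
analyses), and aligns each experimental trial to its label onset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import (
    AOI_ATTENTION,
    AOI_LEFT,
    AOI_OFF,
    AOI_RIGHT,
    FILLER,
    AoiLayout,
)

GAZE_CSV_COLUMNS = ["participant_id", "trial_index", "fix_onset_ms", "fix_offset_ms", "aoi"]
_VALID_AOIS = {AOI_LEFT, AOI_RIGHT, AOI_OFF, AOI_ATTENTION}


@dataclass(frozen=True, slots=True)
class Fixation:
    """One eye-tracker fixation, trial-relative, picture onset = 0."""

    onset_ms: float
    offset_ms: float
    aoi: Optional[str] = None
    trial_index: Optional[int] = None
    participant_id: Optional[str] = None
    x: Optional[float] = None
    y: Optional[float] = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def covers(self, t_ms: float) -> bool:
        """Whether the instant t lies inside the half-open interval."""
        return self.onset_ms <= t_ms < self.offset_ms


class GazeFileError(ValueError):
    """Malformed gaze input; message carries the offending rows/lines."""


# ---------------------------------------------------------------------------
# CSV reading / writing


def read_fixation_csv(path: str | Path) -> list[Fixation]:
    """Read ``gaze.csv`` (participant_id, trial_index, fix_onset_ms,
    fix_offset_ms, aoi) into fixations, enforcing offset > onset.

    Raises :class:`GazeFileError` naming the 1-based data row of the first
    problems found.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFileError(f"{path}: missing columns {missing}")
    problems: list[str] = []
    fixations: list[Fixation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            onset = float(row.fix_onset_ms)
            offset = float(row.fix_offset_ms)
            trial = int(row.trial_index)
        except (TypeError, ValueError):
            problems.append(f"row {i}: non-numeric onset/offset/trial_index")
            continue
        if math.isnan(onset) or math.isnan(offset):
            problems.append(f"row {i}: missing onset/offset")
            continue
        if offset <= onset:
            problems.append(f"row {i}: offset {offset} <= onset {onset}")
            continue
        aoi = str(row.aoi)
        if aoi not in _VALID_AOIS:
            problems.append(f"row {i}: unknown aoi {aoi!r}")
            continue
        fixations.append(
            Fixation(
                onset_ms=onset,
                offset_ms=offset,
                aoi=aoi,
                trial_index=trial,
                participant_id=str(row.participant_id),
            )
        )
    if problems:
        raise GazeFileError(f"{path}: " + "; ".join(problems))
    return fixations


def write_fixation_csv(fixations: Iterable[Fixation], path: str | Path) -> None:
    fixations_to_frame(fixations).to_csv(path, index=False)


def fixations_to_frame(fixations: Iterable[Fixation]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": f.participant_id,
            "trial_index": f.trial_index,
            "fix_onset_ms": f.onset_ms,
            "fix_offset_ms": f.offset_ms,
            "aoi": f.aoi,
        }
        for f in fixations
    ]
    return pd.DataFrame(rows, columns=GAZE_CSV_COLUMNS)


# ---------------------------------------------------------------------------
# EyeLink ASCII (minimal EFIX/MSG dialect)


def parse_asc_efix(
    lines: Iterable[str],
) -> tuple[list[Fixation], pd.DataFrame]:
    """Parse the minimal EyeLink ASCII subset: ``EFIX`` fixation-end events
    and ``MSG`` trial markers (TRIAL_START i / EXCL_ONSET / LABEL_ONSET /
    TRIAL_END).

    Fixations are re-based to trial-relative ms (TRIAL_START = picture onset
    = 0) and carry raw x/y; AOIs are assigned separately. When both eyes are
    recorded, only the right eye is kept. Fixations straddling TRIAL_END are
    truncated at trial end and flagged via a warning; EFIX lines before any
    TRIAL_START are dropped and reported. Unknown lines are ignored.

    Returns (fixations, events) where events has one row per trial with
    columns trial_index, excl_onset_ms, label_onset_ms, trial_end_ms
    (trial-relative).
    """
    raw_fix: list[tuple[str, float, float, float, float]] = []  # eye,start,end,x,y
    msgs: list[tuple[float, str, Optional[int]]] = []
    for line in lines:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "EFIX" and len(parts) >= 7:
            try:
                eye = parts[1]
                start, end = float(parts[2]), float(parts[3])
                x, y = float(parts[5]), float(parts[6])
            except ValueError:
                continue
            raw_fix.append((eye, start, end, x, y))
        elif parts[0] == "MSG" and len(parts) >= 3:
            try:
                t = float(parts[1])
            except ValueError:
                continue
            tag = parts[2]
            arg = None
            if len(parts) >= 4:
                try:
                    arg = int(parts[3])
                except ValueError:
                    arg = None
            msgs.append((t, tag, arg))

    if not msgs:
        warnings.warn("ASC input contains no MSG trial markers; nothing parsed")
        return [], pd.DataFrame(
            columns=["trial_index", "excl_onset_ms", "label_onset_ms", "trial_end_ms"]
        )

    eyes = {f[0] for f in raw_fix}
    if "R" in eyes and "L" in eyes:
        raw_fix = [f for f in raw_fix if f[0] == "R"]

    # Build trial windows from MSG stream
    trials: list[dict] = []
    current: Optional[dict] = None
    for t, tag, arg in sorted(msgs, key=lambda m: m[0]):
        if tag == "TRIAL_START":
            current = {"trial_index": arg, "start": t}
            trials.append(current)
        elif current is not None and tag == "EXCL_ONSET":
            current["excl_onset"] = t
        elif current is not None and tag == "LABEL_ONSET":
            current["label_onset"] = t
        elif current is not None and tag == "TRIAL_END":
            current["end"] = t
            current = None

    fixations: list[Fixation] = []
    dropped = 0
    truncated = 0
    for eye, start, end, x, y in sorted(raw_fix, key=lambda f: f[1]):
        home = None
        for tr in trials:
            if tr.get("start") is not None and start >= tr["start"] and (
                "end" not in tr or start < tr["end"]
            ):
                home = tr
        if home is None or start < trials[0]["start"]:
            dropped += 1
            continue
        t0 = home["start"]
        off = end
        if "end" in home and end > home["end"]:
            off = home["end"]
            truncated += 1
        if off <= start:
            continue
        fixations.append(
            Fixation(
                onset_ms=start - t0,
                offset_ms=off - t0,
                trial_index=home["trial_index"],
                x=x,
                y=y,
            )
        )
    if dropped:
        warnings.warn(f"{dropped} EFIX event(s) before any TRIAL_START dropped")
    if truncated:
        warnings.warn(f"{truncated} EFIX event(s) truncated at TRIAL_END")

    events = pd.DataFrame(
        [
            {
                "trial_index": tr["trial_index"],
                "excl_onset_ms": tr.get("excl_onset", float("nan")) - tr["start"]
                if "excl_onset" in tr
                else float("nan"),
                "label_onset_ms": tr.get("label_onset", float("nan")) - tr["start"]
                if "label_onset" in tr
                else float("nan"),
                "trial_end_ms": tr["end"] - tr["start"] if "end" in tr else float("nan"),
            }
            for tr in trials
        ],
        columns=["trial_index", "excl_onset_ms", "label_onset_ms", "trial_end_ms"],
    )
    return fixations, events


# ---------------------------------------------------------------------------
# Fixation filtering and AOI assignment


def filter_short_fixations(
    fixations: Sequence[Fixation], min_ms: float = 100.0
) -> list[Fixation]:
    """Keep fixations lasting at least ``min_ms`` (closed threshold: a fixation
    of exactly 100 ms is kept). Order is preserved."""
    return [f for f in fixations if f.duration_ms >= min_ms]


def assign_aoi(x: float, y: float, layout: AoiLayout | None = None) -> str:
    """Classify a gaze point into left / right / off by half-open rectangle
    containment (a point exactly on the far edge falls outside)."""
    layout = layout or AoiLayout()
    for region, label in ((layout.left_region, AOI_LEFT), (layout.right_region, AOI_RIGHT)):
        x0, x1, y0, y1 = region
        if x0 <= x < x1 and y0 <= y < y1:
            return label
    return AOI_OFF


def assign_aois(
    fixations: Sequence[Fixation], layout: AoiLayout | None = None
) -> list[Fixation]:
    """AOI-label fixations that carry raw coordinates; fixations that already
    have an AOI pass through unchanged."""
    layout = layout or AoiLayout()
    out = []
    for f in fixations:
        if f.aoi is not None:
            out.append(f)
        elif f.x is None or f.y is None:
            out.append(replace(f, aoi=AOI_OFF))
        else:
            out.append(replace(f, aoi=assign_aoi(f.x, f.y, layout)))
    return out


# ---------------------------------------------------------------------------
# Trial segmentation


def segment_trials(
    fixations: Sequence[Fixation], events: pd.DataFrame
) -> pd.DataFrame:
    """Join fixations onto trial events, keeping only experimental trials.

    Attention-getter fixations (AOI ``attention_getter`` or lying wholly
    before picture onset) and filler trials are removed. The result is one
    row per fixation with both trial-relative and label-relative timestamps.

    ``events`` is the controller's events table (one row per trial with at
    least participant_id, trial_index, trial_type, target_side,
    label_onset_ms). Fixations referencing a trial_index absent from events
    raise :class:`GazeFileError` listing the orphan indices.
    """
    required = {"participant_id", "trial_index", "trial_type", "label_onset_ms"}
    missing = required - set(events.columns)
    if missing:
        raise GazeFileError(f"events table missing columns {sorted(missing)}")

    fix_df = fixations_to_frame(fixations)
    if fix_df.empty:
        cols = list(fix_df.columns) + [
            "trial_type",
            "target_side",
            "label_onset_ms",
            "onset_rel_ms",
            "offset_rel_ms",
        ]
        return pd.DataFrame(columns=cols)

    ev = events.copy()
    ev["trial_index"] = ev["trial_index"].astype(int)
    ev["participant_id"] = ev["participant_id"].astype(str)
    fix_df["trial_index"] = fix_df["trial_index"].astype(int)
    fix_df["participant_id"] = fix_df["participant_id"].astype(str)

    known = set(zip(ev["participant_id"], ev["trial_index"]))
    seen = set(zip(fix_df["participant_id"], fix_df["trial_index"]))
    orphans = sorted(seen - known)
    if orphans:
        raise GazeFileError(f"fixations reference unknown trials: {orphans}")

    keep_cols = ["participant_id", "trial_index", "trial_type", "label_onset_ms"]
    for extra in ("target_side", "target_item", "distractor_item", "bias_corrected",
                  "manual_trigger", "completed", "pair_id", "block_index"):
        if extra in ev.columns:
            keep_cols.append(extra)
    merged = fix_df.merge(ev[keep_cols], on=["participant_id", "trial_index"], how="left")

    merged = merged[merged["trial_type"] != FILLER]
    merged = merged[merged["aoi"] != AOI_ATTENTION]
    merged = merged[merged["fix_offset_ms"] > 0]
    merged = merged.copy()
    merged["onset_rel_ms"] = merged["fix_onset_ms"] - merged["label_onset_ms"]
    merged["offset_rel_ms"] = merged["fix_offset_ms"] - merged["label_onset_ms"]
    return merged.reset_index(drop=True)
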