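"""End-to-end orchestration: schedule -> gaze -> preprocess -> RT -> stats.

Every run writes a manifest (config snapshot, seeds, paths, package version)
sufficient to reproduce any stage. ``simulate`` mode generates a synthetic
cohort; ``replay`` mode ingests existing gaze/events/vocab files and runs
the identical analysis path.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import DesignConfig
from .controller import read_events_csv
from .preprocess import read_fixation_csv, segment_trials
from .rt import apply_inclusion, extract_outcomes, summarize_cohort, summaries_to_frame
from .simulator import simulate_cohort
from .stats import build_report, write_report

logger = logging.getLogger("lwl")


def _analyze(
    gaze_df_path: Path,
    events_path: Path,
    vocab: Optional[pd.DataFrame],
    config: DesignConfig,
    seed: int,
    out: Path,
) -> dict:
    logger.info("preprocess: segmenting trials")
    fixations = read_fixation_csv(gaze_df_path)
    events = read_events_csv(events_path)
    trials = segment_trials(fixations, events)
    trials.to_csv(out / "trials.csv", index=False)

    logger.info("extract: scoring %d experimental trials", len(events))
    outcomes = extract_outcomes(trials, events, config)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    summaries = summarize_cohort(outcomes)
    included, exclusions = apply_inclusion(summaries)
    summaries_to_frame(summaries).to_csv(out / "summary.csv", index=False)
    if exclusions:
        (out / "exclusions.txt").write_text(
            "\n".join(f"{pid}: {reason}" for pid, reason in exclusions) + "\n"
        )
        logger.info("extract: excluded %d participant(s)", len(exclusions))

    logger.info("analyze: building report")
    report = build_report(outcomes, summaries, vocab, seed=seed, config=config)
    write_report(report, out / "report.json", out / "report.md")
    return report


def run_pipeline(
    config: DesignConfig | str | Path | None = None,
    mode: str = "simulate",
    seed: int = 0,
    out_dir: str | Path = "results",
    n: int = 43,
    gaze: str | Path | None = None,
    events: str | Path | None = None,
    vocab: str | Path | None = None,
) -> dict:
    """Run the full pipeline; returns the manifest (also written as
    ``manifest.json`` in ``out_dir``)."""
    if isinstance(config, (str, Path)):
        config = DesignConfig.from_json(config)
    config = config or DesignConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if mode == "simulate":
        logger.info("simulate: cohort of %d infants (seed %d)", n, seed)
        _, gaze_df, events_df, vocab_df = simulate_cohort(n, config, seed, out_dir=out)
        gaze_path, events_path = out / "gaze.csv", out / "events.csv"
        vocab_frame: Optional[pd.DataFrame] = vocab_df
    elif mode == "replay":
        if gaze is None or events is None:
            raise ValueError("replay mode needs --gaze and --events paths")
        gaze_path, events_path = Path(gaze), Path(events)
        vocab_frame = pd.read_csv(vocab) if vocab is not None else None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    _analyze(gaze_path, events_path, vocab_frame, config, seed, out)

    manifest = {
        "lwl_version": __version__,
        "mode": mode,
        "seed": seed,
        "n_participants": n if mode == "simulate" else None,
        "config": json.loads(config.model_dump_json()),
        "inputs": {"gaze": str(gaze_path), "events": str(events_path)},
        "outputs": {
            name: str(out / name)
            for name in ("trials.csv", "outcomes.csv", "summary.csv", "report.json")
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out / "report.json")
    return manifest


def make_demo(out_dir: str | Path, seed: int = 7) -> dict:
    """A small worked example: three simulated infants, full outputs."""
    return run_pipeline(mode="simulate", seed=seed, out_dir=out_dir, n=3)
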