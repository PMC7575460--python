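import pandas as pd
import pytest

from lwl.config import DesignConfig
from lwl.preprocess import Fixation, segment_trials
from lwl.rt import apply_inclusion, extract_outcomes, summarize_cohort
from lwl.simulator import simulate_cohort


@pytest.fixture(scope="session")
def config() -> DesignConfig:
    return DesignConfig()


def frame_to_fixations(gaze: pd.DataFrame) -> list[Fixation]:
    return [
        Fixation(
            float(r.fix_onset_ms),
            float(r.fix_offset_ms),
            r.aoi,
            int(r.trial_index),
            str(r.participant_id),
        )
        for r in gaze.itertuples(index=False)
    ]


def run_cohort(n: int, seed: int, config: DesignConfig):
    """Simulate a cohort and push it through the full analysis path."""
    truth, gaze, events, vocab = simulate_cohort(n, config, seed)
    trials = segment_trials(frame_to_fixations(gaze), events)
    outcomes = extract_outcomes(trials, events, config)
    summaries = summarize_cohort(outcomes)
    apply_inclusion(summaries)
    return truth, gaze, events, vocab, outcomes, summaries


@pytest.fixture(scope="session")
def cohort43(config):
    """One 43-infant simulated cohort shared across read-only tests."""
    return run_cohort(43, seed=20250925, config=config)
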