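"""Reliability and validity statistics for paired-condition RT data.

Implements the analysis battery run on a session's outcomes: a one-sided
paired t test on the percentage of completed trials yielding a valid RT
(gaze-triggered predicted higher), a two-sided paired t on mean RTs, the
between-condition Spearman rank correlation of participant mean RTs,
within-condition split-half reliabilities, a trial-order effect on RTs, a
word-knowledge effect, and the RT-expressive-vocabulary rank correlation.

The paired t statistic is mean(d) / (sd(d)/sqrt(n)) with df = n - 1.
Spearman's rho is the Pearson correlation of average ranks, its p-value the
t approximation rho*sqrt((n-2)/(1-rho^2)), and its 95% CI comes from the
Fisher z transform with standard error 1/sqrt(n-3). Trial-order and
word-knowledge effects use a two-stage summary-statistics approximation to
the mixed model (per-participant estimate, then a one-sample t across
participants); an optional adapter fits the crossed random-effects model via
statsmodels MixedLM.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import GAZE_TRIGGERED, ORIGINAL, DesignConfig
from .rt import ParticipantSummary


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    one_sided: bool
    degenerate: bool = False  # zero variance of differences


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False  # constant input, rho undefined


@dataclass(frozen=True)
class SplitHalfResult:
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n_used: int
    n_dropped: int
    seed: int
    n_splits: int


@dataclass(frozen=True)
class EffectReport:
    estimate: float
    se: float
    t: float
    p: float
    n_participants: int
    method: str


# ---------------------------------------------------------------------------
# Core tests


def paired_t(
    x: Sequence[float],
    y: Sequence[float],
    direction: Optional[str] = None,
) -> TTestResult:
    """Paired t test on x - y. ``direction`` None gives a two-sided p;
    'greater'/'less' give the stated one-sided tail. With zero variance of
    the differences the p-value degenerates to {0, 1} by the sign of the
    mean (0.5 at exactly zero mean) and the result is flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = x - y
    n = len(d)
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        if direction == "greater":
            p = 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
        elif direction == "less":
            p = 0.5 if mean == 0.0 else (0.0 if mean < 0 else 1.0)
        else:
            p = 1.0 if mean == 0.0 else 0.0
        return TTestResult(t, df, p, direction is not None, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    if direction == "greater":
        p = float(sps.t.sf(t, df))
    elif direction == "less":
        p = float(sps.t.cdf(t, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, direction is not None)


def paired_t_one_sided(
    x: Sequence[float], y: Sequence[float], direction: str = "greater"
) -> TTestResult:
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    return paired_t(x, y, direction)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with tie-aware average ranks, t-approximation
    p-value and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(math.nan, math.nan, math.nan, math.nan, n, degenerate=True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    if n > 3 and abs(rho) < 1.0:
        z = math.atanh(rho)
        half = 1.959963984540054 / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    else:
        ci_low, ci_high = -1.0, 1.0
    return SpearmanResult(rho, p, ci_low, ci_high, n)


# ---------------------------------------------------------------------------
# Split-half reliability


def split_half_reliability(
    outcomes: pd.DataFrame,
    condition: str,
    seed: int,
    min_trials: int = 2,
    n_splits: int = 1,
) -> SplitHalfResult:
    """Randomly split each participant's valid RTs in a condition into two
    halves (odd counts: the surplus trial goes to a random half), average
    each half, and rank-correlate the half means across participants.

    Participants with fewer than ``min_trials`` valid RTs are dropped and
    counted. With ``n_splits`` > 1 the rho is a Fisher-z average across
    independent splits (a smoothed estimate, labeled as such in the report).
    """
    valid = outcomes[(outcomes["condition"] == condition) & outcomes["rt_valid"]]
    rts_by_pid = {
        pid: sub["rt_ms"].to_numpy(dtype=float)
        for pid, sub in valid.groupby("participant_id")
    }
    usable = {p: r for p, r in rts_by_pid.items() if len(r) >= min_trials}
    n_dropped = len(rts_by_pid) - len(usable)
    if len(usable) < 3:
        raise ValueError(
            f"split-half needs >= 3 participants with >= {min_trials} valid "
            f"RTs in {condition}; have {len(usable)}"
        )
    cond_tag = zlib.crc32(condition.encode()) % 2**31
    rng = np.random.default_rng(np.random.SeedSequence([seed, cond_tag]))
    pids = sorted(usable)
    zs = []
    last = None
    for _ in range(n_splits):
        h1, h2 = [], []
        for pid in pids:
            r = usable[pid].copy()
            rng.shuffle(r)
            k = len(r) // 2
            if len(r) % 2 == 1 and rng.random() < 0.5:
                k += 1
            h1.append(r[:k].mean())
            h2.append(r[k:].mean())
        last = spearman_rho(h1, h2)
        zs.append(math.atanh(np.clip(last.rho, -0.999999, 0.999999)))
    if n_splits == 1:
        res = last
        rho, p, ci_low, ci_high = res.rho, res.p, res.ci_low, res.ci_high
    else:
        rho = float(math.tanh(np.mean(zs)))
        n = len(pids)
        t = rho * math.sqrt((n - 2) / max(1e-12, 1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
        half = 1.959963984540054 / math.sqrt(n - 3) if n > 3 else math.inf
        z = math.atanh(rho)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return SplitHalfResult(
        rho=rho,
        p=p,
        ci_low=ci_low,
        ci_high=ci_high,
        n_used=len(pids),
        n_dropped=n_dropped,
        seed=seed,
        n_splits=n_splits,
    )


# ---------------------------------------------------------------------------
# Two-stage (summary statistics) effects


def trial_order_effect(
    outcomes: pd.DataFrame,
    condition: str = GAZE_TRIGGERED,
    method: str = "two_stage",
) -> EffectReport:
    """Change in RT per trial position.

    two_stage: an ordinary least-squares slope of RT on trial number per
    participant (participants with < 2 valid RTs or a single trial position
    are skipped), then a one-sample t test of the slopes against zero.
    mixed: random intercepts for participant, target, and target-within-
    participant via variance components (statsmodels MixedLM).
    """
    valid = outcomes[(outcomes["condition"] == condition) & outcomes["rt_valid"]]
    if method == "mixed":
        return _mixed_effect(valid, "trial_index")
    slopes = []
    for _, sub in valid.groupby("participant_id"):
        x = sub["trial_index"].to_numpy(dtype=float)
        y = sub["rt_ms"].to_numpy(dtype=float)
        if len(x) < 2 or len(np.unique(x)) < 2:
            continue
        slope = np.polyfit(x, y, 1)[0]
        slopes.append(slope)
    if len(slopes) < 3:
        raise ValueError("trial-order effect needs >= 3 participants with >= 2 RTs")
    return _one_sample_effect(np.asarray(slopes), "two_stage")


def _one_sample_effect(values: np.ndarray, method: str) -> EffectReport:
    n = len(values)
    est = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if est == 0.0 else math.copysign(math.inf, est)
        p = 1.0 if est == 0.0 else 0.0
        se = 0.0
    else:
        se = sd / math.sqrt(n)
        t = est / se
        p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return EffectReport(est, se, float(t), p, n, method)


def _mixed_effect(valid: pd.DataFrame, fixed: str) -> EffectReport:
    import statsmodels.formula.api as smf

    df = valid.rename(columns={fixed: "x"}).copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["target_item"] = df["target_item"].astype(str)
    df["g"] = 1
    model = smf.mixedlm(
        "rt_ms ~ x",
        data=df,
        groups="g",
        vc_formula={
            "participant": "0 + C(participant_id)",
            "target": "0 + C(target_item)",
            "target_by_participant": "0 + C(target_item):C(participant_id)",
        },
    )
    fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    est = float(fit.params["x"])
    se = float(fit.bse["x"])
    t = est / se if se > 0 else math.nan
    p = float(fit.pvalues["x"])
    return EffectReport(est, se, t, p, df["participant_id"].nunique(), "mixed")


# ---------------------------------------------------------------------------
# Vocabulary


def parse_known_items(vocab: pd.DataFrame) -> dict[str, set[str]]:
    known: dict[str, set[str]] = {}
    for row in vocab.itertuples(index=False):
        items = str(row.known_items) if not pd.isna(row.known_items) else ""
        known[str(row.participant_id)] = {s for s in items.split(";") if s}
    return known


def word_known_filter_and_effect(
    outcomes: pd.DataFrame,
    vocab: pd.DataFrame,
    config: DesignConfig | None = None,
) -> tuple[pd.DataFrame, EffectReport]:
    """(a) outcomes restricted to trials whose target the participant is
    reported to know; (b) a two-stage estimate of the known-minus-unknown RT
    difference (per-participant mean difference over valid RTs, then a
    one-sample t across participants that contribute both).

    Raises ``ValueError`` listing any reported item labels that are not in
    the stimulus inventory.
    """
    config = config or DesignConfig()
    inventory = set(config.item_names) | set(config.filler_items)
    known = parse_known_items(vocab)
    bad = sorted(
        {it for items in known.values() for it in items if it not in inventory}
    )
    if bad:
        raise ValueError(f"vocabulary reports unknown item labels: {bad}")

    def is_known(row) -> bool:
        return row.target_item in known.get(row.participant_id, set())

    mask = [is_known(r) for r in outcomes.itertuples(index=False)]
    filtered = outcomes[pd.Series(mask, index=outcomes.index)].reset_index(drop=True)

    diffs = []
    valid = outcomes[outcomes["rt_valid"]]
    for pid, sub in valid.groupby("participant_id"):
        k = sub[[t in known.get(str(pid), set()) for t in sub["target_item"]]]
        u = sub[[t not in known.get(str(pid), set()) for t in sub["target_item"]]]
        if len(k) and len(u):
            diffs.append(k["rt_ms"].mean() - u["rt_ms"].mean())
    if len(diffs) < 3:
        effect = EffectReport(math.nan, math.nan, math.nan, math.nan, len(diffs), "two_stage")
    else:
        effect = _one_sample_effect(np.asarray(diffs, dtype=float), "two_stage")
    return filtered, effect


def vocab_correlation(
    summaries: Sequence[ParticipantSummary], vocab: pd.DataFrame
) -> SpearmanResult:
    """Spearman correlation between each participant's cross-condition mean
    RT and their expressive vocabulary score."""
    produced = {
        str(r.participant_id): float(r.cdi_produced) for r in vocab.itertuples(index=False)
    }
    xs, ys = [], []
    for s in summaries:
        means = [
            st.mean_rt_ms for st in s.per_condition.values() if st.mean_rt_ms is not None
        ]
        if means and s.participant_id in produced:
            xs.append(float(np.mean(means)))
            ys.append(produced[s.participant_id])
    return spearman_rho(xs, ys)


# ---------------------------------------------------------------------------
# Report assembly


def _cond_block(summaries: Sequence[ParticipantSummary], cond: str) -> dict:
    ns = [s.per_condition[cond].rt_valid_trials for s in summaries]
    pcts = [
        s.per_condition[cond].pct_valid
        for s in summaries
        if s.per_condition[cond].pct_valid is not None
    ]
    rts = [
        s.per_condition[cond].mean_rt_ms
        for s in summaries
        if s.per_condition[cond].mean_rt_ms is not None
    ]
    return {
        "rt_valid_trials_mean": float(np.mean(ns)) if ns else math.nan,
        "rt_valid_trials_sd": float(np.std(ns, ddof=1)) if len(ns) > 1 else math.nan,
        "rt_valid_trials_range": [int(min(ns)), int(max(ns))] if ns else None,
        "pct_valid_mean": float(np.mean(pcts)) if pcts else math.nan,
        "pct_valid_sd": float(np.std(pcts, ddof=1)) if len(pcts) > 1 else math.nan,
        "mean_rt_ms": float(np.mean(rts)) if rts else math.nan,
        "sd_of_mean_rt_ms": float(np.std(rts, ddof=1)) if len(rts) > 1 else math.nan,
    }


def build_report(
    outcomes: pd.DataFrame,
    summaries: Sequence[ParticipantSummary],
    vocab: Optional[pd.DataFrame],
    seed: int,
    config: DesignConfig | None = None,
) -> dict:
    """Assemble the full comparison report on the *included* participants.

    Sections that cannot be computed (too few participants or trials) carry
    an ``insufficient_n`` marker instead of numbers.
    """
    config = config or DesignConfig()
    included = [s for s in summaries if s.included]
    report: dict = {"n_participants": len(included), "seed": seed}

    for cond in (GAZE_TRIGGERED, ORIGINAL):
        report[cond] = (
            _cond_block(included, cond) if included else {"insufficient_n": True}
        )

    def both(attr: str) -> Optional[tuple[list, list]]:
        g, o = [], []
        for s in included:
            a = getattr(s.per_condition[GAZE_TRIGGERED], attr)
            b = getattr(s.per_condition[ORIGINAL], attr)
            if a is None or b is None:
                continue
            g.append(a)
            o.append(b)
        return (g, o) if len(g) >= 3 else None

    pair = both("pct_valid")
    report["pct_valid_paired_t_one_sided"] = (
        asdict(paired_t_one_sided(*pair, direction="greater"))
        if pair
        else {"insufficient_n": True}
    )
    pair = both("mean_rt_ms")
    report["mean_rt_paired_t_two_sided"] = (
        asdict(paired_t(*pair)) if pair else {"insufficient_n": True}
    )
    report["between_condition_spearman"] = (
        asdict(spearman_rho(*pair)) if pair else {"insufficient_n": True}
    )

    report["split_half"] = {}
    for cond in (GAZE_TRIGGERED, ORIGINAL):
        try:
            report["split_half"][cond] = asdict(
                split_half_reliability(outcomes, cond, seed=seed)
            )
        except ValueError:
            report["split_half"][cond] = {"insufficient_n": True}

    try:
        report["trial_order_effect"] = asdict(trial_order_effect(outcomes))
    except ValueError:
        report["trial_order_effect"] = {"insufficient_n": True}

    if vocab is not None and len(vocab):
        _, effect = word_known_filter_and_effect(outcomes, vocab, config)
        report["word_known_effect"] = (
            asdict(effect)
            if not math.isnan(effect.estimate)
            else {"insufficient_n": True}
        )
        try:
            report["vocab_correlation"] = asdict(vocab_correlation(included, vocab))
        except ValueError:
            report["vocab_correlation"] = {"insufficient_n": True}
    else:
        report["word_known_effect"] = {"insufficient_n": True}
        report["vocab_correlation"] = {"insufficient_n": True}
    report["notes"] = {
        "spearman_ci_method": "Fisher z, se = 1/sqrt(n-3)",
        "mixed_model_approximation": "two-stage summary statistics "
        "(per-participant estimate, one-sample t across participants)",
    }
    return report


def write_report(report: dict, out_json: str | Path, out_md: str | Path | None = None) -> None:
    Path(out_json).write_text(json.dumps(report, indent=2, default=float))
    if out_md is not None:
        Path(out_md).write_text(render_report_md(report))


def render_report_md(report: dict) -> str:
    lines = ["# Looking-while-listening comparison report", ""]
    lines.append(f"Included participants: {report.get('n_participants')}")
    for cond in (GAZE_TRIGGERED, ORIGINAL):
        block = report.get(cond, {})
        lines.append(f"\n## {cond}")
        if block.get("insufficient_n"):
            lines.append("insufficient n")
            continue
        lines.append(
            f"- valid RT trials: mean {block['rt_valid_trials_mean']:.2f} "
            f"(SD {block['rt_valid_trials_sd']:.2f}, range {block['rt_valid_trials_range']})"
        )
        lines.append(
            f"- % valid of completed: {block['pct_valid_mean']:.2f} "
            f"(SD {block['pct_valid_sd']:.2f})"
        )
        lines.append(f"- mean RT: {block['mean_rt_ms']:.1f} ms")
    for key in (
        "pct_valid_paired_t_one_sided",
        "mean_rt_paired_t_two_sided",
        "between_condition_spearman",
        "trial_order_effect",
        "word_known_effect",
        "vocab_correlation",
    ):
        lines.append(f"\n## {key}")
        lines.append("```json\n" + json.dumps(report.get(key), indent=2, default=float) + "\n```")
    lines.append("\n## split_half")
    lines.append("```json\n" + json.dumps(report.get("split_half"), indent=2, default=float) + "\n```")
    return "\n".join(lines) + "\n"
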