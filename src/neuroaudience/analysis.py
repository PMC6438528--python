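"""Study-level orchestration: from per-episode minute data and timelines to
the segment table, the headline segment-level statistics, episode-level
ANOVAs, and the segment-vs-break comparisons.

These entry points operate on the minute-dataset layout (pre-processed EEG
minute scores plus raw audience counts per episode) so they apply equally
to the deposited study data and to synthetic studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audience import (
    AudienceSeries,
    EpisodeTimeline,
    build_segment_table,
    trim_omissions,
    zscore_episode,
)
from .inference import (
    AnovaResult,
    TTestResult,
    median_split_models,
    oneway_anova_bonferroni,
    partial_correlation,
    pearson,
    stepwise_regression,
    two_sample_ttest,
)

__all__ = [
    "segment_table_from_minute_data",
    "headline_statistics",
    "episode_anova",
    "segment_break_ttest",
    "results_to_frame",
]

_X_COLS = ["d_attention", "d_motivation", "d_memory"]


def segment_table_from_minute_data(
    dataset: dict[str, dict], timelines: dict[str, EpisodeTimeline]
) -> pd.DataFrame:
    """Segment table from a minute dataset (as returned by read_minute_dataset)."""
    eeg_minutes = {ep: d["scores"] for ep, d in dataset.items()}
    audience = {ep: d["audience"] for ep, d in dataset.items()}
    return build_segment_table(eeg_minutes, audience, timelines)


def headline_statistics(table: pd.DataFrame) -> dict:
    """The segment-level inference battery on a segment table.

    Returns named results: single-predictor correlations of the composite
    score with each audience variable, zero-order correlations of the
    individual scores, the Twitter-viewership correlation and its partial
    correlation controlling the composite score, stepwise models for both
    outcomes, and median-split stepwise models.
    """
    out: dict = {"n_segments": len(table)}
    for outcome in ("twitter", "viewership"):
        out[f"composite_{outcome}"] = pearson(table["d_composite"], table[f"d_{outcome}"])
        for score in ("attention", "motivation", "memory"):
            out[f"{score}_{outcome}"] = pearson(table[f"d_{score}"], table[f"d_{outcome}"])
        out[f"stepwise_{outcome}"] = stepwise_regression(table[_X_COLS], table[f"d_{outcome}"])
        out[f"median_split_{outcome}"] = median_split_models(
            table, split_var=f"d_{outcome}", y_var=f"d_{outcome}", x_vars=_X_COLS
        )
    out["twitter_viewership"] = pearson(table["d_twitter"], table["d_viewership"])
    out["twitter_viewership_partial"] = partial_correlation(
        table["d_twitter"], table["d_viewership"], table["d_composite"],
        control_name="d_composite",
    )
    return out


def episode_anova(
    dataset: dict[str, dict],
    timelines: dict[str, EpisodeTimeline],
    variable: str,
    transform: str | None = "sqrt",
) -> AnovaResult:
    """One-way ANOVA across episodes on minute values (omissions trimmed).

    Audience variables ("twitter", "viewership") are raw counts, square-root
    normalized by default; EEG score columns are already on the bounded
    10-point scale and should be passed with ``transform=None``.
    """
    groups = {}
    for ep_id, d in dataset.items():
        tl = timelines[ep_id]
        if variable in ("twitter", "viewership"):
            trimmed = trim_omissions(d["audience"], tl)
            groups[ep_id] = trimmed.variable(variable)
        else:
            scores = d["scores"]
            keep = (scores["minute"] >= tl.omit_start) & (
                scores["minute"] < tl.n_minutes - tl.omit_end
            )
            groups[ep_id] = scores.loc[keep, variable].to_numpy(dtype=float)
    return oneway_anova_bonferroni(groups, transform=transform)


def _block_level_means(
    series: AudienceSeries, timeline: EpisodeTimeline, variable: str
) -> tuple[list[float], list[float]]:
    """Per-segment and per-break means of trimmed, z-scored minute values."""
    prepared = zscore_episode(trim_omissions(series, timeline), variable)
    v = prepared.variable(variable)
    minutes = prepared.minutes
    seg_means, brk_means = [], []
    for kind, start, stop in timeline.blocks:
        sel = (minutes >= start) & (minutes < stop)
        vals = v[sel]
        vals = vals[np.isfinite(vals)]
        if not vals.size:
            continue
        (seg_means if kind == "segment" else brk_means).append(float(vals.mean()))
    return seg_means, brk_means


def segment_break_ttest(
    dataset: dict[str, dict],
    timelines: dict[str, EpisodeTimeline],
    variable: str,
    exclude_segments: set[tuple[str, int]] = frozenset(),
) -> TTestResult:
    """Pooled t-test of program-segment vs commercial-break minute levels.

    Units are block means of within-episode z-scored values (one mean per
    segment, one per break, across episodes).  ``exclude_segments`` drops
    named ``(episode_id, segment_index)`` pairs, e.g. a segment dominated by
    promotional tweets.
    """
    seg_all, brk_all = [], []
    for ep_id, d in dataset.items():
        tl = timelines[ep_id]
        seg, brk = _block_level_means(d["audience"], tl, variable)
        seg = [m for i, m in enumerate(seg) if (ep_id, i) not in exclude_segments]
        seg_all.extend(seg)
        brk_all.extend(brk)
    return two_sample_ttest(seg_all, brk_all)


def results_to_frame(stats: dict) -> pd.DataFrame:
    """Flatten headline results into a regression-table-style DataFrame."""
    rows = []
    for key, res in stats.items():
        if hasattr(res, "r"):
            rows.append(
                {"analysis": key, "model": "LR", "r": res.r, "R2": res.r2,
                 "p": res.p, "n": res.n}
            )
        elif hasattr(res, "r_partial"):
            rows.append(
                {"analysis": key, "model": "partial", "r": res.r_partial,
                 "R2": res.r_partial**2, "p": res.p, "n": res.n}
            )
        elif hasattr(res, "entered"):
            rows.append(
                {"analysis": key, "model": "SWMR",
                 "predictors": " + ".join(res.entered) or "-",
                 "R2": res.r2, "adj_R2": res.adj_r2, "p": res.model_p}
            )
            for name in res.entered:
                rows.append(
                    {"analysis": key, "model": "SWMR beta", "predictors": name,
                     "beta_std": res.std_betas[name], "p": res.beta_pvalues[name]}
                )
    return pd.DataFrame(rows)
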