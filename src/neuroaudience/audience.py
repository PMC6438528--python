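"""Minute-level audience series (Twitter volume, TV viewership) and their
reduction to per-segment rate-of-change values.

The preparation order is fixed, and enforced through stage tags:

    trim omissions -> z-score within episode -> (twitter: lag alignment)
    -> (viewership: break drop-off detrending) -> minute-to-minute diffs
    -> per-segment pooling

Segment pooling follows the commercial-break reallocation rules: a
segment's Twitter mean also pools the diffs led by the first two minutes of
the following break (delayed tweeting), and its viewership mean pools the
diff led by the first break minute (delayed channel switching).  EEG score
diffs pool only diffs interior to the segment, because the EEG session ran
without commercials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recording import (
    DegenerateSeriesError,
    EmptyInputError,
    InvalidTimelineError,
    NeuroaudienceError,
)

__all__ = [
    "EpisodeTimeline",
    "AudienceSeries",
    "PipelineOrderError",
    "make_blocks_from_labels",
    "label_transition_minutes",
    "zscore_episode",
    "trim_omissions",
    "trim_minute_frame",
    "apply_twitter_lag",
    "detrend_viewership",
    "diff_audience",
    "segment_twitter",
    "segment_viewership",
    "segment_eeg",
    "optimize_twitter_lag",
    "build_segment_table",
]


class PipelineOrderError(NeuroaudienceError):
    """Raised when preparation stages are applied out of order."""


logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpisodeTimeline:
    """Minute-indexed program/break structure for one episode.

    ``blocks`` is an ordered list of ``(kind, start_minute, stop_minute)``
    half-open minute ranges with ``kind`` in {"segment", "break"}, contiguous
    from minute 0 and alternating.
    """

    episode_id: str
    blocks: tuple[tuple[str, int, int], ...]
    omit_start: int = 0
    omit_end: int = 0
    twitter_lag: int = 0

    def __post_init__(self) -> None:
        if self.omit_start < 0 or self.omit_end < 0:
            raise InvalidTimelineError("omission windows must be non-negative")
        if self.twitter_lag not in (0, 1, 2):
            raise InvalidTimelineError(f"twitter_lag must be in {{0,1,2}}, got {self.twitter_lag}")
        pos = 0
        prev_kind = None
        for kind, start, stop in self.blocks:
            if kind not in ("segment", "break"):
                raise InvalidTimelineError(f"unknown block kind {kind!r}")
            if start != pos or stop <= start:
                raise InvalidTimelineError("blocks must be contiguous from minute 0")
            if kind == prev_kind:
                raise InvalidTimelineError("segments and breaks must alternate")
            pos, prev_kind = stop, kind

    @property
    def n_minutes(self) -> int:
        return self.blocks[-1][2]

    @property
    def segments(self) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.blocks if k == "segment"]

    @property
    def breaks(self) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.blocks if k == "break"]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def minute_kinds(self) -> np.ndarray:
        """Array of "segment"/"break" labels, one per minute."""
        out = np.empty(self.n_minutes, dtype=object)
        for kind, start, stop in self.blocks:
            out[start:stop] = kind
        return out

    def following_break(self, segment_index: int) -> tuple[int, int] | None:
        """Minute range of the break right after the given segment, if any."""
        seg_end = self.segments[segment_index][1]
        for start, stop in self.breaks:
            if start == seg_end:
                return (start, stop)
        return None

    def program_minutes(self) -> np.ndarray:
        return np.concatenate([np.arange(s, e) for s, e in self.segments])


def make_blocks_from_labels(kinds: list[str]) -> tuple[tuple[str, int, int], ...]:
    """Coalesce a per-minute kind list into contiguous timeline blocks."""
    blocks: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            blocks.append((kinds[start], start, i))
            start = i
    return tuple(blocks)


def label_transition_minutes(
    boundaries_s: list[tuple[str, float, float]]
) -> list[str]:
    """Label each minute "segment"/"break" from second-resolution content spans.

    A transition minute counts as program only if program content occupies
    strictly more than 30 s of it; exactly 30 s of program is a break minute.
    """
    if not boundaries_s:
        raise InvalidTimelineError("no content spans supplied")
    pos = 0.0
    for kind, start, stop in boundaries_s:
        if abs(start - pos) > 1e-9 or stop <= start:
            raise InvalidTimelineError("content spans must be contiguous and non-overlapping")
        pos = stop
    total_s = boundaries_s[-1][2]
    n_minutes = int(total_s // 60)
    labels = []
    for m in range(n_minutes):
        m0, m1 = m * 60.0, (m + 1) * 60.0
        program_s = sum(
            max(0.0, min(stop, m1) - max(start, m0))
            for kind, start, stop in boundaries_s
            if kind == "segment"
        )
        labels.append("segment" if program_s > 30.0 else "break")
    return labels


@dataclass
class AudienceSeries:
    """Minute-level Twitter volume and TV viewership for one episode.

    ``minutes`` are absolute broadcast-minute indices (0-based from episode
    onset) and survive trimming unchanged.  Stage tags record the applied
    preparation steps per variable and enforce the pipeline order.
    """

    episode_id: str
    minutes: np.ndarray
    twitter: np.ndarray
    viewership: np.ndarray
    stages: dict = field(default_factory=lambda: {"twitter": "raw", "viewership": "raw"})

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=int)
        self.twitter = np.asarray(self.twitter, dtype=float)
        self.viewership = np.asarray(self.viewership, dtype=float)
        if not (len(self.minutes) == len(self.twitter) == len(self.viewership)):
            raise EmptyInputError("minute/twitter/viewership lengths must match")
        for name in ("twitter", "viewership"):
            if self.stages[name] == "raw":
                v = getattr(self, name)
                if np.nanmin(v, initial=np.inf) < 0:
                    raise NeuroaudienceError(f"raw {name} counts must be non-negative")

    def variable(self, name: str) -> np.ndarray:
        if name not in ("twitter", "viewership"):
            raise NeuroaudienceError(f"unknown audience variable {name!r}")
        return getattr(self, name)

    def with_variable(self, name: str, values: np.ndarray, stage: str) -> "AudienceSeries":
        new = replace(self, stages=dict(self.stages))
        setattr(new, name, np.asarray(values, dtype=float))
        new.stages[name] = stage
        return new


def trim_omissions(series: AudienceSeries, timeline: EpisodeTimeline) -> AudienceSeries:
    """Drop the first ``omit_start`` and last ``omit_end`` minutes.

    Must run before z-scoring so that the declared outlier minutes do not
    influence the normalization.
    """
    for var in ("twitter", "viewership"):
        if series.stages[var] != "raw":
            raise PipelineOrderError("omission trimming must precede z-scoring")
    n = len(series.minutes)
    if timeline.omit_start + timeline.omit_end >= n:
        raise InvalidTimelineError("omission windows cover the entire series")
    sl = slice(timeline.omit_start, n - timeline.omit_end or None)
    out = AudienceSeries(
        episode_id=series.episode_id,
        minutes=series.minutes[sl],
        twitter=series.twitter[sl],
        viewership=series.viewership[sl],
        stages=dict(series.stages),
    )
    out.stages = {k: "trimmed" for k in out.stages}
    logger.info(
        "trim_omissions[%s]: dropped %d start + %d end minutes, %d retained",
        series.episode_id, timeline.omit_start, timeline.omit_end, len(out.minutes),
    )
    return out


def trim_minute_frame(frame: pd.DataFrame, timeline: EpisodeTimeline) -> pd.DataFrame:
    """Apply the same omission windows to a minute-score DataFrame."""
    keep = (frame["minute"] >= timeline.omit_start) & (
        frame["minute"] < timeline.n_minutes - timeline.omit_end
    )
    return frame.loc[keep].reset_index(drop=True)


def zscore_episode(series: AudienceSeries, variable: str) -> AudienceSeries:
    """Within-episode z-transform of one audience variable (population SD)."""
    if series.stages[variable] != "trimmed":
        raise PipelineOrderError(
            f"z-scoring requires the trimmed stage, got {series.stages[variable]!r}"
        )
    v = series.variable(variable)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise DegenerateSeriesError("need at least 2 minutes to z-score")
    sd = v[finite].std()
    if sd == 0:
        raise DegenerateSeriesError(f"zero variance in {variable}")
    return series.with_variable(variable, (v - v[finite].mean()) / sd, "zscored")


def apply_twitter_lag(series: AudienceSeries, lag: int) -> AudienceSeries:
    """Align tweets with on-screen content: value at minute t := value at t+lag.

    Trailing minutes with no source data become NaN and are dropped from
    segment pooling.  Lag is a pure re-indexing, applied after z-scoring.
    """
    if lag < 0:
        raise InvalidTimelineError(f"twitter lag must be non-negative, got {lag}")
    if series.stages["twitter"] != "zscored":
        raise PipelineOrderError("lag alignment requires the z-scored stage")
    v = series.twitter
    out = np.full_like(v, np.nan)
    if lag == 0:
        out[:] = v
    else:
        out[:-lag] = v[lag:]
    return series.with_variable("twitter", out, "lagged")


def detrend_viewership(series: AudienceSeries, timeline: EpisodeTimeline) -> AudienceSeries:
    """Remove break-induced audience drop-off from following segments.

    For each break, the within-break change d = value(last break minute) -
    value(first break minute) is subtracted from every later minute
    (cumulatively across breaks), so consecutive segments are continuous when
    the only change across a break is the drop-off itself.
    """
    if series.stages["viewership"] != "zscored":
        raise PipelineOrderError("detrending requires the z-scored stage")
    v = series.viewership.copy()
    minutes = series.minutes
    correction = np.zeros_like(v)
    for b_start, b_stop in timeline.breaks:
        in_break = np.where((minutes >= b_start) & (minutes < b_stop))[0]
        if len(in_break) < 2:
            continue  # single-minute break: no internal change to remove
        d = v[in_break[-1]] - v[in_break[0]]
        correction[minutes >= b_stop] -= d
    return series.with_variable("viewership", v + correction, "detrended")


def diff_audience(series: AudienceSeries, variable: str) -> tuple[np.ndarray, np.ndarray]:
    """Minute-to-minute diffs of a prepared variable.

    Returns ``(diff_values, leading_minutes)``; the diff at position i spans
    ``leading_minutes[i] -> leading_minutes[i] + 1``.  Diffs across
    non-adjacent retained minutes are not formed.
    """
    allowed = {"twitter": ("zscored", "lagged"), "viewership": ("zscored", "detrended")}
    if series.stages[variable] not in allowed[variable]:
        raise PipelineOrderError(
            f"diffs require a z-scored/aligned series, got {series.stages[variable]!r}"
        )
    v = series.variable(variable)
    m = series.minutes
    adjacent = np.diff(m) == 1
    return (v[1:] - v[:-1])[adjacent], m[:-1][adjacent]


def _pool_segment_diffs(
    diffs: np.ndarray,
    leading_minutes: np.ndarray,
    timeline: EpisodeTimeline,
    include_break_minutes: int,
) -> list[float]:
    """Per-segment mean diff, pooling diffs led by the first few break minutes."""
    means: list[float] = []
    for i, (s_start, s_stop) in enumerate(timeline.segments):
        pool_minutes = set(range(s_start, s_stop))
        brk = timeline.following_break(i)
        if brk is not None:
            b_start, b_stop = brk
            pool_minutes |= set(range(b_start, min(b_start + include_break_minutes, b_stop)))
        sel = np.array([m in pool_minutes for m in leading_minutes], dtype=bool)
        vals = diffs[sel]
        vals = vals[np.isfinite(vals)]
        means.append(float(vals.mean()) if vals.size else np.nan)
    return means


def segment_twitter(series: AudienceSeries, timeline: EpisodeTimeline) -> list[float]:
    """Per-segment mean Twitter diff, pooling the first two break minutes."""
    diffs, minutes = diff_audience(series, "twitter")
    return _pool_segment_diffs(diffs, minutes, timeline, include_break_minutes=2)


def segment_viewership(series: AudienceSeries, timeline: EpisodeTimeline) -> list[float]:
    """Per-segment mean viewership diff, pooling the first break minute."""
    diffs, minutes = diff_audience(series, "viewership")
    return _pool_segment_diffs(diffs, minutes, timeline, include_break_minutes=1)


def optimize_twitter_lag(
    series: AudienceSeries,
    timeline: EpisodeTimeline,
    eeg_segment_diffs: np.ndarray,
    candidate_lags: tuple[int, ...] = (0, 1, 2),
) -> int:
    """Grid-search extension: pick the lag maximizing |segment correlation|.

    The core pipeline consumes the lag as a supplied per-episode parameter;
    this helper is an optional extension that scores each candidate lag by
    the absolute Pearson correlation between the lag-aligned per-segment
    Twitter diff means and a reference EEG segment-diff vector.
    """
    if series.stages["twitter"] != "zscored":
        raise PipelineOrderError("lag search requires the z-scored stage")
    ref = np.asarray(eeg_segment_diffs, dtype=float)
    best_lag, best_score = candidate_lags[0], -np.inf
    for lag in candidate_lags:
        means = np.asarray(segment_twitter(apply_twitter_lag(series, lag), timeline))
        keep = np.isfinite(means) & np.isfinite(ref)
        if keep.sum() < 3 or means[keep].std() == 0 or ref[keep].std() == 0:
            continue
        score = abs(np.corrcoef(means[keep], ref[keep])[0, 1])
        if score > best_score:
            best_lag, best_score = lag, score
    return best_lag


def segment_eeg(minute_frame: pd.DataFrame, timeline: EpisodeTimeline) -> pd.DataFrame:
    """Per-segment mean diffs of the four EEG scores.

    ``minute_frame`` holds broadcast-minute-indexed scores (NaN in break
    minutes).  Only diffs whose two endpoint minutes lie in the same segment
    are pooled: the EEG session ran without commercials, so the diff
    spanning a break boundary compares non-adjacent broadcast content.
    """
    minutes = minute_frame["minute"].to_numpy()
    rows = []
    for i, (s_start, s_stop) in enumerate(timeline.segments):
        row: dict = {"episode_id": timeline.episode_id, "segment_id": i}
        sel = (minutes >= s_start) & (minutes < s_stop)
        for metric in ("motivation", "attention", "memory", "composite"):
            v = minute_frame.loc[sel, metric].to_numpy()
            d = v[1:] - v[:-1] if len(v) >= 2 else np.array([])
            d = d[np.isfinite(d)]
            row[f"d_{metric}"] = float(d.mean()) if d.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_segment_table(
    eeg_minutes: dict[str, pd.DataFrame],
    audience: dict[str, AudienceSeries],
    timelines: dict[str, EpisodeTimeline],
) -> pd.DataFrame:
    """Assemble the per-segment analysis table across episodes.

    Inputs are broadcast-minute-aligned, *untrimmed* per-episode frames;
    this function applies the full preparation order per episode and keeps
    only segments with a complete set of cells.  Raises when no complete
    row survives.
    """
    rows = []
    for ep_id, timeline in timelines.items():
        prepared = trim_omissions(audience[ep_id], timeline)
        prepared = zscore_episode(prepared, "twitter")
        prepared = zscore_episode(prepared, "viewership")
        prepared = apply_twitter_lag(prepared, timeline.twitter_lag)
        prepared = detrend_viewership(prepared, timeline)
        tw = segment_twitter(prepared, timeline)
        vw = segment_viewership(prepared, timeline)
        eeg = segment_eeg(trim_minute_frame(eeg_minutes[ep_id], timeline), timeline)
        eeg = eeg.assign(d_twitter=tw, d_viewership=vw)
        rows.append(eeg)
    table = pd.concat(rows, ignore_index=True)
    value_cols = [c for c in table.columns if c.startswith("d_")]
    complete = table.dropna(subset=value_cols).reset_index(drop=True)
    n_dropped = len(table) - len(complete)
    if n_dropped:
        excluded = table.loc[table[value_cols].isna().any(axis=1),
                             ["episode_id", "segment_id"]]
        logger.info(
            "build_segment_table: excluded %d incomplete segments: %s",
            n_dropped,
            "; ".join(f"{r.episode_id}#{r.segment_id}" for r in excluded.itertuples()),
        )
    if complete.empty:
        raise EmptyInputError("no segment has a complete set of variables")
    logger.info("build_segment_table: %d segments retained", len(complete))
    return complete
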