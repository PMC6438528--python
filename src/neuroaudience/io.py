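"""File formats: minute-level datasets (CSV/XLSX, one sheet or file per
episode), delimited-text EEG matrices with YAML sidecars, EDF reading,
timeline configs, and ground-truth JSON.

The minute-dataset layout mirrors the study's deposited spreadsheet: one
sheet (or CSV file) per episode with minute-by-minute raw Twitter volume,
raw TV viewership and the pre-processed EEG metrics, with ad breaks and
missing values indicated in a Notes column.  Header synonyms are tolerated
through a configurable column map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audience import AudienceSeries, EpisodeTimeline, make_blocks_from_labels
from .recording import ConfigurationError, EEGRecording, MissingChannelError

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_minute_dataset",
    "write_minute_dataset",
    "minute_frame_from_episode",
    "timeline_from_notes",
    "read_eeg_text",
    "write_eeg_text",
    "read_eeg_edf",
    "read_timeline_config",
    "write_timeline_config",
    "write_ground_truth",
]

#: canonical column -> accepted header synonyms (case-insensitive)
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "minute": ("minute", "min", "time (min)", "time"),
    "twitter_raw": ("twitter_raw", "twitter volume", "twitter", "tweets", "twitter volume (raw)"),
    "viewership_raw": ("viewership_raw", "tv viewership", "viewership", "viewers",
                       "tv viewership (raw)"),
    "attention": ("attention", "attention score", "alpha/theta", "alpha/theta power"),
    "motivation": ("motivation", "motivation score", "alpha/beta asym.", "asymmetry",
                   "alpha/beta asymmetry"),
    "memory": ("memory", "memory score", "theta/gamma", "theta/gamma power"),
    "composite": ("composite", "composite eeg", "composite score", "composite eeg score"),
    "notes": ("notes", "note", "flags"),
}

_BREAK_TOKENS = ("ad break", "break", "commercial")
_MISSING_TOKENS = ("missing", "n/a", "na")


def _normalize_columns(df: pd.DataFrame, column_map: dict) -> pd.DataFrame:
    renames = {}
    lower = {str(c).strip().lower(): c for c in df.columns}
    for canonical, synonyms in column_map.items():
        for syn in synonyms:
            if syn in lower:
                renames[lower[syn]] = canonical
                break
    out = df.rename(columns=renames)
    required = ("minute", "twitter_raw", "viewership_raw")
    missing = [c for c in required if c not in out.columns]
    if missing:
        raise ConfigurationError(
            f"minute dataset is missing required columns {missing}; found {list(df.columns)}"
        )
    return out


def _parse_episode_frame(df: pd.DataFrame, episode_id: str, column_map: dict) -> dict:
    df = _normalize_columns(df, column_map)
    notes = df["notes"].fillna("").astype(str).str.lower() if "notes" in df else pd.Series(
        [""] * len(df)
    )
    is_break = notes.apply(lambda s: any(tok in s for tok in _BREAK_TOKENS))
    is_missing = notes.apply(
        lambda s: any(tok in s for tok in _MISSING_TOKENS) and not any(
            tok in s for tok in _BREAK_TOKENS
        )
    )
    numeric = {}
    for col in ("minute", "twitter_raw", "viewership_raw",
                "attention", "motivation", "memory", "composite"):
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ConfigurationError(
                f"episode {episode_id!r}: malformed numeric cell in column {col!r}, "
                f"row {row} (value {df[col][row]!r})"
            )
        numeric[col] = parsed.to_numpy(dtype=float)
    minutes = numeric["minute"].astype(int)
    audience = AudienceSeries(
        episode_id=episode_id,
        minutes=minutes,
        twitter=np.where(is_missing, np.nan, numeric["twitter_raw"]),
        viewership=np.where(is_missing, np.nan, numeric["viewership_raw"]),
    )
    score_cols = {c: numeric[c] for c in ("attention", "motivation", "memory", "composite")
                  if c in numeric}
    scores = pd.DataFrame({"episode_id": episode_id, "minute": minutes, **score_cols})
    kinds = ["break" if b else "segment" for b in is_break]
    return {"audience": audience, "scores": scores, "minute_kinds": kinds}


def read_minute_dataset(
    path: str | Path, column_map: dict | None = None
) -> dict[str, dict]:
    """Read a minute-level dataset (XLSX with one sheet per episode, a single
    CSV, or a directory of per-episode CSVs).

    Returns ``{episode_id: {"audience": AudienceSeries, "scores": DataFrame,
    "minute_kinds": [...]}}``.
    """
    path = Path(path)
    column_map = column_map or DEFAULT_COLUMN_MAP
    out: dict[str, dict] = {}
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ConfigurationError(f"no per-episode CSV files in {path}")
        for f in files:
            out[f.stem] = _parse_episode_frame(pd.read_csv(f), f.stem, column_map)
    elif path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        for name, df in sheets.items():
            out[str(name)] = _parse_episode_frame(df, str(name), column_map)
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "episode_id" in df.columns:
            for ep, sub in df.groupby("episode_id"):
                out[str(ep)] = _parse_episode_frame(sub, str(ep), column_map)
        else:
            out[path.stem] = _parse_episode_frame(df, path.stem, column_map)
    else:
        raise ConfigurationError(f"unsupported minute-dataset format: {path}")
    return out


def minute_frame_from_episode(
    audience: AudienceSeries,
    scores: pd.DataFrame | None,
    minute_kinds: list[str],
) -> pd.DataFrame:
    """Combine one episode's series into the writable sheet layout."""
    notes = ["ad break" if k == "break" else "" for k in minute_kinds]
    frame = pd.DataFrame(
        {
            "minute": audience.minutes,
            "twitter_raw": audience.twitter,
            "viewership_raw": audience.viewership,
        }
    )
    if scores is not None:
        frame = frame.merge(
            scores[["minute", "attention", "motivation", "memory", "composite"]],
            on="minute",
            how="left",
        )
    frame["notes"] = notes[: len(frame)]
    return frame


def write_minute_dataset(
    path: str | Path,
    episodes: dict[str, pd.DataFrame],
    fmt: str = "csv",
) -> None:
    """Write per-episode minute frames as a CSV directory or an XLSX workbook."""
    path = Path(path)
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for ep_id, frame in episodes.items():
            frame.to_csv(path / f"{ep_id}.csv", index=False)
    elif fmt == "xlsx":
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for ep_id, frame in episodes.items():
                frame.to_excel(writer, sheet_name=ep_id[:31], index=False)
    else:
        raise ConfigurationError(f"unsupported format {fmt!r}")


def timeline_from_notes(
    episode_id: str,
    minute_kinds: list[str],
    omit_start: int = 0,
    omit_end: int = 0,
    twitter_lag: int = 0,
) -> EpisodeTimeline:
    """Build a timeline from per-minute break annotations plus prep params."""
    return EpisodeTimeline(
        episode_id=episode_id,
        blocks=make_blocks_from_labels(minute_kinds),
        omit_start=omit_start,
        omit_end=omit_end,
        twitter_lag=twitter_lag,
    )


# ---------------------------------------------------------------------------
# EEG files


def write_eeg_text(path: str | Path, rec: EEGRecording) -> None:
    """Delimited-text matrix (header row of channel labels) + YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(rec.channel_labels)
    np.savetxt(path, rec.data.T, fmt="%.6g", delimiter="\t", header=header, comments="")
    sidecar = {
        "sampling_rate": float(rec.sampling_rate),
        "baseline_window_ms": [float(v) for v in rec.baseline_window_ms],
        "episode_onset_ms": float(rec.episode_onset_ms),
        "participant_id": rec.participant_id,
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_eeg_text(path: str | Path) -> EEGRecording:
    """Read a delimited-text EEG matrix and its YAML sidecar."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".yaml")
    if not sidecar_path.exists():
        raise ConfigurationError(
            f"missing sidecar {sidecar_path.name}: sampling rate and markers are required"
        )
    sidecar = yaml.safe_load(sidecar_path.read_text())
    for key in ("sampling_rate", "baseline_window_ms", "episode_onset_ms"):
        if key not in sidecar:
            raise ConfigurationError(f"sidecar missing required key {key!r}")
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
    data = np.loadtxt(path, skiprows=1, delimiter="\t").T
    if data.ndim == 1:
        data = data[None, :]
    return EEGRecording(
        data=data,
        sampling_rate=float(sidecar["sampling_rate"]),
        channel_labels=labels,
        baseline_window_ms=tuple(sidecar["baseline_window_ms"]),
        episode_onset_ms=float(sidecar["episode_onset_ms"]),
        participant_id=str(sidecar.get("participant_id", "p0")),
    )


def read_eeg_edf(
    path: str | Path,
    baseline_window_ms: tuple[float, float],
    episode_onset_ms: float,
    required_channels: tuple[str, ...] = (),
) -> EEGRecording:
    """Read an EDF recording (via mne) into an EEGRecording."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    missing = [c for c in required_channels if c not in labels]
    if missing:
        raise MissingChannelError(f"EDF file lacks required ROI channels: {missing}")
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        baseline_window_ms=baseline_window_ms,
        episode_onset_ms=episode_onset_ms,
    )


# ---------------------------------------------------------------------------
# Timeline configs and ground truth


def write_timeline_config(path: str | Path, timelines: dict[str, EpisodeTimeline]) -> None:
    payload = {
        ep_id: {
            "blocks": [[k, int(s), int(e)] for k, s, e in tl.blocks],
            "omit_start": tl.omit_start,
            "omit_end": tl.omit_end,
            "twitter_lag": tl.twitter_lag,
        }
        for ep_id, tl in timelines.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_timeline_config(path: str | Path) -> dict[str, EpisodeTimeline]:
    payload = yaml.safe_load(Path(path).read_text())
    out = {}
    for ep_id, spec in payload.items():
        out[str(ep_id)] = EpisodeTimeline(
            episode_id=str(ep_id),
            blocks=tuple((str(k), int(s), int(e)) for k, s, e in spec["blocks"]),
            omit_start=int(spec.get("omit_start", 0)),
            omit_end=int(spec.get("omit_end", 0)),
            twitter_lag=int(spec.get("twitter_lag", 0)),
        )
    return out


def write_ground_truth(path: str | Path, study) -> None:
    """Serialize a synthetic study's ground truth for recovery scoring."""
    from dataclasses import asdict

    payload = {
        "seed": study.seed,
        "coupling": asdict(study.coupling),
        "latents": {
            ep: {k: v.tolist() for k, v in lat.traces.items()}
            for ep, lat in study.latents.items()
        },
        "eeg_dropped_segments": study.eeg_dropped_segments,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
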