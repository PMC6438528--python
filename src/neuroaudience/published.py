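"""Loading the deposited nine-episode broadcast study.

The deposited workbook (one sheet per episode: minute-by-minute raw Twitter
volume, raw TV viewership, pre-processed EEG metrics, ad breaks and missing
values flagged in a Notes column) carries the break structure; the
per-episode omission windows and Twitter lags ship with the package as
configuration data (``data/published_prep.yaml``).  Together they are enough
to rebuild the study's 49-segment analysis table.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import yaml

from .audience import EpisodeTimeline
from .io import read_minute_dataset, timeline_from_notes
from .recording import ConfigurationError

__all__ = ["published_prep_params", "load_published_study"]


def _slug(name: str) -> str:
    s = re.sub(r"[^a-z0-9]+", "_", str(name).strip().lower()).strip("_")
    return re.sub(r"\bepisode\b", "ep", s)


def published_prep_params() -> dict[str, dict]:
    """Per-episode omission windows and Twitter lags, keyed by episode slug."""
    with resources.files("neuroaudience").joinpath(
        "data", "published_prep.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def load_published_study(path: str | Path) -> tuple[dict, dict[str, EpisodeTimeline]]:
    """Read the deposited minute dataset and attach the published timelines.

    ``path`` is the workbook (XLSX) or a directory of per-episode CSVs;
    sheet/file names are matched to the published per-episode parameters by
    normalized name.  Returns ``(dataset, timelines)`` ready for
    :func:`neuroaudience.analysis.segment_table_from_minute_data`.
    """
    dataset = read_minute_dataset(path)
    prep = published_prep_params()
    timelines: dict[str, EpisodeTimeline] = {}
    for ep_id, d in dataset.items():
        slug = _slug(ep_id)
        match = None
        for key in prep:
            if key == slug or key in slug or slug in key:
                match = key
                break
        if match is None:
            raise ConfigurationError(
                f"episode {ep_id!r} does not match any published episode; "
                f"known: {sorted(prep)}"
            )
        p = prep[match]
        timelines[ep_id] = timeline_from_notes(
            ep_id,
            d["minute_kinds"],
            omit_start=int(p["omit_start"]),
            omit_end=int(p["omit_end"]),
            twitter_lag=int(p["twitter_lag"]),
        )
    return dataset, timelines
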