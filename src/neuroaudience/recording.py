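"""Domain containers for cleaned EEG recordings, frequency bands, and the
fronto-central region of interest.

The analyses in this package operate on a fixed 15-electrode fronto-central
ROI from the 10-20 system (6 left, 3 midline, 6 right sites) and four
canonical frequency bands: theta (4-8 Hz), alpha (8-12 Hz), beta (13-30 Hz)
and gamma (31-55 Hz).  Band membership uses half-open intervals
``f_lo <= f < f_hi`` so the four bands partition the spectrum without a
shared 8 Hz edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NeuroaudienceError(Exception):
    """Base class for all package errors."""


class InvalidBandError(NeuroaudienceError):
    pass


class MissingChannelError(NeuroaudienceError):
    pass


class EmptyInputError(NeuroaudienceError):
    pass


class DegenerateSeriesError(NeuroaudienceError):
    pass


class AlignmentError(NeuroaudienceError):
    pass


class ConfigurationError(NeuroaudienceError):
    pass


class InvalidTimelineError(NeuroaudienceError):
    pass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open in frequency: ``f_lo <= f < f_hi``."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi})"
            )

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.f_hi > sampling_rate / 2:
            raise InvalidBandError(
                f"band {self.name!r} upper edge {self.f_hi} Hz exceeds Nyquist "
                f"({sampling_rate / 2} Hz)"
            )


#: Canonical band set: theta, alpha, beta, gamma.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 55.0),
}


@dataclass(frozen=True)
class FrontoCentralMontage:
    """The 15-site fronto-central ROI split into left / midline / right groups."""

    left: tuple[str, ...] = ("Fp1", "AF3", "F7", "F3", "FC5", "FC3")
    midline: tuple[str, ...] = ("Fpz", "Fz", "FCz")
    right: tuple[str, ...] = ("Fp2", "AF4", "F4", "F8", "FC4", "FC6")

    def __post_init__(self) -> None:
        labels = self.all_sites
        if len(set(labels)) != len(labels):
            raise ConfigurationError("montage labels must be distinct")
        if len(self.left) != len(self.right):
            raise ConfigurationError("left and right groups must be size-matched")
        if len(labels) != 15:
            raise ConfigurationError(f"ROI must have 15 sites, got {len(labels)}")

    @property
    def all_sites(self) -> tuple[str, ...]:
        return self.left + self.midline + self.right

    def group(self, name: str) -> tuple[str, ...]:
        if name == "left":
            return self.left
        if name == "right":
            return self.right
        if name == "all":
            return self.all_sites
        if name == "midline":
            return self.midline
        raise ConfigurationError(f"unknown ROI group {name!r}")


CANONICAL_MONTAGE = FrontoCentralMontage()


@dataclass
class EEGRecording:
    """A cleaned multi-channel EEG recording with episode markers.

    Parameters
    ----------
    data
        Channel x sample array of amplitudes (microvolts).
    sampling_rate
        Samples per second (Hz).
    channel_labels
        One 10-20 label per row of ``data``; must be unique.
    baseline_window_ms
        ``(start_ms, end_ms)`` of the pre-episode black-screen window used
        for baseline correction; must span at least 1000 ms.
    episode_onset_ms
        Offset of program start from the beginning of ``data``.
    artifact_mask
        Optional per-second boolean flags (True = excluded second), aligned
        to whole seconds since episode onset.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    baseline_window_ms: tuple[float, float] = (0.0, 1000.0)
    episode_onset_ms: float = 1000.0
    artifact_mask: np.ndarray | None = None
    participant_id: str = "p0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be channels x samples")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ConfigurationError("one label per channel row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")
        b0, b1 = self.baseline_window_ms
        if b1 - b0 < 1000:
            raise ConfigurationError("baseline window must span at least 1000 ms")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def episode_seconds(self) -> int:
        """Number of whole seconds of episode content after onset."""
        onset = int(round(self.episode_onset_ms / 1000.0 * self.sampling_rate))
        return int((self.n_samples - onset) // int(round(self.sampling_rate)))

    def channel_index(self, labels: tuple[str, ...] | list[str]) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.channel_labels)}
        missing = [lab for lab in labels if lab not in lut]
        if missing:
            raise MissingChannelError(f"channels missing from recording: {missing}")
        return np.array([lut[lab] for lab in labels], dtype=int)

    def episode_data(self) -> np.ndarray:
        """Channel x sample view trimmed to whole seconds from episode onset."""
        fs = int(round(self.sampling_rate))
        onset = int(round(self.episode_onset_ms / 1000.0 * self.sampling_rate))
        n_sec = self.episode_seconds
        if n_sec < 1:
            raise EmptyInputError("recording holds less than 1 s of episode data")
        return self.data[:, onset:onset + n_sec * fs]

    def baseline_data(self) -> np.ndarray:
        """Channel x sample view of the first 1000 ms of the baseline window."""
        fs = self.sampling_rate
        b0 = int(round(self.baseline_window_ms[0] / 1000.0 * fs))
        n = int(round(fs))
        if b0 + n > self.n_samples:
            raise ConfigurationError("baseline window exceeds recording length")
        return self.data[:, b0:b0 + n]
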