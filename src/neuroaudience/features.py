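"""Per-second EEG band power and the three minute-level engagement scores.

The processing chain, applied per participant and then aggregated:

1. band power per channel in non-overlapping 1-s rectangular windows
   (short-time Fourier transform, summed squared spectral amplitude over the
   band's bins);
2. subtraction of the per-channel band power of the 1-s black-screen
   baseline window;
3. unweighted averaging over ROI channel groups (left 6, right 6, all 15);
4. z-scoring over time within participant (population SD);
5. combination into raw scores:
   motivation = 0.5 * [(z_alpha_R - z_alpha_L) + (z_beta_L - z_beta_R)]
   attention  = z_theta_all - z_alpha_all
   memory     = (z_theta_all + z_gamma_all) / 2
6. unweighted mean over participants at each second;
7. logistic squashing onto a continuous (0, 10) scale;
8. averaging within each whole minute.

Artifact-masked seconds are carried as NaN and excluded from all statistics;
a minute with more than half of its seconds masked is flagged missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import (
    AlignmentError,
    BandDefinition,
    CANONICAL_BANDS,
    CANONICAL_MONTAGE,
    DegenerateSeriesError,
    EEGRecording,
    EmptyInputError,
    FrontoCentralMontage,
    NeuroaudienceError,
)

__all__ = [
    "SecondBandPower",
    "compute_band_power",
    "baseline_band_power",
    "baseline_correct",
    "roi_average",
    "zscore_series",
    "motivation_raw",
    "attention_raw",
    "memory_raw",
    "group_aggregate",
    "SigmoidCalibration",
    "calibrate_sigmoid",
    "sigmoid_scale",
    "minute_average",
    "composite_score",
    "diff_series",
    "episode_minute_scores",
]


@dataclass
class SecondBandPower:
    """Per-second band power values with a processing-stage tag.

    ``values`` is ``(n_channels, n_seconds)`` for per-channel series or
    ``(n_seconds,)`` after ROI averaging.
    """

    values: np.ndarray
    band: str
    stage: str  # raw | baseline_corrected | zscored

    @property
    def n_seconds(self) -> int:
        return self.values.shape[-1]


def _window_band_power(windows: np.ndarray, band: BandDefinition, fs: int) -> np.ndarray:
    """Summed |DFT|^2 over the band's one-sided bins for each 1-s window.

    ``windows`` has shape (..., fs); frequency resolution is exactly 1 Hz, so
    bin k sits at k Hz and the half-open band [f_lo, f_hi) maps to bins
    ceil(f_lo) .. ceil(f_hi)-1.
    """
    spec = np.fft.rfft(windows, axis=-1)
    lo = int(np.ceil(band.f_lo))
    hi = int(np.ceil(band.f_hi))  # exclusive
    return np.sum(np.abs(spec[..., lo:hi]) ** 2, axis=-1)


def compute_band_power(rec: EEGRecording, band: BandDefinition) -> SecondBandPower:
    """Raw per-channel band power for each whole second since episode onset."""
    band.validate_for_rate(rec.sampling_rate)
    fs = int(round(rec.sampling_rate))
    x = rec.episode_data()
    windows = x.reshape(rec.n_channels, -1, fs)
    values = _window_band_power(windows, band, fs)
    return SecondBandPower(values=values, band=band.name, stage="raw")


def baseline_band_power(rec: EEGRecording, band: BandDefinition) -> np.ndarray:
    """Per-channel band power of the 1000 ms black-screen baseline window."""
    band.validate_for_rate(rec.sampling_rate)
    fs = int(round(rec.sampling_rate))
    return _window_band_power(rec.baseline_data(), band, fs)


def baseline_correct(power: SecondBandPower, baseline: np.ndarray) -> SecondBandPower:
    """Subtract the per-channel baseline value from every second."""
    baseline = np.asarray(baseline, dtype=float)
    if power.values.ndim != 2 or baseline.shape != (power.values.shape[0],):
        raise AlignmentError("baseline must hold one value per channel")
    return SecondBandPower(
        values=power.values - baseline[:, None], band=power.band, stage="baseline_corrected"
    )


def roi_average(
    power: SecondBandPower,
    channel_labels: list[str],
    montage: FrontoCentralMontage = CANONICAL_MONTAGE,
    group: str = "all",
) -> SecondBandPower:
    """Unweighted mean over the ROI group's channels at each second."""
    labels = montage.group(group)
    lut = {lab: i for i, lab in enumerate(channel_labels)}
    missing = [lab for lab in labels if lab not in lut]
    if missing:
        from .recording import MissingChannelError

        raise MissingChannelError(f"channels missing from recording: {missing}")
    idx = np.array([lut[lab] for lab in labels], dtype=int)
    return SecondBandPower(
        values=power.values[idx].mean(axis=0), band=power.band, stage=power.stage
    )


def zscore_series(values: np.ndarray) -> np.ndarray:
    """z-transform over time using the population SD; NaNs are pass-through.

    Masked (NaN) entries are excluded from the mean/SD and stay NaN in the
    output.  Raises on fewer than two finite values or zero variance.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise DegenerateSeriesError("need at least 2 unmasked values to z-score")
    mu = values[finite].mean()
    sd = values[finite].std()  # population SD (divisor n)
    if sd == 0:
        raise DegenerateSeriesError("zero variance: cannot z-score a constant series")
    return (values - mu) / sd


def _check_equal_lengths(*series: np.ndarray) -> None:
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise AlignmentError(f"series lengths differ: {sorted(lengths)}")


def motivation_raw(
    z_alpha_left: np.ndarray,
    z_alpha_right: np.ndarray,
    z_beta_left: np.ndarray,
    z_beta_right: np.ndarray,
) -> np.ndarray:
    """Approach-motivation score from fronto-central alpha/beta asymmetry.

    Higher values mean relatively less left-hemisphere alpha (the inverse
    relation) together with relatively more left beta.
    """
    _check_equal_lengths(z_alpha_left, z_alpha_right, z_beta_left, z_beta_right)
    return 0.5 * ((z_alpha_right - z_alpha_left) + (z_beta_left - z_beta_right))


def attention_raw(z_theta_all: np.ndarray, z_alpha_all: np.ndarray) -> np.ndarray:
    """Attention score: theta increase combined with alpha decrease."""
    _check_equal_lengths(z_theta_all, z_alpha_all)
    return z_theta_all - z_alpha_all


def memory_raw(z_theta_all: np.ndarray, z_gamma_all: np.ndarray) -> np.ndarray:
    """Memory score: mean of theta and gamma power over all ROI sites."""
    _check_equal_lengths(z_theta_all, z_gamma_all)
    return (z_theta_all + z_gamma_all) / 2.0


def group_aggregate(participant_series: list[np.ndarray]) -> np.ndarray:
    """Unweighted mean over participants at each second, ignoring NaNs.

    Seconds masked for every participant propagate as NaN.
    """
    if not participant_series:
        raise EmptyInputError("need at least one participant series")
    _check_equal_lengths(*participant_series)
    stacked = np.vstack(participant_series)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN second -> NaN
        out = np.nanmean(stacked, axis=0)
    return out


@dataclass(frozen=True)
class SigmoidCalibration:
    """Center / scale constants for the logistic 10-point squashing."""

    center: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise NeuroaudienceError(f"sigmoid scale must be positive, got {self.scale}")


_LOGISTIC_SD_FACTOR = np.sqrt(3.0) / np.pi


def calibrate_sigmoid(series: np.ndarray) -> SigmoidCalibration:
    """Moment-matched calibration: center = median, scale = (sqrt(3)/pi) * SD.

    A logistic distribution with these constants has the calibration
    sample's spread, so the squashed values use the (0, 10) range evenly.
    """
    series = np.asarray(series, dtype=float)
    finite = series[np.isfinite(series)]
    if finite.size < 2:
        raise DegenerateSeriesError("need at least 2 finite values to calibrate")
    sd = finite.std()
    if sd == 0:
        raise DegenerateSeriesError("zero variance: cannot calibrate sigmoid")
    return SigmoidCalibration(center=float(np.median(finite)), scale=float(_LOGISTIC_SD_FACTOR * sd))


def sigmoid_scale(series: np.ndarray, calibration: SigmoidCalibration) -> np.ndarray:
    """Map raw scores onto the open (0, 10) scale: 10 / (1 + exp(-(x-c)/s)).

    Extreme inputs that would saturate in floating point are clamped to the
    nearest representable value inside the open interval, keeping the
    (0, 10) bounds strict.
    """
    x = np.asarray(series, dtype=float)
    with np.errstate(over="ignore"):
        y = 10.0 / (1.0 + np.exp(-(x - calibration.center) / calibration.scale))
    return np.clip(y, np.nextafter(0.0, 1.0), np.nextafter(10.0, 0.0))


def minute_average(
    series: np.ndarray, max_missing_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute mean over unmasked seconds; trailing partial minute dropped.

    Returns ``(minute_values, missing_flags)``; a minute with more than
    ``max_missing_fraction`` of its seconds NaN is NaN with its flag set.
    """
    series = np.asarray(series, dtype=float)
    n_min = len(series) // 60
    if n_min < 1:
        raise EmptyInputError("series must cover at least one full minute")
    blocks = series[: n_min * 60].reshape(n_min, 60)
    n_missing = np.isnan(blocks).sum(axis=1)
    missing = n_missing > max_missing_fraction * 60
    with np.errstate(invalid="ignore"):
        values = np.nanmean(blocks, axis=1)
    values[missing] = np.nan
    return values, missing


def composite_score(
    motivation: np.ndarray, attention: np.ndarray, memory: np.ndarray
) -> np.ndarray:
    """Unweighted mean of the three minute-level scores."""
    _check_equal_lengths(motivation, attention, memory)
    return (np.asarray(motivation) + np.asarray(attention) + np.asarray(memory)) / 3.0


def diff_series(values: np.ndarray) -> np.ndarray:
    """Minute-to-minute rate of change, V_{t+1} - V_t (length n-1).

    The diff at index t spans minute t -> t+1 (aligned to the leading minute).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise EmptyInputError("need at least 2 values to difference")
    return values[1:] - values[:-1]


# ---------------------------------------------------------------------------
# Orchestration


def _participant_z_series(
    rec: EEGRecording,
    montage: FrontoCentralMontage,
    bands: dict[str, BandDefinition],
) -> dict[tuple[str, str], np.ndarray]:
    """Baseline-corrected, ROI-averaged, z-scored series per (band, group)."""
    out: dict[tuple[str, str], np.ndarray] = {}
    needed = {"theta": ("all",), "alpha": ("left", "right", "all"),
              "beta": ("left", "right"), "gamma": ("all",)}
    mask = rec.artifact_mask
    # one STFT pass shared across bands
    fs = int(round(rec.sampling_rate))
    spec_sq = np.abs(np.fft.rfft(rec.episode_data().reshape(rec.n_channels, -1, fs),
                                 axis=-1)) ** 2
    base_sq = np.abs(np.fft.rfft(rec.baseline_data(), axis=-1)) ** 2
    for band_name, groups in needed.items():
        band = bands[band_name]
        band.validate_for_rate(rec.sampling_rate)
        lo, hi = int(np.ceil(band.f_lo)), int(np.ceil(band.f_hi))
        power = SecondBandPower(spec_sq[..., lo:hi].sum(axis=-1), band.name, "raw")
        corrected = baseline_correct(power, base_sq[..., lo:hi].sum(axis=-1))
        for grp in groups:
            series = roi_average(corrected, rec.channel_labels, montage, grp).values
            if mask is not None:
                series = series.copy()
                series[mask[: len(series)]] = np.nan
            out[(band_name, grp)] = zscore_series(series)
    return out


def participant_raw_scores(
    rec: EEGRecording,
    montage: FrontoCentralMontage = CANONICAL_MONTAGE,
    bands: dict[str, BandDefinition] | None = None,
) -> dict[str, np.ndarray]:
    """Per-second raw motivation/attention/memory scores for one participant."""
    z = _participant_z_series(rec, montage, bands or CANONICAL_BANDS)
    return {
        "motivation": motivation_raw(
            z[("alpha", "left")], z[("alpha", "right")],
            z[("beta", "left")], z[("beta", "right")],
        ),
        "attention": attention_raw(z[("theta", "all")], z[("alpha", "all")]),
        "memory": memory_raw(z[("theta", "all")], z[("gamma", "all")]),
    }


def episode_minute_scores(
    recordings: list[EEGRecording],
    montage: FrontoCentralMontage = CANONICAL_MONTAGE,
    bands: dict[str, BandDefinition] | None = None,
    calibrations: dict[str, SigmoidCalibration] | None = None,
    episode_id: str = "episode",
) -> pd.DataFrame:
    """Group-level minute scores for one episode from cleaned recordings.

    Runs the full per-participant chain, averages raw scores over
    participants second by second, squashes each score onto the (0, 10)
    scale (calibrating on the episode's own group series unless explicit
    constants are supplied) and averages within minutes.  The composite is
    the mean of the three minute-level group scores.
    """
    if not recordings:
        raise EmptyInputError("need at least one recording")
    per_participant = [participant_raw_scores(r, montage, bands) for r in recordings]
    n_seconds = min(len(p["attention"]) for p in per_participant)

    minute_cols: dict[str, np.ndarray] = {}
    missing_any = None
    for metric in ("motivation", "attention", "memory"):
        group_series = group_aggregate(
            [p[metric][:n_seconds] for p in per_participant]
        )
        cal = (calibrations or {}).get(metric) or calibrate_sigmoid(group_series)
        scaled = sigmoid_scale(group_series, cal)
        values, missing = minute_average(scaled)
        minute_cols[metric] = values
        missing_any = missing if missing_any is None else (missing_any | missing)

    composite = composite_score(
        minute_cols["motivation"], minute_cols["attention"], minute_cols["memory"]
    )
    n_min = len(composite)
    return pd.DataFrame(
        {
            "episode_id": episode_id,
            "minute": np.arange(n_min),
            "motivation": minute_cols["motivation"],
            "attention": minute_cols["attention"],
            "memory": minute_cols["memory"],
            "composite": composite,
            "n_participants": len(recordings),
            "missing_flag": missing_any,
        }
    )
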