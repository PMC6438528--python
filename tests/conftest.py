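import numpy as np
import pytest

from neuroaudience import CANONICAL_MONTAGE, EEGRecording
from neuroaudience.audience import AudienceSeries, EpisodeTimeline

ROI_LABELS = list(CANONICAL_MONTAGE.all_sites)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    signal: np.ndarray | None = None,
    n_channels: int = 15,
    n_seconds: int = 4,
    fs: int = 128,
    rng: np.random.Generator | None = None,
    labels: list[str] | None = None,
) -> EEGRecording:
    """Recording with a 1-s baseline prepended before episode onset."""
    rng = rng or np.random.default_rng(0)
    n = (n_seconds + 1) * fs
    if signal is None:
        data = rng.standard_normal((n_channels, n))
    else:
        data = np.broadcast_to(signal, (n_channels, n)).copy()
    return EEGRecording(
        data=data,
        sampling_rate=fs,
        channel_labels=(labels or ROI_LABELS)[:n_channels],
        baseline_window_ms=(0.0, 1000.0),
        episode_onset_ms=1000.0,
    )


@pytest.fixture
def sinusoid_recording():
    """Unit-amplitude 10 Hz sinusoid on all 15 ROI channels at 512 Hz."""
    fs = 512
    t = np.arange((4 + 1) * fs) / fs
    return make_recording(signal=np.sin(2 * np.pi * 10 * t), fs=fs, n_seconds=4)


@pytest.fixture
def random_recording(rng):
    return make_recording(rng=rng, n_seconds=6)


@pytest.fixture
def toy_timeline():
    """10-minute episode: seg(0-4) break(4-7) seg(7-10)."""
    return EpisodeTimeline(
        episode_id="toy",
        blocks=(("segment", 0, 4), ("break", 4, 7), ("segment", 7, 10)),
    )


def toy_audience(twitter=None, viewership=None, n=10, episode_id="toy"):
    return AudienceSeries(
        episode_id=episode_id,
        minutes=np.arange(n),
        twitter=np.asarray(twitter if twitter is not None else np.arange(n) + 10.0),
        viewership=np.asarray(
            viewership if viewership is not None else 1000.0 + 5 * np.arange(n)
        ),
    )
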