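"""Preparing minute-level audience series for segment-level analysis.

Builds a 44-minute episode with five commercial breaks, simulates Twitter
counts (with a 2-minute posting lag and break surges) and viewership (with
break drop-offs), then runs the fixed preparation order: trim omissions ->
z-score -> lag alignment / break detrending -> minute diffs -> per-segment
pooling.
"""

import numpy as np

from neuroaudience import make_timeline, simulate_audience, simulate_latents
from neuroaudience.audience import (
    apply_twitter_lag,
    detrend_viewership,
    segment_twitter,
    segment_viewership,
    trim_omissions,
    zscore_episode,
)

timeline = make_timeline("demo", n_minutes=44, n_breaks=5, break_len=3,
                         omit_start=3, omit_end=2, twitter_lag=2)
latents = simulate_latents(timeline, seed=7)
audience = simulate_audience(latents, timeline, seed=8)

print(f"timeline: {timeline.n_segments} segments, breaks at "
      f"{[s for s, _ in timeline.breaks]}; omit 3 start / 2 end; lag 2 min")
print(f"raw twitter counts, first 8 minutes: {audience.twitter[:8].astype(int)}")

prepared = trim_omissions(audience, timeline)
prepared = zscore_episode(prepared, "twitter")
prepared = zscore_episode(prepared, "viewership")
prepared = apply_twitter_lag(prepared, timeline.twitter_lag)
prepared = detrend_viewership(prepared, timeline)

tw = segment_twitter(prepared, timeline)
vw = segment_viewership(prepared, timeline)
for i, (t, v) in enumerate(zip(tw, vw)):
    print(f"segment {i}: mean twitter diff = {t:+.3f}, "
          f"mean viewership diff = {v:+.3f}")
print("\nEach value is the mean minute-to-minute change of the z-scored "
      "series within the segment (plus the first two break minutes for "
      "Twitter, one for viewership) - the unit of all downstream inference.")
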