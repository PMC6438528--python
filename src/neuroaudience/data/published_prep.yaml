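# Per-episode preprocessing parameters of the nine-episode broadcast study:
# minutes omitted at the start/end of each show (outlier tweet/viewership
# windows) and the per-episode Twitter lag, in minutes.
big_brother_ep_1: {omit_start: 3, omit_end: 2, twitter_lag: 2}
big_brother_ep_2: {omit_start: 2, omit_end: 1, twitter_lag: 0}
gang_related: {omit_start: 0, omit_end: 0, twitter_lag: 2}
masterchef: {omit_start: 3, omit_end: 2, twitter_lag: 1}
naked_and_afraid: {omit_start: 3, omit_end: 2, twitter_lag: 0}
ny_med: {omit_start: 0, omit_end: 0, twitter_lag: 1}
reckless: {omit_start: 2, omit_end: 2, twitter_lag: 2}
suits: {omit_start: 2, omit_end: 2, twitter_lag: 1}
taxi_brooklyn: {omit_start: 2, omit_end: 3, twitter_lag: 1}
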