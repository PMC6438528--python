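"""Segment-level inference on a complete synthetic study.

Generates a study at nearly the default scale (9 episodes x 8
participants, ~45 s of compute), runs the full
pipeline to the segment table, and applies the inference battery:
correlations of each EEG score with both audience variables, stepwise
regression, and the partial correlation between the audience variables
controlling for the composite EEG score.
"""

from neuroaudience import make_study
from neuroaudience.analysis import headline_statistics
from neuroaudience.simulate import run_recovery_experiment

study = make_study(n_episodes=9, n_participants=8, seed=44,
                   drop_last_segment_episode=None, keep_eeg=False)
report = run_recovery_experiment(study)
table = report.segment_table
print(f"segment table: {len(table)} rows "
      f"(episodes x segments, complete cells only)\n")

stats = headline_statistics(table)
for score in ("attention", "motivation", "memory"):
    for outcome in ("viewership", "twitter"):
        res = stats[f"{score}_{outcome}"]
        print(f"{score:>10} vs {outcome:<10} r = {res.r:+.2f}  p = {res.p:.3f}")
for outcome in ("viewership", "twitter"):
    sw = stats[f"stepwise_{outcome}"]
    print(f"\nstepwise ({outcome}): entered {sw.entered or 'none'}; "
          f"R^2 = {sw.r2:.2f}, adj. R^2 = {sw.adj_r2:.2f}")
pr = stats["twitter_viewership_partial"]
print(f"\ntwitter~viewership r = {stats['twitter_viewership'].r:.2f}; "
      f"partial r controlling composite EEG = {pr.r_partial:.2f} (p = {pr.p:.3f})")
print("\nUnder the default coupling (attention drives both outcomes, "
      "motivation adds to Twitter), attention typically dominates the "
      "stepwise models.  Segment-level correlations at ~50 segments are "
      "noisy: across study seeds the attention-viewership r swings by "
      "+/-0.15 or more, which is why the acceptance checks average over "
      "many seeded replicates.")
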