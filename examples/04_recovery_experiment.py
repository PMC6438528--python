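"""Parameter recovery: does the full pipeline find the couplings we put in?

Generates a study where only the latent attention trace drives viewership
and Twitter, runs EEG synthesis -> scores -> audience prep -> segment table
-> stepwise regression, and reports which predictors the model selects
(one full-scale study, ~15 s; the package-level acceptance checks repeat
this over many seeded replicates).
"""

from neuroaudience import attention_only_coupling, make_study
from neuroaudience.simulate import run_recovery_experiment

study = make_study(n_episodes=9, n_participants=12,
                   coupling=attention_only_coupling(), seed=11, keep_eeg=False)
report = run_recovery_experiment(study)

print(f"{len(report.segment_table)} segments; ground truth: only attention "
      f"drives the audience (b = {study.coupling.b_attention}, "
      f"c = {study.coupling.c_attention})\n")
for outcome in ("viewership", "twitter"):
    sw = report.stepwise[outcome]
    print(f"stepwise for {outcome}: entered {sw.entered or 'none'} "
          f"(R^2 = {sw.r2:.2f})")
for score in ("attention", "motivation", "memory"):
    r = report.correlations[(score, "viewership")].r
    print(f"  {score:>10} vs viewership: r = {r:+.2f}")
print("\nWith attention-only coupling the attention score should lead the "
      "model and carry the largest correlation.  The memory score shares "
      "the theta band with the attention score, so it tracks the attention "
      "latent indirectly and can show a secondary correlation; the "
      "asymmetry (motivation) score is genuine noise here.")
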