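"""Behavior-sorted split-half pattern correlations for one subject.

Trial amplitudes are split into odd and even runs, averaged per
condition-by-response cell, cocktail-blank centered, and correlated across
halves.  Under the holistic scenario, only the veridical condition should
show higher reliability on correct than incorrect trials.
"""
import facemvpa as fm
from facemvpa.patterns import filter_trials, match_trial_counts, roi_mean_magnitude, split_half_correlations

gt = fm.make_ground_truth("holistic", seed=5)
est, _ = fm.simulate_session_estimates(gt, "ffa_like", n_runs=10, seed=5)
est = filter_trials(est)

res = split_half_correlations(est, subject="demo", roi="ffa_like")
print("split-half correlations (odd vs even runs):")
for (cond, resp), r in res.correlations.items():
    n = res.n_trials["odd"][(cond, resp)], res.n_trials["even"][(cond, resp)]
    print(f"  {cond:10s} {resp:9s}: r = {r:+.3f}   (trials odd/even {n[0]}/{n[1]})")

matched = split_half_correlations(match_trial_counts(est, seed=5))
print("\nwith trial counts matched across conditions:")
for (cond, resp), r in matched.correlations.items():
    print(f"  {cond:10s} {resp:9s}: r = {r:+.3f}")

mags = roi_mean_magnitude(est)
print("\npooled mean amplitudes (the traditional magnitude analysis):")
for (cond, resp), m in mags.items():
    print(f"  {cond:10s} {resp:9s}: {m:+.3f}")
print("\nFor one holistic-scenario subject, veridical-correct reliability "
      "exceeds veridical-incorrect while the scrambled cells are similar, "
      "and the pattern survives trial-count matching.  Pooled magnitudes "
      "carry only the 0.93 condition scaling plus sampling noise -- no "
      "systematic correct-vs-incorrect structure -- which is why the "
      "traditional magnitude analysis misses the effect.")
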