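"""Recover single-trial response amplitudes from a noiseless simulated run.

The gamma HRF (onset delay 2.25 s, dispersion 1.25 s, shape 2) peaks at
delta + alpha*tau = 4.75 s.  With scanner noise switched off, the
least-squares-all trial GLM returns the generative amplitudes exactly.
"""
import numpy as np

import facemvpa as fm

t = np.arange(0, 16, 0.001)
h = fm.gamma_hrf(t)
print(f"HRF peak at {t[np.argmax(h)]:.3f} s (height normalized to {h.max():.1f})")

gt = fm.make_ground_truth("holistic", seed=3)
design = fm.generate_experimental_design(run_id=1, seed=3)
behavior = fm.simulate_behavior(design, seed=3)
quiet = fm.NoiseModel(sigma_thermal=0.0, ar1_coef=0.0, drift_amp=0.0)
bold = fm.simulate_bold_run(design, behavior, gt, quiet, seed=3)
print(f"simulated BOLD: {bold.data.shape} (x, y, z, scans)")

est = fm.estimate_trial_betas(
    bold, design, behavior=behavior, roi_mask=gt.roi_masks["ffa_like"]
)
truth = fm.draw_session_amplitudes(
    est.trial_meta.assign(run_id=1), gt, "ffa_like", fm.child_seed(3, "run", 1)
)
err = np.abs(est.amplitudes - truth).max()
print(f"max |estimated - true| amplitude over {est.n_voxels} voxels x "
      f"{est.n_trials} trials: {err:.2e}")
print("A value near machine precision confirms the estimator inverts the "
      "forward model exactly when noise is absent.")
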