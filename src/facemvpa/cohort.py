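"""Cohort-level simulation studies: calibration and scenario recovery.

These helpers run many simulated cohorts through the split-half analysis at
the amplitude level (the generative trial amplitudes, which the noiseless
GLM recovers exactly) so that thousands of cohorts are affordable.  They
back the package's two standing claims about its own statistics: under the
null scenario every 1-df test rejects at the nominal rate, and under the
effect scenarios the default effect size yields high recovery of the
generating scenario.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .design import DesignParams
from .patterns import cell_key, filter_trials, split_half_correlations
from .report import analyze_cell_table, decide_verdict
from .stats import CONTRASTS_2X2
from .synth import (
    CELLS,
    BehaviorParams,
    Geometry,
    GroundTruthParams,
    RoiSpec,
    make_ground_truth,
    simulate_session_estimates,
)

__all__ = [
    "single_roi_geometry",
    "simulate_cohort_cell_table",
    "scenario_recovery_study",
    "null_calibration_study",
]


def single_roi_geometry(n_voxels: int = 28) -> Geometry:
    """A reduced-volume grid holding one compact ROI (calibration workhorse)."""
    return Geometry(
        shape=(10, 10, 6),
        rois={"ffa_like": RoiSpec(center=(4, 4, 3), n_voxels=n_voxels)},
    )


def simulate_cohort_cell_table(
    scenario: str,
    n_subjects: int = 13,
    n_runs: int = 10,
    seed: int = 0,
    roi: str = "ffa_like",
    geometry: Geometry | None = None,
    gt_params: GroundTruthParams | None = None,
    design_params: DesignParams | None = None,
    behavior_params: BehaviorParams | None = None,
) -> pd.DataFrame:
    """One simulated cohort's subjects x 4 cell-correlation table."""
    rows = {}
    for s in range(n_subjects):
        sub_seed = child_seed(seed, "cohort_subject", s)
        gt = make_ground_truth(scenario, geometry, sub_seed, gt_params)
        te, _ = simulate_session_estimates(
            gt, roi, n_runs=n_runs, design_params=design_params,
            behavior_params=behavior_params, seed=sub_seed,
        )
        res = split_half_correlations(filter_trials(te), subject=s, roi=roi)
        rows[s] = {cell_key(*c): res.correlations.get(c, np.nan) for c in CELLS}
    return pd.DataFrame.from_dict(rows, orient="index")[[cell_key(*c) for c in CELLS]]


def null_calibration_study(
    n_cohorts: int = 2000,
    n_subjects: int = 13,
    n_runs: int = 4,
    n_voxels: int = 28,
    seed: int = 0,
    alpha: float = 0.05,
    design_params: DesignParams | None = None,
    behavior_params: BehaviorParams | None = None,
) -> dict[str, float]:
    """Rejection rate of each 1-df test across null-scenario cohorts.

    Uses the reduced volume (single ROI) and short sessions; returns
    {effect name: empirical rejection rate at ``alpha``}.
    """
    geom = single_roi_geometry(n_voxels)
    rejections = {name: 0 for name in CONTRASTS_2X2}
    for c in range(n_cohorts):
        table = simulate_cohort_cell_table(
            "null", n_subjects=n_subjects, n_runs=n_runs,
            seed=child_seed(seed, "null_cohort", c), geometry=geom,
            design_params=design_params, behavior_params=behavior_params,
        )
        analysis = analyze_cell_table(table, alpha)
        for name, eff in analysis["effects"].items():
            rejections[name] += int(np.isfinite(eff.p) and eff.p < alpha)
    return {name: k / n_cohorts for name, k in rejections.items()}


def scenario_recovery_study(
    scenario: str,
    n_cohorts: int = 50,
    n_subjects: int = 13,
    n_runs: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    geometry: Geometry | None = None,
) -> dict[str, float]:
    """How often the analysis recovers the generating scenario.

    Returns the verdict-match rate plus the rates of the individual effects
    that define it (interaction, response main effect, post-hoc pattern).
    """
    geom = geometry or single_roi_geometry()
    verdict_match = 0
    inter_sig = 0
    resp_sig = 0
    pattern = 0
    for c in range(n_cohorts):
        table = simulate_cohort_cell_table(
            scenario, n_subjects=n_subjects, n_runs=n_runs,
            seed=child_seed(seed, "recovery_cohort", c), geometry=geom,
        )
        analysis = analyze_cell_table(table, alpha)
        verdict = decide_verdict(analysis, alpha)
        eff = analysis["effects"]
        post = analysis["posthoc"]
        inter_ok = eff["condition_x_response"].p < alpha
        resp_ok = eff["response"].p < alpha
        post_v = post["veridical"].p < alpha and post["veridical"].mean_diff > 0
        post_s = post["scrambled"].p < alpha and post["scrambled"].mean_diff > 0
        inter_sig += int(inter_ok)
        resp_sig += int(resp_ok)
        if scenario == "holistic":
            pattern += int(inter_ok and post_v and not post_s)
        elif scenario == "parts_based":
            pattern += int(resp_ok and not inter_ok)
        verdict_match += int(verdict["scenario"] == scenario)
    n = float(n_cohorts)
    return {
        "verdict_match_rate": verdict_match / n,
        "interaction_rate": inter_sig / n,
        "response_main_rate": resp_sig / n,
        "pattern_rate": pattern / n,
    }
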