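"""Synthetic fMRI cohort generator with known ground truth.

A simulated subject has a 3-D voxel grid (default 20 x 20 x 10 at 3 x 3 x 4
mm) holding two compact face-selective regions, ``ffa_like`` (28 voxels) and
``ofa_like`` (32 voxels), sized after typical right-hemisphere localizer
counts.  Behavioral correctness is Bernoulli per condition (defaults 84.7 %
veridical, 72.7 % scrambled, no-response rate 0.1 %); reaction times are a
shifted lognormal with the veridical mean below the scrambled mean.

Neural ground truth follows one of four scenarios describing how pattern
reliability depends on behavior:

* ``holistic``     -- correct > incorrect reliability for veridical faces only
  (an interaction, the integrated-whole account);
* ``parts_based``  -- correct > incorrect for both configurations (a response
  main effect);
* ``both``         -- interaction plus main effect;
* ``null``         -- all four cells equal.

The trial amplitude in cell c (condition x response), data half h (odd/even
runs) is::

    a[v, t] = mu_cond + s_c * p[v, c]
              + (1 - s_c) * (sqrt(1 - w) * eta[v, c, h] + sqrt(w) * eps[v, t])

where ``p`` is the subject's fixed cell pattern, ``eta`` a cell-by-half state
fluctuation, ``eps`` i.i.d. per-trial noise, ``s_c`` the cell's stability in
[0, 1] and ``w`` the per-trial share of the unstable variance.  The across-
half correlation of cell-mean patterns is therefore 1 at ``s = 1`` and falls
to 0 as ``s -> 0``; the half-level term keeps the expected correlation nearly
independent of how many trials land in a cell, so differences between cells
reflect stability, not trial counts.

BOLD time series are built by pushing these amplitudes through the same
boxcar-convolved gamma HRF used for estimation, then adding linear drift and
AR(1) noise around a baseline of 100.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator
from scipy import signal as _signal

from ._seeds import child_seed
from .design import CONDITIONS, DesignParams, EventDesign, generate_experimental_design
from .glm import (
    DEFAULT_STIM_WINDOW,
    BoldRun,
    HrfParams,
    TrialEstimates,
    build_design_matrix,
)

__all__ = [
    "BehavioralRecord",
    "BehaviorParams",
    "RoiSpec",
    "Geometry",
    "GroundTruthParams",
    "GroundTruth",
    "NoiseModel",
    "SCENARIOS",
    "CELLS",
    "simulate_behavior",
    "behavior_frame",
    "make_ground_truth",
    "scenario_stability",
    "draw_session_amplitudes",
    "simulate_bold_run",
    "simulate_localizer_bold",
    "simulate_session_estimates",
]

SCENARIOS = ("holistic", "parts_based", "both", "null")

#: The four analysis cells: condition x behavioral response.
CELLS: tuple[tuple[str, str], ...] = (
    ("veridical", "correct"),
    ("veridical", "incorrect"),
    ("scrambled", "correct"),
    ("scrambled", "incorrect"),
)

BASELINE = 100.0


@dataclass(frozen=True)
class BehavioralRecord:
    """One trial's behavioral outcome; rt_s is None iff no response was made."""

    trial_id: int
    condition: str
    response: str  # {"correct", "incorrect", "none"}
    rt_s: float | None = None

    def __post_init__(self) -> None:
        if (self.rt_s is None) != (self.response == "none"):
            raise ValueError("rt_s must be absent exactly when response is 'none'")
        if self.rt_s is not None and self.rt_s <= 0:
            raise ValueError("rt_s must be positive")


class BehaviorParams(BaseModel):
    """Per-condition correctness and RT parameters.

    Accuracy defaults are the published in-scanner values; the no-response
    rate matches the published "<0.1 %".  RT is shift + lognormal(mu, sd);
    the defaults order veridical faster than scrambled.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    p_correct_veridical: float = 0.847
    p_correct_scrambled: float = 0.727
    p_no_response: float = 0.001
    rt_shift_s: float = 0.3
    rt_log_mean_veridical: float = math.log(0.55)
    rt_log_mean_scrambled: float = math.log(0.75)
    rt_log_sd: float = 0.35

    @field_validator("p_correct_veridical", "p_correct_scrambled", "p_no_response")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    def p_correct(self, condition: str) -> float:
        return {
            "veridical": self.p_correct_veridical,
            "scrambled": self.p_correct_scrambled,
        }[condition]

    def rt_log_mean(self, condition: str) -> float:
        return {
            "veridical": self.rt_log_mean_veridical,
            "scrambled": self.rt_log_mean_scrambled,
        }[condition]


def simulate_behavior(
    design: EventDesign, behavior_params: BehaviorParams | None = None, seed: int = 0
) -> list[BehavioralRecord]:
    """One behavioral record per stimulus trial of ``design`` (seeded)."""
    p = behavior_params or BehaviorParams()
    rng = np.random.default_rng(child_seed(seed, "behavior", design.run_id))
    records: list[BehavioralRecord] = []
    for e in design.events:
        if e.trial_id is None:
            continue
        if rng.random() < p.p_no_response:
            records.append(BehavioralRecord(e.trial_id, e.condition, "none"))
            continue
        correct = rng.random() < p.p_correct(e.condition)
        rt = p.rt_shift_s + rng.lognormal(p.rt_log_mean(e.condition), p.rt_log_sd)
        records.append(
            BehavioralRecord(e.trial_id, e.condition, "correct" if correct else "incorrect", rt)
        )
    return records


def behavior_frame(records: list[BehavioralRecord]) -> pd.DataFrame:
    """Records as a tidy table (trial_id, condition, response, rt_s)."""
    return pd.DataFrame(
        [(r.trial_id, r.condition, r.response, r.rt_s) for r in records],
        columns=["trial_id", "condition", "response", "rt_s"],
    )


class RoiSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    center: tuple[int, int, int]
    n_voxels: int


class Geometry(BaseModel):
    """A single 3-D grid holding compact ellipsoid-ish ROIs; no anatomy."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    shape: tuple[int, int, int] = (20, 20, 10)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
    rois: dict[str, RoiSpec] = {
        "ffa_like": RoiSpec(center=(5, 5, 4), n_voxels=28),
        "ofa_like": RoiSpec(center=(14, 14, 5), n_voxels=32),
    }

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


class GroundTruthParams(BaseModel):
    """Generative parameters for the voxel-pattern model.

    ``stability_base``/``stability_effect`` were chosen so that a default
    13-subject, 10-run cohort detects the holistic interaction with power
    about 0.95 (and the full verdict pattern about 0.9) while the null
    scenario stays calibrated; ``trial_noise_fraction`` keeps per-trial
    variability present without letting cell trial counts drive reliability.
    ``condition_mean_scrambled`` sets the pooled scrambled response to 93 %
    of the veridical one.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    stability_base: float = 0.4
    stability_effect: float = 0.25
    trial_noise_fraction: float = 0.2
    pattern_sd: float = 1.0
    condition_mean_veridical: float = 1.0
    condition_mean_scrambled: float = 0.93
    localizer_amp_faces: float = 2.0
    localizer_amp_other: float = 0.5

    @field_validator("stability_base", "stability_effect", "trial_noise_fraction")
    @classmethod
    def _unit(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("must lie in [0, 1]")
        return v

    def condition_mean(self, condition: str) -> float:
        return {
            "veridical": self.condition_mean_veridical,
            "scrambled": self.condition_mean_scrambled,
        }[condition]


class NoiseModel(BaseModel):
    """Scan-level noise: thermal sd, AR(1) coefficient, linear drift scale."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    sigma_thermal: float = 0.5
    ar1_coef: float = 0.3
    drift_amp: float = 1.0

    @field_validator("ar1_coef")
    @classmethod
    def _stationary(cls, v: float) -> float:
        if not -1.0 < v < 1.0:
            raise ValueError("ar1_coef must lie strictly inside (-1, 1)")
        return v


def scenario_stability(
    scenario: str, base: float, effect: float
) -> dict[tuple[str, str], float]:
    """Per-cell stability table implementing the hypothetical representations."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    s = {cell: base for cell in CELLS}
    if scenario == "holistic":
        s[("veridical", "correct")] = base + effect
    elif scenario == "parts_based":
        s[("veridical", "correct")] = base + effect
        s[("scrambled", "correct")] = base + effect
    elif scenario == "both":
        # interaction (effect/2) on top of a response main effect
        s[("veridical", "correct")] = base + effect
        s[("scrambled", "correct")] = base + effect / 2.0
    for cell, v in s.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"stability {v} for cell {cell} outside [0, 1]")
    return s


@dataclass
class GroundTruth:
    """Everything the generator knows and the analysis must recover."""

    scenario: str
    geometry: Geometry
    params: GroundTruthParams
    roi_masks: dict[str, np.ndarray]  # name -> sorted flat voxel indices
    condition_patterns: dict[str, dict[tuple[str, str], np.ndarray]]
    stability: dict[tuple[str, str], float]
    localizer_amplitudes: dict[str, dict[str, float]]
    seed: int = 0


def _compact_roi(geometry: Geometry, spec: RoiSpec) -> np.ndarray:
    """Flat indices of the ``n_voxels`` grid points nearest the center (mm)."""
    nx, ny, nz = geometry.shape
    gx, gy, gz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vx, vy, vz = geometry.voxel_size_mm
    cx, cy, cz = spec.center
    d2 = ((gx - cx) * vx) ** 2 + ((gy - cy) * vy) ** 2 + ((gz - cz) * vz) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    return np.sort(order[: spec.n_voxels])


def make_ground_truth(
    scenario: str,
    geometry: Geometry | None = None,
    seed: int = 0,
    params: GroundTruthParams | None = None,
) -> GroundTruth:
    """Draw one subject's ground truth: ROI masks, cell patterns, stabilities."""
    geom = geometry or Geometry()
    p = params or GroundTruthParams()
    masks: dict[str, np.ndarray] = {}
    taken = np.zeros(geom.n_voxels, dtype=bool)
    for name, spec in geom.rois.items():
        idx = _compact_roi(geom, spec)
        if taken[idx].any():
            raise ValueError(f"ROI {name!r} overlaps a previously placed ROI")
        taken[idx] = True
        masks[name] = idx
    stability = scenario_stability(scenario, p.stability_base, p.stability_effect)
    rng = np.random.default_rng(child_seed(seed, "ground_truth"))
    patterns: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for name, idx in masks.items():
        patterns[name] = {
            cell: rng.standard_normal(idx.size) * p.pattern_sd for cell in CELLS
        }
    loc_amp = {
        name: {
            "faces": p.localizer_amp_faces,
            "objects": p.localizer_amp_other,
            "houses": p.localizer_amp_other,
            "scrambled_objects": p.localizer_amp_other,
        }
        for name in masks
    }
    return GroundTruth(
        scenario=scenario,
        geometry=geom,
        params=p,
        roi_masks=masks,
        condition_patterns=patterns,
        stability=stability,
        localizer_amplitudes=loc_amp,
        seed=seed,
    )


def _half_of_run(run_id: int) -> str:
    """Odd/even data half by 1-based run number."""
    return "odd" if run_id % 2 == 1 else "even"


def draw_session_amplitudes(
    trial_meta: pd.DataFrame,
    ground_truth: GroundTruth,
    roi: str,
    seed: int,
) -> np.ndarray:
    """True voxel x trial amplitudes for one ROI across a whole session.

    ``trial_meta`` needs columns run_id, condition, response (one row per
    trial, session-wide order).  The cell-by-half state term is shared by all
    runs of a half, so this must be drawn per session, not per run.
    """
    p = ground_truth.params
    pats = ground_truth.condition_patterns[roi]
    nvox = ground_truth.roi_masks[roi].size
    n_trials = len(trial_meta)
    rng = np.random.default_rng(child_seed(seed, "amplitudes", roi))
    amps = np.empty((nvox, n_trials))
    halves = trial_meta["run_id"].map(lambda r: _half_of_run(int(r))).to_numpy()
    cond = trial_meta["condition"].to_numpy()
    resp = trial_meta["response"].to_numpy()
    w = p.trial_noise_fraction
    for cell in CELLS:
        c_cond, c_resp = cell
        s = ground_truth.stability[cell]
        mu = p.condition_mean(c_cond)
        for half in ("odd", "even"):
            eta = rng.standard_normal(nvox) * p.pattern_sd
            sel = np.flatnonzero((cond == c_cond) & (resp == c_resp) & (halves == half))
            if sel.size == 0:
                continue
            eps = rng.standard_normal((nvox, sel.size)) * p.pattern_sd
            amps[:, sel] = (
                mu
                + s * pats[cell][:, None]
                + (1.0 - s)
                * (math.sqrt(1.0 - w) * eta[:, None] + math.sqrt(w) * eps)
            )
    # no-response trials: condition mean plus unit trial noise, no stable pattern
    none_sel = np.flatnonzero(resp == "none")
    for j in none_sel:
        mu = p.condition_mean(cond[j])
        amps[:, j] = mu + rng.standard_normal(nvox) * p.pattern_sd
    return amps


def _ar1_noise(rng: np.random.Generator, shape_vox: int, n_scans: int, noise: NoiseModel) -> np.ndarray:
    """AR(1) series with marginal sd ``sigma_thermal`` per voxel (vox x scans)."""
    if noise.sigma_thermal == 0:
        return np.zeros((shape_vox, n_scans))
    innov_sd = noise.sigma_thermal * math.sqrt(1.0 - noise.ar1_coef**2)
    if noise.ar1_coef == 0:
        return rng.standard_normal((shape_vox, n_scans)) * innov_sd
    burn = 50  # reach stationarity before the run starts
    e = rng.standard_normal((shape_vox, n_scans + burn)) * innov_sd
    x = _signal.lfilter([1.0], [1.0, -noise.ar1_coef], e, axis=1)
    return x[:, burn:]


def simulate_bold_run(
    design: EventDesign,
    behavior: list[BehavioralRecord],
    ground_truth: GroundTruth,
    noise: NoiseModel | None = None,
    seed: int = 0,
    amplitudes: dict[str, np.ndarray] | None = None,
    hrf_params: HrfParams | None = None,
    stim_window: tuple[float, float] | None = DEFAULT_STIM_WINDOW,
) -> BoldRun:
    """Forward-model one experimental run to a 4-D BOLD array.

    ``amplitudes`` maps ROI name to a voxel x trial array for *this run's*
    trials (in trial_id order); when omitted it is drawn here, treating the
    run as its own session half.  Background voxels carry baseline, drift and
    noise only.
    """
    nz = noise or NoiseModel()
    design_ids = sorted(e.trial_id for e in design.events if e.trial_id is not None)
    behav_ids = sorted(r.trial_id for r in behavior)
    if design_ids != behav_ids:
        raise ValueError("behavior records do not match the design's trial set")
    if amplitudes is None:
        meta = design.trial_frame().sort_values("trial_id", ignore_index=True)
        meta["run_id"] = design.run_id
        resp = {r.trial_id: r.response for r in behavior}
        meta["response"] = meta["trial_id"].map(resp)
        amplitudes = {
            roi: draw_session_amplitudes(meta, ground_truth, roi, child_seed(seed, "run", design.run_id))
            for roi in ground_truth.roi_masks
        }
    dm = build_design_matrix(
        design, hrf_params, mode="trial", drift_order=0, stim_window=stim_window
    )
    R = dm.matrix[:, dm.columns_of_kind("trial")]  # scans x trials
    geom = ground_truth.geometry
    n_scans = design.n_scans
    rng = np.random.default_rng(child_seed(seed, "bold", design.run_id))
    flat = np.full((geom.n_voxels, n_scans), BASELINE)
    for roi, idx in ground_truth.roi_masks.items():
        a = amplitudes[roi]
        if a.shape != (idx.size, R.shape[1]):
            raise ValueError(
                f"amplitudes for {roi!r} have shape {a.shape}, expected {(idx.size, R.shape[1])}"
            )
        flat[idx] += a @ R.T
    if nz.drift_amp != 0:
        ramp = np.linspace(-0.5, 0.5, n_scans)
        coeff = rng.standard_normal(geom.n_voxels) * nz.drift_amp
        flat += coeff[:, None] * ramp[None, :]
    flat += _ar1_noise(rng, geom.n_voxels, n_scans, nz)
    return BoldRun(data=flat.reshape(*geom.shape, n_scans), tr_s=design.tr_s, run_id=design.run_id)


def simulate_localizer_bold(
    design: EventDesign,
    ground_truth: GroundTruth,
    noise: NoiseModel | None = None,
    seed: int = 0,
    hrf_params: HrfParams | None = None,
) -> BoldRun:
    """Forward-model a blocked localizer run (category-level amplitudes)."""
    nz = noise or NoiseModel()
    dm = build_design_matrix(design, hrf_params, mode="condition", drift_order=0)
    cols = dm.columns_of_kind("condition")
    names = [dm.regressor_names[i] for i in cols]
    geom = ground_truth.geometry
    n_scans = design.n_scans
    rng = np.random.default_rng(child_seed(seed, "localizer_bold", design.run_id))
    flat = np.full((geom.n_voxels, n_scans), BASELINE)
    for roi, idx in ground_truth.roi_masks.items():
        amp = ground_truth.localizer_amplitudes[roi]
        for name, col in zip(names, cols):
            flat[idx] += amp.get(name, 0.0) * dm.matrix[:, col][None, :]
    if nz.drift_amp != 0:
        ramp = np.linspace(-0.5, 0.5, n_scans)
        coeff = rng.standard_normal(geom.n_voxels) * nz.drift_amp
        flat += coeff[:, None] * ramp[None, :]
    flat += _ar1_noise(rng, geom.n_voxels, n_scans, nz)
    return BoldRun(data=flat.reshape(*geom.shape, n_scans), tr_s=design.tr_s, run_id=design.run_id)


def simulate_session_estimates(
    ground_truth: GroundTruth,
    roi: str,
    n_runs: int = 10,
    design_params: DesignParams | None = None,
    behavior_params: BehaviorParams | None = None,
    seed: int = 0,
) -> tuple[TrialEstimates, list[list[BehavioralRecord]]]:
    """Generative trial amplitudes for a whole session, bypassing the scanner.

    This is the amplitude-level shortcut: the exact ``a[v, t]`` that
    :func:`simulate_bold_run` would embed (and that the noiseless GLM
    recovers), packaged as :class:`TrialEstimates`.  Used for large
    calibration studies where the BOLD forward model + GLM inversion would
    only add symmetric estimation noise.
    """
    trial_ids: list[int] = []
    run_ids: list[int] = []
    conds: list[str] = []
    resps: list[str] = []
    behaviors: list[list[BehavioralRecord]] = []
    for run_id in range(1, n_runs + 1):
        design = generate_experimental_design(run_id, seed, design_params)
        recs = simulate_behavior(design, behavior_params, seed)
        behaviors.append(recs)
        # records come back in presentation order == trial_id order
        for r in recs:
            trial_ids.append(r.trial_id)
            run_ids.append(run_id)
            conds.append(r.condition)
            resps.append(r.response)
    meta = pd.DataFrame(
        {"trial_id": trial_ids, "run_id": run_ids, "condition": conds, "response": resps}
    )
    amps = draw_session_amplitudes(meta, ground_truth, roi, seed)
    return TrialEstimates(amps, meta, roi=roi), behaviors
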