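"""End-to-end orchestration: simulate -> estimate -> correlate -> infer.

A single JSON-serializable :class:`PipelineConfig` (validated against its
published JSON schema; unknown keys rejected) drives the whole run.  The
``simulate`` stage writes per-stage artifacts (events TSV, BOLD volumes,
ground-truth record); ``analyze`` reads those artifacts back -- so real data
in the same formats could be analyzed -- and writes beta tables, a tidy
correlation table and the report.  ``full`` is simulate followed by analyze
on its own outputs, and a manifest records the config hash and master seed so
a rerun is bit-identical.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as fio
from ._seeds import child_seed
from .design import (
    DesignParams,
    LocalizerParams,
    generate_experimental_design,
    generate_localizer_design,
)
from .glm import (
    BoldRun,
    HrfParams,
    RoiMask,
    TrialEstimates,
    build_design_matrix,
    define_roi,
    estimate_trial_betas,
    fit_glm,
    smooth_volume,
)
from .patterns import filter_trials, match_trial_counts, roi_mean_magnitude, split_half_correlations
from .report import Report, compile_report
from .stats import behavioral_summary
from .synth import (
    BehaviorParams,
    Geometry,
    GroundTruthParams,
    NoiseModel,
    draw_session_amplitudes,
    make_ground_truth,
    simulate_behavior,
    simulate_bold_run,
    simulate_localizer_bold,
)

__all__ = ["AnalysisParams", "PipelineConfig", "PipelineError", "simulate", "analyze", "run_pipeline"]


class AnalysisParams(BaseModel):
    """Knobs of the estimation and MVPA stages."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    drift_order: int = 1
    beta_method: str = "lsa"  # or "lss"
    stim_window: tuple[float, float] | None = (0.7, 1.5)
    smoothing_fwhm_mm: float = 0.0
    roi_p_threshold: float = 0.01
    roi_min_size: int = 4
    connectivity: int = 26
    alpha: float = 0.05
    fisher_z: bool = False
    center: bool = True
    rt_correct_only: bool = True
    verdict_on_matched: bool = False
    primary_roi: str = "ffa_like"
    localizer_contrast: tuple[str, str] = ("faces", "objects")


class PipelineConfig(BaseModel):
    """Full run configuration; every generator default is overridable."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    master_seed: int = 0
    n_subjects: int = 13
    n_runs: int = 10
    scenario: str = "holistic"
    output_dir: str | None = None
    bold_format: str = "nifti"  # or "flat"
    design: DesignParams = Field(default_factory=DesignParams)
    localizer: LocalizerParams = Field(default_factory=LocalizerParams)
    behavior: BehaviorParams = Field(default_factory=BehaviorParams)
    geometry: Geometry = Field(default_factory=Geometry)
    ground_truth: GroundTruthParams = Field(default_factory=GroundTruthParams)
    noise: NoiseModel = Field(default_factory=NoiseModel)
    hrf: HrfParams = Field(default_factory=HrfParams)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode("utf-8")
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name and subject id."""


def _subjects(config: PipelineConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]


def _bold_ext(fmt: str) -> str:
    return "_bold.nii" if fmt == "nifti" else "_bold.bin"


def simulate(config: PipelineConfig, output_dir: str | Path) -> Path:
    """Generate and write the whole synthetic cohort under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "scenario": config.scenario,
        "n_subjects": config.n_subjects,
        "n_runs": config.n_runs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    vox = config.geometry.voxel_size_mm
    for si, subject in enumerate(_subjects(config)):
        try:
            sdir = out / subject
            sdir.mkdir(exist_ok=True)
            sub_seed = child_seed(config.master_seed, "subject", si)
            gt = make_ground_truth(config.scenario, config.geometry, sub_seed, config.ground_truth)
            gt_record = {
                "scenario": gt.scenario,
                "stability": {f"{c}:{r}": v for (c, r), v in gt.stability.items()},
                "roi_masks": {k: v.tolist() for k, v in gt.roi_masks.items()},
            }
            (sdir / "ground_truth.json").write_text(json.dumps(gt_record, indent=2, sort_keys=True))

            loc_design = generate_localizer_design(sub_seed, config.localizer)
            loc_bold = simulate_localizer_bold(
                loc_design, gt, config.noise, seed=child_seed(sub_seed, "loc"), hrf_params=config.hrf
            )
            fio.write_events_tsv(loc_design, sdir / "localizer_events.tsv")
            fio.write_bold(loc_bold, sdir / ("localizer" + _bold_ext(config.bold_format)),
                           fmt=config.bold_format, voxel_size_mm=vox)

            metas, designs, behaviors = [], [], []
            for run_id in range(1, config.n_runs + 1):
                design = generate_experimental_design(run_id, sub_seed, config.design)
                behav = simulate_behavior(design, config.behavior, sub_seed)
                designs.append(design)
                behaviors.append(behav)
                tf = design.trial_frame().sort_values("trial_id", ignore_index=True)
                tf["run_id"] = run_id
                tf["response"] = tf["trial_id"].map({r.trial_id: r.response for r in behav})
                metas.append(tf[["trial_id", "run_id", "condition", "response"]])
            session_meta = pd.concat(metas, ignore_index=True)
            amps = {
                roi: draw_session_amplitudes(session_meta, gt, roi, sub_seed)
                for roi in gt.roi_masks
            }
            col = 0
            for design, behav in zip(designs, behaviors):
                n_tr = design.n_trials
                run_amps = {roi: a[:, col:col + n_tr] for roi, a in amps.items()}
                col += n_tr
                bold = simulate_bold_run(
                    design, behav, gt, config.noise,
                    seed=child_seed(sub_seed, "run", design.run_id),
                    amplitudes=run_amps, hrf_params=config.hrf,
                    stim_window=config.analysis.stim_window,
                )
                stem = f"run-{design.run_id:02d}"
                fio.write_events_tsv(design, sdir / f"{stem}_events.tsv", behavior=behav)
                fio.write_bold(bold, sdir / (stem + _bold_ext(config.bold_format)),
                               fmt=config.bold_format, voxel_size_mm=vox)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"simulate stage failed for subject {subject}: {e}") from e
    return out


def _analyze_subject_localizer(
    config: PipelineConfig, sdir: Path
) -> tuple[dict[str, RoiMask], np.ndarray, int]:
    """Localizer GLM + contrast + ROI definition for one subject."""
    a = config.analysis
    loc_design, _ = fio.read_events_tsv(sdir / "localizer_events.tsv")
    loc_bold = fio.read_bold(sdir / ("localizer" + _bold_ext(config.bold_format)))
    if a.smoothing_fwhm_mm > 0:
        loc_bold = BoldRun(
            smooth_volume(loc_bold.data, a.smoothing_fwhm_mm, config.geometry.voxel_size_mm),
            loc_bold.tr_s, loc_bold.run_id,
        )
    dm = build_design_matrix(loc_design, config.hrf, mode="condition", drift_order=a.drift_order)
    pos, neg = a.localizer_contrast
    fit = fit_glm(loc_bold, dm, contrasts={"localizer": {pos: 1.0, neg: -1.0}})
    t_map = fit.contrast_t["localizer"].reshape(config.geometry.shape)
    rois: dict[str, RoiMask] = {}
    for name, spec in config.geometry.rois.items():
        mask = define_roi(
            t_map, fit.dof, p_threshold=a.roi_p_threshold, component_seed=spec.center,
            min_size=a.roi_min_size, connectivity=a.connectivity, name=name,
        )
        if mask is not None:
            rois[name] = mask
    return rois, t_map, fit.dof


def analyze(config: PipelineConfig, input_dir: str | Path, output_dir: str | Path | None = None) -> Report:
    """Run GLM -> MVPA -> inference on artifacts in ``input_dir``."""
    inp = Path(input_dir)
    out = Path(output_dir) if output_dir else inp / "derivatives"
    out.mkdir(parents=True, exist_ok=True)
    a = config.analysis
    behavior_by_subject: dict[str, pd.DataFrame] = {}
    roi_results: dict[str, list] = {name: [] for name in config.geometry.rois}
    matched_results: dict[str, list] = {name: [] for name in config.geometry.rois}
    magnitudes: dict[str, dict] = {name: {} for name in config.geometry.rois}
    excluded: dict[str, list[str]] = {}
    tidy_rows: list[pd.DataFrame] = []

    for si, subject in enumerate(_subjects(config)):
        sdir = inp / subject
        sub_seed = child_seed(config.master_seed, "subject", si)
        try:
            rois, t_map, loc_dof = _analyze_subject_localizer(config, sdir)
            sub_out = out / subject
            sub_out.mkdir(parents=True, exist_ok=True)
            fio.write_tmap_nifti(t_map, sub_out / "localizer_tmap.nii", config.geometry.voxel_size_mm)
            for name in config.geometry.rois:
                if name in rois:
                    fio.write_mask_json(rois[name], sub_out / f"roi_{name}_mask.json")
                else:
                    excluded.setdefault(name, []).append(subject)

            run_paths = sorted(sdir.glob("run-*_events.tsv"))
            designs, behaviors = [], []
            for p in run_paths:
                d, b = fio.read_events_tsv(p)
                designs.append(d)
                behaviors.append(b)
            behavior_by_subject[subject] = pd.concat(
                [
                    pd.DataFrame(
                        [(r.trial_id, d.run_id, r.condition, r.response, r.rt_s) for r in b],
                        columns=["trial_id", "run_id", "condition", "response", "rt_s"],
                    )
                    for d, b in zip(designs, behaviors)
                ],
                ignore_index=True,
            )
            for name, mask in rois.items():
                per_run = []
                for d, b in zip(designs, behaviors):
                    bold = fio.read_bold(sdir / (f"run-{d.run_id:02d}" + _bold_ext(config.bold_format)))
                    te = estimate_trial_betas(
                        bold, d, behavior=b, hrf_params=config.hrf, roi_mask=mask,
                        drift_order=a.drift_order, method=a.beta_method,
                        stim_window=a.stim_window,
                    )
                    te.trial_meta["run_id"] = d.run_id
                    per_run.append(te)
                session = TrialEstimates(
                    np.hstack([t.amplitudes for t in per_run]),
                    pd.concat([t.trial_meta for t in per_run], ignore_index=True),
                    roi=name,
                )
                session = filter_trials(session)
                res = split_half_correlations(
                    session, subject=subject, roi=name, center=a.center, fisher_z=a.fisher_z
                )
                roi_results[name].append(res)
                tidy_rows.append(res.to_frame())
                matched = match_trial_counts(session, seed=child_seed(sub_seed, "match", name))
                matched_results[name].append(
                    split_half_correlations(matched, subject=subject, roi=name,
                                            center=a.center, fisher_z=a.fisher_z)
                )
                magnitudes[name][subject] = {
                    f"{c}:{r}": v for (c, r), v in roi_mean_magnitude(session).items()
                }
                beta_table = session.trial_meta.copy()
                beta_table["mean_amplitude"] = session.amplitudes.mean(axis=0)
                beta_table.to_csv(sub_out / f"betas_{name}.tsv", sep="\t", index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"analyze stage failed for subject {subject}: {e}") from e

    try:
        behav = behavioral_summary(behavior_by_subject, rt_correct_only=a.rt_correct_only)
        roi_results = {k: v for k, v in roi_results.items() if v}
        matched_results = {k: v for k, v in matched_results.items() if v}
        report = compile_report(
            behavioral=behav,
            roi_results=roi_results,
            matched_results=matched_results,
            magnitudes=magnitudes,
            config=json.loads(config.model_dump_json()),
            alpha=a.alpha,
            primary_roi=a.primary_roi,
            excluded_subjects=excluded,
            verdict_on_matched=a.verdict_on_matched,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"inference stage failed: {e}") from e

    if tidy_rows:
        pd.concat(tidy_rows, ignore_index=True).to_csv(
            out / "split_half_correlations.tsv", sep="\t", index=False
        )
    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.render_text())
    return report


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> Report:
    """simulate + analyze in one reproducible pass (the ``full`` command)."""
    out = Path(output_dir or config.output_dir or "facemvpa_output")
    simulate(config, out)
    return analyze(config, out)
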