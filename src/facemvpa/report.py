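"""Assemble group results into a structured, serializable report.

The report gathers behavioral statistics, per-ROI split-half correlations
with their 2x2 within-subject ANOVA and post-hoc tests (raw and with matched
trial counts), the pooled mean-magnitude control, cross-ROI effects, and a
scenario verdict: which hypothetical representation (holistic, parts-based,
both, or null) the data support, decided by which effects crossed alpha.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import SplitHalfResult, cell_key
from .stats import CONTRASTS_2X2, AnovaEffect, TTestResult, paired_t, rm_anova_1df
from .synth import CELLS

__all__ = [
    "Report",
    "cell_table",
    "analyze_cell_table",
    "decide_verdict",
    "compile_report",
    "region_cell_table",
]


def cell_table(results: list[SplitHalfResult]) -> pd.DataFrame:
    """Subjects x 4 table of cell correlations (columns keyed condition:response)."""
    rows = {}
    for res in results:
        rows[res.subject] = {
            cell_key(*cell): res.correlations.get(cell, np.nan) for cell in CELLS
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        [cell_key(*c) for c in CELLS]
    ]


def analyze_cell_table(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """2x2 ANOVA effects plus correct-vs-incorrect post-hocs on one ROI's table."""
    effects = {
        name: rm_anova_1df(table, weights, name=name)
        for name, weights in CONTRASTS_2X2.items()
    }
    posthoc = {
        "veridical": paired_t(
            table[cell_key("veridical", "correct")].to_numpy(),
            table[cell_key("veridical", "incorrect")].to_numpy(),
        ),
        "scrambled": paired_t(
            table[cell_key("scrambled", "correct")].to_numpy(),
            table[cell_key("scrambled", "incorrect")].to_numpy(),
        ),
    }
    group_means = {c: float(np.nanmean(table[c].to_numpy())) for c in table.columns}
    return {
        "effects": effects,
        "posthoc": posthoc,
        "group_mean_r": group_means,
        "alpha": alpha,
    }


def decide_verdict(analysis: dict, alpha: float = 0.05) -> dict:
    """Map significant effects to a scenario label.

    Interaction significant: "holistic" when only the veridical
    correct-vs-incorrect post-hoc is significant, "both" when the scrambled
    one is too, otherwise "indeterminate".  No interaction: "parts_based"
    when the response main effect is significant, else "null".
    """
    effects: dict[str, AnovaEffect] = analysis["effects"]
    post: dict[str, TTestResult] = analysis["posthoc"]
    inter = effects["condition_x_response"]
    resp = effects["response"]

    def sig_pos(t: TTestResult) -> bool:
        return np.isfinite(t.p) and t.p < alpha and t.mean_diff > 0

    inter_sig = np.isfinite(inter.p) and inter.p < alpha
    if inter_sig:
        if sig_pos(post["veridical"]) and not sig_pos(post["scrambled"]):
            label = "holistic"
        elif sig_pos(post["veridical"]) and sig_pos(post["scrambled"]):
            label = "both"
        else:
            label = "indeterminate"
    else:
        label = "parts_based" if (np.isfinite(resp.p) and resp.p < alpha and resp.mean_contrast > 0) else "null"
    return {
        "scenario": label,
        "alpha": alpha,
        "evidence": {
            "interaction_p": inter.p,
            "response_main_p": resp.p,
            "posthoc_veridical_p": post["veridical"].p,
            "posthoc_scrambled_p": post["scrambled"].p,
        },
    }


def region_cell_table(
    table_a: pd.DataFrame, table_b: pd.DataFrame, name_a: str, name_b: str
) -> pd.DataFrame:
    """Subjects x 8 table over two ROIs (columns ``roi|condition:response``).

    Only subjects present in both ROI tables are kept (listwise deletion).
    """
    a = table_a.add_prefix(f"{name_a}|")
    b = table_b.add_prefix(f"{name_b}|")
    return a.join(b, how="inner")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class Report:
    """Structured results document; values are JSON-native after construction."""

    behavioral: dict
    rois: dict
    cross_roi: dict
    verdict: dict
    config: dict = field(default_factory=dict)
    excluded_subjects: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _to_jsonable(dataclasses.asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        d = json.loads(text)
        return cls(
            behavioral=d["behavioral"],
            rois=d["rois"],
            cross_roi=d["cross_roi"],
            verdict=d["verdict"],
            config=d.get("config", {}),
            excluded_subjects=d.get("excluded_subjects", {}),
        )

    def render_text(self) -> str:
        lines = ["facemvpa analysis report", "=" * 40]
        acc = self.behavioral.get("group_accuracy", {})
        if acc:
            lines.append(
                f"behavior: accuracy veridical {100 * acc['veridical']:.1f}%, "
                f"scrambled {100 * acc['scrambled']:.1f}%"
            )
        for roi, block in self.rois.items():
            lines.append(f"\nROI {roi} (n = {block.get('n_subjects', '?')})")
            for name, eff in block.get("analysis", {}).get("effects", {}).items():
                lines.append(
                    f"  {name}: F(1,{eff['df2']}) = {eff['F']:.2f}, p = {eff['p']:.3g}, "
                    f"partial eta^2 = {eff['partial_eta_sq']:.2f}"
                )
            for name, t in block.get("analysis", {}).get("posthoc", {}).items():
                lines.append(
                    f"  post-hoc {name} correct-vs-incorrect: t({t['df']}) = {t['t']:.2f}, "
                    f"p = {t['p']:.3g}, d = {t['d']:.2f}"
                )
        for name, eff in self.cross_roi.items():
            if isinstance(eff, dict) and "F" in eff:
                lines.append(
                    f"\ncross-ROI {name}: F(1,{eff['df2']}) = {eff['F']:.2f}, p = {eff['p']:.3g}"
                )
        lines.append(f"\nverdict: {self.verdict.get('scenario')}")
        return "\n".join(lines)


def compile_report(
    behavioral: dict,
    roi_results: dict[str, list[SplitHalfResult]],
    matched_results: dict[str, list[SplitHalfResult]] | None = None,
    magnitudes: dict[str, dict] | None = None,
    config: dict | None = None,
    alpha: float = 0.05,
    primary_roi: str = "ffa_like",
    excluded_subjects: dict | None = None,
    verdict_on_matched: bool = False,
) -> Report:
    """Build the full report from per-subject split-half results.

    The verdict is decided on ``primary_roi`` (raw analysis by default, the
    matched-count control when ``verdict_on_matched``).
    """
    rois: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}
    for roi, results in roi_results.items():
        table = cell_table(results)
        tables[roi] = table
        block = {
            "n_subjects": int(table.dropna().shape[0]),
            "cell_table": table,
            "analysis": analyze_cell_table(table, alpha),
        }
        if matched_results and roi in matched_results:
            block["matched"] = analyze_cell_table(cell_table(matched_results[roi]), alpha)
        if magnitudes and roi in magnitudes:
            block["mean_magnitude"] = magnitudes[roi]
        rois[roi] = block

    cross: dict = {}
    names = list(roi_results)
    if len(names) >= 2:
        a, b = names[0], names[1]
        wide = region_cell_table(tables[a], tables[b], a, b)
        if wide.dropna().shape[0] >= 2:
            w3 = {}
            for roi_i, roi_name in ((1, a), (-1, b)):
                for cond_i, cond in ((1, "veridical"), (-1, "scrambled")):
                    for resp_i, r_ in ((1, "correct"), (-1, "incorrect")):
                        w3[f"{roi_name}|{cell_key(cond, r_)}"] = roi_i * cond_i * resp_i
            cross["region_x_condition_x_response"] = rm_anova_1df(
                wide, w3, name="region_x_condition_x_response"
            )
            w_scr = {
                f"{a}|{cell_key('scrambled', 'correct')}": 1,
                f"{a}|{cell_key('scrambled', 'incorrect')}": -1,
                f"{b}|{cell_key('scrambled', 'correct')}": -1,
                f"{b}|{cell_key('scrambled', 'incorrect')}": 1,
            }
            cross["region_x_response_scrambled"] = rm_anova_1df(
                wide, w_scr, name="region_x_response_scrambled"
            )

    verdict_block = rois[primary_roi]["matched" if verdict_on_matched and "matched" in rois[primary_roi] else "analysis"]
    verdict = decide_verdict(verdict_block, alpha)

    report = Report(
        behavioral={k: v for k, v in behavioral.items()},
        rois=rois,
        cross_roi=cross,
        verdict=verdict,
        config=config or {},
        excluded_subjects=excluded_subjects or {},
    )
    # normalize to JSON-native values so serialization round-trips losslessly
    d = report.to_dict()
    return Report(
        behavioral=d["behavioral"],
        rois=d["rois"],
        cross_roi=d["cross_roi"],
        verdict=d["verdict"],
        config=d["config"],
        excluded_subjects=d["excluded_subjects"],
    )
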