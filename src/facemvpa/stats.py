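"""Group-level statistics: paired t, 1-df within-subject ANOVA, effect sizes.

All within-subject 1-df effects are computed through contrast scores: per
subject, cell values are combined with weights normalized so the score is a
difference of cell means; the effect's F is the square of the one-sample t of
those scores against zero, with df = (1, n - 1), and

    partial eta^2 = F * df1 / (F * df1 + df2).

This is the standard equivalence between a 1-df repeated-measures ANOVA
effect and the paired t-test on its contrast.  Cohen's d for paired designs
is mean(diff) / sd(diff).  Subjects with a missing cell are dropped listwise
per effect, and the resulting dfs are reported, never assumed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import CELLS, BehavioralRecord, behavior_frame

__all__ = [
    "TTestResult",
    "AnovaEffect",
    "paired_t",
    "one_sample_t",
    "rm_anova_1df",
    "partial_eta_sq",
    "behavioral_summary",
    "CONTRASTS_2X2",
]

#: Standard 2x2 contrast weights over cells ordered as in ``CELLS``
#: (veridical-correct, veridical-incorrect, scrambled-correct,
#: scrambled-incorrect).
CONTRASTS_2X2: dict[str, tuple[float, float, float, float]] = {
    "condition": (1, 1, -1, -1),
    "response": (1, -1, 1, -1),
    "condition_x_response": (1, -1, -1, 1),
}


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    mean_diff: float
    n: int
    degenerate: bool = False  # sd(diff) == 0: t carries no sampling information


@dataclass
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    mean_contrast: float = np.nan
    n: int = 0


def one_sample_t(values: np.ndarray) -> TTestResult:
    """One-sample t of ``values`` against zero (NaNs dropped)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        if m == 0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, d=0.0, mean_diff=0.0, n=n, degenerate=True)
        # nonzero mean with zero spread: no finite t (degenerate signal)
        return TTestResult(t=np.nan, df=n - 1, p=np.nan, d=np.nan, mean_diff=m, n=n, degenerate=True)
    t = m / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, d=m / sd, mean_diff=m, n=n)


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> TTestResult:
    """Paired t-test with Cohen's d = mean(diff)/sd(diff); pairwise deletion."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    return one_sample_t(a[ok] - b[ok])


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Effect size for an ANOVA effect: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def _normalize_weights(w: np.ndarray) -> np.ndarray:
    """Scale weights so the contrast score is a difference of cell means."""
    w = np.asarray(w, dtype=float)
    pos, neg = w[w > 0].sum(), -w[w < 0].sum()
    out = w.copy()
    if pos > 0:
        out[w > 0] /= pos
    if neg > 0:
        out[w < 0] /= neg
    return out


def rm_anova_1df(
    cell_table: pd.DataFrame | np.ndarray,
    contrast_weights: np.ndarray | dict[str, float] | tuple,
    name: str = "effect",
) -> AnovaEffect:
    """A 1-df within-subject ANOVA effect via its contrast score.

    ``cell_table`` is subjects x cells (4 cells for a 2x2, 8 for a 2x2x2);
    ``contrast_weights`` has one weight per cell (or a {column: weight} dict
    for a DataFrame).  Subjects with any missing (NaN) cell are dropped
    listwise; fewer than 2 complete subjects is an error.
    """
    if isinstance(cell_table, pd.DataFrame):
        if isinstance(contrast_weights, dict):
            w = np.array([contrast_weights.get(c, 0.0) for c in cell_table.columns])
        else:
            w = np.asarray(contrast_weights, dtype=float)
        table = cell_table.to_numpy(dtype=float)
    else:
        table = np.asarray(cell_table, dtype=float)
        w = np.asarray(contrast_weights, dtype=float)
    if table.ndim != 2 or table.shape[1] != w.size:
        raise ValueError("contrast weights must match the table's cell count")
    complete = np.isfinite(table).all(axis=1)
    table = table[complete]
    if table.shape[0] < 2:
        raise ValueError("fewer than 2 complete subjects")
    scores = table @ _normalize_weights(w)
    tt = one_sample_t(scores)
    F = tt.t**2 if np.isfinite(tt.t) else np.nan
    df2 = tt.df
    p = float(sps.f.sf(F, 1, df2)) if np.isfinite(F) else np.nan
    pes = partial_eta_sq(F, 1, df2) if np.isfinite(F) else np.nan
    return AnovaEffect(
        name=name, F=float(F), df1=1, df2=df2, p=p, partial_eta_sq=pes,
        mean_contrast=tt.mean_diff, n=tt.n,
    )


def behavioral_summary(
    behavior_by_subject: dict[object, list[BehavioralRecord] | pd.DataFrame],
    rt_correct_only: bool = True,
) -> dict:
    """Per-subject accuracy and mean RT per condition, plus group paired tests.

    Accuracy is correct / (correct + incorrect); RT averages correct trials
    by default.  Subjects lacking valid trials in a condition are dropped
    from the affected test with a warning.
    """
    if len(behavior_by_subject) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for subject, recs in behavior_by_subject.items():
        bf = recs if isinstance(recs, pd.DataFrame) else behavior_frame(recs)
        for condition in ("veridical", "scrambled"):
            sub = bf[(bf["condition"] == condition) & (bf["response"] != "none")]
            if len(sub) == 0:
                warnings.warn(
                    f"subject {subject!r} has no valid {condition} trials; dropped",
                    stacklevel=2,
                )
                acc = np.nan
                rt = np.nan
            else:
                acc = float((sub["response"] == "correct").mean())
                rt_sub = sub[sub["response"] == "correct"] if rt_correct_only else sub
                rt = float(rt_sub["rt_s"].mean()) if len(rt_sub) else np.nan
            rows.append({"subject": subject, "condition": condition, "accuracy": acc, "mean_rt_s": rt})
    table = pd.DataFrame(rows)
    wide_acc = table.pivot(index="subject", columns="condition", values="accuracy")
    wide_rt = table.pivot(index="subject", columns="condition", values="mean_rt_s")
    acc_test = paired_t(wide_acc["veridical"].to_numpy(), wide_acc["scrambled"].to_numpy())
    rt_test = paired_t(wide_rt["veridical"].to_numpy(), wide_rt["scrambled"].to_numpy())
    return {
        "per_subject": table,
        "group_accuracy": {
            "veridical": float(np.nanmean(wide_acc["veridical"])),
            "scrambled": float(np.nanmean(wide_acc["scrambled"])),
        },
        "group_mean_rt_s": {
            "veridical": float(np.nanmean(wide_rt["veridical"])),
            "scrambled": float(np.nanmean(wide_rt["scrambled"])),
        },
        "accuracy_test": acc_test,
        "rt_test": rt_test,
    }
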