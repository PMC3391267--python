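"""Behavior-sorted odd/even split-half spatial-pattern correlation.

For one subject and ROI, trials are split by run parity into odd and even
halves.  Within each half the voxel x trial amplitudes are averaged in each
of the four condition-by-response cells; each voxel's mean across the four
cell patterns of that half is subtracted (cocktail-blank centering); and the
Pearson correlation between the odd and even centered pattern of the SAME
cell is the reliability statistic.  Cells with no trials in a half, or a
zero-variance centered vector, yield NaN (flagged, never silently 0), which
downstream inference treats as subject exclusion for the affected contrast.

Controls: :func:`match_trial_counts` equalizes trial counts across the two
stimulus conditions within each response type and half (the matched-trial
control), and :func:`roi_mean_magnitude` gives the pooled-activation analogue
of the traditional magnitude analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .glm import TrialEstimates
from .synth import CELLS

__all__ = [
    "SplitHalfResult",
    "filter_trials",
    "split_half_correlations",
    "match_trial_counts",
    "roi_mean_magnitude",
    "cell_key",
    "HALVES",
]

HALVES = ("odd", "even")


def cell_key(condition: str, response: str) -> str:
    """Stable string key for a (condition, response) cell."""
    return f"{condition}:{response}"


def _halves_of(meta: pd.DataFrame) -> np.ndarray:
    return np.where(meta["run_id"].to_numpy().astype(int) % 2 == 1, "odd", "even")


@dataclass
class SplitHalfResult:
    """Per-subject, per-ROI split-half correlations for the four cells."""

    correlations: dict[tuple[str, str], float]  # NaN marks an undefined cell
    n_trials: dict[str, dict[tuple[str, str], int]]  # half -> cell -> count
    subject: object = None
    roi: str | None = None
    fisher_z: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Tidy rows: subject, roi, condition, response, r, n_odd, n_even."""
        rows = []
        for cell in CELLS:
            rows.append(
                {
                    "subject": self.subject,
                    "roi": self.roi,
                    "condition": cell[0],
                    "response": cell[1],
                    "r": self.correlations.get(cell, np.nan),
                    "n_odd": self.n_trials["odd"].get(cell, 0),
                    "n_even": self.n_trials["even"].get(cell, 0),
                }
            )
        return pd.DataFrame(rows)


def filter_trials(trial_estimates: TrialEstimates) -> TrialEstimates:
    """Drop trials without a behavioral response; error if none remain."""
    resp = trial_estimates.trial_meta["response"].to_numpy()
    keep = resp != "none"
    if not keep.any():
        raise ValueError("all trials lack a response; nothing to analyze")
    return trial_estimates.select(keep)


def split_half_correlations(
    trial_estimates: TrialEstimates,
    subject: object = None,
    roi: str | None = None,
    center: bool = True,
    fisher_z: bool = False,
) -> SplitHalfResult:
    """Odd/even split-half Pearson correlation per condition-response cell.

    ``center`` applies cocktail-blank centering (on by default, as in the
    published analysis); ``fisher_z`` additionally arctanh-transforms the
    correlations (off by default).
    """
    te = trial_estimates
    if te.n_voxels < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    halves = _halves_of(te.trial_meta)
    cond = te.trial_meta["condition"].to_numpy()
    resp = te.trial_meta["response"].to_numpy()
    mean_patterns: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    counts: dict[str, dict[tuple[str, str], int]] = {}
    for half in HALVES:
        pats, ns = {}, {}
        for cell in CELLS:
            sel = (cond == cell[0]) & (resp == cell[1]) & (halves == half)
            ns[cell] = int(sel.sum())
            if ns[cell] > 0:
                pats[cell] = te.amplitudes[:, sel].mean(axis=1)
        if center and pats:
            grand = np.mean(list(pats.values()), axis=0)
            pats = {cell: v - grand for cell, v in pats.items()}
        mean_patterns[half] = pats
        counts[half] = ns
    corrs: dict[tuple[str, str], float] = {}
    for cell in CELLS:
        a = mean_patterns["odd"].get(cell)
        b = mean_patterns["even"].get(cell)
        if a is None or b is None:
            corrs[cell] = np.nan
            continue
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(
                f"zero-variance centered pattern in cell {cell}; correlation undefined",
                stacklevel=2,
            )
            corrs[cell] = np.nan
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        corrs[cell] = float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))) if fisher_z else r
    return SplitHalfResult(
        correlations=corrs, n_trials=counts, subject=subject, roi=roi, fisher_z=fisher_z
    )


def match_trial_counts(trial_estimates: TrialEstimates, seed: int = 0) -> TrialEstimates:
    """Equalize trial counts across stimulus conditions within response x half.

    Within each (response type, half), the condition with more trials is
    randomly subsampled (seeded, without replacement) to the other
    condition's count; a zero-count cell leaves its response type unmatched
    with a warning.  A single subsample is drawn per seed.
    """
    te = trial_estimates
    halves = _halves_of(te.trial_meta)
    cond = te.trial_meta["condition"].to_numpy()
    resp = te.trial_meta["response"].to_numpy()
    rng = np.random.default_rng(child_seed(seed, "match_trial_counts"))
    keep = np.ones(te.n_trials, dtype=bool)
    for half in HALVES:
        for response in ("correct", "incorrect"):
            sel_v = np.flatnonzero((cond == "veridical") & (resp == response) & (halves == half))
            sel_s = np.flatnonzero((cond == "scrambled") & (resp == response) & (halves == half))
            if sel_v.size == 0 or sel_s.size == 0:
                if sel_v.size != sel_s.size:
                    warnings.warn(
                        f"cell with zero trials in half {half!r}, response {response!r}; "
                        "left unmatched",
                        stacklevel=2,
                    )
                continue
            big, small_n = (sel_v, sel_s.size) if sel_v.size > sel_s.size else (sel_s, sel_v.size)
            if big.size == small_n:
                continue
            drop = rng.choice(big, size=big.size - small_n, replace=False)
            keep[drop] = False
    return te.select(keep)


def roi_mean_magnitude(
    trial_estimates: TrialEstimates,
) -> dict[tuple[str, str], float]:
    """Grand mean amplitude over ROI voxels and trials, per cell (both halves).

    Empty cells come back NaN (absent-value flag).
    """
    te = trial_estimates
    cond = te.trial_meta["condition"].to_numpy()
    resp = te.trial_meta["response"].to_numpy()
    out: dict[tuple[str, str], float] = {}
    for cell in CELLS:
        sel = (cond == cell[0]) & (resp == cell[1])
        if not sel.any():
            warnings.warn(f"empty cell {cell}; mean magnitude absent", stacklevel=2)
            out[cell] = np.nan
        else:
            out[cell] = float(te.amplitudes[:, sel].mean())
    return out
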