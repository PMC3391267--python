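"""Gamma HRF, design matrices, run-level GLM, trial-wise betas, ROI definition.

The hemodynamic response is the FS-FAST gamma form with onset delay ``delta``
and dispersion ``tau``::

    h(t) = ((t - delta) / tau)**alpha * exp(-(t - delta) / tau),   t > delta

peak-normalized to 1 (the analytic peak sits at ``t = delta + alpha * tau``).
Regressors are boxcars convolved with h on an oversampled grid (0.1 s) and
sampled at scan acquisition midpoints ``t = (k + 0.5) * TR``.  Trial-wise
response amplitudes use a least-squares-all model (every trial its own
regressor in one run-level GLM), with a least-squares-separate variant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator
from scipy import ndimage, stats

from .design import FIXATION, EventDesign

__all__ = [
    "HrfParams",
    "DesignMatrix",
    "GlmFit",
    "RoiMask",
    "BoldRun",
    "TrialEstimates",
    "gamma_hrf",
    "build_design_matrix",
    "fit_glm",
    "estimate_trial_betas",
    "smooth_volume",
    "define_roi",
    "DEFAULT_STIM_WINDOW",
]

#: Compound-trial boxcar: the stimulation window of a trial, from first-image
#: onset (0.7 s after trial start) to second-image offset (2.2 s), i.e. 1.5 s.
DEFAULT_STIM_WINDOW: tuple[float, float] = (0.7, 1.5)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class HrfParams(BaseModel):
    """Gamma HRF parameters (onset delay, dispersion, shape exponent)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    delta_s: float = 2.25
    tau_s: float = 1.25
    alpha: float = 2.0

    @field_validator("tau_s", "alpha")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("tau_s and alpha must be positive")
        return v

    @field_validator("delta_s")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("delta_s must be non-negative")
        return v

    @property
    def peak_time_s(self) -> float:
        return self.delta_s + self.alpha * self.tau_s


def gamma_hrf(time_grid: np.ndarray, hrf_params: HrfParams | None = None) -> np.ndarray:
    """Evaluate the peak-normalized gamma HRF on ``time_grid`` (seconds)."""
    p = hrf_params or HrfParams()
    t = np.asarray(time_grid, dtype=float)
    out = np.zeros_like(t)
    m = t > p.delta_s
    x = (t[m] - p.delta_s) / p.tau_s
    out[m] = x**p.alpha * np.exp(-x)
    peak = p.alpha**p.alpha * np.exp(-p.alpha)  # value at x = alpha
    return out / peak


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # scans x regressors
    regressor_names: list[str]
    regressor_kinds: list[str]  # {"trial", "condition", "drift", "constant"}

    def columns_of_kind(self, kind: str) -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.regressor_kinds) if k == kind], dtype=int
        )

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Build a contrast vector from {regressor name: weight}."""
        unknown = set(weights) - set(self.regressor_names)
        if unknown:
            raise KeyError(f"unknown regressors in contrast: {sorted(unknown)}")
        c = np.zeros(len(self.regressor_names))
        for name, w in weights.items():
            c[self.regressor_names.index(name)] = w
        return c


@dataclass
class GlmFit:
    betas: np.ndarray  # regressors x voxels
    residual_variance: np.ndarray  # per voxel
    dof: int
    contrast_t: dict[str, np.ndarray] = field(default_factory=dict)
    contrast_effect: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class RoiMask:
    """A connected set of voxels defined by a localizer contrast threshold."""

    voxel_indices: np.ndarray  # sorted flat indices into the 3-D grid
    name: str
    threshold_p: float
    component_seed: tuple[int, int, int] | None = None

    @property
    def size(self) -> int:
        return int(self.voxel_indices.size)

    def to_flat_bool(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(int(np.prod(shape)), dtype=bool)
        m[self.voxel_indices] = True
        return m


@dataclass
class BoldRun:
    """4-D voxel x time BOLD signal for one run."""

    data: np.ndarray  # (nx, ny, nz, n_scans)
    tr_s: float
    run_id: int

    @property
    def n_scans(self) -> int:
        return int(self.data.shape[-1])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def flat(self) -> np.ndarray:
        """Time x voxel view (scans x n_voxels, C voxel order)."""
        return self.data.reshape(-1, self.data.shape[-1]).T


@dataclass
class TrialEstimates:
    """Voxel x trial response amplitudes joined with trial metadata."""

    amplitudes: np.ndarray  # voxels x trials
    trial_meta: pd.DataFrame  # columns: trial_id, run_id, condition, response
    roi: str | None = None

    def __post_init__(self) -> None:
        if self.amplitudes.shape[1] != len(self.trial_meta):
            raise ValueError("amplitude columns must match metadata rows")

    @property
    def n_trials(self) -> int:
        return int(self.amplitudes.shape[1])

    @property
    def n_voxels(self) -> int:
        return int(self.amplitudes.shape[0])

    def select(self, mask: np.ndarray) -> "TrialEstimates":
        """Subset trials by boolean mask or integer index, keeping order."""
        meta = self.trial_meta.iloc[mask].reset_index(drop=True)
        return TrialEstimates(self.amplitudes[:, mask], meta, roi=self.roi)


def _oversampled_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr_s: float,
    hrf_params: HrfParams,
    dt: float,
) -> np.ndarray:
    """Boxcar-convolved-with-HRF regressor sampled at scan midpoints."""
    span = n_scans * tr_s
    n_fine = int(round(span / dt))
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0:min(i1, n_fine)] = 1.0
    kernel_t = np.arange(0.0, hrf_params.delta_s + 16.0 * hrf_params.tau_s, dt)
    kernel = gamma_hrf(kernel_t, hrf_params)
    conv = np.convolve(box, kernel)[:n_fine] * dt
    scan_idx = np.floor(((np.arange(n_scans) + 0.5) * tr_s) / dt).astype(int)
    return conv[np.minimum(scan_idx, n_fine - 1)]


def _drift_columns(n_scans: int, drift_order: int) -> np.ndarray:
    """Legendre polynomial drift columns of order 1..drift_order."""
    if drift_order <= 0:
        return np.empty((n_scans, 0))
    x = np.linspace(-1.0, 1.0, n_scans)
    cols = [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(1, drift_order + 1)]
    return np.column_stack(cols)


def build_design_matrix(
    design: EventDesign,
    hrf_params: HrfParams | None = None,
    mode: str = "condition",
    drift_order: int = 1,
    oversample_dt: float = 0.1,
    stim_window: tuple[float, float] | None = None,
) -> DesignMatrix:
    """Construct a scans x regressors matrix for one run.

    ``mode='condition'`` gives one column per non-fixation condition (blocks
    and trials pooled); ``mode='trial'`` one column per trial_id, in trial_id
    order.  ``stim_window=(offset_s, duration_s)`` replaces each stimulus
    event's boxcar by the compound-trial stimulation window; ``None`` uses
    the event's own duration.  Polynomial drift columns up to ``drift_order``
    and a constant are appended.
    """
    p = hrf_params or HrfParams()
    if mode not in ("condition", "trial"):
        raise ValueError(f"unknown mode {mode!r}")
    stim_events = [e for e in design.events if e.condition != FIXATION]

    def window(e) -> tuple[float, float]:
        if stim_window is None:
            return e.onset_s, e.duration_s
        off, dur = stim_window
        return e.onset_s + off, dur

    cols, names, kinds = [], [], []
    if mode == "condition":
        for cond in sorted({e.condition for e in stim_events}):
            evs = [window(e) for e in stim_events if e.condition == cond]
            onsets = np.array([w[0] for w in evs])
            durs = np.array([w[1] for w in evs])
            cols.append(
                _oversampled_regressor(onsets, durs, design.n_scans, design.tr_s, p, oversample_dt)
            )
            names.append(cond)
            kinds.append("condition")
    else:
        trials = sorted(
            (e for e in stim_events if e.trial_id is not None), key=lambda e: e.trial_id
        )
        for e in trials:
            onset, dur = window(e)
            cols.append(
                _oversampled_regressor(
                    np.array([onset]), np.array([dur]), design.n_scans, design.tr_s, p, oversample_dt
                )
            )
            names.append(f"trial_{e.trial_id:04d}")
            kinds.append("trial")

    drift = _drift_columns(design.n_scans, drift_order)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
        kinds.append("drift")
    cols.append(np.ones(design.n_scans))
    names.append("constant")
    kinds.append("constant")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cond_number = np.linalg.cond(X)
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}, "
            f"condition number {cond_number:.3g})",
            stacklevel=2,
        )
    return DesignMatrix(X, names, kinds)


def fit_glm(
    bold: BoldRun | np.ndarray,
    design_matrix: DesignMatrix,
    contrasts: dict[str, dict[str, float]] | None = None,
) -> GlmFit:
    """Ordinary least squares per voxel, with t-maps for named contrasts.

    ``bold`` may be a :class:`BoldRun` or a scans x voxels array.  Contrasts
    map a name to ``{regressor_name: weight}``.
    """
    Y = bold.flat() if isinstance(bold, BoldRun) else np.asarray(bold, dtype=float)
    X = design_matrix.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"scan count mismatch: data {Y.shape[0]}, design {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    xtx = X.T @ X
    if rank < X.shape[1]:
        warnings.warn("singular normal equations; using pseudo-inverse", stacklevel=2)
        xtx_inv = np.linalg.pinv(xtx)
    else:
        xtx_inv = np.linalg.inv(xtx)
    betas = xtx_inv @ X.T @ Y
    resid = Y - X @ betas
    dof = Y.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / max(dof, 1)
    fit = GlmFit(betas=betas, residual_variance=sigma2, dof=dof)
    for name, wts in (contrasts or {}).items():
        c = design_matrix.contrast_vector(wts)
        effect = c @ betas
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            tmap = np.where(var > 0, effect / np.sqrt(var), 0.0)
        fit.contrast_t[name] = tmap
        fit.contrast_effect[name] = effect
    return fit


def estimate_trial_betas(
    bold_run: BoldRun,
    design: EventDesign,
    behavior: "pd.DataFrame | list | None" = None,
    hrf_params: HrfParams | None = None,
    roi_mask: RoiMask | np.ndarray | None = None,
    drift_order: int = 1,
    method: str = "lsa",
    stim_window: tuple[float, float] | None = DEFAULT_STIM_WINDOW,
    max_regressor_r: float = 0.99,
) -> TrialEstimates:
    """Trial-wise BOLD response amplitudes for one run.

    ``method='lsa'`` (default) fits all trials in one GLM with linear drift;
    ``'lss'`` fits one GLM per trial with the remaining trials pooled.
    ``behavior`` (records or a frame with trial_id/response columns) supplies
    correctness labels; trials without a record are labeled ``'none'``.
    Rejects designs in which any two trial regressors correlate above
    ``max_regressor_r`` in absolute value (unestimable).
    """
    dm = build_design_matrix(
        design, hrf_params, mode="trial", drift_order=drift_order, stim_window=stim_window
    )
    tcols = dm.columns_of_kind("trial")
    if tcols.size == 0:
        raise ValueError("design has no trials")
    T = dm.matrix[:, tcols]
    if T.shape[1] >= 2:
        cc = np.corrcoef(T.T)
        off = np.abs(cc[np.triu_indices_from(cc, k=1)])
        if np.any(off > max_regressor_r):
            raise ValueError(
                f"trial regressors nearly collinear (max |r| = {off.max():.4f} "
                f"> {max_regressor_r}); trials unestimable"
            )
    Y = bold_run.flat()
    if roi_mask is not None:
        flat_idx = (
            roi_mask.voxel_indices if isinstance(roi_mask, RoiMask) else np.asarray(roi_mask)
        )
        Y = Y[:, flat_idx]

    if method == "lsa":
        fit = fit_glm(Y, dm)
        amps = fit.betas[tcols, :].T  # voxels x trials
    elif method == "lss":
        amps = np.empty((Y.shape[1], T.shape[1]))
        nuis = dm.matrix[:, [i for i in range(dm.matrix.shape[1]) if i not in set(tcols)]]
        for j in range(T.shape[1]):
            others = np.delete(T, j, axis=1).sum(axis=1, keepdims=True)
            Xj = np.column_stack([T[:, [j]], others, nuis])
            beta = np.linalg.lstsq(Xj, Y, rcond=None)[0]
            amps[:, j] = beta[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    tf = design.trial_frame()
    meta = pd.DataFrame(
        {
            "trial_id": tf["trial_id"].to_numpy(),
            "run_id": design.run_id,
            "condition": tf["condition"].to_numpy(),
        }
    ).sort_values("trial_id", ignore_index=True)
    responses = pd.Series("none", index=meta["trial_id"])
    if behavior is not None:
        bf = behavior if isinstance(behavior, pd.DataFrame) else pd.DataFrame(
            [{"trial_id": r.trial_id, "response": r.response} for r in behavior]
        )
        responses.update(bf.set_index("trial_id")["response"])
    meta["response"] = responses.to_numpy()
    return TrialEstimates(amps, meta)


def smooth_volume(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: tuple[float, float, float]
) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D (or 4-D, per-frame) volume.

    ``fwhm_mm = 0`` is the identity.  Sigma per axis is
    ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel units.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return volume
    sig = [fwhm_mm * _FWHM_TO_SIGMA / v for v in voxel_size_mm]
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 4:
        return ndimage.gaussian_filter(vol, sigma=sig + [0.0])
    return ndimage.gaussian_filter(vol, sigma=sig)


def define_roi(
    t_map: np.ndarray,
    dof: int,
    p_threshold: float = 0.01,
    component_seed: tuple[int, int, int] | None = None,
    min_size: int = 1,
    connectivity: int = 26,
    name: str = "roi",
) -> RoiMask | None:
    """Threshold a 3-D t-map (one-tailed) and return one connected component.

    The component containing ``component_seed`` is returned; if the seed voxel
    is sub-threshold, the nearest surviving component is used.  Components
    smaller than ``min_size`` are ignored.  Returns ``None`` when nothing
    survives -- the subject-exclusion signal.
    """
    t_map = np.asarray(t_map)
    if t_map.ndim != 3:
        raise ValueError("t_map must be 3-D")
    thr = stats.t.isf(p_threshold, dof)
    supra = t_map > thr
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n_lab = ndimage.label(supra, structure=structure)
    sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n_lab + 1))
    keep = [lab for lab in range(1, n_lab + 1) if sizes[lab - 1] >= min_size]
    if not keep:
        return None
    if component_seed is not None:
        seed_lab = labels[tuple(component_seed)]
        if seed_lab in keep:
            chosen = seed_lab
        else:
            seed = np.asarray(component_seed, dtype=float)
            best, best_d = None, np.inf
            for lab in keep:
                coords = np.argwhere(labels == lab)
                d = np.sqrt(((coords - seed) ** 2).sum(axis=1)).min()
                if d < best_d:
                    best, best_d = lab, d
            chosen = best
    else:
        chosen = keep[int(np.argmax([sizes[lab - 1] for lab in keep]))]
    flat = np.flatnonzero((labels == chosen).ravel())
    return RoiMask(
        voxel_indices=np.sort(flat),
        name=name,
        threshold_p=p_threshold,
        component_seed=tuple(component_seed) if component_seed is not None else None,
    )
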