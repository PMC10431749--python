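"""Least-squares-separate (LSS) single-trial GLM.

Each trial receives its own general linear model containing a trial-specific
regressor, one pooled regressor for all other trials of the same run, six
motion regressors and an intercept.  Trial regressors are 1.2-s boxcars
convolved with a canonical double-gamma haemodynamic response function.  The
per-trial coefficient images are the voxel patterns that all similarity
analyses operate on.

Ordinary least squares only: no temporal filtering, prewhitening or
autocorrelation model is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "BoldRun",
    "BetaImage",
    "DesignError",
    "canonical_hrf",
    "hrf_dense",
    "convolve_trials",
    "build_lss_design",
    "fit_trial_betas",
]

# canonical double-gamma parameters (SPM convention): response gamma with
# peak delay 6 s, undershoot gamma with delay 16 s, unit dispersions,
# peak:undershoot amplitude ratio 6, kernel length 32 s.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0
HRF_LENGTH_S = 32.0

_CONV_DT = 0.1  # convolution oversampling step (s); 1.2-s events are sub-TR


class DesignError(ValueError):
    """Invalid event timing or design matrix."""


@dataclass
class BoldRun:
    """One preprocessed BOLD run on a common voxel grid.

    data: 4D array (x, y, z, time); motion: (time, 6) parameter table.
    """

    data: np.ndarray
    tr_s: float
    motion: np.ndarray
    run_id: int
    phase: str

    def __post_init__(self):
        if self.tr_s <= 0:
            raise DesignError("tr_s must be positive")
        if self.data.shape[-1] != self.motion.shape[0]:
            raise DesignError("motion length does not match time axis")

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]


@dataclass
class BetaImage:
    """Stack of trial-wise beta patterns restricted to a mask.

    betas: (n_trials, n_in_mask_voxels); row order matches ``trials``.
    """

    betas: np.ndarray
    trials: pd.DataFrame
    mask: np.ndarray
    affine: np.ndarray
    voxel_size_mm: float
    bad_trials: list = field(default_factory=list)

    def __post_init__(self):
        if self.betas.shape[0] != len(self.trials):
            raise ValueError("beta row count does not match trial table")
        if self.betas.shape[1] != int(self.mask.sum()):
            raise ValueError("beta column count does not match mask voxel count")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def volume(self, i: int) -> np.ndarray:
        """Scatter trial ``i`` back onto the 3D grid (NaN outside mask)."""
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.betas[i]
        return vol

    def to_4d(self) -> np.ndarray:
        out = np.full(self.mask.shape + (self.n_trials,), np.nan)
        out[self.mask, :] = self.betas.T
        return out


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp - gammaln(shape)) / scale
    return out


def hrf_dense(t: np.ndarray) -> np.ndarray:
    """Un-normalized double-gamma response evaluated at arbitrary times."""
    return (
        _gamma_pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, HRF_PEAK_DISP)
        - _gamma_pdf(t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, HRF_UNDERSHOOT_DISP)
        / HRF_RATIO
    )


def canonical_hrf(tr_s: float) -> np.ndarray:
    """Canonical HRF sampled every ``tr_s`` seconds over 32 s, peak-normalized.

    The value at t = 0 is exactly 0 and the kernel maximum is 1.
    """
    if tr_s <= 0:
        raise DesignError("tr_s must be positive")
    t = np.arange(0.0, HRF_LENGTH_S + 0.5 * tr_s, tr_s)
    h = hrf_dense(t)
    return h / np.max(h)


def convolve_trials(
    onsets: np.ndarray,
    duration_s: float,
    tr_s: float,
    n_scans: int,
    dt: float = _CONV_DT,
) -> np.ndarray:
    """Boxcar-convolved trial regressors sampled on the scan grid.

    Convolution is carried out on a ``dt``-spaced grid (default 0.1 s) and
    downsampled at scan acquisition times; returns (n_scans, n_trials).
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if np.any(onsets < 0):
        raise DesignError("negative trial onset")
    run_len = n_scans * tr_s
    if np.any(onsets + duration_s > run_len):
        raise DesignError("trial onsets exceed run length")
    t_hi = np.arange(0.0, run_len, dt)
    kernel = hrf_dense(np.arange(0.0, HRF_LENGTH_S + dt, dt))
    kernel = kernel / kernel.max()
    out = np.empty((n_scans, onsets.size))
    scan_idx = np.round(np.arange(n_scans) * tr_s / dt).astype(int)
    for j, onset in enumerate(onsets):
        box = ((t_hi >= onset) & (t_hi < onset + duration_s)).astype(float)
        conv = np.convolve(box, kernel)[: t_hi.size]
        out[:, j] = conv[scan_idx]
    return out


def build_lss_design(
    trials: pd.DataFrame,
    trial_id,
    run: BoldRun,
    duration_s: float = 1.2,
) -> tuple[np.ndarray, list]:
    """LSS design matrix for one target trial.

    Columns: [target trial, all other trials pooled, 6 motion, intercept].
    The pooled column sums the convolved regressors of every other trial in
    the run (both stimulus categories); it is dropped for single-trial runs.
    """
    if trial_id not in trials.index:
        raise KeyError(f"trial {trial_id!r} not found in this run")
    onsets = trials["onset_s"].to_numpy(dtype=float)
    reg = convolve_trials(onsets, duration_s, run.tr_s, run.n_scans)
    target_pos = trials.index.get_loc(trial_id)
    target = reg[:, target_pos]
    others_mask = np.ones(reg.shape[1], dtype=bool)
    others_mask[target_pos] = False
    cols = [target]
    names = ["target"]
    if others_mask.any():
        cols.append(reg[:, others_mask].sum(axis=1))
        names.append("others")
    # all-zero motion columns (e.g. motion-free simulations) carry no
    # information and would only make the design rank-deficient
    keep_motion = np.ptp(run.motion, axis=0) > 0
    if keep_motion.any():
        cols.append(run.motion[:, keep_motion])
        names += [f"motion{k}" for k in np.flatnonzero(keep_motion)]
    cols.append(np.ones(run.n_scans))
    names.append("intercept")
    X = np.column_stack(cols)
    return X, names


def fit_trial_betas(
    run: BoldRun,
    trials: pd.DataFrame,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    voxel_size_mm: float = 2.0,
    duration_s: float = 1.2,
) -> BetaImage:
    """One OLS fit per trial; rows are the trial-specific coefficients.

    Rank-deficient designs are flagged and the affected trial is set to
    missing rather than silently fitted.
    """
    if mask.shape != run.data.shape[:-1]:
        raise DesignError("mask does not match data grid")
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    Y = run.data[mask].T.astype(float)  # (n_scans, V)
    betas = np.empty((len(trials), Y.shape[1]))
    bad = []
    for i, trial_id in enumerate(trials.index):
        X, _ = build_lss_design(trials, trial_id, run, duration_s=duration_s)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"rank-deficient design for trial {trial_id!r}; set to NaN")
            betas[i] = np.nan
            bad.append(trial_id)
            continue
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        betas[i] = coef[0]
    return BetaImage(
        betas=betas,
        trials=trials.copy(),
        mask=mask.astype(bool),
        affine=affine,
        voxel_size_mm=voxel_size_mm,
        bad_trials=bad,
    )
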