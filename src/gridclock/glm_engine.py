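"""Design-matrix construction and per-voxel ordinary least squares.

Regressors are built on a microtime grid (16 bins per TR), convolved with
the canonical double-gamma HRF, and decimated back to TR resolution.  The
directional modulators cos(n*theta_t) and sin(n*theta_t) scale the
imagination-period boxcar; they are mean-centered across trials before
convolution so the unmodulated response loads on the boxcar itself.  Slow
drifts are absorbed by a discrete-cosine high-pass basis; jump periods and
the target-to-response period enter as regressors of no interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

MICROTIME_BINS = 16
DEFAULT_HIGHPASS_HZ = 1.0 / 128.0


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # timepoints x columns
    names: list[str]
    tr_s: float
    highpass_cutoff_hz: float

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def column(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class GLMFit:
    betas: np.ndarray            # voxels x columns
    residual_variance: np.ndarray  # per voxel
    dof: int
    names: list[str]

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at microtime resolution.

    Peak at ~5 s, undershoot at ~15 s, peak:undershoot ratio 6, unit peak.
    Returned on the microtime grid (``tr_s / 16`` spacing).
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    dt = tr_s / MICROTIME_BINS
    t = np.arange(0, duration_s, dt)
    h = gamma_dist.pdf(t, a=6, scale=1.0) - gamma_dist.pdf(t, a=16, scale=1.0) / 6.0
    return h / h.max()


def dct_highpass_basis(n_scans: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis: all components slower than the cutoff.

    The number of retained components is floor(2 * T * cutoff) for a run of
    T seconds, matching the standard high-pass filter construction.
    """
    duration = n_scans * tr_s
    k_max = int(np.floor(2.0 * duration * cutoff_hz))
    t = np.arange(n_scans)
    basis = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(basis) if basis else np.empty((n_scans, 0))


def boxcar_microtime(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr_s: float,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Amplitude-weighted boxcar sampled on the microtime grid."""
    dt = tr_s / MICROTIME_BINS
    n_micro = n_scans * MICROTIME_BINS
    x = np.zeros(n_micro)
    if amplitudes is None:
        amplitudes = np.ones(len(onsets))
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        if i1 > n_micro:
            raise ValueError("event extends beyond run duration")
        x[i0:i1] += amp
    return x


def convolve_decimate(x_micro: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    """HRF-convolve a microtime regressor and sample at TR (slice midpoint)."""
    conv = fftconvolve(x_micro, hrf)[: len(x_micro)]
    return conv[MICROTIME_BINS // 2 :: MICROTIME_BINS]


def no_interest_columns(
    events: pd.DataFrame, n_scans: int, tr_s: float, hrf: np.ndarray
) -> list[tuple[np.ndarray, str]]:
    """Convolved regressors of no interest: cue periods, jump periods, and
    the target-to-response period."""
    out = []
    cue = events[events["trial_type"].isin(["start_cue", "end_cue"])]
    if not cue.empty:
        x = boxcar_microtime(
            cue["onset"].to_numpy(float), cue["duration"].to_numpy(float), n_scans, tr_s
        )
        out.append((convolve_decimate(x, hrf), "cue"))
    jump = events[events["trial_type"] == "jump"]
    if not jump.empty:
        x = boxcar_microtime(
            jump["onset"].to_numpy(float), jump["duration"].to_numpy(float), n_scans, tr_s
        )
        out.append((convolve_decimate(x, hrf), "jump"))
    tgt = events[events["trial_type"] == "target"]
    resp = events[events["trial_type"] == "response"]
    if not tgt.empty and not resp.empty:
        t_on = tgt["onset"].to_numpy(float)
        t_end = resp["onset"].to_numpy(float) + resp["duration"].to_numpy(float)
        x = boxcar_microtime(t_on, t_end - t_on, n_scans, tr_s)
        out.append((convolve_decimate(x, hrf), "target_response"))
    return out


def _imagination_trials(events: pd.DataFrame) -> pd.DataFrame:
    imag = events[events["trial_type"] == "imagination"]
    if imag.empty:
        raise ValueError("no imagination events in table")
    return imag


def build_design(
    events: pd.DataFrame,
    fold_n: int,
    tr_s: float,
    n_scans: int,
    reference_phase: float | None = None,
    highpass_cutoff_hz: float = DEFAULT_HIGHPASS_HZ,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Per-run design matrix for the directional-modulation GLM.

    With ``reference_phase`` omitted this is the estimation model: the
    imagination boxcar plus two parametric modulators cos(n*theta) and
    sin(n*theta).  With ``reference_phase`` given it is the test model: a
    single modulator cos(n*(theta - phi)) realigned to the estimated grid
    orientation phi (degrees).  Jump and target-to-response periods are
    regressors of no interest; a DCT basis below the cutoff and an
    intercept complete the matrix.
    """
    if highpass_cutoff_hz >= 1.0 / (2.0 * tr_s):
        raise ValueError("high-pass cutoff at or above Nyquist")
    hrf = canonical_hrf(tr_s)
    imag = _imagination_trials(events)
    onsets = imag["onset"].to_numpy(float)
    durs = imag["duration"].to_numpy(float)
    if np.any(onsets + durs > n_scans * tr_s):
        raise ValueError("events outside run duration")
    theta = np.deg2rad(imag["angle_deg"].to_numpy(float))

    cols: list[np.ndarray] = []
    names: list[str] = []

    box = boxcar_microtime(onsets, durs, n_scans, tr_s)
    cols.append(convolve_decimate(box, hrf))
    names.append("imagination")

    if reference_phase is None:
        mods = {
            f"cos{fold_n}theta": np.cos(fold_n * theta),
            f"sin{fold_n}theta": np.sin(fold_n * theta),
        }
    else:
        phi = np.deg2rad(reference_phase)
        mods = {f"cos{fold_n}aligned": np.cos(fold_n * (theta - phi))}
    for name, amp in mods.items():
        amp = amp - amp.mean()  # center across trials before convolution
        x = boxcar_microtime(onsets, durs, n_scans, tr_s, amplitudes=amp)
        cols.append(convolve_decimate(x, hrf))
        names.append(name)

    for col, name in no_interest_columns(events, n_scans, tr_s, hrf):
        cols.append(col)
        names.append(name)

    drift = dct_highpass_basis(n_scans, tr_s, highpass_cutoff_hz)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"dct{k + 1}")

    if nuisance is not None and nuisance.size:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        for k in range(nuisance.shape[1]):
            if np.allclose(nuisance[:, k], 0):
                continue  # all-zero motion columns carry no information
            cols.append(nuisance[:, k])
            names.append(f"nuisance{k + 1}")

    cols.append(np.ones(n_scans))
    names.append("intercept")

    X = np.column_stack(cols)
    if np.any(np.all(X == 0, axis=0)):
        raise ValueError("design contains an all-zero column")
    return DesignMatrix(matrix=X, names=names, tr_s=tr_s, highpass_cutoff_hz=highpass_cutoff_hz)


def fit_ols(design: DesignMatrix, timeseries: np.ndarray) -> GLMFit:
    """Voxelwise OLS: ``timeseries`` is voxels x timepoints (or 1-D)."""
    Y = np.atleast_2d(np.asarray(timeseries, float))
    X = design.matrix
    if Y.shape[1] != X.shape[0]:
        raise ValueError(
            f"timeseries length {Y.shape[1]} does not match design rows {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design; using pseudo-inverse", RuntimeWarning)
        betas = (np.linalg.pinv(X) @ Y.T).T
    else:
        betas, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        betas = betas.T
    resid = Y - betas @ X.T
    dof = X.shape[0] - rank
    resvar = (resid**2).sum(axis=1) / max(dof, 1)
    return GLMFit(betas=betas, residual_variance=resvar, dof=dof, names=list(design.names))


def write_betas(fit: GLMFit, path) -> None:
    """Write a voxels x regressors beta table as named-column TSV."""
    pd.DataFrame(fit.betas, columns=fit.names).to_csv(path, sep="\t", index=False)


def read_betas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
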