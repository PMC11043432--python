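"""Cross-validated quadrature-filter estimation of n-fold grid-like coding.

The estimator works in two stages.  On training runs, each voxel's
response is regressed on cos(n*theta_t) and sin(n*theta_t); the resulting
betas (b1, b2) define the voxel's preferred orientation
phi = atan2(b2, b1) / n and response amplitude sqrt(b1^2 + b2^2).  The
ROI orientation is the amplitude-weighted circular mean of voxel
orientations taken in fold-space, which reduces algebraically to
atan2(sum b2, sum b1) / n.  On held-out runs, a single realigned
modulator cos(n*(theta_t - phi)) tests whether the BOLD signal is indeed
higher for movements aligned with the estimated orientation: its beta,
averaged over ROI voxels and the four cross-validation iterations, is the
magnitude of the grid-like representation.

Cross-validation uses four partitions of two runs each (one forward, one
backward), so every direction is equally represented in each partition;
each partition serves as the test set exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import glm_engine as glm
from .synthetic_data import RunData

VALID_FOLDS = (4, 5, 6, 7, 8)
N_PARTITIONS = 4
N_BINS = 12  # 30-degree direction bins for the aligned/misaligned profile


@dataclass(frozen=True)
class FoldSpec:
    n: int = 6

    def __post_init__(self) -> None:
        if self.n not in VALID_FOLDS:
            raise ValueError(f"fold must be one of {VALID_FOLDS}")

    @property
    def domain_deg(self) -> float:
        return 360.0 / self.n


@dataclass
class OrientationMap:
    phi_v: np.ndarray     # degrees per voxel, fundamental domain
    weight_v: np.ndarray  # response amplitude per voxel
    fold: FoldSpec


@dataclass(frozen=True)
class CVPartition:
    """Four disjoint (forward, backward) run-index pairs covering all 8 runs."""

    pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5), (6, 7))

    def __post_init__(self) -> None:
        flat = [i for pair in self.pairs for i in pair]
        if len(self.pairs) != N_PARTITIONS or sorted(flat) != list(range(8)):
            raise ValueError("partition must split runs 0..7 into 4 disjoint pairs")


@dataclass
class GridEstimate:
    fold: FoldSpec
    fold_beta: float                 # mean held-out modulation beta
    per_fold_betas: np.ndarray       # 4 test betas
    per_fold_phis: np.ndarray        # 4 estimated ROI orientations (deg)
    aligned_profile: np.ndarray | None = None


def voxel_orientation(beta1, beta2, fold: FoldSpec | int) -> np.ndarray | float:
    """Preferred orientation from quadrature betas, in [0, 360/n) degrees.

    Uses the full-quadrant arctangent: atan2 distinguishes (b1, b2) from
    (-b1, -b2), which a plain arctan of the ratio would conflate.
    """
    n = fold.n if isinstance(fold, FoldSpec) else FoldSpec(n=fold).n
    b1 = np.asarray(beta1, float)
    b2 = np.asarray(beta2, float)
    if np.any((b1 == 0) & (b2 == 0)):
        raise ValueError("orientation undefined when both betas are zero")
    phi = np.rad2deg(np.arctan2(b2, b1)) / n % (360.0 / n)
    return float(phi) if phi.ndim == 0 else phi


def voxel_amplitude(beta1, beta2) -> np.ndarray | float:
    """Response amplitude sqrt(b1^2 + b2^2)."""
    amp = np.hypot(np.asarray(beta1, float), np.asarray(beta2, float))
    return float(amp) if amp.ndim == 0 else amp


def roi_orientation(omap: OrientationMap) -> float:
    """Amplitude-weighted circular mean orientation of the ROI, in degrees.

    Computed in fold-space: atan2(sum w sin(n phi), sum w cos(n phi)) / n,
    equal to atan2(sum b2, sum b1) / n when weights are the amplitudes.
    """
    w = np.asarray(omap.weight_v, float)
    if np.all(w <= 0):
        raise ValueError("ROI orientation undefined: all weights zero")
    n = omap.fold.n
    ang = np.deg2rad(omap.phi_v * n)
    phi = np.arctan2((w * np.sin(ang)).sum(), (w * np.cos(ang)).sum())
    return float(np.rad2deg(phi) / n % (360.0 / n))


def _fit_run_quadrature(run: RunData, roi: np.ndarray, fold_n: int) -> tuple[np.ndarray, np.ndarray]:
    design = glm.build_design(
        run.events, fold_n, run.tr_s, run.n_scans, nuisance=run.nuisance
    )
    fit = glm.fit_ols(design, run.bold[roi])
    return fit.beta(f"cos{fold_n}theta"), fit.beta(f"sin{fold_n}theta")


class QuadratureCache:
    """Precomputed per-run modulator bases for one session design and fold.

    The quadrature betas (b1, b2) and the realigned test beta both live in
    the 2-D span of the cos/sin modulator columns after residualizing on
    the remaining design columns; by the Frisch-Waugh-Lovell theorem the
    OLS coefficients can then be read off from two dot products per voxel
    against the residualized basis.  Because the realigned regressor
    cos(n*(theta - phi)) is an exact linear combination of the cos/sin
    columns, its held-out beta is also available from the same basis.
    Runs sharing one session design can reuse the cache across subjects;
    results are identical to the full design-matrix OLS route.
    """

    def __init__(self, runs: list[RunData], fold: FoldSpec | int):
        self.fold = fold if isinstance(fold, FoldSpec) else FoldSpec(n=fold)
        n = self.fold.n
        self._basis: list[np.ndarray] = []   # per run: timepoints x 2, residualized
        self._gram: list[np.ndarray] = []    # per run: 2 x 2
        for run in runs:
            design = glm.build_design(
                run.events, n, run.tr_s, run.n_scans, nuisance=run.nuisance
            )
            X = design.matrix
            ic, isn = design.column(f"cos{n}theta"), design.column(f"sin{n}theta")
            mod = X[:, [ic, isn]]
            Z = np.delete(X, [ic, isn], axis=1)
            coef, *_ = np.linalg.lstsq(Z, mod, rcond=None)
            B = mod - Z @ coef
            self._basis.append(B)
            self._gram.append(B.T @ B)

    def quadrature_betas(self, run_idx: int, bold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        U = bold @ self._basis[run_idx]            # voxels x 2
        betas = np.linalg.solve(self._gram[run_idx], U.T)
        return betas[0], betas[1]

    def test_beta(self, run_idx: int, bold: np.ndarray, phi_deg: float) -> float:
        n = self.fold.n
        w = np.array([np.cos(np.deg2rad(n * phi_deg)), np.sin(np.deg2rad(n * phi_deg))])
        U = bold @ self._basis[run_idx]
        denom = w @ self._gram[run_idx] @ w
        return float((U @ w).mean() / denom)


def estimate_orientation_map(
    runs: list[RunData], roi: np.ndarray, fold: FoldSpec
) -> OrientationMap:
    """Quadrature betas averaged across training runs, per ROI voxel."""
    b1s, b2s = zip(*(_fit_run_quadrature(r, roi, fold.n) for r in runs))
    b1 = np.mean(b1s, axis=0)
    b2 = np.mean(b2s, axis=0)
    return OrientationMap(
        phi_v=voxel_orientation(b1, b2, fold),
        weight_v=voxel_amplitude(b1, b2),
        fold=fold,
    )


def _test_beta(run: RunData, roi: np.ndarray, fold_n: int, phi: float) -> float:
    design = glm.build_design(
        run.events,
        fold_n,
        run.tr_s,
        run.n_scans,
        reference_phase=phi,
        nuisance=run.nuisance,
    )
    fit = glm.fit_ols(design, run.bold[roi])
    return float(fit.beta(f"cos{fold_n}aligned").mean())


def _roi_indices(runs: list[RunData], roi) -> np.ndarray:
    n_vox = runs[0].bold.shape[0]
    return np.arange(n_vox) if roi is None else np.asarray(roi, int)


def crossval_symmetry(
    runs: list[RunData],
    fold: FoldSpec | int,
    roi=None,
    partition: CVPartition | None = None,
    cache: QuadratureCache | None = None,
) -> GridEstimate:
    """Four-way cross-validated n-fold symmetry magnitude.

    Each iteration estimates the ROI orientation on three partitions (six
    runs) and measures the realigned cosine's beta on the held-out pair;
    the estimate is the mean of the four held-out betas.  A
    :class:`QuadratureCache` built on the same session design may be
    passed to amortize design construction across subjects.
    """
    if len(runs) != 8:
        raise ValueError("cross-validation requires exactly 8 runs")
    fold = fold if isinstance(fold, FoldSpec) else FoldSpec(n=fold)
    partition = partition or CVPartition()
    roi_idx = _roi_indices(runs, roi)
    if cache is None:
        cache = QuadratureCache(runs, fold)
    elif cache.fold.n != fold.n:
        raise ValueError("cache built for a different fold")

    # quadrature betas are iteration-independent per run: fit each run once
    run_betas = [cache.quadrature_betas(j, r.bold[roi_idx]) for j, r in enumerate(runs)]

    test_betas = np.empty(N_PARTITIONS)
    phis = np.empty(N_PARTITIONS)
    for i, test_pair in enumerate(partition.pairs):
        train = [j for pair in partition.pairs if pair != test_pair for j in pair]
        b1 = np.mean([run_betas[j][0] for j in train], axis=0)
        b2 = np.mean([run_betas[j][1] for j in train], axis=0)
        omap = OrientationMap(
            phi_v=voxel_orientation(b1, b2, fold),
            weight_v=voxel_amplitude(b1, b2),
            fold=fold,
        )
        phi = roi_orientation(omap)
        phis[i] = phi
        test_betas[i] = np.mean(
            [cache.test_beta(j, runs[j].bold[roi_idx], phi) for j in test_pair]
        )
    return GridEstimate(
        fold=fold,
        fold_beta=float(test_betas.mean()),
        per_fold_betas=test_betas,
        per_fold_phis=phis,
    )


def aligned_profile(
    runs: list[RunData],
    phi: float,
    roi=None,
    fold: FoldSpec | int = 6,
) -> np.ndarray:
    """Mean response in 12 direction bins realigned to the grid orientation.

    Trials are binned by (theta - phi) mod 360 into 30-degree bins centered
    on 0, 30, ..., 330; each bin becomes a separate boxcar regressor whose
    betas are averaged over ROI voxels and runs.  Bins centered on
    multiples of 60 degrees are "aligned" for 6-fold coding.  Empty bins
    yield NaN.
    """
    fold = fold if isinstance(fold, FoldSpec) else FoldSpec(n=fold)
    roi_idx = _roi_indices(runs, roi)
    hrf_cache = {}
    sums = np.zeros(N_BINS)
    counts = np.zeros(N_BINS)
    for run in runs:
        events = run.events
        imag = events[events["trial_type"] == "imagination"]
        theta = imag["angle_deg"].to_numpy(float)
        # bin b spans [30b - 15, 30b + 15); edge trials go to the next bin
        bins = np.floor(((theta - phi) % 360.0 + 15.0) / 30.0).astype(int) % N_BINS

        cols = []
        names = []
        present = []
        for b in range(N_BINS):
            sel = bins == b
            if not sel.any():
                continue
            x = glm.boxcar_microtime(
                imag["onset"].to_numpy(float)[sel],
                imag["duration"].to_numpy(float)[sel],
                run.n_scans,
                run.tr_s,
            )
            hrf = hrf_cache.setdefault(run.tr_s, glm.canonical_hrf(run.tr_s))
            cols.append(glm.convolve_decimate(x, hrf))
            names.append(f"bin{b}")
            present.append(b)
        hrf = hrf_cache.setdefault(run.tr_s, glm.canonical_hrf(run.tr_s))
        for col, name in glm.no_interest_columns(events, run.n_scans, run.tr_s, hrf):
            cols.append(col)
            names.append(name)
        drift = glm.dct_highpass_basis(run.n_scans, run.tr_s, glm.DEFAULT_HIGHPASS_HZ)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            names.append(f"dct{k + 1}")
        cols.append(np.ones(run.n_scans))
        names.append("intercept")
        design = glm.DesignMatrix(
            matrix=np.column_stack(cols),
            names=names,
            tr_s=run.tr_s,
            highpass_cutoff_hz=glm.DEFAULT_HIGHPASS_HZ,
        )
        fit = glm.fit_ols(design, run.bold[roi_idx])
        for b in present:
            sums[b] += fit.beta(f"bin{b}").mean()
            counts[b] += 1
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return profile


ALIGNED_BINS = (0, 2, 4, 6, 8, 10)     # centers at multiples of 60 deg
MISALIGNED_BINS = (1, 3, 5, 7, 9, 11)  # offset by 30 deg
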