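"""Synthetic BOLD, behavior, and path-integration response generators.

The voxel model plants an n-fold directional tuning: during each
imagination period the neural drive is ``baseline * (1 + gain *
cos(n * (theta_t - phase)))``, a boxcar whose amplitude is sinusoidally
modulated by the trial's movement direction ``theta_t`` with rotational
symmetry ``n`` and voxel-specific orientation ``phase``.  Cue, target and
response events add fixed-amplitude boxcars.  The drive is convolved with
the canonical HRF and corrupted by slow cosine drift plus AR(1) Gaussian
noise.  Voxel orientations scatter around a subject-level (ROI)
orientation with von Mises jitter in fold-space; voxel gains are
lognormal, emulating response-amplitude heterogeneity.

Group generators emulate the two study populations: one expressing 6-fold
(hexadirectional) coding with uniformly distributed orientations, the
other expressing 4-fold coding with orientations clustered around an
environmental axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, lfilter

from . import clock_design as cd
from . import glm_engine as glm
from . import path_integration as pi

VALID_FOLDS = (4, 5, 6, 7, 8)


@dataclass(frozen=True)
class TuningModel:
    """Planted n-fold directional tuning of one voxel or ROI."""

    fold_n: int = 6
    phase_deg: float = 0.0       # orientation in [0, 360/fold_n)
    gain: float = 0.03           # modulation depth
    baseline: float = 100.0      # imagination-period drive (a.u.)

    def __post_init__(self) -> None:
        if self.fold_n not in VALID_FOLDS:
            raise ValueError(f"fold_n must be one of {VALID_FOLDS}")
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")

    @property
    def domain_deg(self) -> float:
        return 360.0 / self.fold_n


@dataclass(frozen=True)
class NoiseModel:
    sigma: float = 10.0          # innovation SD (a.u.)
    ar1_rho: float = 0.3
    drift_amplitudes: tuple[float, ...] = (4.0, 2.0)  # slow cosines (a.u.)

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    tr_s: float = 1.0
    n_voxels: int = 110           # matches an entorhinal ROI at 3 mm
    phase_jitter_kappa: float | None = 4.0  # von Mises in fold-space; None = no jitter
    amplitude_sigma: float = 0.4  # lognormal sigma of voxel gain heterogeneity
    event_response_amplitude: float = 20.0  # cue/target/response drive (a.u.)
    p_correct: float = 0.92
    seed: int = 0


@dataclass
class RunData:
    """One simulated run: voxel x time BOLD plus its event/nuisance tables."""

    bold: np.ndarray             # voxels x timepoints
    events: pd.DataFrame
    nuisance: np.ndarray         # timepoints x columns (may be empty)
    tr_s: float

    @property
    def n_scans(self) -> int:
        return self.bold.shape[1]


@dataclass
class SimulatedSubject:
    session: cd.SessionDesign
    runs: list[RunData]
    roi_tuning: TuningModel
    voxel_tunings: list[TuningModel]
    behavior: pd.DataFrame       # per-trial correct / response time


@dataclass(frozen=True)
class PIBehaviorModel:
    distance_gain: float = 0.85  # multiplicative distance bias (under-estimation)
    distance_cv: float = 0.1     # coefficient of variation of reports
    angular_sd_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.distance_gain <= 0:
            raise ValueError("distance_gain must be positive")
        if self.distance_cv < 0 or self.angular_sd_deg < 0:
            raise ValueError("noise parameters must be nonnegative")


def _run_n_scans(run: cd.RunDesign, tr_s: float, pad_s: float = 16.0) -> int:
    return int(np.ceil((run.duration_s + pad_s) / tr_s))


def simulate_voxel_timeseries(
    run: cd.RunDesign,
    tuning: TuningModel,
    noise: NoiseModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_scans: int | None = None,
) -> np.ndarray:
    """Simulate one voxel's BOLD time series for one run."""
    ts = simulate_run_matrix(run, [tuning], noise, config, rng, n_scans=n_scans)
    return ts[0]


def simulate_run_matrix(
    run: cd.RunDesign,
    tunings: list[TuningModel],
    noise: NoiseModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_scans: int | None = None,
) -> np.ndarray:
    """Simulate a voxels x timepoints matrix for one run (vectorized)."""
    tr = config.tr_s
    if n_scans is None:
        n_scans = _run_n_scans(run, tr)
    events = cd.run_events(run)
    hrf = glm.canonical_hrf(tr)

    imag = events[events["trial_type"] == "imagination"]
    onsets = imag["onset"].to_numpy(float)
    durs = imag["duration"].to_numpy(float)
    theta = np.deg2rad(imag["angle_deg"].to_numpy(float))
    if np.any(durs <= 0):
        raise ValueError("imagination durations must be positive")

    other = events[events["trial_type"].isin(["start_cue", "end_cue", "target", "response"])]
    ev_box = glm.boxcar_microtime(
        other["onset"].to_numpy(float), other["duration"].to_numpy(float), n_scans, tr
    )

    # per-trial indicator rows let all voxels share one matrix product
    n_micro = n_scans * glm.MICROTIME_BINS
    dt = tr / glm.MICROTIME_BINS
    trial_rows = np.zeros((len(onsets), n_micro))
    for j, (onset, dur) in enumerate(zip(onsets, durs)):
        trial_rows[j, int(round(onset / dt)) : int(round((onset + dur) / dt))] = 1.0

    phases = np.deg2rad([t.phase_deg for t in tunings])
    gains = np.array([t.gain for t in tunings])
    baselines = np.array([t.baseline for t in tunings])
    folds = np.array([t.fold_n for t in tunings])
    amps = baselines[:, None] * (
        1.0 + gains[:, None] * np.cos(folds[:, None] * (theta[None, :] - phases[:, None]))
    )
    neural = amps @ trial_rows + config.event_response_amplitude * ev_box

    conv = fftconvolve(neural, hrf[None, :], axes=1)[:, :n_micro]
    conv = conv[:, glm.MICROTIME_BINS // 2 :: glm.MICROTIME_BINS]

    # slow cosine drift: lowest DCT components, random phase per voxel
    if noise.drift_amplitudes:
        t = np.arange(n_scans)
        for k, amp in enumerate(noise.drift_amplitudes, start=1):
            phase = rng.uniform(0, 2 * np.pi, size=len(tunings))
            conv += amp * np.cos(
                np.pi * k * (2 * t + 1) / (2 * n_scans) + phase[:, None]
            )

    if noise.sigma > 0:
        eps = rng.normal(0.0, noise.sigma, size=(len(tunings), n_scans))
        eps[:, 0] /= np.sqrt(1 - noise.ar1_rho**2)  # stationary start
        conv += lfilter([1.0], [1.0, -noise.ar1_rho], eps, axis=1)
    return conv


def draw_voxel_tunings(
    roi: TuningModel, config: SimulationConfig, rng: np.random.Generator
) -> list[TuningModel]:
    """Voxel tunings scattered around the ROI tuning.

    Phases: von Mises in fold-space (kappa = ``phase_jitter_kappa``;
    ``None`` or inf collapses onto the ROI phase).  Gains: lognormal around
    the ROI gain.
    """
    n = config.n_voxels
    if n < 1:
        raise ValueError("n_voxels must be >= 1")
    kappa = config.phase_jitter_kappa
    if kappa is None or np.isinf(kappa):
        phases = np.full(n, roi.phase_deg)
    else:
        jitter = rng.vonmises(0.0, kappa, size=n)  # in fold-space radians
        phases = (roi.phase_deg + np.rad2deg(jitter) / roi.fold_n) % roi.domain_deg
    if config.amplitude_sigma > 0 and roi.gain > 0:
        gains = roi.gain * rng.lognormal(
            -config.amplitude_sigma**2 / 2, config.amplitude_sigma, size=n
        )
    else:
        gains = np.full(n, roi.gain)
    return [
        replace(roi, phase_deg=float(p), gain=float(g)) for p, g in zip(phases, gains)
    ]


def simulate_subject(
    session: cd.SessionDesign,
    roi_tuning: TuningModel | None = None,
    noise: NoiseModel | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SimulatedSubject:
    """Simulate all eight runs of one subject, fully seeded."""
    roi_tuning = roi_tuning or TuningModel()
    noise = noise or NoiseModel()
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    tunings = draw_voxel_tunings(roi_tuning, config, rng)

    runs = []
    beh_rows = []
    for run in session.runs:
        n_scans = _run_n_scans(run, config.tr_s)
        bold = simulate_run_matrix(run, tunings, noise, config, rng, n_scans=n_scans)
        events = cd.run_events(run)
        nuisance = np.zeros((n_scans, 0))
        runs.append(RunData(bold=bold, events=events, nuisance=nuisance, tr_s=config.tr_s))
        for i, trial in enumerate(run.trials):
            correct = bool(rng.random() < config.p_correct)
            rt = float(rng.lognormal(np.log(1.0), 0.3))
            beh_rows.append(
                (run.run_index, i, trial.correct_side, correct, min(rt, 2.0))
            )
    behavior = pd.DataFrame(
        beh_rows, columns=["run", "trial", "correct_side", "correct", "rt_s"]
    )
    return SimulatedSubject(
        session=session,
        runs=runs,
        roi_tuning=roi_tuning,
        voxel_tunings=tunings,
        behavior=behavior,
    )


def draw_group_phases(
    n_subjects: int,
    fold_n: int,
    phase_distribution: str,
    rng: np.random.Generator,
    mean_deg: float = 30.0,
    kappa: float = 6.0,
) -> np.ndarray:
    """Subject-level grid orientations, uniform or von Mises clustered.

    Clustering operates in fold-space: a draw of von Mises(n*mean, kappa)
    mapped back to the fundamental domain [0, 360/n).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    domain = 360.0 / fold_n
    if phase_distribution == "uniform":
        return rng.uniform(0.0, domain, size=n_subjects)
    if phase_distribution == "clustered":
        draws = rng.vonmises(np.deg2rad(mean_deg * fold_n), kappa, size=n_subjects)
        return (np.rad2deg(draws) / fold_n) % domain
    raise ValueError(f"unknown phase distribution: {phase_distribution}")


def simulate_group(
    n_subjects: int,
    fold_n: int = 6,
    phase_distribution: str = "uniform",
    seed: int = 0,
    session: cd.SessionDesign | None = None,
    roi_gain: float | None = None,
    noise: NoiseModel | None = None,
    config: SimulationConfig | None = None,
    mean_deg: float = 30.0,
    kappa: float = 6.0,
) -> list[SimulatedSubject]:
    """Simulate a cohort of subjects.

    Each subject receives their own randomized session design (trial
    orders, durations, targets) unless a shared ``session`` is supplied —
    per-subject randomization mirrors the experimental protocol and
    prevents design-locked estimation artifacts from aligning across
    subjects.  Per-subject ROI gains are lognormal around ``roi_gain`` so
    that individual differences in coding strength exist at the group
    level.
    """
    rng = np.random.default_rng(seed)
    config = config or SimulationConfig()
    noise = noise or NoiseModel()
    phases = draw_group_phases(
        n_subjects, fold_n, phase_distribution, rng, mean_deg=mean_deg, kappa=kappa
    )
    base_gain = TuningModel().gain if roi_gain is None else roi_gain
    subjects = []
    for i in range(n_subjects):
        subj_session = session or cd.build_session(int(rng.integers(2**31)))
        gain = float(base_gain * rng.lognormal(0.0, 0.3)) if base_gain > 0 else 0.0
        tuning = TuningModel(fold_n=fold_n, phase_deg=float(phases[i]), gain=gain)
        subjects.append(
            simulate_subject(
                subj_session,
                roi_tuning=tuning,
                noise=noise,
                config=config,
                seed=int(rng.integers(2**31)),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# path-integration responses
# ---------------------------------------------------------------------------

def simulate_pi_responses(
    paths: list[pi.PIPathSpec],
    model: PIBehaviorModel,
    seed: int = 0,
    n_repetitions: int = 2,
) -> tuple[list[pi.PIResponse], pi.StandardizationSet]:
    """Reported distances/orientations for each traversal plus the
    standardization-walk responses.

    Reported distance = gain * true * (1 + eps), eps ~ N(0, cv); reported
    orientation = true + N(0, angular_sd).  The standardization walks use
    the same multiplicative gain, which makes the correction-factor
    procedure recover true distances exactly when cv = 0.
    """
    rng = np.random.default_rng(seed)

    def report_distance(true: float) -> float:
        d = model.distance_gain * true * (1.0 + rng.normal(0.0, model.distance_cv))
        return max(d, 0.1)

    responses = []
    for rep in range(n_repetitions):
        for path in paths:
            for k, stop in enumerate(path.stops):
                responses.append(
                    pi.PIResponse(
                        path_id=f"{path.path_id}_rep{rep + 1}",
                        stop_index=k,
                        d_response=report_distance(stop.true_distance_m),
                        ori_response_deg=stop.true_orientation_deg
                        + rng.normal(0.0, model.angular_sd_deg),
                    )
                )
    std = pi.StandardizationSet(
        responses_5m=(report_distance(5.0), report_distance(5.0)),
        responses_10m=(report_distance(10.0), report_distance(10.0)),
    )
    return responses, std


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_subject(subject: SimulatedSubject, out_dir, fmt: str = "tsv") -> list[str]:
    """Write each run's voxel x time matrix plus its events table.

    ``fmt`` selects delimited text ("tsv"), a binary array ("npy"), or a
    NIfTI volume with a companion all-ones ROI mask ("nifti"; voxels are
    laid out along the first axis).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for i, run in enumerate(subject.runs, start=1):
        stem = os.path.join(out_dir, f"run-{i:02d}")
        if fmt == "tsv":
            path = f"{stem}_bold.tsv"
            np.savetxt(path, run.bold, delimiter="\t")
        elif fmt == "npy":
            path = f"{stem}_bold.npy"
            np.save(path, run.bold)
        elif fmt == "nifti":
            import nibabel as nib

            path = f"{stem}_bold.nii.gz"
            img = nib.Nifti1Image(run.bold[:, None, None, :].astype("f4"), np.eye(4))
            nib.save(img, path)
            mask = nib.Nifti1Image(
                np.ones((run.bold.shape[0], 1, 1), dtype="u1"), np.eye(4)
            )
            nib.save(mask, os.path.join(out_dir, "roi_mask.nii.gz"))
        else:
            raise ValueError(f"unknown export format: {fmt}")
        run.events.to_csv(f"{stem}_events.tsv", sep="\t", index=False, na_rep="n/a")
        written.append(path)
    return written


def load_run_data(bold_path, events_path, tr_s: float = 1.0) -> RunData:
    """Read a voxel x time matrix (TSV or .npy) and its events TSV."""
    bold_path = str(bold_path)
    if bold_path.endswith(".npy"):
        bold = np.load(bold_path)
    else:
        bold = np.loadtxt(bold_path, delimiter="\t", ndmin=2)
    events = pd.read_csv(events_path, sep="\t", na_values=["n/a"])
    return RunData(bold=bold, events=events,
                   nuisance=np.zeros((bold.shape[1], 0)), tr_s=tr_s)
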