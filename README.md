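# gridclock

Grid-like coding analysis for imagined navigation in a clock-shaped
environment, packaged so that every stage — experimental design
generation, BOLD simulation, GLM estimation, cross-validated symmetry
scoring, circular statistics, path-integration scoring, and group-level
inference — runs end to end without any scanner data.

## Who this is for

Researchers studying hexadirectional (grid-cell-like) fMRI signals during
imagined spatial navigation: the package generates fully counterbalanced
clock-navigation session designs, simulates ROI voxel time series with a
planted n-fold directional tuning, and provides the cross-validated
quadrature-filter estimator used to quantify that tuning, together with
the surrounding statistical battery (Rayleigh clustering of grid
orientations, normality-gated group tests, path-integration performance).

## The estimator

During imagined movement in direction θ, a grid-like code modulates the
BOLD signal as cos(n·(θ − φ)) with n = 6 (60° periodicity) and a
subject-specific grid orientation φ; n = 4, 5, 7, 8 serve as control
periodicities. Estimation is cross-validated over 4 partitions of 2 runs
(one forward + one backward):

1. **Estimate** (6 training runs): regress each voxel on cos(n·θ_t) and
   sin(n·θ_t) → betas (β₁, β₂); voxel orientation φ = atan2(β₂, β₁)/n,
   amplitude √(β₁² + β₂²); ROI orientation = amplitude-weighted circular
   mean in fold-space.
2. **Test** (2 held-out runs): regress on the realigned modulator
   cos(n·(θ_t − φ)); its beta, averaged over ROI voxels and the four
   iterations, is the magnitude of the grid-like representation.

Path-integration sessions are scored by correcting reported distances
with 5 m / 10 m standardization-walk factors (Cf = true/reported),
projecting each report to a presumed start, taking the displacement
between successive presumed starts as the per-segment error, and defining
performance = 1 / mean error.

## Worked example

```python
from gridclock import clock_design as cd, synthetic_data as sd, grid_analysis as ga

session = cd.build_session(seed=7)          # 8 runs x 24 trials = 192 trials
subject = sd.simulate_subject(
    session,
    roi_tuning=sd.TuningModel(fold_n=6, phase_deg=23.0, gain=0.03),
    noise=sd.NoiseModel(sigma=0.0, ar1_rho=0.0, drift_amplitudes=()),
    config=sd.SimulationConfig(n_voxels=4, phase_jitter_kappa=None,
                               amplitude_sigma=0.0),
    seed=1,
)
est6 = ga.crossval_symmetry(subject.runs, fold=6)
est4 = ga.crossval_symmetry(subject.runs, fold=4)
print("recovered orientations:", est6.per_fold_phis)
print("6-fold magnitude:", est6.fold_beta)
print("4-fold control:", est4.fold_beta)
```

prints

```
recovered orientations: [23. 23. 23. 23.]
6-fold magnitude: 3.000000000000007
4-fold control: 0.1270200630228333
```

— in noiseless data the planted orientation (23°) is recovered to machine
precision in all four cross-validation folds, the 6-fold magnitude equals
the planted modulation amplitude (gain × baseline = 0.03 × 100 = 3), and
the 4-fold control beta is an order of magnitude smaller (a small
session-dependent residual of the time-series GLM; see
`docs/methods.md`).

A command-line entry point wraps the two I/O-heavy stages:

```bash
gridclock design --seed 7 --out events/        # writes 8 BIDS-style events TSVs
gridclock report --records records.tsv --out report/
```

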