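"""Synthetic BOLD, behavior, and PI-response generators."""

import numpy as np
import pytest

from gridclock import clock_design as cd
from gridclock import path_integration as pi
from gridclock import synthetic_data as sd


def test_tuning_model_validation():
    with pytest.raises(ValueError):
        sd.TuningModel(fold_n=3)
    with pytest.raises(ValueError):
        sd.TuningModel(gain=-0.1)
    with pytest.raises(ValueError):
        sd.NoiseModel(ar1_rho=1.0)


def test_no_modulation_makes_direction_and_phase_irrelevant(session_design):
    """gain=0: the planted orientation cannot influence the signal."""
    run = session_design.runs[0]
    noise0 = sd.NoiseModel(sigma=0.0, ar1_rho=0.0, drift_amplitudes=())
    cfg = sd.SimulationConfig(n_voxels=1)
    a = sd.simulate_run_matrix(
        run, [sd.TuningModel(6, 0.0, gain=0.0)], noise0, cfg, np.random.default_rng(0)
    )
    b = sd.simulate_run_matrix(
        run, [sd.TuningModel(6, 41.0, gain=0.0)], noise0, cfg, np.random.default_rng(0)
    )
    assert np.array_equal(a, b)


def _isolated_trial_run():
    """A single well-separated trial, for overlap-free amplitude probes."""
    path = cd.make_path(9, 12)  # direction 45 deg
    onsets = cd.TrialOnsets(
        start_cue_s=10.0, end_cue_s=11.0, imagination_onset_s=11.5,
        imagination_duration_s=5.0, target_onset_s=16.5, response_window_s=2.0,
    )
    trial = cd.TrialSpec(path=path, target=3, correct_side="right",
                         jump_flag=False, onsets=onsets)
    return cd.RunDesign(trials=(trial,), polarity="forward", run_index=1)


def test_cosine_extremes_amplitude_ratio():
    """Aligned vs anti-aligned movement responds in ratio (1+g)/(1-g)."""
    run = _isolated_trial_run()
    gain = 0.25
    theta = run.trials[0].path.direction_deg
    noise0 = sd.NoiseModel(sigma=0.0, ar1_rho=0.0, drift_amplitudes=())
    cfg = sd.SimulationConfig(n_voxels=1, event_response_amplitude=0.0)

    def peak_for(phase):
        tuning = sd.TuningModel(fold_n=6, phase_deg=phase, gain=gain)
        bold = sd.simulate_run_matrix(run, [tuning], noise0, cfg,
                                      np.random.default_rng(0))[0]
        return bold.max()

    aligned = peak_for(theta % 60.0)               # cos term = +1
    misaligned = peak_for((theta + 30.0) % 60.0)   # cos term = -1
    assert aligned / misaligned == pytest.approx((1 + gain) / (1 - gain), rel=1e-9)


def test_subject_simulation_is_deterministic(session_design):
    cfg = sd.SimulationConfig(n_voxels=3)
    a = sd.simulate_subject(session_design, config=cfg, seed=5)
    b = sd.simulate_subject(session_design, config=cfg, seed=5)
    assert np.array_equal(a.runs[0].bold, b.runs[0].bold)
    assert a.behavior.equals(b.behavior)
    assert [t.phase_deg for t in a.voxel_tunings] == [t.phase_deg for t in b.voxel_tunings]


def test_infinite_concentration_collapses_voxel_phases(session_design):
    cfg = sd.SimulationConfig(n_voxels=20, phase_jitter_kappa=None)
    subj = sd.simulate_subject(session_design, config=cfg, seed=2)
    phases = {t.phase_deg for t in subj.voxel_tunings}
    assert phases == {subj.roi_tuning.phase_deg}


def test_behavioral_accuracy_matches_target_probability(session_design):
    cfg = sd.SimulationConfig(n_voxels=1, p_correct=0.92)
    correct = []
    for i in range(10):
        subj = sd.simulate_subject(session_design, config=cfg, seed=100 + i)
        correct.append(subj.behavior["correct"].mean())
    # 1920 Bernoulli draws: SE ~ 0.006
    assert np.mean(correct) == pytest.approx(0.92, abs=0.02)


def test_pure_noise_variance_matches_ar1_theory(session_design):
    """Stationary AR(1) variance is sigma^2 / (1 - rho^2)."""
    rho, sigma = 0.4, 2.0
    noise = sd.NoiseModel(sigma=sigma, ar1_rho=rho, drift_amplitudes=())
    cfg = sd.SimulationConfig(n_voxels=40, event_response_amplitude=0.0)
    tuning = sd.TuningModel(gain=0.0, baseline=0.0)
    rng = np.random.default_rng(3)
    samples = np.concatenate(
        [sd.simulate_run_matrix(r, [tuning] * 40, noise, cfg, rng).ravel()
         for r in session_design.runs[:2]]
    )
    assert len(samples) >= 10_000
    assert samples.var() == pytest.approx(sigma**2 / (1 - rho**2), rel=0.05)


def test_group_phase_distributions():
    rng = np.random.default_rng(0)
    uni = sd.draw_group_phases(500, 6, "uniform", rng)
    assert np.all((uni >= 0) & (uni < 60))
    clus = sd.draw_group_phases(500, 4, "clustered", rng, mean_deg=30.0, kappa=8.0)
    assert np.all((clus >= 0) & (clus < 90))
    # clustered spread (fold-space circular SD) far below uniform's
    def circ_R(ph, n):
        return np.abs(np.exp(1j * np.deg2rad(ph * n)).mean())
    assert circ_R(clus, 4) > 0.8
    assert circ_R(uni, 6) < 0.2
    with pytest.raises(ValueError):
        sd.draw_group_phases(0, 6, "uniform", rng)
    with pytest.raises(ValueError):
        sd.draw_group_phases(5, 6, "bimodal", rng)


def test_pi_responses_seeded_and_gain_recoverable():
    paths = pi.default_court_paths()
    model = sd.PIBehaviorModel(distance_gain=0.8, distance_cv=0.0, angular_sd_deg=0.0)
    r1, s1 = sd.simulate_pi_responses(paths, model, seed=9)
    r2, s2 = sd.simulate_pi_responses(paths, model, seed=9)
    assert r1 == r2 and s1 == s2
    assert len(r1) == 2 * 8 * 2  # 16 traversals x 2 stops
    # shared multiplicative gain cancels exactly through the correction
    cf5, cf10 = pi.correction_factors(s1)
    for resp in r1:
        base = resp.path_id.split("_rep")[0]
        path = next(p for p in paths if p.path_id == base)
        true = path.stops[resp.stop_index].true_distance_m
        assert pi.correct_distance(resp.d_response, cf5, cf10) == pytest.approx(true)


def test_perfect_reports_give_infinite_performance_flag():
    paths = pi.default_court_paths()
    model = sd.PIBehaviorModel(distance_gain=1.0, distance_cv=0.0, angular_sd_deg=0.0)
    responses, std = sd.simulate_pi_responses(paths, model, seed=0)
    card = pi.score_session(paths, responses, std)
    assert card.mean_error == pytest.approx(0.0, abs=1e-9)
    assert np.isinf(card.performance)


def test_export_and_reload_round_trip(tmp_path, session_design):
    cfg = sd.SimulationConfig(n_voxels=3)
    subj = sd.simulate_subject(session_design, config=cfg, seed=8)
    written = sd.export_subject(subj, tmp_path, fmt="tsv")
    assert len(written) == 8
    back = sd.load_run_data(written[0], tmp_path / "run-01_events.tsv")
    assert np.allclose(back.bold, subj.runs[0].bold)
    assert len(back.events) == len(subj.runs[0].events)
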