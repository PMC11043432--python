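"""Clock geometry, path enumeration, and session counterbalancing."""

import math
from collections import Counter

import numpy as np
import pytest

from gridclock import clock_design as cd


@pytest.mark.parametrize(
    "number, expected",
    [(12, (0.0, 1.0)), (3, (1.0, 0.0)), (6, (0.0, -1.0)), (9, (-1.0, 0.0)),
     (7, (-0.5, -math.sqrt(3) / 2))],
)
def test_number_position_matches_clock_layout(number, expected):
    assert cd.number_position(number) == pytest.approx(expected, abs=1e-12)


def test_number_position_rejects_out_of_range():
    with pytest.raises(cd.DesignError):
        cd.number_position(0)
    with pytest.raises(cd.DesignError):
        cd.number_position(13)


@pytest.mark.parametrize("a, b, d", [(9, 12, 3), (1, 2, 1), (2, 8, 6), (11, 2, 3)])
def test_circular_distance(a, b, d):
    assert cd.circular_distance(a, b) == d
    assert cd.circular_distance(b, a) == d


def test_circular_distance_rejects_identical():
    with pytest.raises(cd.DesignError):
        cd.circular_distance(5, 5)


@pytest.mark.parametrize("a, b, deg", [(9, 12, 45.0), (12, 9, 225.0), (12, 3, 315.0)])
def test_path_direction(a, b, deg):
    assert cd.path_direction(a, b) == pytest.approx(deg)


def test_path_direction_always_multiple_of_15():
    for p in cd.directed_paths():
        assert p.direction_deg % 15 == 0


def test_judge_side_worked_examples():
    path = cd.make_path(9, 12)
    assert cd.judge_side(path, 3) == "right"
    assert cd.judge_side(path, 11) == "left"
    with pytest.raises(cd.DesignError):
        cd.judge_side(path, 9)  # start lies on the heading line


def _rotation_oracle(path, target):
    """Rotate the frame so the heading is +x; the target's y sign is the side."""
    xs, ys = cd.number_position(path.start)
    xe, ye = cd.number_position(path.end)
    xt, yt = cd.number_position(target)
    heading = math.atan2(ye - ys, xe - xs)
    c, s = math.cos(-heading), math.sin(-heading)
    rel_x, rel_y = xt - xe, yt - ye
    y_rot = s * rel_x + c * rel_y
    if abs(y_rot) < 1e-9:
        return None
    return "left" if y_rot > 0 else "right"


def test_judge_side_agrees_with_rotation_oracle_everywhere():
    for path in cd.directed_paths():
        for target in range(1, 13):
            if target in (path.start, path.end):
                continue
            expected = _rotation_oracle(path, target)
            if expected is None:
                with pytest.raises(cd.DesignError):
                    cd.judge_side(path, target)
            else:
                assert cd.judge_side(path, target) == expected


def test_reversal_flips_side_only_when_geometry_flips():
    for path in cd.directed_paths():
        rev = cd.make_path(path.end, path.start)
        for target in range(1, 13):
            if target in (path.start, path.end):
                continue
            fwd = _rotation_oracle(path, target)
            bwd = _rotation_oracle(rev, target)
            if fwd is None or bwd is None:
                continue
            assert cd.judge_side(path, target) == fwd
            assert cd.judge_side(rev, target) == bwd


def test_enumerate_valid_paths_counts_and_exclusions():
    pairs = cd.enumerate_valid_paths()
    assert len(pairs) == 36
    assert frozenset((1, 2)) not in pairs      # adjacent
    assert frozenset((1, 7)) not in pairs      # diameter
    assert frozenset((1, 3)) not in pairs      # distance 2
    assert all(cd.circular_distance(*sorted(p)) in (3, 4, 5) for p in pairs)


def test_directed_closure_direction_structure():
    """72 directed paths cover 24 directions; even multiples of 15 deg come
    only from medium (distance-4) chords, odd ones from short and long."""
    by_dir = {}
    for p in cd.directed_paths():
        by_dir.setdefault(p.direction_deg, []).append(p)
    assert len(cd.directed_paths()) == 72
    assert set(by_dir) == {15.0 * k for k in range(24)}  # 360 deg == 0 deg
    for deg, paths in by_dir.items():
        classes = Counter(p.length_class for p in paths)
        if (deg / 15) % 2 == 0:
            assert classes == {"medium": 2}
        else:
            assert classes == {"short": 2, "long": 2}


def _check_run_invariants(run):
    assert len(run.trials) == 24
    dirs = [t.path.direction_deg for t in run.trials]
    assert sorted(dirs) == [15.0 * k for k in range(24)]
    endpoints = Counter()
    for t in run.trials:
        endpoints[t.path.start] += 1
        endpoints[t.path.end] += 1
    assert all(endpoints[n] == 4 for n in range(1, 13))
    lengths = Counter(t.path.length_class for t in run.trials)
    assert lengths == {"short": 6, "medium": 12, "long": 6}
    sides = Counter(t.correct_side for t in run.trials)
    assert sides == {"left": 12, "right": 12}
    for prev, nxt in zip(run.trials, run.trials[1:]):
        if not nxt.jump_flag:
            assert nxt.path.start == prev.path.end
    for t in run.trials:
        assert t.target not in (t.path.start, t.path.end)
        assert cd.circular_distance(t.target, t.path.end) > 1
        assert cd.judge_side(t.path, t.target) == t.correct_side
        assert 4.0 <= t.onsets.imagination_duration_s <= 6.0


@pytest.mark.parametrize("seed", range(25))
def test_build_run_satisfies_all_invariants(seed):
    _check_run_invariants(cd.build_run("forward", 1, seed))


def test_build_run_deterministic():
    assert cd.build_run("forward", 1, 42) == cd.build_run("forward", 1, 42)


def test_session_structure(session_design):
    s = session_design
    assert s.n_trials == 192
    assert [r.polarity for r in s.runs] == ["forward", "backward"] * 4
    for run in s.runs:
        _check_run_invariants(run)
    for run in s.runs:
        assert len({frozenset(t.path.key) for t in run.trials}) == 24  # distinct paths
    fwd_sets = [frozenset(t.path.key for t in r.trials) for r in s.runs[0::2]]
    bwd_sets = [frozenset(t.path.key for t in r.trials) for r in s.runs[1::2]]
    assert len(set(fwd_sets)) == 1  # one shared forward combination
    reversed_fwd = frozenset((b, a) for a, b in fwd_sets[0])
    assert all(b == reversed_fwd for b in bwd_sets)


def test_backward_directions_are_forward_plus_180(session_design):
    fwd = {t.path.key: t.path.direction_deg for t in session_design.runs[0].trials}
    for t in session_design.runs[1].trials:
        a, b = t.path.key
        assert t.path.direction_deg == pytest.approx((fwd[(b, a)] + 180.0) % 360.0)


def test_target_sides_counterbalanced_across_runs(session_design):
    """Each trajectory shows its target twice left, twice right across the
    four runs presenting it."""
    sides = {}
    for run in session_design.runs:
        for t in run.trials:
            sides.setdefault(t.path.key, []).append(t.correct_side)
    for key, lst in sides.items():
        assert len(lst) == 4
        assert Counter(lst) == {"left": 2, "right": 2}


def test_events_roundtrip(tmp_path, session_design):
    paths = cd.write_events(session_design, tmp_path)
    assert len(paths) == 8
    for path, run in zip(paths, session_design.runs):
        table = cd.read_events(path)
        imag = table[table["trial_type"] == "imagination"]
        assert len(imag) == 24
        assert np.all(imag["angle_deg"].to_numpy() % 15 == 0)
        expected = cd.run_events(run)
        assert np.allclose(imag["onset"].to_numpy(),
                           expected[expected["trial_type"] == "imagination"]["onset"])
        assert np.allclose(imag["duration"].to_numpy(),
                           [t.onsets.imagination_duration_s for t in run.trials])
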