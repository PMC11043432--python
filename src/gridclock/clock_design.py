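"""Clock-space geometry and counterbalanced session design.

The imagined environment is a clock face: the integers 1-12 sit on the
vertices of a regular dodecagon, 12 at the top, numbers increasing
clockwise.  A trial is a straight "walk" from one number to another;
because adjacent numbers subtend 30 deg, every chord direction is a
multiple of 15 deg, which gives the angular resolution needed to detect
n-fold directional modulation of the BOLD signal.

A session is 8 runs of 24 trials (192 trials).  Forward and backward runs
alternate; a backward run traverses the forward run's paths with start and
end swapped.  Within a run all 24 movement directions (15..360 deg, step
15) occur exactly once, every number serves as a path endpoint exactly
four times, path lengths are balanced 6 short / 12 medium / 6 long, and
the left/right target judgments split 12/12.  Across runs, each trajectory
shows its target on the left in half of the runs presenting it and on the
right in the other half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_POSITIONS = 12
DEG_PER_POSITION = 360 // N_POSITIONS  # 30
VALID_CIRC_DISTS = (3, 4, 5)
LENGTH_CLASS = {3: "short", 4: "medium", 5: "long"}
RUN_LENGTH_MIX = {"short": 6, "medium": 12, "long": 6}
TRIALS_PER_RUN = 24
RUNS_PER_SESSION = 8

# event timing (seconds); cue gaps follow the stated 0.5 s audio events
CUE_DURATION_S = 0.5
CUE_GAP_S = 0.5
TARGET_DURATION_S = 0.5
RESPONSE_WINDOW_S = 2.0
ITI_S = 0.5
JUMP_CUE_S = 0.5
JUMP_REORIENT_S = 4.0
IMAGINE_CHOICES_S = (4.0, 4.5, 5.0, 5.5, 6.0)


class DesignError(ValueError):
    """Raised for geometric or combinatorial design violations."""


@dataclass(frozen=True)
class ClockSpace:
    """Dodecagon geometry: 12 at top, clockwise numbering, math-convention angles."""

    n_positions: int = N_POSITIONS
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.n_positions != N_POSITIONS:
            raise DesignError("clock space requires exactly 12 positions")
        if self.radius <= 0:
            raise DesignError("radius must be positive")


@dataclass(frozen=True)
class PathSpec:
    start: int
    end: int
    direction_deg: float
    circ_dist: int
    length_class: str

    @property
    def key(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TrialOnsets:
    start_cue_s: float
    end_cue_s: float
    imagination_onset_s: float
    imagination_duration_s: float
    target_onset_s: float
    response_window_s: float
    jump_onset_s: float | None = None


@dataclass(frozen=True)
class TrialSpec:
    path: PathSpec
    target: int
    correct_side: str
    jump_flag: bool
    onsets: TrialOnsets


@dataclass(frozen=True)
class RunDesign:
    trials: tuple[TrialSpec, ...]
    polarity: str  # "forward" | "backward"
    run_index: int  # 1-based

    @property
    def duration_s(self) -> float:
        last = self.trials[-1].onsets
        return last.target_onset_s + TARGET_DURATION_S + last.response_window_s + ITI_S


@dataclass(frozen=True)
class SessionDesign:
    runs: tuple[RunDesign, ...]
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(r.trials) for r in self.runs)


def number_position(n: int, space: ClockSpace | None = None) -> tuple[float, float]:
    """Planar coordinates of clock number ``n``; 12 at top, clockwise numbering."""
    space = space or ClockSpace()
    if not 1 <= n <= N_POSITIONS:
        raise DesignError(f"clock number out of range: {n}")
    angle = math.radians((90 - DEG_PER_POSITION * (n % N_POSITIONS)) % 360)
    return (space.radius * math.cos(angle), space.radius * math.sin(angle))


def circular_distance(a: int, b: int) -> int:
    """Shortest step count between two clock numbers (1..6)."""
    if a == b:
        raise DesignError("circular distance undefined for identical numbers")
    for n in (a, b):
        if not 1 <= n <= N_POSITIONS:
            raise DesignError(f"clock number out of range: {n}")
    d = abs(a - b)
    return min(d, N_POSITIONS - d)


def path_direction(a: int, b: int, space: ClockSpace | None = None) -> float:
    """Movement direction of the chord a -> b, degrees CCW from east in [0, 360)."""
    if a == b:
        raise DesignError("path requires two distinct numbers")
    xa, ya = number_position(a, space)
    xb, yb = number_position(b, space)
    ang = math.degrees(math.atan2(yb - ya, xb - xa)) % 360.0
    # chord directions are exact multiples of 15 deg; snap away float fuzz
    return round(ang / 15.0) % 24 * 15.0


def make_path(a: int, b: int, space: ClockSpace | None = None) -> PathSpec:
    d = circular_distance(a, b)
    return PathSpec(
        start=a,
        end=b,
        direction_deg=path_direction(a, b, space),
        circ_dist=d,
        length_class=LENGTH_CLASS.get(d, "invalid"),
    )


def judge_side(
    path: PathSpec, target: int, space: ClockSpace | None = None
) -> str:
    """Is the target left or right of the heading at the path's end position?

    Sign of the planar cross product between the movement vector and the
    end-to-target vector: positive -> left, negative -> right.
    """
    space = space or ClockSpace()
    if target in (path.start, path.end):
        raise DesignError("target coincides with a path endpoint")
    xs, ys = number_position(path.start, space)
    xe, ye = number_position(path.end, space)
    xt, yt = number_position(target, space)
    dx, dy = xe - xs, ye - ys
    cross = dx * (yt - ye) - dy * (xt - xe)
    if abs(cross) < 1e-9 * space.radius**2:
        raise DesignError(
            f"target {target} collinear with path {path.start}->{path.end}"
        )
    return "left" if cross > 0 else "right"


def enumerate_valid_paths(space: ClockSpace | None = None) -> set[frozenset[int]]:
    """All unordered number pairs usable as experimental paths.

    Keeps pairs at circular distance 3, 4 or 5: adjacent and distance-2
    pairs are too short, diameters cross the center.  Yields 36 pairs.
    """
    pairs = set()
    for a in range(1, N_POSITIONS + 1):
        for b in range(a + 1, N_POSITIONS + 1):
            if circular_distance(a, b) in VALID_CIRC_DISTS:
                pairs.add(frozenset((a, b)))
    return pairs


def directed_paths(space: ClockSpace | None = None) -> list[PathSpec]:
    """Directed closure of the valid path set: 72 paths, 3 per direction bin."""
    out = []
    for pair in sorted(enumerate_valid_paths(space), key=sorted):
        a, b = sorted(pair)
        out.append(make_path(a, b, space))
        out.append(make_path(b, a, space))
    return out


def admissible_targets(path: PathSpec, space: ClockSpace | None = None) -> dict[str, list[int]]:
    """Targets allowed for a path, grouped by the side judgment.

    A target may not be a path endpoint and may not be circularly adjacent
    to the end position.
    """
    excluded = {
        path.start,
        path.end,
        (path.end % N_POSITIONS) + 1,
        ((path.end - 2) % N_POSITIONS) + 1,
    }
    sides: dict[str, list[int]] = {"left": [], "right": []}
    for t in range(1, N_POSITIONS + 1):
        if t in excluded:
            continue
        sides[judge_side(path, t, space)].append(t)
    return sides


# ---------------------------------------------------------------------------
# combination selection: 24 directed paths, one per direction bin,
# 6/12/6 length mix, each number an endpoint exactly 4 times
# ---------------------------------------------------------------------------

def _select_combination(rng: np.random.Generator, space: ClockSpace) -> list[PathSpec]:
    by_dir: dict[float, list[PathSpec]] = {}
    for p in directed_paths(space):
        by_dir.setdefault(p.direction_deg, []).append(p)
    directions = sorted(by_dir)
    assert len(directions) == TRIALS_PER_RUN

    for _ in range(200):  # bounded restarts
        order = list(rng.permutation(len(directions)))
        length_quota = dict(RUN_LENGTH_MIX)
        endpoint_quota = {n: 4 for n in range(1, N_POSITIONS + 1)}
        used_pairs: set[frozenset[int]] = set()  # 24 distinct undirected paths
        chosen: list[PathSpec] = []

        def backtrack(i: int) -> bool:
            if i == len(order):
                return True
            cands = list(by_dir[directions[order[i]]])
            rng.shuffle(cands)
            for p in cands:
                pair = frozenset((p.start, p.end))
                if (
                    length_quota[p.length_class] > 0
                    and endpoint_quota[p.start] > 0
                    and endpoint_quota[p.end] > 0
                    and pair not in used_pairs
                ):
                    length_quota[p.length_class] -= 1
                    endpoint_quota[p.start] -= 1
                    endpoint_quota[p.end] -= 1
                    used_pairs.add(pair)
                    chosen.append(p)
                    if backtrack(i + 1):
                        return True
                    chosen.pop()
                    used_pairs.discard(pair)
                    length_quota[p.length_class] += 1
                    endpoint_quota[p.start] += 1
                    endpoint_quota[p.end] += 1
            return False

        if backtrack(0):
            return chosen
    raise DesignError("could not satisfy run combination constraints")


def _order_chained(
    paths: list[PathSpec], rng: np.random.Generator, n_restarts: int = 20
) -> tuple[list[PathSpec], list[bool]]:
    """Order paths so consecutive trials chain end -> start where possible.

    Greedy trail building with random restarts; keeps the ordering with the
    fewest chain breaks (jumps).
    """
    best: tuple[list[PathSpec], list[bool]] | None = None
    for _ in range(n_restarts):
        pool = list(paths)
        rng.shuffle(pool)
        ordered: list[PathSpec] = []
        jumps: list[bool] = []
        current_end: int | None = None
        while pool:
            nxt = next((p for p in pool if p.start == current_end), None)
            if nxt is None:
                nxt = pool[0]
                jumps.append(current_end is not None)
            else:
                jumps.append(False)
            pool.remove(nxt)
            ordered.append(nxt)
            current_end = nxt.end
        if best is None or sum(jumps) < sum(best[1]):
            best = (ordered, jumps)
        if sum(best[1]) == 0:
            break
    assert best is not None
    return best


def _timing(
    ordered: list[PathSpec], jumps: list[bool], rng: np.random.Generator
) -> list[TrialOnsets]:
    onsets = []
    t = 2.0  # initial silence
    for jump in jumps:
        jump_onset = None
        if jump:
            jump_onset = t
            t += JUMP_CUE_S + JUMP_REORIENT_S
        start_cue = t
        end_cue = start_cue + CUE_DURATION_S + CUE_GAP_S
        imag_onset = end_cue + CUE_DURATION_S
        imag_dur = float(rng.choice(IMAGINE_CHOICES_S))
        target_onset = imag_onset + imag_dur
        onsets.append(
            TrialOnsets(
                start_cue_s=start_cue,
                end_cue_s=end_cue,
                imagination_onset_s=imag_onset,
                imagination_duration_s=imag_dur,
                target_onset_s=target_onset,
                response_window_s=RESPONSE_WINDOW_S,
                jump_onset_s=jump_onset,
            )
        )
        t = target_onset + TARGET_DURATION_S + RESPONSE_WINDOW_S + ITI_S
    return onsets


def _assign_targets(
    ordered: list[PathSpec],
    sides: list[str],
    rng: np.random.Generator,
    space: ClockSpace,
) -> list[int]:
    targets = []
    for path, side in zip(ordered, sides):
        cands = admissible_targets(path, space)[side]
        if not cands:
            raise DesignError(f"no {side}-side target for path {path.key}")
        targets.append(int(rng.choice(cands)))
    return targets


def _balanced_sides(rng: np.random.Generator) -> list[str]:
    sides = ["left"] * (TRIALS_PER_RUN // 2) + ["right"] * (TRIALS_PER_RUN // 2)
    rng.shuffle(sides)
    return sides


def build_run(
    polarity: str,
    run_index: int,
    rng_seed: int,
    paths: list[PathSpec] | None = None,
    side_by_path: dict[tuple[int, int], str] | None = None,
    space: ClockSpace | None = None,
) -> RunDesign:
    """Build one 24-trial run satisfying all within-run balance constraints.

    ``paths`` and ``side_by_path`` let the session builder impose a shared
    path combination and the across-run target-side counterbalancing; when
    omitted the run draws its own combination and a random 12/12 split.
    """
    if polarity not in ("forward", "backward"):
        raise DesignError(f"unknown polarity: {polarity}")
    space = space or ClockSpace()
    rng = np.random.default_rng(rng_seed)
    if paths is None:
        paths = _select_combination(rng, space)
        if polarity == "backward":
            paths = [make_path(p.end, p.start, space) for p in paths]
    ordered, jumps = _order_chained(list(paths), rng)
    if side_by_path is None:
        sides = _balanced_sides(rng)
    else:
        sides = [side_by_path[p.key] for p in ordered]
        if sides.count("left") != TRIALS_PER_RUN // 2:
            raise DesignError("imposed sides are not balanced 12/12")
    targets = _assign_targets(ordered, sides, rng, space)
    onsets = _timing(ordered, jumps, rng)
    trials = tuple(
        TrialSpec(path=p, target=t, correct_side=s, jump_flag=j, onsets=o)
        for p, t, s, j, o in zip(ordered, targets, sides, jumps, onsets)
    )
    return RunDesign(trials=trials, polarity=polarity, run_index=run_index)


def _side_patterns(rng: np.random.Generator) -> list[tuple[str, ...]]:
    """24 left/right patterns over 4 runs: 2 lefts per row, 12 per column."""
    base = [
        ("left", "left", "right", "right"),
        ("left", "right", "left", "right"),
        ("left", "right", "right", "left"),
        ("right", "left", "left", "right"),
        ("right", "left", "right", "left"),
        ("right", "right", "left", "left"),
    ]
    patterns = base * 4
    rng.shuffle(patterns)
    return patterns


def build_session(seed: int, space: ClockSpace | None = None) -> SessionDesign:
    """Build the full 8-run session: interleaved forward/backward runs.

    Forward runs share one 24-path combination; backward runs traverse it
    with start and end swapped.  Target sides are counterbalanced so each
    trajectory shows its target twice left and twice right across the four
    runs presenting it.
    """
    space = space or ClockSpace()
    rng = np.random.default_rng(seed)
    forward = _select_combination(rng, space)
    backward = [make_path(p.end, p.start, space) for p in forward]

    fwd_patterns = _side_patterns(rng)
    bwd_patterns = _side_patterns(rng)
    runs = []
    for k in range(4):
        fwd_sides = {p.key: pat[k] for p, pat in zip(forward, fwd_patterns)}
        bwd_sides = {p.key: pat[k] for p, pat in zip(backward, bwd_patterns)}
        runs.append(
            build_run(
                "forward",
                2 * k + 1,
                int(rng.integers(2**31)),
                paths=forward,
                side_by_path=fwd_sides,
                space=space,
            )
        )
        runs.append(
            build_run(
                "backward",
                2 * k + 2,
                int(rng.integers(2**31)),
                paths=backward,
                side_by_path=bwd_sides,
                space=space,
            )
        )
    return SessionDesign(runs=tuple(runs), seed=seed)


# ---------------------------------------------------------------------------
# BIDS-style events I/O
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "angle_deg",
    "target_number",
    "correct_side",
]


import functools


@functools.lru_cache(maxsize=256)
def run_events(run: RunDesign) -> pd.DataFrame:
    """Long-format event table for one run (one row per cue/period).

    Cached per run design; treat the returned frame as read-only.
    """
    rows = []
    for trial in run.trials:
        o = trial.onsets
        ang = trial.path.direction_deg
        if trial.jump_flag:
            rows.append(
                (o.jump_onset_s, JUMP_CUE_S + JUMP_REORIENT_S, "jump", "n/a", "n/a", "n/a")
            )
        rows.append((o.start_cue_s, CUE_DURATION_S, "start_cue", "n/a", "n/a", "n/a"))
        rows.append((o.end_cue_s, CUE_DURATION_S, "end_cue", "n/a", "n/a", "n/a"))
        rows.append(
            (o.imagination_onset_s, o.imagination_duration_s, "imagination", ang, "n/a", "n/a")
        )
        rows.append(
            (o.target_onset_s, TARGET_DURATION_S, "target", "n/a", trial.target, "n/a")
        )
        rows.append(
            (
                o.target_onset_s + TARGET_DURATION_S,
                o.response_window_s,
                "response",
                "n/a",
                "n/a",
                trial.correct_side,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(session: SessionDesign, out_dir) -> list[str]:
    """One BIDS-style events TSV per run; returns the written paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for run in session.runs:
        path = os.path.join(out_dir, f"run-{run.run_index:02d}_events.tsv")
        run_events(run).to_csv(path, sep="\t", index=False, na_rep="n/a")
        paths.append(path)
    return paths


def read_events(path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events`."""
    return pd.read_csv(path, sep="\t", na_values=["n/a"])
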