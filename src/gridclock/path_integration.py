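"""Scoring of the real-world path-integration (homing) task.

Blindfolded participants are led along paths inside half a tennis court
(10.97 x 11.88 m) and, at two stopping points per path, report the
Euclidean distance and the direction back to the start.  Distance reports
are first rescaled by correction factors obtained from 5 m and 10 m
standardization walks (removing a participant's global tendency to under-
or over-estimate distances), then each report is converted into a
"presumed start" position.  The error of each path segment is the
displacement between successive presumed starts (the first one is
compared against the true start), which scores each segment independently
instead of accumulating bias along the path.  Overall performance is the
reciprocal of the mean error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

COURT_WIDTH_M = 10.97
COURT_LENGTH_M = 11.88
DISTANCE_BRANCH_M = 7.5  # reports up to here use the 5 m factor


@dataclass(frozen=True)
class CourtGeometry:
    width_m: float = COURT_WIDTH_M
    length_m: float = COURT_LENGTH_M

    def contains(self, xy: tuple[float, float], tol: float = 1e-9) -> bool:
        x, y = xy
        return -tol <= x <= self.width_m + tol and -tol <= y <= self.length_m + tol


@dataclass(frozen=True)
class StopSpec:
    xy: tuple[float, float]
    true_distance_m: float
    true_orientation_deg: float  # direction from stop back to the start


@dataclass(frozen=True)
class PIPathSpec:
    path_id: str
    start_xy: tuple[float, float]
    stops: tuple[StopSpec, StopSpec]


@dataclass(frozen=True)
class PIResponse:
    path_id: str
    stop_index: int
    d_response: float
    ori_response_deg: float


@dataclass(frozen=True)
class StandardizationSet:
    """Distance reports for the 5 m and 10 m walks at session start and end."""

    responses_5m: tuple[float, float]
    responses_10m: tuple[float, float]

    @property
    def avg_5m(self) -> float:
        return sum(self.responses_5m) / 2.0

    @property
    def avg_10m(self) -> float:
        return sum(self.responses_10m) / 2.0


@dataclass
class PIScorecard:
    cf5: float
    cf10: float
    corrected: dict[tuple[str, int], float]
    presumed_starts: dict[tuple[str, int], tuple[float, float]]
    errors: dict[tuple[str, int], float]
    mean_error: float
    performance: float  # math.inf flags a zero mean error


def make_stop(start_xy, stop_xy) -> StopSpec:
    """Derive the true distance and homing direction of a stopping point."""
    dx = start_xy[0] - stop_xy[0]
    dy = start_xy[1] - stop_xy[1]
    return StopSpec(
        xy=tuple(stop_xy),
        true_distance_m=math.hypot(dx, dy),
        true_orientation_deg=math.degrees(math.atan2(dy, dx)) % 360.0,
    )


def make_path(path_id: str, start_xy, stop1_xy, stop2_xy) -> PIPathSpec:
    return PIPathSpec(
        path_id=path_id,
        start_xy=tuple(start_xy),
        stops=(make_stop(start_xy, stop1_xy), make_stop(start_xy, stop2_xy)),
    )


def default_court_paths() -> list[PIPathSpec]:
    """Synthetic eight-path fixture along court lines.

    The study's own path table is not reproduced here; these paths follow
    the court's grid lines with stop distances inside the 4-14 m range and
    serve as a stand-in session of eight unique paths (each walked twice
    for the 16 experimental traversals).
    """
    w, l = COURT_WIDTH_M, COURT_LENGTH_M
    half_w, half_l = w / 2.0, l / 2.0
    specs = [
        ("p1", (0.0, 0.0), (half_w, 0.0), (half_w, half_l)),
        ("p2", (w, 0.0), (w, half_l), (half_w, half_l)),
        ("p3", (0.0, l), (0.0, half_l), (half_w, half_l)),
        ("p4", (w, l), (half_w, l), (half_w, half_l)),
        ("p5", (0.0, 0.0), (0.0, half_l), (half_w, l)),
        ("p6", (w, 0.0), (half_w, 0.0), (0.0, half_l)),
        ("p7", (half_w, 0.0), (w, half_l), (w, l)),
        ("p8", (0.0, half_l), (half_w, half_l), (half_w, l)),
    ]
    court = CourtGeometry()
    paths = []
    for pid, start, s1, s2 in specs:
        path = make_path(pid, start, s1, s2)
        assert all(court.contains(s.xy) for s in path.stops)
        assert all(4.0 <= s.true_distance_m <= 14.0 for s in path.stops)
        paths.append(path)
    return paths


def correction_factors(std: StandardizationSet) -> tuple[float, float]:
    """Cf = true walk length / averaged reported length, for 5 m and 10 m."""
    if std.avg_5m <= 0 or std.avg_10m <= 0:
        raise ValueError("standardization responses must be positive")
    return 5.0 / std.avg_5m, 10.0 / std.avg_10m


def correct_distance(d_response: float, cf5: float, cf10: float) -> float:
    """Rescale a reported distance by the appropriate correction factor.

    Reports up to 7.5 m use the 5 m factor, larger ones the 10 m factor;
    reports below the 4 m task range also use the 5 m factor.
    """
    if d_response <= 0:
        raise ValueError("reported distance must be positive")
    return d_response * (cf5 if d_response <= DISTANCE_BRANCH_M else cf10)


def presumed_start(
    stop_xy: tuple[float, float], d_corrected: float, ori_deg: float
) -> tuple[float, float]:
    """Project the corrected report from the stop to the presumed start."""
    ori = math.radians(ori_deg)
    return (
        stop_xy[0] + d_corrected * math.cos(ori),
        stop_xy[1] + d_corrected * math.sin(ori),
    )


def segment_errors(
    path: PIPathSpec,
    responses: list[PIResponse],
    cf5: float,
    cf10: float,
) -> tuple[list[float], list[tuple[float, float]]]:
    """Per-stop errors for one traversal.

    Error k is the distance between the presumed start computed at stop k
    and the one computed at stop k-1; the reference for the first stop is
    the true start.  A perfect integrator scores zero at every stop.
    """
    by_stop = {r.stop_index: r for r in responses}
    errors = []
    presumed = []
    prev = path.start_xy
    for k, stop in enumerate(path.stops):
        if k not in by_stop:
            raise ValueError(f"missing response for stop {k} of {path.path_id}")
        r = by_stop[k]
        d_corr = correct_distance(r.d_response, cf5, cf10)
        p = presumed_start(stop.xy, d_corr, r.ori_response_deg)
        errors.append(math.hypot(p[0] - prev[0], p[1] - prev[1]))
        presumed.append(p)
        prev = p
    return errors, presumed


def pi_performance(all_errors) -> tuple[float, float]:
    """Mean error across stops and traversals, and its reciprocal."""
    errors = np.asarray(list(all_errors), float)
    if errors.size == 0:
        raise ValueError("no errors supplied")
    mean_error = float(errors.mean())
    # a perfect integrator scores zero up to trigonometric round-off
    performance = math.inf if mean_error < 1e-12 else 1.0 / mean_error
    return mean_error, performance


def score_session(
    paths: list[PIPathSpec],
    responses: list[PIResponse],
    std: StandardizationSet,
) -> PIScorecard:
    """Score a full session: corrections, presumed starts, errors, performance.

    ``responses`` may cover repeated traversals; a response's ``path_id``
    must match ``<path_id>`` or ``<path_id>_repN``.
    """
    cf5, cf10 = correction_factors(std)
    by_traversal: dict[str, list[PIResponse]] = {}
    for r in responses:
        by_traversal.setdefault(r.path_id, []).append(r)
    base = {p.path_id: p for p in paths}

    corrected = {}
    presumed = {}
    errors = {}
    for trav_id, resp in sorted(by_traversal.items()):
        base_id = trav_id.split("_rep")[0]
        if base_id not in base:
            raise ValueError(f"response references unknown path {trav_id}")
        errs, pres = segment_errors(base[base_id], resp, cf5, cf10)
        for k, (e, p) in enumerate(zip(errs, pres)):
            errors[(trav_id, k)] = e
            presumed[(trav_id, k)] = p
        for r in resp:
            corrected[(trav_id, r.stop_index)] = correct_distance(r.d_response, cf5, cf10)

    mean_error, performance = pi_performance(errors.values())
    return PIScorecard(
        cf5=cf5,
        cf10=cf10,
        corrected=corrected,
        presumed_starts=presumed,
        errors=errors,
        mean_error=mean_error,
        performance=performance,
    )
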