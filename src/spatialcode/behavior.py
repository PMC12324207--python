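"""Behavioral scoring: clockmaze strategies and probe zones, exploration
ratios for object-memory and anxiety tasks.

Clockmaze trials are classified per trial as ``spatial`` (escaped within
60 s with at most 4 decoy errors), ``chain`` (escaped within 60 s with more
than 4 errors) or ``futile`` (no escape within 60 s); the strategy score of
a trial block is the mean of the ranks futile=0 / chain=1 / spatial=2
rescaled to [0, 1].  Probe-test paths are partitioned into twelve equal
30-degree arcs — one target zone containing the true exit, eleven
non-target zones.  Object tasks use signed exploration-time contrasts:
OPM = (moved - stable) / total, NOR = (novel - familiar) / total,
investigation = right / total, anxiety tasks = (closed - open) / total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import Trajectory

__all__ = ["TrialRecord", "ZoneOccupancy", "RatioResult",
           "classify_strategy", "strategy_score", "task_ratio",
           "probe_zones", "ESCAPE_LIMIT_S", "ERROR_LIMIT"]

#: Escape deadline (s) separating futile from successful trials.
ESCAPE_LIMIT_S = 60.0
#: Maximum decoy-zone errors for a trial to count as spatial.
ERROR_LIMIT = 4

_RANK = {"futile": 0, "chain": 1, "spatial": 2}


@dataclass
class TrialRecord:
    trial_id: str
    latency: float  # s to escape (or deadline if not escaped)
    errors: int  # decoy-zone inspections
    escaped: bool
    distance: float = float("nan")  # cm
    strategy: str | None = None

    def __post_init__(self) -> None:
        if self.errors < 0:
            raise ValueError("error count cannot be negative")


@dataclass
class ZoneOccupancy:
    tz_time: float
    nz_times: np.ndarray  # 11 values, s

    @property
    def total(self) -> float:
        return float(self.tz_time + self.nz_times.sum())


@dataclass
class RatioResult:
    task: str
    ratio: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.ratio)


def classify_strategy(trial: TrialRecord) -> str:
    """Strategy class of one trial: futile if no escape within 60 s;
    otherwise chain if more than 4 errors, else spatial.

    A trial with exactly 4 errors counts as spatial.
    """
    if not trial.escaped or trial.latency >= ESCAPE_LIMIT_S:
        return "futile"
    return "chain" if trial.errors > ERROR_LIMIT else "spatial"


def strategy_score(trials: list[TrialRecord]) -> float:
    """Mean strategy rank (futile=0, chain=1, spatial=2) rescaled to [0, 1]."""
    if not trials:
        raise ValueError("no trials supplied")
    ranks = [_RANK[classify_strategy(t)] for t in trials]
    return float(np.mean(ranks) / 2.0)


_RATIO_KEYS: dict[str, tuple[str, str] | tuple[str, str, str]] = {
    "opm": ("moved", "stable"),
    "nor": ("novel", "familiar"),
    "investigation": ("right", "left"),
    "epm": ("closed", "open"),
    "lightdark": ("closed", "open"),
    "zeromaze": ("closed", "open"),
}


def task_ratio(task: str, times: dict[str, float]) -> RatioResult:
    """Signed exploration-time ratio for a behavioral task.

    opm: (moved - stable)/(moved + stable); nor: (novel - familiar)/total;
    investigation: right/(right + left); epm/lightdark/zeromaze:
    (closed - open)/(closed + open).  A zero total yields NaN with a flag.
    """
    task = task.lower()
    if task not in _RATIO_KEYS:
        raise ValueError(f"unknown task {task!r}")
    a_key, b_key = _RATIO_KEYS[task]
    a, b = float(times[a_key]), float(times[b_key])
    if a < 0 or b < 0:
        raise ValueError("durations must be non-negative")
    total = a + b
    if total == 0:
        return RatioResult(task=task, ratio=float("nan"))
    if task == "investigation":
        return RatioResult(task=task, ratio=a / total)
    return RatioResult(task=task, ratio=(a - b) / total)


def probe_zones(path: Trajectory, maze_center: tuple[float, float],
                true_exit_angle: float, maze_radius: float | None = None
                ) -> ZoneOccupancy:
    """Dwell time in the twelve 30-degree arcs of the clockmaze probe.

    Arcs are centered on the twelve exits; the target zone (TZ) is the arc
    centered on ``true_exit_angle`` (radians, math convention).  Frames
    outside ``maze_radius`` are assigned by angle anyway (clipped), so zone
    times always partition the tracked duration.
    """
    dx = path.x - maze_center[0]
    dy = path.y - maze_center[1]
    if maze_radius is not None and np.any(np.hypot(dx, dy) > maze_radius):
        import warnings
        warnings.warn("frames outside the maze radius were clipped to arcs")
    ang = np.arctan2(dy, dx)
    # zone index 0 = TZ; arcs are 30 deg wide, centered on the exits
    rel = (ang - true_exit_angle + np.pi / 12) % (2 * np.pi)
    zone = (rel // (np.pi / 6)).astype(int) % 12
    dt = np.empty_like(path.t)
    dt[:-1] = np.diff(path.t)
    dt[-1] = dt[-2] if path.t.size > 1 else 0.0
    times = np.zeros(12)
    np.add.at(times, zone, dt)
    return ZoneOccupancy(tz_time=float(times[0]), nz_times=times[1:])
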