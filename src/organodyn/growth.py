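"""Discrete-time progenitor/neuron growth model and cell-cycle utilities.

The model tracks a progenitor pool ``p_t`` and a neuron pool ``n_t`` on a
1-day grid. During the first half of the simulated period divisions are
symmetric expansive and the pool doubles ``f(t)`` times per day::

    p_t = p_{t-1} * 2**f(t)

During the second half a fraction ``r_a(t)`` of divisions is asymmetric
neurogenic (one progenitor, one neuron) and the remainder ``r_s = 1 - r_a``
stays symmetric::

    p_t = p_{t-1} * r_a(t) + p_{t-1} * r_s(t) * 2**f(t)
    n_t = n_{t-1} + p_{t-1} * r_a(t)

``f`` is the number of divisions per day, obtained from a measured mean
cell-cycle length ``T`` (hours) as ``f = 24 / T``. A species-specific
``f`` may be applied inside a window of the symmetric phase; when two runs
differ only in the window ``f``, the final-count ratio is exactly
``2 ** (delta_f * window_days)`` regardless of every other parameter
(initial pool size, total duration, asymmetric-division schedule), which is
what makes the fold-change prediction robust.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DivisionTrackSet",
    "GrowthParams",
    "Trajectory",
    "cycle_length",
    "divisions_per_day",
    "simulate_growth",
    "fold_change",
    "invariance_scan",
]


# ---------------------------------------------------------------------------
# cell-cycle measurements


@dataclass(frozen=True)
class DivisionTrackSet:
    """Ordered division timestamps (hours) for a set of tracked cells."""

    tracks: tuple[tuple[str, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        for tid, times in self.tracks:
            arr = np.asarray(times, dtype=float)
            if arr.size >= 2 and not np.all(np.diff(arr) > 0):
                raise ValueError(
                    f"division times must be strictly increasing (track {tid!r})"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DivisionTrackSet":
        """Build from a long table with columns ``track_id`` and ``event_time_h``."""
        tracks = []
        for tid, grp in df.groupby("track_id", sort=True):
            times = tuple(sorted(float(t) for t in grp["event_time_h"]))
            tracks.append((str(tid), times))
        return cls(tuple(tracks))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"track_id": tid, "event_time_h": t}
            for tid, times in self.tracks
            for t in times
        ]
        return pd.DataFrame(rows, columns=["track_id", "event_time_h"])


def cycle_length(tracks: DivisionTrackSet) -> float:
    """Mean cell-cycle length in hours.

    The cycle of one cell is the interval between two consecutive divisions.
    Tracks with more than two divisions contribute the mean of their
    intervals, so every tracked cell carries equal weight; tracks with fewer
    than two divisions carry no cycle information and are skipped.
    """
    per_cell: list[float] = []
    for _tid, times in tracks.tracks:
        if len(times) < 2:
            continue
        intervals = np.diff(np.asarray(times, dtype=float))
        per_cell.append(float(np.mean(intervals)))
    if not per_cell:
        raise ValueError("no track contains two divisions; cannot measure a cycle")
    return float(np.mean(per_cell))


def divisions_per_day(cycle_hours: float) -> float:
    """Convert a mean cell-cycle length (hours) to divisions per day, f = 24/T."""
    if cycle_hours <= 0:
        raise ValueError(f"cycle length must be positive, got {cycle_hours}")
    return 24.0 / cycle_hours


# ---------------------------------------------------------------------------
# growth model


def _linear_schedule(t_grid: np.ndarray, start: float, stop: float) -> np.ndarray:
    if t_grid.size == 1:
        return np.array([start], dtype=float)
    return np.linspace(start, stop, t_grid.size)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one growth-model run.

    Parameters
    ----------
    t_total
        Total simulated duration in days; the symmetric expansive phase is
        days ``1 .. t_total//2``, the mixed neurogenic phase the rest.
    p0
        Initial progenitor count (arbitrary units; the model is linear in it).
    f_early, f_late
        Endpoints of the baseline divisions-per-day schedule, interpolated
        linearly across the symmetric phase (higher early, lower late).
    window
        Optional ``(start_day, end_day, f_window)`` override: ``f_window``
        replaces the baseline ``f`` for days ``start_day < t <= end_day``,
        i.e. for ``end_day - start_day`` division steps. Must lie inside the
        symmetric phase.
    ra_schedule
        Asymmetric-division fraction per mixed-phase day. Either ``None``
        (linear ramp 0 -> 1 across the mixed phase) or an explicit sequence
        with one value in [0, 1] per mixed-phase day.
    """

    t_total: int = 20
    p0: float = 1.0
    f_early: float = 1.4
    f_late: float = 0.9
    window: tuple[int, int, float] | None = None
    ra_schedule: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.t_total < 2:
            raise ValueError("t_total must be at least 2 days")
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")
        if self.f_early <= 0 or self.f_late <= 0:
            raise ValueError("divisions per day must be positive")
        half = self.t_total // 2
        if self.window is not None:
            start, end, f_w = self.window
            if not (0 <= start < end <= half):
                raise ValueError(
                    f"window ({start}, {end}) must lie inside the symmetric "
                    f"phase (days 0..{half})"
                )
            if f_w <= 0:
                raise ValueError("window f must be positive")
        if self.ra_schedule is not None:
            n_mixed = self.t_total - half
            if len(self.ra_schedule) != n_mixed:
                raise ValueError(
                    f"ra_schedule needs {n_mixed} values (one per mixed-phase day)"
                )
            if any(not (0.0 <= r <= 1.0) for r in self.ra_schedule):
                raise ValueError("r_a values must lie in [0, 1]")

    @property
    def half(self) -> int:
        return self.t_total // 2

    def f_of_day(self, t: int) -> float:
        """Divisions per day applied at step ``t`` (1-based day index)."""
        half = self.half
        if self.window is not None:
            start, end, f_w = self.window
            if start < t <= end:
                return f_w
        if t <= half:
            sched = _linear_schedule(np.arange(1, half + 1), self.f_early, self.f_late)
            return float(sched[t - 1])
        # baseline f continues at its late value through the mixed phase
        return self.f_late

    def ra_of_day(self, t: int) -> float:
        """Asymmetric fraction at step ``t``; zero throughout the symmetric phase."""
        half = self.half
        if t <= half:
            return 0.0
        n_mixed = self.t_total - half
        idx = t - half - 1
        if self.ra_schedule is not None:
            return float(self.ra_schedule[idx])
        ramp = _linear_schedule(np.arange(n_mixed), 0.0, 1.0)
        return float(ramp[idx])


@dataclass(frozen=True)
class Trajectory:
    """Per-day progenitor and neuron counts."""

    days: tuple[int, ...]
    p: tuple[float, ...]
    n: tuple[float, ...]

    @property
    def final_p(self) -> float:
        return self.p[-1]

    @property
    def final_n(self) -> float:
        return self.n[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "p": self.p, "n": self.n})


def simulate_growth(params: GrowthParams) -> Trajectory:
    """Run the two-phase difference-equation model day by day."""
    p = float(params.p0)
    n = 0.0
    days = [0]
    ps = [p]
    ns = [n]
    for t in range(1, params.t_total + 1):
        f = params.f_of_day(t)
        ra = params.ra_of_day(t)
        if ra == 0.0:
            p_next = p * 2.0**f
            n_next = n
        else:
            rs = 1.0 - ra
            p_next = p * ra + p * rs * 2.0**f
            n_next = n + p * ra
        p, n = p_next, n_next
        days.append(t)
        ps.append(p)
        ns.append(n)
    return Trajectory(tuple(days), tuple(ps), tuple(ns))


def fold_change(traj_a: Trajectory, traj_b: Trajectory) -> tuple[float, float]:
    """Final-day (progenitor, neuron) ratios of trajectory A over B."""
    if traj_a.days[-1] != traj_b.days[-1]:
        raise ValueError("trajectories must span the same number of days")
    n_ratio = (
        traj_a.final_n / traj_b.final_n if traj_b.final_n > 0 else float("nan")
    )
    return traj_a.final_p / traj_b.final_p, n_ratio


def predicted_ratio(f_a: float, f_b: float, window_days: int) -> float:
    """Closed-form fold change 2**((f_a - f_b) * window_days)."""
    return 2.0 ** ((f_a - f_b) * window_days)


def invariance_scan(
    f_a: float,
    f_b: float,
    window: tuple[int, int],
    p0_grid: Sequence[float] = (1.0, 10.0, 100.0),
    t_total_grid: Sequence[int] = (16, 20, 30),
    ra_factories: Sequence[Callable[[int], tuple[float, ...]] | None] = (None,),
) -> pd.DataFrame:
    """Fold-change ratios across a grid of arbitrary model parameters.

    Every grid point runs two trajectories that differ only in the window
    ``f`` (``f_a`` vs ``f_b``) and records the final progenitor and neuron
    ratios; all of them equal ``2**((f_a - f_b) * window_days)`` up to
    floating-point rounding. ``ra_factories`` maps a mixed-phase length to an
    explicit asymmetric-division schedule (``None`` = default linear ramp).
    """
    start, end = window
    rows = []
    for p0 in p0_grid:
        for t_total in t_total_grid:
            half = t_total // 2
            if not (0 <= start < end <= half):
                raise ValueError(
                    f"window {window} outside symmetric phase for t_total={t_total}"
                )
            for i, factory in enumerate(ra_factories):
                ra = factory(t_total - half) if factory is not None else None
                base = dict(t_total=t_total, p0=p0, ra_schedule=ra)
                ta = simulate_growth(
                    GrowthParams(window=(start, end, f_a), **base)
                )
                tb = simulate_growth(
                    GrowthParams(window=(start, end, f_b), **base)
                )
                p_ratio, n_ratio = fold_change(ta, tb)
                rows.append(
                    {
                        "p0": p0,
                        "t_total": t_total,
                        "ra_variant": i,
                        "p_ratio": p_ratio,
                        "n_ratio": n_ratio,
                    }
                )
    return pd.DataFrame(rows)
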