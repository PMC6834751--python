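"""Zone-occupancy scoring: avoidance preference and novel-tank endpoints.

Trajectories are timestamped point samples; between samples the fish is
assumed to stay where last seen (zero-order hold), so every scored quantity
is a time-weighted sum of sample holding intervals.  Holding intervals longer
than a gap tolerance are truncated and the score is reported over the time
actually covered, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConditioningSchedule, SessionConfig
from .io import DataError

__all__ = ["OccupancyResult", "preference_fraction", "score_conditioning", "tank_endpoints"]


@dataclass
class OccupancyResult:
    """Per-subject occupancy endpoints.

    Conditioning fields are fractions of phase time spent on the CS+ side;
    tank fields are the novel-tank endpoints.  Either block may be None when
    only one assay was scored.
    """

    subject_id: str
    # Pavlovian avoidance
    baseline_pref: float | None = None
    probe_pref: float | None = None
    delta_pref: float | None = None
    baseline_cs_plus_s: float | None = None
    probe_cs_plus_s: float | None = None
    # novel tank
    total_distance_cm: float | None = None
    time_bottom_s: float | None = None
    time_middle_s: float | None = None
    time_top_s: float | None = None
    immobility_s: float | None = None
    thigmotaxis_s: float | None = None
    covered_time_s: float | None = None

    def to_record(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _hold_intervals(
    times: np.ndarray, window_end: float, gap_tolerance_s: float
) -> tuple[np.ndarray, float]:
    """Holding interval of each sample, truncated at the gap tolerance.

    The last sample holds until the window end.  Returns the per-sample
    weights and the total truncated (uncovered) time.
    """
    dt = np.append(np.diff(times), max(window_end - times[-1], 0.0))
    capped = np.minimum(dt, gap_tolerance_s)
    return capped, float(np.sum(dt - capped))


def preference_fraction(
    traj: pd.DataFrame,
    schedule: ConditioningSchedule,
    phase: str,
    arena_length_cm: float = 25.0,
    midline_cm: float | None = None,
    gap_tolerance_s: float = 1.0,
) -> float:
    """Fraction of a phase's covered time spent on the CS+ side.

    ``traj`` holds one subject's samples (columns ``time_s``, ``u``) in
    session time; ``phase`` is ``'baseline'`` or ``'probe'``.  The arena is
    split at the midline (default half the length): ``u`` strictly below the
    midline is the left side.  The CS+ side at each instant follows the
    schedule, including the habituation/baseline side alternation and the
    mid-probe switch.
    """
    if phase == "baseline":
        start, end = schedule.baseline_window
    elif phase == "probe":
        start, end = schedule.probe_window
    else:
        raise ValueError(f"phase must be 'baseline' or 'probe', got {phase!r}")
    mid = arena_length_cm / 2.0 if midline_cm is None else midline_cm

    sel = traj[(traj["time_s"] >= start) & (traj["time_s"] < end)]
    if sel.empty:
        raise DataError(f"no trajectory samples inside the {phase} window")
    t = sel["time_s"].to_numpy(dtype=float)
    u = sel["u"].to_numpy(dtype=float)
    weights, uncovered = _hold_intervals(t, end, gap_tolerance_s)
    if uncovered > 0 or t[0] - start > gap_tolerance_s:
        warnings.warn(
            f"{phase} phase has {uncovered + max(t[0] - start, 0):.1f} s of "
            "trajectory gaps; preference computed over covered time",
            stacklevel=2,
        )
    side = np.where(u < mid, "left", "right")
    cs_side = np.array([schedule.cs_plus_side(ti) for ti in t])
    covered = float(weights.sum())
    return float(weights[side == cs_side].sum() / covered)


def score_conditioning(
    traj: pd.DataFrame,
    schedule: ConditioningSchedule,
    subject_id: str | None = None,
    arena_length_cm: float = 25.0,
    midline_cm: float | None = None,
    gap_tolerance_s: float = 1.0,
) -> OccupancyResult:
    """Baseline and probe CS+ preference plus their difference.

    ``delta_pref = probe - baseline``; avoidance learning shows as a negative
    delta.  Habituation samples are ignored.  Absolute CS+ seconds are also
    reported alongside the fractions.
    """
    sid = subject_id or str(traj["subject_id"].iloc[0])
    kw = dict(
        arena_length_cm=arena_length_cm,
        midline_cm=midline_cm,
        gap_tolerance_s=gap_tolerance_s,
    )
    base = preference_fraction(traj, schedule, "baseline", **kw)
    probe = preference_fraction(traj, schedule, "probe", **kw)
    return OccupancyResult(
        subject_id=sid,
        baseline_pref=base,
        probe_pref=probe,
        delta_pref=probe - base,
        baseline_cs_plus_s=base * schedule.baseline_s,
        probe_cs_plus_s=probe * schedule.probe_s,
    )


def tank_endpoints(
    traj_front: pd.DataFrame,
    traj_top: pd.DataFrame,
    cfg: SessionConfig,
    subject_id: str | None = None,
) -> OccupancyResult:
    """Novel-tank endpoints from synchronized front- and top-view tracks.

    * thirds of the tank = three equal horizontal slabs of the height;
      the front view's ``v`` is height above the floor
    * total distance = summed Euclidean step lengths in the top view
    * immobility = total time inside runs where top-view speed stays below
      ``cfg.immobility_speed_cms`` for at least ``cfg.immobility_min_duration_s``
    * thigmotaxis = time with the top-view position within
      ``cfg.thigmotaxis_margin_cm`` of any wall

    The two views must share a time base sample for sample.
    """
    sid = subject_id or str(traj_front["subject_id"].iloc[0])
    t_f = traj_front["time_s"].to_numpy(dtype=float)
    t_t = traj_top["time_s"].to_numpy(dtype=float)
    if len(t_f) != len(t_t) or not np.allclose(t_f, t_t):
        raise DataError(f"subject {sid}: front/top trajectory time bases differ")
    t = t_f
    depth = traj_front["v"].to_numpy(dtype=float)  # height above floor
    x = traj_top["u"].to_numpy(dtype=float)
    y = traj_top["v"].to_numpy(dtype=float)

    end = float(t[-1]) + (float(np.median(np.diff(t))) if len(t) > 1 else 0.0)
    weights, _ = _hold_intervals(t, end, cfg.trajectory_gap_tolerance_s)
    covered = float(weights.sum())

    third = cfg.tank_height_cm / 3.0
    time_bottom = float(weights[depth < third].sum())
    time_top = float(weights[depth >= 2.0 * third].sum())
    time_middle = covered - time_bottom - time_top

    steps = np.hypot(np.diff(x), np.diff(y))
    total_distance = float(steps.sum())

    # immobility: contiguous sub-threshold-speed runs lasting long enough
    immobility = 0.0
    if len(t) > 1:
        dt = np.diff(t)
        speed = steps / np.where(dt > 0, dt, np.inf)
        slow = speed < cfg.immobility_speed_cms
        i = 0
        while i < len(slow):
            if slow[i]:
                j = i
                while j < len(slow) and slow[j]:
                    j += 1
                # a run reaching the final sample extends through its hold
                run_end = end if j == len(slow) else float(t[j])
                duration = run_end - float(t[i])
                if duration >= cfg.immobility_min_duration_s:
                    immobility += duration
                i = j
            else:
                i += 1

    m = cfg.thigmotaxis_margin_cm
    near_wall = (
        (x < m)
        | (x > cfg.tank_length_cm - m)
        | (y < m)
        | (y > cfg.tank_width_cm - m)
    )
    thigmotaxis = float(weights[near_wall].sum())

    return OccupancyResult(
        subject_id=sid,
        total_distance_cm=total_distance,
        time_bottom_s=time_bottom,
        time_middle_s=time_middle,
        time_top_s=time_top,
        immobility_s=immobility,
        thigmotaxis_s=thigmotaxis,
        covered_time_s=covered,
    )
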