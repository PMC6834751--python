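"""Turn coding: from arm-entry events to left/right choice sequences.

Every passage from one maze arm to a different arm is a binary choice.  With
the three arms laid out at 120 degrees and labelled in clockwise order (seen
from above), moving to the clockwise neighbour is coded ``R`` and to the
counter-clockwise neighbour ``L``.  Centre-zone entries and repeated entries
into the same arm complete no choice and emit no token; both are counted for
quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SessionConfig

__all__ = ["MazeGeometry", "TurnSequence", "events_to_turns", "assign_bins"]


@dataclass(frozen=True)
class MazeGeometry:
    """Three-arm maze layout.

    ``arms`` lists the arm zone labels in clockwise order viewed from above;
    ``reflect=True`` flips the left/right convention to match rigs filmed or
    labelled mirror-wise.  ``debounce_s`` drops zone entries dwelt in for less
    than that long before any coding (default 0: every entry counts).
    """

    arms: tuple[str, str, str] = ("arm0", "arm1", "arm2")
    centre: str = "centre"
    debounce_s: float = 0.0
    reflect: bool = False

    def __post_init__(self) -> None:
        if len(self.arms) != 3 or len(set(self.arms)) != 3:
            raise ValueError("geometry requires exactly three distinct arm labels")
        if self.centre in self.arms:
            raise ValueError("centre label must differ from arm labels")
        if self.debounce_s < 0:
            raise ValueError("debounce_s must be non-negative")

    @property
    def zones(self) -> frozenset[str]:
        return frozenset(self.arms) | {self.centre}


@dataclass
class TurnSequence:
    """Ordered left/right tokens with the entry time of each new arm."""

    subject_id: str
    tokens: np.ndarray  # dtype '<U1', values 'L'/'R'
    turn_times_s: np.ndarray
    bin_index: np.ndarray | None = None
    # QC counters: events that completed no choice
    n_centre_events: int = 0
    n_same_arm_reentries: int = 0
    n_debounced: int = 0

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype="<U1")
        self.turn_times_s = np.asarray(self.turn_times_s, dtype=float)
        if self.tokens.shape != self.turn_times_s.shape:
            raise ValueError("tokens and turn_times_s must have equal length")
        if self.turn_times_s.size and np.any(np.diff(self.turn_times_s) < 0):
            raise ValueError("turn times must be non-decreasing")
        bad = set(self.tokens.tolist()) - {"L", "R"}
        if bad:
            raise ValueError(f"tokens must be 'L' or 'R', found {sorted(bad)}")

    @property
    def n_turns(self) -> int:
        return int(self.tokens.size)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "token": self.tokens,
                "turn_time_s": self.turn_times_s,
            }
        )
        if self.bin_index is not None:
            out["bin_index"] = self.bin_index
        return out


def events_to_turns(events: pd.DataFrame, geometry: MazeGeometry) -> TurnSequence:
    """Code an arm-entry event stream into a left/right turn sequence.

    ``events`` holds one subject's rows with columns ``time_s``, ``subject_id``
    and ``zone``, sorted by time.  Entries dwelt in for less than
    ``geometry.debounce_s`` are dropped first (the final entry's dwell is
    open-ended and always kept), then centre entries are set aside, then runs
    of the same arm are collapsed; each remaining transition between distinct
    arms emits one token stamped with the entry time into the new arm.

    Fewer than two distinct arm entries yield an empty sequence — a valid,
    non-engaged session, not an error.
    """
    if events.empty:
        raise ValueError("empty event stream")
    subjects = events["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"expected one subject per call, got {list(subjects)}")
    subject_id = str(subjects[0])

    times = events["time_s"].to_numpy(dtype=float)
    zones = events["zone"].to_numpy(dtype=object)
    if np.any(np.diff(times) < 0):
        raise ValueError(f"events for subject {subject_id} are not time-sorted")
    unknown = set(zones) - geometry.zones
    if unknown:
        raise ValueError(
            f"unknown zone labels for subject {subject_id}: {sorted(unknown)}"
        )

    # debounce: dwell of entry i runs to the next event; the last is open-ended
    n_debounced = 0
    if geometry.debounce_s > 0 and len(times) > 1:
        dwell = np.diff(times)
        keep = np.append(dwell >= geometry.debounce_s, True)
        n_debounced = int((~keep).sum())
        times, zones = times[keep], zones[keep]

    is_centre = np.array([z == geometry.centre for z in zones])
    n_centre = int(is_centre.sum())
    times, zones = times[~is_centre], zones[~is_centre]

    # collapse consecutive same-arm runs; each collapsed run after the first
    # entry is a same-arm re-entry (arm -> centre -> same arm)
    if len(zones):
        new_arm = np.append(True, zones[1:] != zones[:-1])
        n_reentry = int((~new_arm).sum())
        times, zones = times[new_arm], zones[new_arm]
    else:
        n_reentry = 0

    arm_index = {arm: i for i, arm in enumerate(geometry.arms)}
    tokens: list[str] = []
    turn_times: list[float] = []
    for prev, cur, t in zip(zones[:-1], zones[1:], times[1:]):
        step = (arm_index[cur] - arm_index[prev]) % 3
        token = "R" if step == 1 else "L"
        if geometry.reflect:
            token = "L" if token == "R" else "R"
        tokens.append(token)
        turn_times.append(t)

    return TurnSequence(
        subject_id=subject_id,
        tokens=np.array(tokens, dtype="<U1"),
        turn_times_s=np.array(turn_times, dtype=float),
        n_centre_events=n_centre,
        n_same_arm_reentries=n_reentry,
        n_debounced=n_debounced,
    )


def assign_bins(seq: TurnSequence, cfg: SessionConfig) -> TurnSequence:
    """Assign each turn to its half-open time bin ``[k*w, (k+1)*w)``.

    A turn stamped exactly at the session end falls into the last bin.
    Turns beyond the session length are a data error.
    """
    t = seq.turn_times_s
    beyond = np.flatnonzero(t > cfg.session_length_s)
    if beyond.size:
        raise ValueError(
            f"subject {seq.subject_id}: {beyond.size} turn(s) beyond the "
            f"{cfg.session_length_s} s session, first at t={t[beyond[0]]}"
        )
    if np.any(t < 0):
        raise ValueError(f"subject {seq.subject_id}: negative turn times")
    bins = np.minimum(np.floor(t / cfg.bin_width_s).astype(int), cfg.n_bins - 1)
    seq.bin_index = bins
    return seq
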