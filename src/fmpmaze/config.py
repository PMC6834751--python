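"""Run configuration for maze, tank and conditioning analyses.

All times are seconds from the start of the relevant session, 0-based.
Time bins are half-open intervals ``[k*bin_width_s, (k+1)*bin_width_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["SessionConfig", "ConditioningSchedule", "load_config"]


@dataclass(frozen=True)
class SessionConfig:
    """Parameters shared across the Y-maze, novel-tank and conditioning assays.

    Parameters
    ----------
    session_length_s
        Length of the Y-maze session (default one hour).
    bin_width_s
        Width of the analysis time bins (default 10 min); must divide
        ``session_length_s`` evenly.
    bias_threshold_pct
        Strict threshold on the overall side-bias percentage above which a
        subject is classed as lateralized (default 60, i.e. > 60 %).
    min_turns_for_inclusion
        Subjects completing fewer total turns are flagged as non-engaged and
        excluded from cohort summaries.
    tank_length_cm, tank_height_cm, tank_width_cm
        Novel-tank dimensions (default 30 x 15 x 12 cm).
    thigmotaxis_margin_cm
        Distance from any wall (top view) inside which a sample counts as
        wall-hugging.  Default 2.4 cm, 20 % of the tank width.
    immobility_speed_cms, immobility_min_duration_s
        A fish is immobile while its speed stays below
        ``immobility_speed_cms`` for at least ``immobility_min_duration_s``.
    trajectory_gap_tolerance_s
        Largest tolerated gap between trajectory samples inside a scored
        phase before a coverage warning is raised.
    random_seed
        Seed propagated to every stochastic stage of a run.
    """

    session_length_s: float = 3600.0
    bin_width_s: float = 600.0
    bias_threshold_pct: float = 60.0
    min_turns_for_inclusion: int = 20
    tank_length_cm: float = 30.0
    tank_height_cm: float = 15.0
    tank_width_cm: float = 12.0
    thigmotaxis_margin_cm: float = 2.4
    immobility_speed_cms: float = 0.5
    immobility_min_duration_s: float = 2.0
    trajectory_gap_tolerance_s: float = 1.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length_s <= 0 or self.bin_width_s <= 0:
            raise ValueError("session_length_s and bin_width_s must be positive")
        n = self.session_length_s / self.bin_width_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "session_length_s must be an integer multiple of bin_width_s "
                f"(got {self.session_length_s} / {self.bin_width_s})"
            )
        if not 50.0 < self.bias_threshold_pct < 100.0:
            raise ValueError("bias_threshold_pct must lie strictly between 50 and 100")
        if self.min_turns_for_inclusion < 0:
            raise ValueError("min_turns_for_inclusion must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(round(self.session_length_s / self.bin_width_s))

    def with_overrides(self, **kwargs) -> "SessionConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ConditioningSchedule:
    """Phase schedule of the Pavlovian avoidance assay.

    The session runs habituation -> baseline -> conditioning trials -> probe,
    contiguously and in that order.  During habituation and baseline the CS+
    and CS- patterns occupy opposite halves of the arena and swap sides every
    ``alternation_s``; during each conditioning trial the CS+ fills the whole
    arena for ``cs_s`` followed by ``iti_s`` of the CS- pattern; during the
    probe both patterns are shown at opposite ends, swapping sides once at
    ``probe_switch_s``.  The shock parameters are metadata only — nothing
    electrical is modelled.
    """

    habituation_s: float = 1800.0
    alternation_s: float = 300.0
    baseline_s: float = 600.0
    n_trials: int = 9
    cs_s: float = 1.5
    iti_s: float = 8.5
    probe_s: float = 60.0
    probe_switch_s: float = 30.0
    cs_plus_pattern: Literal["check", "grey"] = "check"
    cs_plus_start_side: Literal["left", "right"] = "left"
    us_voltage_v: float = 9.0
    us_duration_ms: float = 80.0

    def __post_init__(self) -> None:
        for name in ("habituation_s", "alternation_s", "baseline_s", "probe_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if not 0 < self.probe_switch_s < self.probe_s:
            raise ValueError("probe_switch_s must lie inside the probe window")
        if self.cs_plus_pattern not in ("check", "grey"):
            raise ValueError("cs_plus_pattern must be 'check' or 'grey'")
        if self.cs_plus_start_side not in ("left", "right"):
            raise ValueError("cs_plus_start_side must be 'left' or 'right'")

    # --- phase windows (half-open [start, end) in session seconds) ---

    @property
    def baseline_window(self) -> tuple[float, float]:
        start = self.habituation_s
        return start, start + self.baseline_s

    @property
    def conditioning_window(self) -> tuple[float, float]:
        start = self.habituation_s + self.baseline_s
        return start, start + self.n_trials * (self.cs_s + self.iti_s)

    @property
    def probe_window(self) -> tuple[float, float]:
        start = self.conditioning_window[1]
        return start, start + self.probe_s

    @property
    def total_s(self) -> float:
        return self.probe_window[1]

    def cs_plus_side(self, time_s: float) -> str | None:
        """Side ('left'/'right') holding the CS+ pattern at ``time_s``.

        Returns None during conditioning trials, when a single pattern fills
        the arena and sidedness is undefined.
        """
        other = "right" if self.cs_plus_start_side == "left" else "left"
        if time_s < self.habituation_s + self.baseline_s:
            k = int(time_s // self.alternation_s)
            return self.cs_plus_start_side if k % 2 == 0 else other
        if time_s < self.probe_window[0]:
            return None
        t = time_s - self.probe_window[0]
        return self.cs_plus_start_side if t < self.probe_switch_s else other


def load_config(path: str | Path) -> tuple[SessionConfig, ConditioningSchedule]:
    """Read a YAML key-value config file.

    Top-level keys matching :class:`SessionConfig` fields override session
    defaults; keys under a ``conditioning:`` block override
    :class:`ConditioningSchedule` defaults.  Unknown keys are rejected so
    typos fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    cond_raw = raw.pop("conditioning", {}) or {}
    session_names = {f.name for f in fields(SessionConfig)}
    cond_names = {f.name for f in fields(ConditioningSchedule)}
    unknown = set(raw) - session_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    unknown = set(cond_raw) - cond_names
    if unknown:
        raise ValueError(f"unknown conditioning config keys: {sorted(unknown)}")
    return SessionConfig(**raw), ConditioningSchedule(**cond_raw)
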