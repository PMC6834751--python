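"""Synthetic behavior with known ground truth.

Turn streams come from a two-state first-order Markov chain over {L, R} —
the minimal model expressing both a marginal side bias and the
alternation/repetition axis the tetragram analysis measures:

* ``a = P(next = R | prev = L)``
* ``b = P(next = R | prev = R)``

``a = b`` collapses to an i.i.d. Bernoulli(a) stream; ``a > b`` favours
alternation, ``a < b`` perseveration.  The stationary right-turn probability
is ``a / (a + 1 - b)`` and the chain's second eigenvalue is ``b - a``, which
gives closed forms for the expected tetragram frequencies and for the
sampling variance of overlapping tetragram counts.

Turn times follow a homogeneous Poisson process (exponential inter-turn
intervals) truncated at the session length; class differences in turn rate
implement lower turn counts for particular phenotypes.  Tank and
conditioning trajectories are reflected random walks with optional
depth mean-reversion, wall attraction, and CS+-avoidance drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .config import ConditioningSchedule, SessionConfig
from .laterality import TETRAGRAMS
from .turns import MazeGeometry, TurnSequence

__all__ = [
    "TurnModelParams",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_turn_sequence",
    "simulate_tokens",
    "turns_to_events",
    "expected_tetragram_freqs",
    "tetragram_freq_std",
    "estimate_turn_model",
    "simulate_cohort",
    "simulate_tank_trajectory",
    "simulate_conditioning_trajectory",
]


@dataclass(frozen=True)
class TurnModelParams:
    """First-order Markov turn model with Poisson turn timing."""

    a: float = 0.5  # P(R | prev L)
    b: float = 0.5  # P(R | prev R)
    initial_R_prob: float | None = None  # None: start from the stationary law
    turn_rate_per_min: float = 6.0
    session_length_s: float = 3600.0

    def __post_init__(self) -> None:
        for name in ("a", "b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.initial_R_prob is not None and not 0.0 <= self.initial_R_prob <= 1.0:
            raise ValueError("initial_R_prob must lie in [0, 1]")
        if self.turn_rate_per_min <= 0:
            raise ValueError("turn_rate_per_min must be positive")
        if self.session_length_s <= 0:
            raise ValueError("session_length_s must be positive")

    @property
    def is_ergodic(self) -> bool:
        """True when a unique stationary law exists (a + 1 - b > 0)."""
        return (self.a + 1.0 - self.b) > 0.0

    @property
    def stationary_R(self) -> float:
        """Long-run P(R).  For the reducible chain (a=0, b=1) each state is
        absorbing and the long-run frequency equals the initial law, so the
        initial probability (default 0.5) is returned instead."""
        if self.is_ergodic:
            return self.a / (self.a + 1.0 - self.b)
        return 0.5 if self.initial_R_prob is None else self.initial_R_prob

    @property
    def transition_matrix(self) -> np.ndarray:
        """Rows/cols ordered (L, R)."""
        return np.array([[1.0 - self.a, self.a], [1.0 - self.b, self.b]])


def _start_prob(params: TurnModelParams) -> float:
    if params.initial_R_prob is not None:
        return params.initial_R_prob
    return params.stationary_R


def simulate_turn_sequence(
    params: TurnModelParams, seed: int | np.random.Generator, subject_id: str = "sim0"
) -> TurnSequence:
    """Draw one session's turn stream from the chain and the Poisson clock."""
    rng = np.random.default_rng(seed)
    mean_gap = 60.0 / params.turn_rate_per_min
    # draw arrivals until past the session end
    times: list[float] = []
    t = rng.exponential(mean_gap)
    while t <= params.session_length_s:
        times.append(t)
        t += rng.exponential(mean_gap)
    n = len(times)
    tokens = np.empty(n, dtype="<U1")
    if n:
        state = rng.random() < _start_prob(params)  # True = R
        for i in range(n):
            tokens[i] = "R" if state else "L"
            p_next = params.b if state else params.a
            state = rng.random() < p_next
    return TurnSequence(
        subject_id=subject_id,
        tokens=tokens,
        turn_times_s=np.asarray(times, dtype=float),
    )


def simulate_tokens(
    params: TurnModelParams, n_tokens: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a fixed-length token stream from the chain (no timing)."""
    rng = np.random.default_rng(seed)
    tokens = np.empty(n_tokens, dtype="<U1")
    state = rng.random() < _start_prob(params)
    for i in range(n_tokens):
        tokens[i] = "R" if state else "L"
        state = rng.random() < (params.b if state else params.a)
    return tokens


def turns_to_events(
    seq: TurnSequence,
    geometry: MazeGeometry | None = None,
    start_arm: int = 0,
    include_centre: bool = True,
) -> pd.DataFrame:
    """Encode a turn sequence as the arm-entry event log that produces it.

    The fish starts in ``start_arm`` at t=0; each R moves to the clockwise
    neighbour and each L to the counter-clockwise one (honouring the
    geometry's reflect flag), with an optional centre passage halfway between
    successive arm entries.  Feeding the result through the turn coder
    recovers the token stream exactly.
    """
    geometry = geometry or MazeGeometry()
    arm = start_arm
    rows = [(0.0, seq.subject_id, geometry.arms[arm])]
    prev_t = 0.0
    for token, t in zip(seq.tokens, seq.turn_times_s):
        step = 1 if token == "R" else -1
        if geometry.reflect:
            step = -step
        arm = (arm + step) % 3
        if include_centre:
            rows.append(((prev_t + t) / 2.0, seq.subject_id, geometry.centre))
        rows.append((t, seq.subject_id, geometry.arms[arm]))
        prev_t = t
    return pd.DataFrame(rows, columns=["time_s", "subject_id", "zone"])


def expected_tetragram_freqs(params: TurnModelParams) -> dict[str, float]:
    """Stationary expected relative frequency of each of the 16 tetragrams.

    For word ``w1 w2 w3 w4``: ``pi(w1) * prod_k P(w_{k+1} | w_k)``.  The
    frequencies sum to 1.  For the reducible chain (a=0, b=1) the initial
    law replaces the (non-unique) stationary one, matching the long-run
    window frequencies of a chain frozen in its initial state.
    """
    pi_R = params.stationary_R
    pi = {"l": 1.0 - pi_R, "r": pi_R}
    P = {
        ("l", "r"): params.a,
        ("l", "l"): 1.0 - params.a,
        ("r", "r"): params.b,
        ("r", "l"): 1.0 - params.b,
    }
    out: dict[str, float] = {}
    for w in TETRAGRAMS:
        p = pi[w[0]]
        for x, y in zip(w, w[1:]):
            p *= P[(x, y)]
        out[w] = p
    return out


def _word_prob(word: str, pi: dict, P: dict) -> float:
    p = pi[word[0]]
    for x, y in zip(word, word[1:]):
        p *= P[(x, y)]
    return p


def tetragram_freq_std(params: TurnModelParams, n_tetragrams: int) -> dict[str, float]:
    """Exact sampling SD of each word's relative frequency over ``n`` windows.

    Overlapping windows are dependent: a self-overlapping word such as
    ``llll`` recurs in bursts, inflating its count variance well above the
    binomial value, while non-self-overlapping words are deflated.  Both the
    short-range overlap covariances (lags 1-3, from the joint probability of
    the merged word) and the geometric tail (lags >= 4, via the chain's
    second eigenvalue ``lam = b - a``) are summed in closed form:

        Var(count) = sum_{i,j} Cov(I_i, I_j)
                   = n p(1-p) + 2 sum_{d=1}^{n-1} (n-d) cov_d

    with, for d >= 4,
        cov_d = p q (lam^{d-3}) (delta(w4, w1) - pi(w1))
    where q is the word's internal transition product.
    """
    if not params.is_ergodic:
        return {w: 0.0 for w in TETRAGRAMS}
    n = n_tetragrams
    pi_R = params.stationary_R
    pi = {"l": 1.0 - pi_R, "r": pi_R}
    P = {
        ("l", "r"): params.a,
        ("l", "l"): 1.0 - params.a,
        ("r", "r"): params.b,
        ("r", "l"): 1.0 - params.b,
    }
    lam = params.b - params.a
    out: dict[str, float] = {}
    for w in TETRAGRAMS:
        p = _word_prob(w, pi, P)
        q = p / pi[w[0]] if pi[w[0]] > 0 else 0.0
        var = n * p * (1.0 - p)
        # lags 1..3: overlap must be consistent; joint prob = merged word prob
        for d in (1, 2, 3):
            if d >= n:
                break
            if w[d:] == w[:-d]:  # self-overlap at shift d
                joint = _word_prob(w + w[4 - d :], pi, P)
            else:
                joint = 0.0
            var += 2.0 * (n - d) * (joint - p * p)
        # lags 4..n-1: geometric decay through the chain's spectral gap
        delta = 1.0 if w[3] == w[0] else 0.0
        coef = p * q * (delta - pi[w[0]])
        if abs(lam) > 0:
            # sum_{d=4}^{n-1} (n-d) lam^{d-3} = sum_{m=1}^{n-4} (n-3-m) lam^m
            m = np.arange(1, max(n - 3, 1))
            tail = float(np.sum((n - 3 - m) * lam**m))
            var += 2.0 * coef * tail
        out[w] = float(np.sqrt(max(var, 0.0)) / n)
    return out


def estimate_turn_model(tokens: np.ndarray) -> tuple[float, float]:
    """Conditional-frequency estimates of (a, b) from an observed stream.

    ``a_hat = #(L->R) / #(L->.)``, ``b_hat = #(R->R) / #(R->.)``; NaN when a
    state is never visited before the final token.
    """
    tokens = np.asarray(tokens, dtype="<U1")
    if tokens.size < 2:
        return float("nan"), float("nan")
    prev, nxt = tokens[:-1], tokens[1:]
    from_L = prev == "L"
    from_R = ~from_L
    a_hat = float(np.sum(from_L & (nxt == "R")) / from_L.sum()) if from_L.any() else float("nan")
    b_hat = float(np.sum(from_R & (nxt == "R")) / from_R.sum()) if from_R.any() else float("nan")
    return a_hat, b_hat


# --- cohort simulation -----------------------------------------------------

#: Default class-level turn-model parameters.  Non-biased fish alternate
#: (a > b) with a symmetric marginal; biased fish are i.i.d. with a marginal
#: past the 60 % threshold (a = b, so repetitions rise and alternations
#: fall); right-biased fish turn less often.
DEFAULT_CLASS_PARAMS: dict[str, dict[str, float]] = {
    "non_biased": {"a": 0.65, "b": 0.35, "turn_rate_per_min": 6.0},
    "left_biased": {"a": 0.28, "b": 0.28, "turn_rate_per_min": 6.0},
    "right_biased": {"a": 0.72, "b": 0.72, "turn_rate_per_min": 4.5},
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cohort.

    The default class mix (28 left / 28 right / 47 non-biased) matches the
    laterality profile reported for a 103-fish zebrafish cohort.  Individual
    fish jitter around their class parameters: additive Gaussian noise
    (``ab_jitter_sd``, clipped to [0.01, 0.99]) on a and b, multiplicative
    log-normal noise (``rate_jitter_sd`` on the log scale) on the turn rate.
    """

    n_left: int = 28
    n_right: int = 28
    n_non: int = 47
    class_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()}
    )
    ab_jitter_sd: float = 0.02
    rate_jitter_sd: float = 0.10
    session_length_s: float = 3600.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_left, self.n_right, self.n_non) < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_left + self.n_right + self.n_non == 0:
            raise ValueError("cohort must contain at least one subject")
        missing = {"non_biased", "left_biased", "right_biased"} - set(self.class_params)
        if missing:
            raise ValueError(f"class_params missing classes: {sorted(missing)}")

    @property
    def n_total(self) -> int:
        return self.n_left + self.n_right + self.n_non


@dataclass
class SimulatedCohort:
    """Event logs plus the ground truth each fish was drawn from."""

    events: dict[str, pd.DataFrame]
    truth: pd.DataFrame  # subject_id, true_class, a, b, turn_rate_per_min
    sequences: dict[str, TurnSequence]

    def events_frame(self) -> pd.DataFrame:
        return pd.concat(self.events.values(), ignore_index=True)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events_frame().to_csv(out / "arm_entries.csv", index=False)
        self.truth.to_csv(out / "ground_truth.csv", index=False)


def simulate_cohort(
    spec: CohortSpec, geometry: MazeGeometry | None = None
) -> SimulatedCohort:
    """Simulate a full Y-maze cohort, one event log per fish.

    Deterministic given ``spec.random_seed``.  Subject ids are
    ``fish000 ...`` in a fixed interleaved class order so ids carry no class
    information.
    """
    geometry = geometry or MazeGeometry()
    rng = np.random.default_rng(spec.random_seed)
    classes = (
        ["left_biased"] * spec.n_left
        + ["right_biased"] * spec.n_right
        + ["non_biased"] * spec.n_non
    )
    order = rng.permutation(len(classes))
    events: dict[str, pd.DataFrame] = {}
    sequences: dict[str, TurnSequence] = {}
    truth_rows = []
    for i, k in enumerate(order):
        cls = classes[k]
        base = spec.class_params[cls]
        a = float(np.clip(base["a"] + rng.normal(0, spec.ab_jitter_sd), 0.01, 0.99))
        b = float(np.clip(base["b"] + rng.normal(0, spec.ab_jitter_sd), 0.01, 0.99))
        rate = float(
            base["turn_rate_per_min"] * np.exp(rng.normal(0, spec.rate_jitter_sd))
        )
        params = TurnModelParams(
            a=a, b=b, turn_rate_per_min=rate, session_length_s=spec.session_length_s
        )
        sid = f"fish{i:03d}"
        seq = simulate_turn_sequence(params, rng, subject_id=sid)
        sequences[sid] = seq
        events[sid] = turns_to_events(seq, geometry, start_arm=int(rng.integers(3)))
        truth_rows.append(
            {
                "subject_id": sid,
                "true_class": cls,
                "a": a,
                "b": b,
                "turn_rate_per_min": rate,
                "true_n_turns": seq.n_turns,
            }
        )
    return SimulatedCohort(
        events=events, truth=pd.DataFrame(truth_rows), sequences=sequences
    )


# --- trajectory simulation -------------------------------------------------


def _reflect(x: np.ndarray | float, lo: float, hi: float):
    """Reflect positions into [lo, hi] (single bounce is enough for small steps)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def simulate_tank_trajectory(
    anxiety_depth_bias: float = 0.0,
    wall_bias: float = 0.0,
    speed_cm_s: float = 4.0,
    duration_s: float = 300.0,
    sample_hz: float = 60.0,
    cfg: SessionConfig | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim0",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reflected random walk in the novel-tank box; returns (front, top) views.

    ``anxiety_depth_bias`` in [-1, 1] sets the preferred height via
    mean-reversion: +1 pulls to the floor (bottom-dwelling), -1 to the
    surface, 0 disables the vertical pull entirely so the stationary depth
    law is uniform.  ``wall_bias`` >= 0 adds horizontal drift toward the
    nearest wall (thigmotaxis); 0 disables it.  All drifts and steps scale
    with ``speed_cm_s``, so a speed of 0 freezes the fish in place.
    """
    if not -1.0 <= anxiety_depth_bias <= 1.0:
        raise ValueError("anxiety_depth_bias must lie in [-1, 1]")
    if wall_bias < 0:
        raise ValueError("wall_bias must be non-negative")
    if speed_cm_s < 0:
        raise ValueError("speed_cm_s must be non-negative")
    cfg = cfg or SessionConfig()
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_hz
    n = int(round(duration_s * sample_hz))
    L, H, W = cfg.tank_length_cm, cfg.tank_height_cm, cfg.tank_width_cm

    times = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    x[0], y[0] = rng.uniform(0, L), rng.uniform(0, W)
    z[0] = rng.uniform(0, H)
    z_pref = H / 2.0 * (1.0 - anxiety_depth_bias)
    sigma = speed_cm_s * np.sqrt(dt)
    # mean-reversion rate scales with |bias| so bias 0 leaves a pure walk
    # pull strength sized so full bias confines the stationary depth law to
    # roughly +/- 2 cm around the preferred height (OU sd = sqrt(speed*H/16))
    kappa = 8.0 * abs(anxiety_depth_bias) * speed_cm_s / max(H, 1e-9)
    noise = rng.normal(size=(n - 1, 3))
    for i in range(1, n):
        dx = sigma * noise[i - 1, 0]
        dy = sigma * noise[i - 1, 1]
        dz = sigma * noise[i - 1, 2] + kappa * (z_pref - z[i - 1]) * dt
        if wall_bias > 0 and speed_cm_s > 0:
            # drift toward the nearest wall along each horizontal axis
            dx += wall_bias * speed_cm_s * dt * (1.0 if x[i - 1] > L / 2 else -1.0)
            dy += wall_bias * speed_cm_s * dt * (1.0 if y[i - 1] > W / 2 else -1.0)
        x[i] = _reflect(x[i - 1] + dx, 0.0, L)
        y[i] = _reflect(y[i - 1] + dy, 0.0, W)
        z[i] = _reflect(z[i - 1] + dz, 0.0, H)

    front = pd.DataFrame(
        {"time_s": times, "subject_id": subject_id, "u": x, "v": z}
    )
    top = pd.DataFrame({"time_s": times, "subject_id": subject_id, "u": x, "v": y})
    return front, top


def simulate_conditioning_trajectory(
    avoidance_strength: float = 0.0,
    schedule: ConditioningSchedule | None = None,
    arena_length_cm: float = 25.0,
    speed_cm_s: float = 4.0,
    sample_hz: float = 10.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim0",
    include_habituation: bool = False,
) -> pd.DataFrame:
    """1-D reflected walk along the conditioning lane.

    Before the conditioning phase the walk is driftless; from conditioning
    onset onward, whenever the schedule defines a CS+ side, the fish drifts
    away from it at ``avoidance_strength`` cm/s.  With strength 0 the probe
    preference equals the baseline preference in expectation; large strengths
    pin the fish to the CS- side during the probe.
    """
    if avoidance_strength < 0:
        raise ValueError("avoidance_strength must be non-negative")
    schedule = schedule or ConditioningSchedule()
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_hz
    t0 = 0.0 if include_habituation else schedule.baseline_window[0]
    times = np.arange(t0, schedule.total_s, dt)
    n = len(times)
    u = np.empty(n)
    u[0] = rng.uniform(0, arena_length_cm)
    sigma = speed_cm_s * np.sqrt(dt)
    cond_onset = schedule.conditioning_window[0]
    noise = rng.normal(size=n - 1)
    for i in range(1, n):
        drift = 0.0
        t = times[i - 1]
        if t >= cond_onset and avoidance_strength > 0:
            side = schedule.cs_plus_side(t)
            if side is not None:
                away = 1.0 if side == "left" else -1.0
                drift = avoidance_strength * away * dt
        u[i] = _reflect(u[i - 1] + sigma * noise[i - 1] + drift, 0.0, arena_length_cm)
    return pd.DataFrame({"time_s": times, "subject_id": subject_id, "u": u, "v": 0.0})
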