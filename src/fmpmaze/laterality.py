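"""Tetragram search-strategy metrics and left/right laterality scoring.

A session's choice stream is summarized two ways:

* **Tetragrams** — the 16 possible words of four consecutive choices over
  {l, r}, counted in a sliding window of stride 1 across the whole session.
  ``lrlr + rlrl`` is the alternation score (working-memory-like strategy),
  ``llll + rrrr`` the repetition score (perseveration).
* **Bias percentage** — ``100 * turns to one side / total turns``, overall
  and per 10-min bin.  A subject whose overall bias strictly exceeds the
  configured threshold (default 60 %) on either side is classed
  ``left_biased`` or ``right_biased``, otherwise ``non_biased``.

Consistency of lateralization across the session is the mean and coefficient
of variation (CV) of the per-bin bias percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .config import SessionConfig
from .turns import TurnSequence, assign_bins

__all__ = [
    "TETRAGRAMS",
    "ALTERNATION_WORDS",
    "REPETITION_WORDS",
    "TetragramProfile",
    "BinConsistency",
    "LateralityResult",
    "count_tetragrams",
    "bias_percentage",
    "per_bin_consistency",
    "classify_laterality",
    "analyze_subject",
    "cohort_class_summary",
]

#: The 16 length-4 words over {l, r} in lexicographic order (llll ... rrrr).
TETRAGRAMS: tuple[str, ...] = tuple("".join(w) for w in product("lr", repeat=4))
ALTERNATION_WORDS = ("lrlr", "rlrl")
REPETITION_WORDS = ("llll", "rrrr")


@dataclass
class TetragramProfile:
    """Counts and relative frequencies of the 16 overlapping tetragrams.

    With fewer than 4 turns there are no windows: counts are all zero and the
    relative frequencies and scores are undefined (NaN).
    """

    counts: dict[str, int]
    n_turns: int

    @property
    def n_tetragrams(self) -> int:
        return max(0, self.n_turns - 3)

    @property
    def rel_freq(self) -> dict[str, float]:
        n = self.n_tetragrams
        if n == 0:
            return {w: float("nan") for w in TETRAGRAMS}
        return {w: self.counts[w] / n for w in TETRAGRAMS}

    @property
    def alternation_score(self) -> float:
        if self.n_tetragrams == 0:
            return float("nan")
        return sum(self.counts[w] for w in ALTERNATION_WORDS) / self.n_tetragrams

    @property
    def repetition_score(self) -> float:
        if self.n_tetragrams == 0:
            return float("nan")
        return sum(self.counts[w] for w in REPETITION_WORDS) / self.n_tetragrams


def count_tetragrams(seq: TurnSequence | np.ndarray) -> TetragramProfile:
    """Slide a width-4, stride-1 window over the whole-session token stream.

    Accepts a :class:`~fmpmaze.turns.TurnSequence` or a bare token array.
    """
    tokens = seq.tokens if isinstance(seq, TurnSequence) else np.asarray(seq)
    s = "".join(tokens.tolist()).lower()
    counts = {w: 0 for w in TETRAGRAMS}
    for i in range(max(0, len(s) - 3)):
        counts[s[i : i + 4]] += 1
    return TetragramProfile(counts=counts, n_turns=len(s))


def tetragram_counts_per_bin(seq: TurnSequence, cfg: SessionConfig) -> pd.DataFrame:
    """Tetragram counts resolved by time bin.

    A window is assigned to the bin of its final (4th) turn, since that is
    when the choice pattern completes.  Windows therefore straddle bin edges
    without being lost.  Returns a frame indexed by bin with one column per
    word plus alternation/repetition counts.
    """
    if seq.bin_index is None:
        seq = assign_bins(seq, cfg)
    s = "".join(seq.tokens.tolist()).lower()
    rows = np.zeros((cfg.n_bins, len(TETRAGRAMS)), dtype=int)
    word_idx = {w: j for j, w in enumerate(TETRAGRAMS)}
    for i in range(max(0, len(s) - 3)):
        rows[seq.bin_index[i + 3], word_idx[s[i : i + 4]]] += 1
    out = pd.DataFrame(rows, columns=list(TETRAGRAMS))
    out.index.name = "bin_index"
    out["alternations"] = out[list(ALTERNATION_WORDS)].sum(axis=1)
    out["repetitions"] = out[list(REPETITION_WORDS)].sum(axis=1)
    return out


def bias_percentage(tokens: np.ndarray, side: str) -> float:
    """``100 * count(side) / total`` over a token collection; NaN if empty."""
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    tokens = np.asarray(tokens)
    if tokens.size == 0:
        return float("nan")
    return 100.0 * float(np.sum(tokens == side)) / tokens.size


@dataclass
class BinConsistency:
    """Mean and CV (%) of per-bin bias percentages across usable bins."""

    mean_L_pct: float
    mean_R_pct: float
    cv_L_pct: float
    cv_R_pct: float
    n_bins_used: int
    n_bins_empty: int
    per_bin: pd.DataFrame  # bin_index, n_turns, bias_L_pct, bias_R_pct


def per_bin_consistency(seq: TurnSequence, cfg: SessionConfig) -> BinConsistency:
    """Per-bin bias percentages and their mean / coefficient of variation.

    Bins without turns are excluded from the statistics and counted.  The CV
    uses the sample standard deviation (n-1) and is reported as a percentage
    of the mean; with fewer than two usable bins all four statistics are NaN.
    """
    if seq.bin_index is None:
        seq = assign_bins(seq, cfg)
    records = []
    for b in range(cfg.n_bins):
        tok = seq.tokens[seq.bin_index == b]
        records.append(
            {
                "bin_index": b,
                "n_turns": tok.size,
                "bias_L_pct": bias_percentage(tok, "L"),
                "bias_R_pct": bias_percentage(tok, "R"),
            }
        )
    per_bin = pd.DataFrame(records)
    used = per_bin[per_bin["n_turns"] > 0]
    n_used = len(used)
    n_empty = cfg.n_bins - n_used

    def _stats(col: str) -> tuple[float, float]:
        if n_used < 2:
            return float("nan"), float("nan")
        vals = used[col].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = 100.0 * sd / mean if mean > 0 else float("nan")
        return mean, cv

    mean_L, cv_L = _stats("bias_L_pct")
    mean_R, cv_R = _stats("bias_R_pct")
    return BinConsistency(mean_L, mean_R, cv_L, cv_R, n_used, n_empty, per_bin)


def classify_laterality(bias_R_pct: float, threshold_pct: float = 60.0) -> str | None:
    """Three-way label from the whole-session right-bias percentage.

    The threshold is strict: a bias of exactly ``threshold_pct`` on either
    side is non-biased.  Undefined bias (no turns) returns None.
    """
    if np.isnan(bias_R_pct):
        return None
    if bias_R_pct > threshold_pct:
        return "right_biased"
    if 100.0 - bias_R_pct > threshold_pct:
        return "left_biased"
    return "non_biased"


@dataclass
class LateralityResult:
    """Full per-subject laterality scoring for one Y-maze session."""

    subject_id: str
    n_turns: int
    overall_bias_L_pct: float
    overall_bias_R_pct: float
    consistency: BinConsistency
    tetragrams: TetragramProfile
    label: str | None
    included: bool

    def to_record(self) -> dict:
        rec = {
            "subject_id": self.subject_id,
            "n_turns": self.n_turns,
            "bias_L_pct": self.overall_bias_L_pct,
            "bias_R_pct": self.overall_bias_R_pct,
            "mean_L_pct": self.consistency.mean_L_pct,
            "mean_R_pct": self.consistency.mean_R_pct,
            "cv_L_pct": self.consistency.cv_L_pct,
            "cv_R_pct": self.consistency.cv_R_pct,
            "alternation_score": self.tetragrams.alternation_score,
            "repetition_score": self.tetragrams.repetition_score,
            "label": self.label,
            "included": self.included,
        }
        rec.update({f"freq_{w}": f for w, f in self.tetragrams.rel_freq.items()})
        return rec


def analyze_subject(seq: TurnSequence, cfg: SessionConfig) -> LateralityResult:
    """Score one subject: bias, per-bin consistency, tetragrams, class label.

    Classification uses the whole-hour bias (not the mean of per-bin biases);
    subjects below ``cfg.min_turns_for_inclusion`` turns keep their metrics
    but are flagged ``included=False`` as non-engaged.
    """
    seq = assign_bins(seq, cfg)
    bias_L = bias_percentage(seq.tokens, "L")
    bias_R = bias_percentage(seq.tokens, "R")
    label = classify_laterality(bias_R, cfg.bias_threshold_pct)
    included = seq.n_turns >= cfg.min_turns_for_inclusion and label is not None
    return LateralityResult(
        subject_id=seq.subject_id,
        n_turns=seq.n_turns,
        overall_bias_L_pct=bias_L,
        overall_bias_R_pct=bias_R,
        consistency=per_bin_consistency(seq, cfg),
        tetragrams=count_tetragrams(seq),
        label=label,
        included=included,
    )


def cohort_class_summary(results) -> pd.DataFrame:
    """Class counts and percentages over the included subjects of a cohort.

    ``results`` is an iterable of :class:`LateralityResult` or a sequence of
    label strings (every label then counts as included).  Percentages are
    ``100 * count / total included``.
    """
    labels = []
    for r in results:
        if isinstance(r, LateralityResult):
            if r.included:
                labels.append(r.label)
        elif r is not None:
            labels.append(str(r))
    if not labels:
        raise ValueError("no included subjects")
    order = ["left_biased", "right_biased", "non_biased"]
    counts = pd.Series(labels).value_counts()
    out = pd.DataFrame(
        {
            "label": order,
            "count": [int(counts.get(k, 0)) for k in order],
        }
    )
    out["pct"] = 100.0 * out["count"] / out["count"].sum()
    return out
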