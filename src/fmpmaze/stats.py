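"""Group-level descriptive summaries and permutation contrasts.

Group effects are reported as mean ± SEM per laterality class and compared
with label-shuffle permutation tests on the difference of group means — a
distribution-free stand-in appropriate for simulated cohorts, where
exchangeability under the null holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PermutationResult", "group_summary", "permutation_test", "bh_adjust"]


def group_summary(
    metrics: pd.DataFrame,
    label_col: str = "label",
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class n, mean and SEM for each metric column.

    SEM = sample SD / sqrt(n); classes with a single subject report SEM as
    NaN rather than 0.  Rows with a missing label are dropped with a note in
    the returned frame's ``attrs``.
    """
    df = metrics.copy()
    n_dropped = int(df[label_col].isna().sum())
    df = df.dropna(subset=[label_col])
    if df.empty:
        raise ValueError("no labelled subjects to summarize")
    if value_cols is None:
        value_cols = [
            c
            for c in df.columns
            if c != label_col and pd.api.types.is_numeric_dtype(df[c])
        ]
    rows = []
    for label, grp in df.groupby(label_col, sort=True):
        for col in value_cols:
            vals = grp[col].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    "label": label,
                    "metric": col,
                    "n": n,
                    "mean": float(vals.mean()) if n else float("nan"),
                    "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped_unlabelled"] = n_dropped
    return out


@dataclass
class PermutationResult:
    """Two-sided label-shuffle test on |difference of group means|."""

    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int | None

    def __repr__(self) -> str:  # compact for logs
        return (
            f"PermutationResult(diff={self.observed_diff:.4g}, "
            f"p={self.p_value:.4g}, B={self.n_permutations})"
        )


def permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Two-group permutation test of the difference in means.

    The p-value is the add-one estimate
    ``(1 + #{|null diff| >= |observed|}) / (B + 1)``, which is valid
    (conservative) under exchangeability and never returns 0.  Requires
    exactly two label values with n >= 2 each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    mask = labels == groups[0]
    n1 = int(mask.sum())
    if n1 < 2 or len(values) - n1 < 2:
        raise ValueError("each group needs at least 2 observations")

    observed = float(values[mask].mean() - values[~mask].mean())
    rng = np.random.default_rng(seed)
    total = values.sum()
    n = len(values)
    # permute by drawing random subsets of size n1 (vectorized via argsort)
    keys = rng.random((n_permutations, n))
    idx = np.argsort(keys, axis=1)[:, :n1]
    sum1 = values[idx].sum(axis=1)
    null_diff = sum1 / n1 - (total - sum1) / (n - n1)
    exceed = int(np.sum(np.abs(null_diff) >= abs(observed) - 1e-12))
    p = (1 + exceed) / (n_permutations + 1)
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return PermutationResult(
        observed_diff=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed_out,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj
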