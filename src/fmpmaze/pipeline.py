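"""End-to-end orchestration: simulate or load -> code turns -> score -> write."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ConditioningSchedule, SessionConfig
from .io import read_arm_entries, write_results
from .laterality import LateralityResult, analyze_subject, cohort_class_summary
from .occupancy import score_conditioning, tank_endpoints
from .simulate import CohortSpec, simulate_cohort
from .stats import group_summary, permutation_test
from .turns import MazeGeometry, events_to_turns

__all__ = ["analyze_ymaze", "run_pipeline"]

#: metrics contrasted between laterality classes in the report stage
CONTRAST_METRICS = ("n_turns", "alternation_score", "repetition_score")


def analyze_ymaze(
    events: dict[str, pd.DataFrame],
    cfg: SessionConfig,
    geometry: MazeGeometry | None = None,
) -> tuple[pd.DataFrame, list[LateralityResult]]:
    """Score every subject's event stream; returns (tidy table, results).

    The table has one row per subject including excluded (non-engaged) ones,
    which are flagged ``included=False``.
    """
    geometry = geometry or MazeGeometry()
    results = []
    for sid in sorted(events):
        seq = events_to_turns(events[sid], geometry)
        results.append(analyze_subject(seq, cfg))
    table = pd.DataFrame([r.to_record() for r in results])
    return table, results


def run_pipeline(
    cfg: SessionConfig,
    out_dir: str | Path,
    arm_entries_path: str | Path | None = None,
    cohort_spec: CohortSpec | None = None,
    geometry: MazeGeometry | None = None,
    n_permutations: int = 999,
) -> dict:
    """Full Y-maze run: load or simulate events, score, summarize, write.

    Exactly one of ``arm_entries_path`` (analyze recorded data) or
    ``cohort_spec`` (simulate first) must be provided.  Writes per-subject
    metrics, the cohort class summary, per-class group summaries, pairwise
    permutation contrasts and a JSON run manifest into ``out_dir``; returns
    the tables in memory keyed by name.
    """
    if (arm_entries_path is None) == (cohort_spec is None):
        raise ValueError("provide exactly one of arm_entries_path or cohort_spec")
    geometry = geometry or MazeGeometry()
    out_dir = Path(out_dir)

    truth = None
    if cohort_spec is not None:
        cohort = simulate_cohort(cohort_spec, geometry)
        events = cohort.events
        truth = cohort.truth
    else:
        events = read_arm_entries(arm_entries_path, geometry)

    metrics, results = analyze_ymaze(events, cfg, geometry)
    excluded = metrics.loc[~metrics["included"], "subject_id"].tolist()
    class_summary = cohort_class_summary(results)

    included = metrics[metrics["included"]]
    summaries = group_summary(
        included, value_cols=[*CONTRAST_METRICS, "bias_R_pct", "cv_L_pct", "cv_R_pct"]
    )

    contrast_rows = []
    labels_present = included["label"].dropna().unique().tolist()
    pairs = [
        (a, b)
        for i, a in enumerate(labels_present)
        for b in labels_present[i + 1 :]
    ]
    for metric in CONTRAST_METRICS:
        for g1, g2 in pairs:
            sub = included[included["label"].isin([g1, g2])]
            if (sub["label"] == g1).sum() < 2 or (sub["label"] == g2).sum() < 2:
                continue
            res = permutation_test(
                sub[metric].to_numpy(),
                sub["label"].to_numpy(),
                n_permutations=n_permutations,
                seed=cfg.random_seed,
            )
            contrast_rows.append(
                {
                    "metric": metric,
                    "group1": g1,
                    "group2": g2,
                    "observed_diff": res.observed_diff,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            )

    tables = {
        "subject_metrics": metrics,
        "class_summary": class_summary,
        "group_summary": summaries,
    }
    if contrast_rows:
        tables["contrasts"] = pd.DataFrame(contrast_rows)
    if truth is not None:
        tables["ground_truth"] = truth
    write_results(tables, out_dir)

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "seed": cfg.random_seed,
        "mode": "simulate" if cohort_spec is not None else "analyze",
        "n_subjects": int(len(metrics)),
        "excluded_subjects": excluded,
        "tables": sorted(tables),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return tables
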