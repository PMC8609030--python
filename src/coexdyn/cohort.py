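"""Sample QC, 10-day analysis windows, and age/sex-matched control selection.

Samples are assigned to analysis windows spaced every ``step_days`` over the
``span_days`` before diagnosis: for each window a subject contributes the
single sample drawn closest to the window day, provided the gap is under
``max_offset_days``.  For each case sample in a window, same-sex controls
are greedily matched on age; two independent control sets are drawn so
downstream statistics can be averaged over matched sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WindowAssignment",
    "qc_filter_samples",
    "assign_windows",
    "window_sample_selection",
    "match_controls",
    "build_window_assignments",
    "assignments_to_frame",
]


@dataclass
class WindowAssignment:
    """One analysis window: its cases and (after matching) its control sets.

    ``window_day`` is stored as non-negative days before diagnosis; output
    tables label time as negative days.
    """

    window_day: int
    case_samples: List[str]
    control_sets: List[List[str]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


def qc_filter_samples(
    expr: pd.DataFrame, min_mean_correlation: float = 0.95
) -> Tuple[List[str], pd.DataFrame]:
    """Drop samples whose mean correlation with all other samples is below
    threshold.

    Returns (kept sample IDs, report frame with sample_id, mean_correlation,
    kept).  Requires at least 3 samples for the mean correlation to be a
    meaningful QC statistic.
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"QC needs >= 3 samples, got {n}")
    vals = expr.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(vals.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    mean_corr = corr.sum(axis=1) / (n - 1)
    kept_mask = mean_corr >= min_mean_correlation
    report = pd.DataFrame(
        {
            "sample_id": expr.columns,
            "mean_correlation": mean_corr,
            "kept": kept_mask,
        }
    )
    removed = report.loc[~report["kept"], "sample_id"].tolist()
    if removed:
        logger.info("QC removed %d/%d samples: %s", len(removed), n, removed[:10])
    return report.loc[kept_mask, "sample_id"].tolist(), report


def window_sample_selection(
    samples: pd.DataFrame, window_day: int, max_offset_days: float = 100.0
) -> pd.DataFrame:
    """Per subject, the sample drawn closest to ``window_day`` (days before
    diagnosis), kept only when the gap is < ``max_offset_days``.

    Ties in closeness are broken toward the earlier-drawn sample (more days
    before diagnosis).  Returns the selected rows of ``samples``.
    """
    df = samples.copy()
    df["days_before"] = -df["offset_days"].to_numpy(dtype=float)
    df["gap"] = (df["days_before"] - window_day).abs()
    # stable sort: smallest gap first, earlier-drawn (larger days_before) first
    df = df.sort_values(
        ["subject_id", "gap", "days_before"], ascending=[True, True, False],
        kind="mergesort",
    )
    best = df.groupby("subject_id", sort=True).head(1)
    best = best[best["gap"] < max_offset_days]
    return best.drop(columns=["gap"]).sort_values("subject_id").reset_index(drop=True)


def assign_windows(
    samples: pd.DataFrame,
    span_days: int = 600,
    step_days: int = 10,
    max_offset_days: float = 100.0,
) -> List[WindowAssignment]:
    """Case-only window assignments for window days span, span-step, ..., 0."""
    cases = samples[samples["group"] == "case"]
    if cases["offset_days"].isna().any():
        raise ValueError("case samples must all have offset_days")
    out = []
    for w in range(span_days, -1, -step_days):
        sel = window_sample_selection(cases, w, max_offset_days)
        out.append(WindowAssignment(window_day=w, case_samples=sel["sample_id"].tolist()))
    return out


def match_controls(
    window: WindowAssignment,
    case_info: pd.DataFrame,
    control_pool: pd.DataFrame,
    age_tolerance_days: float = 90.0,
    n_sets: int = 2,
    seed: int = 0,
) -> WindowAssignment:
    """Fill ``window.control_sets`` with ``n_sets`` greedy same-sex,
    age-nearest matchings.

    ``case_info`` must contain rows for ``window.case_samples``;
    ``control_pool`` holds the candidate control samples for this window
    (one per control subject).  Within a set each control sample is used at
    most once; sets are drawn independently (seeded case order differs per
    set), so a control may recur across sets.  A case with no same-sex
    candidate raises; a nearest match beyond ``age_tolerance_days`` is
    accepted with a logged warning.
    """
    ci = case_info.set_index("sample_id").loc[window.case_samples]
    pool = control_pool.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    window.control_sets = []
    for s in range(n_sets):
        order = rng.permutation(len(window.case_samples))
        chosen: Dict[int, str] = {}
        used: set = set()
        for pos in order:
            case_id = window.case_samples[pos]
            sex = ci.loc[case_id, "sex"]
            age = float(ci.loc[case_id, "age_days"])
            cand = pool[(pool["sex"] == sex) & (~pool["sample_id"].isin(used))]
            if cand.empty:
                raise ValueError(
                    f"window {window.window_day}: no same-sex ({sex}) control "
                    f"available for case sample {case_id}"
                )
            diffs = (cand["age_days"].astype(float) - age).abs()
            cand = cand.assign(age_diff=diffs).sort_values(
                ["age_diff", "sample_id"], kind="mergesort"
            )
            best = cand.iloc[0]
            if best["age_diff"] > age_tolerance_days:
                msg = (
                    f"window {window.window_day} set {s}: case {case_id} matched "
                    f"to {best['sample_id']} with age gap "
                    f"{best['age_diff']:.0f} d > tolerance {age_tolerance_days:.0f} d"
                )
                logger.warning(msg)
                window.warnings.append(msg)
            chosen[pos] = str(best["sample_id"])
            used.add(str(best["sample_id"]))
        window.control_sets.append([chosen[i] for i in range(len(window.case_samples))])
    return window


def build_window_assignments(
    samples: pd.DataFrame,
    span_days: int = 600,
    step_days: int = 10,
    max_offset_days: float = 100.0,
    age_tolerance_days: float = 90.0,
    n_sets: int = 2,
    seed: int = 0,
    sex: Optional[str] = None,
) -> List[WindowAssignment]:
    """Windows with matched controls, optionally restricted to one sex."""
    df = samples if sex is None else samples[samples["sex"] == sex]
    windows = assign_windows(df, span_days, step_days, max_offset_days)
    controls = df[df["group"] == "control"]
    cases = df[df["group"] == "case"]
    out = []
    for i, w in enumerate(windows):
        if not w.case_samples:
            out.append(w)
            continue
        pool = window_sample_selection(controls, w.window_day, max_offset_days)
        # per-window deterministic sub-seed keeps matching independent of
        # which windows are computed
        sub_seed = np.random.SeedSequence(entropy=seed, spawn_key=(w.window_day,))
        out.append(
            match_controls(
                w,
                cases,
                pool,
                age_tolerance_days=age_tolerance_days,
                n_sets=n_sets,
                seed=sub_seed.generate_state(1)[0] % (2**31),
            )
        )
    return out


def assignments_to_frame(windows: Sequence[WindowAssignment]) -> pd.DataFrame:
    """Flatten window assignments to a TSV-ready frame."""
    rows = []
    for w in windows:
        for i, cs in enumerate(w.case_samples):
            row = {"window_day": w.window_day, "case_sample": cs}
            for s, cset in enumerate(w.control_sets, start=1):
                row[f"control_sample_set{s}"] = cset[i]
            rows.append(row)
    return pd.DataFrame(rows)
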