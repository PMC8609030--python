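"""Module eigengenes via a fixed reference rotation, and differential
expression.

The module eigengene (ME) is the first principal component of a module's
expression.  The rotation (loadings) and the gene means/scales are computed
once, on the reference-window samples, and reused for every other time
point: projecting all windows through the same affine map is what makes ME
values comparable across time.  Differential module expression (DME) and
per-probe differential expression use two-sided Welch t-tests; per-probe
significance is Bonferroni-controlled at 0.05 / n_probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceRotation",
    "reference_rotation",
    "project_eigengene",
    "differential_eigengene",
    "differential_expression",
]


@dataclass
class ReferenceRotation:
    """First-PC loadings plus the reference centering/scaling statistics."""

    module: str
    genes: list
    loadings: np.ndarray  # (g,)
    means: np.ndarray     # (g,) reference gene means
    scales: np.ndarray    # (g,) reference gene SDs (1 where degenerate)
    reference_scores: pd.Series  # ME of the reference samples themselves


def reference_rotation(
    expr_ref: pd.DataFrame,
    module_genes: Sequence[str],
    module: str = "",
    scale: bool = True,
) -> ReferenceRotation:
    """First principal component of the module over the reference samples.

    Genes are centered (and by default scaled to unit variance) across the
    reference samples; the sign is fixed so the largest-magnitude loading
    is positive.
    """
    genes = list(module_genes)
    if expr_ref.shape[1] < 2:
        raise ValueError("reference rotation needs >= 2 samples")
    missing = [g for g in genes if g not in expr_ref.index]
    if missing:
        raise KeyError(f"module genes absent from reference data: {missing[:5]}")
    x = expr_ref.loc[genes].to_numpy(dtype=float).T  # samples x genes
    means = x.mean(axis=0)
    if scale:
        scales = x.std(axis=0, ddof=1)
        scales = np.where(scales == 0, 1.0, scales)
    else:
        scales = np.ones(len(genes))
    xs = (x - means) / scales
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    loadings = vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    scores = pd.Series(xs @ loadings, index=expr_ref.columns, name="ME")
    return ReferenceRotation(module, genes, loadings, means, scales, scores)


def project_eigengene(
    expr_window: pd.DataFrame, rotation: ReferenceRotation
) -> pd.Series:
    """ME per sample, through the reference rotation and reference scaling."""
    missing = [g for g in rotation.genes if g not in expr_window.index]
    if missing:
        raise KeyError(f"module genes absent from window data: {missing[:5]}")
    x = expr_window.loc[rotation.genes].to_numpy(dtype=float).T
    xs = (x - rotation.means) / rotation.scales
    return pd.Series(xs @ rotation.loadings, index=expr_window.columns, name="ME")


def _welch(a: np.ndarray, b: np.ndarray, axis: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Two-sided Welch t-test; degenerate (zero-variance, equal-mean) inputs
    get t = 0, p = 1 instead of NaN."""
    t, p = stats.ttest_ind(a, b, axis=axis, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return t, p


def differential_eigengene(
    me_cases: pd.Series | np.ndarray, me_controls: pd.Series | np.ndarray
) -> Tuple[float, float]:
    """DME: two-sided Welch t-test on ME scores; returns (t, p)."""
    a = np.asarray(me_cases, dtype=float)
    b = np.asarray(me_controls, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("DME needs >= 2 samples per group")
    t, p = _welch(a, b)
    return float(t), float(p)


def differential_expression(
    expr_cases: pd.DataFrame,
    expr_controls: pd.DataFrame,
    probes: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, float]:
    """Per-probe two-sided Welch t-tests with Bonferroni control.

    Returns (results frame, Bonferroni threshold = alpha / n_probes).  The
    frame reports t, p, the significance flag, and the case/control mean
    expression ratio.
    """
    if probes is not None:
        expr_cases = expr_cases.loc[list(probes)]
        expr_controls = expr_controls.loc[list(probes)]
    if expr_cases.shape[1] < 2 or expr_controls.shape[1] < 2:
        raise ValueError("differential expression needs >= 2 samples per group")
    a = expr_cases.to_numpy(dtype=float)
    b = expr_controls.to_numpy(dtype=float)
    t, p = _welch(a, b, axis=1)
    threshold = alpha / expr_cases.shape[0]
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_b != 0, a.mean(axis=1) / mean_b, np.nan)
    out = pd.DataFrame({
        "probe": expr_cases.index,
        "t": t,
        "p": p,
        "bonferroni_sig": p < threshold,
        "case_control_ratio": ratio,
    })
    return out, threshold
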