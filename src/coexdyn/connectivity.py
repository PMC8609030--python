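"""Differential connectivity statistics: GC, MC, MDC, GDC, and permutation
significance.

Gene connectivity (GC) is a gene's summed soft-threshold adjacency to the
other genes of its module; module connectivity (MC) is the upper-triangle
sum of the module's topological overlap matrix.  Modular differential
connectivity compares the two study groups,

    MDC(x, y) = MC(cases) / MC(controls),

with the control MC averaged over matched control sets.  Significance is
the empirical tail probability of the observed MDC under case/control
label permutation: p_gain is the fraction of permutations whose MDC
exceeds the observed value (gain of connectivity, MDC > 1) and p_loss the
fraction below it (loss, MDC < 1).  The gene-level analogues are
``delta_H = GC_cases - GC_controls`` and ``GDC = GC_cases / GC_controls``;
differentially connected genes are ranked by delta_H within each sex and
the per-sex ranks summed into a final list.

Group-specific statistics always reuse the *reference* module membership:
only correlations (hence adjacency and TOM) are recomputed per group per
window.  TOM for MC is computed on the module's gene submatrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .network import adjacency_from_correlation, tom
from .cohort import WindowAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "MDCResult",
    "PermutationResult",
    "gene_connectivity",
    "module_connectivity",
    "mdc",
    "mdc_significance",
    "mdc_timecourse",
    "gene_differential_connectivity",
    "rank_dhg",
    "connectivity_rank_correlation",
]


# ---------------------------------------------------------------------------
# batched low-level kernels (leading axes = permutations)

def _batch_corr(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Correlation matrices for row subsets of ``x`` (samples x genes).

    ``idx`` has shape (M, k); returns (M, g, g).  Constant genes within a
    subset get zero correlation.
    """
    xs = x[idx]  # (M, k, g)
    xc = xs - xs.mean(axis=1, keepdims=True)
    ss = np.sqrt((xc ** 2).sum(axis=1))  # (M, g)
    ss = np.where(ss == 0, 1.0, ss)
    xn = xc / ss[:, None, :]
    c = xn.swapaxes(-1, -2) @ xn  # batched BLAS
    np.clip(c, -1.0, 1.0, out=c)
    return c


def _corr_rows(x: np.ndarray) -> np.ndarray:
    """Plain gene-gene correlation of a samples x genes array."""
    xc = x - x.mean(axis=0, keepdims=True)
    ss = np.sqrt((xc ** 2).sum(axis=0))
    ss = np.where(ss == 0, 1.0, ss)
    xn = xc / ss
    c = xn.T @ xn
    np.clip(c, -1.0, 1.0, out=c)
    return c


def _mc_from_corr(corr: np.ndarray, power: float, signed: bool) -> np.ndarray:
    """Module connectivity (upper-triangle TOM sum) from correlation
    matrices, batched over leading axes."""
    a = adjacency_from_correlation(corr, power=power, signed_mode=signed)
    t = tom(a)
    g = t.shape[-1]
    iu, ju = np.triu_indices(g, k=1)
    return t[..., iu, ju].sum(axis=-1)


def _gc_from_corr(corr: np.ndarray, power: float, signed: bool) -> np.ndarray:
    """Within-module gene connectivity vectors, batched: (..., g)."""
    a = adjacency_from_correlation(corr, power=power, signed_mode=signed)
    return a.sum(axis=-1)


def _as_matrix(expr: pd.DataFrame, module_genes: Optional[Sequence[str]]) -> np.ndarray:
    """samples x genes array restricted to module genes."""
    sub = expr if module_genes is None else expr.loc[list(module_genes)]
    return sub.to_numpy(dtype=float).T


# ---------------------------------------------------------------------------
# observed statistics

def gene_connectivity(
    adj: pd.DataFrame, module_genes: Optional[Sequence[str]] = None
) -> pd.Series:
    """GC per gene: summed adjacency to the other genes of the module.

    ``adj`` is a genes x genes adjacency frame (zero diagonal); the sum is
    restricted to within-module pairs.
    """
    genes = list(module_genes) if module_genes is not None else adj.index.tolist()
    sub = adj.loc[genes, genes]
    if len(genes) == 1:
        logger.warning("singleton module: GC = 0 for %s", genes[0])
        return pd.Series(0.0, index=genes)
    return sub.sum(axis=1)


def module_connectivity(
    tom_m: pd.DataFrame, module_genes: Optional[Sequence[str]] = None
) -> float:
    """MC: upper-triangle sum of the module's TOM entries."""
    genes = list(module_genes) if module_genes is not None else tom_m.index.tolist()
    if len(genes) < 2:
        raise ValueError("module connectivity needs >= 2 genes")
    vals = tom_m.loc[genes, genes].to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    return float(vals[iu, ju].sum())


@dataclass
class MDCResult:
    mdc: float
    log_mdc: float
    mc_cases: float
    mc_controls: float  # mean over control sets
    mc_controls_sets: List[float]

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mdc)


def mdc(
    expr_cases: pd.DataFrame,
    expr_controls_sets: Sequence[pd.DataFrame],
    module_genes: Optional[Sequence[str]] = None,
    power: float = 8.0,
    signed_mode: bool = False,
) -> MDCResult:
    """Observed modular differential connectivity.

    MC is computed separately on the case samples and on each matched
    control set from group-specific correlation matrices; the control MCs
    are averaged.  A zero control MC yields an NaN-flagged result.
    """
    if expr_cases.shape[1] < 3 or any(c.shape[1] < 3 for c in expr_controls_sets):
        raise ValueError("MDC needs >= 3 samples per group")
    xc = _as_matrix(expr_cases, module_genes)
    mc_cases = float(_mc_from_corr(_corr_rows(xc), power, signed_mode))
    mc_sets = [
        float(_mc_from_corr(_corr_rows(_as_matrix(c, module_genes)), power, signed_mode))
        for c in expr_controls_sets
    ]
    mc_ctrl = float(np.mean(mc_sets))
    if mc_ctrl == 0:
        logger.warning("control MC = 0; MDC undefined")
        return MDCResult(np.nan, np.nan, mc_cases, mc_ctrl, mc_sets)
    val = mc_cases / mc_ctrl
    return MDCResult(val, float(np.log(val)) if val > 0 else np.nan,
                     mc_cases, mc_ctrl, mc_sets)


# ---------------------------------------------------------------------------
# permutation machinery

def _pool_and_set_positions(
    expr_cases: pd.DataFrame, expr_controls_sets: Sequence[pd.DataFrame],
    module_genes: Optional[Sequence[str]],
) -> Tuple[np.ndarray, int, List[np.ndarray]]:
    """Unique sample pool (samples x genes) and per-set index positions.

    Control samples recurring across sets are pooled once; each set is
    recorded as index positions into the unique control block.  Permuted
    pseudo-control sets reuse these positions on the shuffled remainder, so
    every permutation reproduces the observed group sizes *and* the
    observed overlap structure between sets — both matter because the
    noise bias of a TOM sum depends strongly on group size.
    """
    case_ids = list(expr_cases.columns)
    ctrl_ids: List[str] = []
    seen = set(case_ids)
    for cset in expr_controls_sets:
        for s in cset.columns:
            if s not in seen:
                seen.add(s)
                ctrl_ids.append(s)
    where = {s: i for i, s in enumerate(ctrl_ids)}
    positions = [
        np.array([where[s] for s in cset.columns], dtype=int)
        for cset in expr_controls_sets
    ]
    sub = expr_cases if module_genes is None else expr_cases.loc[list(module_genes)]
    blocks = [sub.to_numpy(dtype=float).T]
    lookup = pd.concat(
        [c if module_genes is None else c.loc[list(module_genes)]
         for c in expr_controls_sets], axis=1
    )
    lookup = lookup.loc[:, ~lookup.columns.duplicated()]
    blocks.append(lookup[ctrl_ids].to_numpy(dtype=float).T)
    x = np.concatenate(blocks, axis=0)
    return x, len(case_ids), positions


@dataclass
class PermutationResult:
    observed: MDCResult
    p_gain: float
    p_loss: float
    n_permutations: int


def mdc_significance(
    expr_cases: pd.DataFrame,
    expr_controls_sets: Sequence[pd.DataFrame],
    module_genes: Optional[Sequence[str]] = None,
    M: int = 1000,
    seed: int = 0,
    power: float = 8.0,
    signed_mode: bool = False,
    max_chunk_elems: int = 4_000_000,
) -> PermutationResult:
    """Permutation tail probabilities for gain/loss of connectivity.

    Case/control labels are shuffled over the pooled window samples
    preserving group sizes; MDC is recomputed per permutation.  Deterministic
    given ``seed``.
    """
    if M < 100:
        logger.warning("M = %d permutations gives an unstable p estimate", M)
    obs = mdc(expr_cases, expr_controls_sets, module_genes, power, signed_mode)
    x, n_cases, positions = _pool_and_set_positions(
        expr_cases, expr_controls_sets, module_genes
    )
    n_pool, g = x.shape
    rng = np.random.default_rng(seed)
    mdc_perm = np.empty(M)
    chunk = max(1, int(max_chunk_elems / max(1, n_pool * g)))
    done = 0
    while done < M:
        m = min(chunk, M - done)
        perms = rng.random((m, n_pool)).argsort(axis=1)
        mc_case = _mc_from_corr(
            _batch_corr(x, perms[:, :n_cases]), power, signed_mode
        )
        remainder = perms[:, n_cases:]
        mc_ctrl = np.zeros(m)
        for pos in positions:
            mc_ctrl += _mc_from_corr(
                _batch_corr(x, remainder[:, pos]), power, signed_mode
            )
        mc_ctrl /= len(positions)
        with np.errstate(divide="ignore", invalid="ignore"):
            mdc_perm[done:done + m] = mc_case / mc_ctrl
        done += m
    valid = np.isfinite(mdc_perm)
    if not valid.all():
        logger.warning("%d permutations had zero control MC", (~valid).sum())
    p_gain = float(np.mean(mdc_perm[valid] > obs.mdc)) if obs.defined else np.nan
    p_loss = float(np.mean(mdc_perm[valid] < obs.mdc)) if obs.defined else np.nan
    return PermutationResult(obs, p_gain, p_loss, int(valid.sum()))


def _window_seed(seed: int, window_day: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(window_day,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def mdc_timecourse(
    expr: pd.DataFrame,
    windows: Sequence[WindowAssignment],
    module_genes: Sequence[str],
    M: int = 1000,
    seed: int = 0,
    power: float = 8.0,
    signed_mode: bool = False,
    min_samples_per_group: int = 10,
) -> pd.DataFrame:
    """MDC and permutation significance per analysis window, BH-adjusted.

    Windows with fewer than ``min_samples_per_group`` samples in any group
    are reported with NaN statistics and ``skipped = True``.  Benjamini-
    Hochberg adjustment runs across the module's non-skipped windows,
    separately for the gain and loss tails.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for w in windows:
        sets = [s for s in w.control_sets]
        n_min = min([len(w.case_samples)] + [len(s) for s in sets]) if sets else 0
        if not sets or n_min < min_samples_per_group:
            rows.append({
                "window_day": w.window_day, "n_cases": len(w.case_samples),
                "mc_cases": np.nan, "mc_controls": np.nan, "mdc": np.nan,
                "log_mdc": np.nan, "p_gain": np.nan, "p_loss": np.nan,
                "skipped": True,
            })
            continue
        res = mdc_significance(
            expr[w.case_samples], [expr[s] for s in sets], module_genes,
            M=M, seed=_window_seed(seed, w.window_day),
            power=power, signed_mode=signed_mode,
        )
        rows.append({
            "window_day": w.window_day, "n_cases": len(w.case_samples),
            "mc_cases": res.observed.mc_cases,
            "mc_controls": res.observed.mc_controls,
            "mdc": res.observed.mdc, "log_mdc": res.observed.log_mdc,
            "p_gain": res.p_gain, "p_loss": res.p_loss, "skipped": False,
        })
    df = pd.DataFrame(rows)
    for tail in ("gain", "loss"):
        q = np.full(len(df), np.nan)
        mask = df[f"p_{tail}"].notna().to_numpy()
        if mask.any():
            q[mask] = multipletests(df.loc[mask, f"p_{tail}"], method="fdr_bh")[1]
        df[f"q_{tail}"] = q
    df["adjusted_q"] = df[["q_gain", "q_loss"]].min(axis=1)
    return df


def gene_differential_connectivity(
    expr_cases: pd.DataFrame,
    expr_controls_sets: Sequence[pd.DataFrame],
    module_genes: Sequence[str],
    M: int = 1000,
    seed: int = 0,
    power: float = 8.0,
    signed_mode: bool = False,
    max_chunk_elems: int = 4_000_000,
) -> pd.DataFrame:
    """Per-gene differential connectivity within one module.

    Returns a frame with GC in cases and controls (averaged over sets), the
    hub difference ``delta_h = GC_cases - GC_controls``, the ratio
    ``gdc = GC_cases / GC_controls`` (NaN when the control GC is 0), and
    permutation tail probabilities computed under the same label-shuffling
    scheme as MDC.
    """
    genes = list(module_genes)
    xc = _as_matrix(expr_cases, genes)
    gc_cases = _gc_from_corr(_corr_rows(xc), power, signed_mode)
    gc_sets = [
        _gc_from_corr(_corr_rows(_as_matrix(c, genes)), power, signed_mode)
        for c in expr_controls_sets
    ]
    gc_ctrl = np.mean(gc_sets, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gdc_obs = np.where(gc_ctrl > 0, gc_cases / gc_ctrl, np.nan)
    dh_obs = gc_cases - gc_ctrl

    x, n_cases, positions = _pool_and_set_positions(expr_cases, expr_controls_sets, genes)
    n_pool, g = x.shape
    rng = np.random.default_rng(seed)
    exceed = np.zeros(g)
    below = np.zeros(g)
    chunk = max(1, int(max_chunk_elems / max(1, n_pool * g)))
    done = 0
    while done < M:
        m = min(chunk, M - done)
        perms = rng.random((m, n_pool)).argsort(axis=1)
        gcc = _gc_from_corr(_batch_corr(x, perms[:, :n_cases]), power, signed_mode)
        remainder = perms[:, n_cases:]
        gct = np.zeros((m, g))
        for pos in positions:
            gct += _gc_from_corr(
                _batch_corr(x, remainder[:, pos]), power, signed_mode
            )
        gct /= len(positions)
        dh_perm = gcc - gct
        exceed += (dh_perm > dh_obs[None, :]).sum(axis=0)
        below += (dh_perm < dh_obs[None, :]).sum(axis=0)
        done += m
    return pd.DataFrame({
        "gene": genes,
        "gc_cases": gc_cases,
        "gc_controls": gc_ctrl,
        "gdc": gdc_obs,
        "delta_h": dh_obs,
        "p_gain": exceed / M,
        "p_loss": below / M,
    })


def rank_dhg(gdc_female: pd.DataFrame, gdc_male: pd.DataFrame) -> pd.DataFrame:
    """Cross-sex differential-hub ranking.

    Within each sex genes are ranked descending by delta_h (rank 1 =
    largest); the final rank is the per-sex sum, ties broken by the larger
    of the two delta_h values, then gene ID.
    """
    f = gdc_female.set_index("gene")
    m = gdc_male.set_index("gene")
    if set(f.index) != set(m.index):
        only_f = sorted(set(f.index) - set(m.index))
        only_m = sorted(set(m.index) - set(f.index))
        raise ValueError(
            f"gene universes differ: only-female {only_f[:5]}, only-male {only_m[:5]}"
        )
    m = m.loc[f.index]

    def _ranks(dh: pd.Series) -> pd.Series:
        order = sorted(dh.index, key=lambda gn: (-dh[gn], gn))
        return pd.Series(np.arange(1, len(order) + 1), index=order).loc[dh.index]

    rank_f = _ranks(f["delta_h"])
    rank_m = _ranks(m["delta_h"])
    out = pd.DataFrame({
        "gene": f.index,
        "gc_cases_F": f["gc_cases"].to_numpy(),
        "gc_controls_F": f["gc_controls"].to_numpy(),
        "gc_cases_M": m["gc_cases"].to_numpy(),
        "gc_controls_M": m["gc_controls"].to_numpy(),
        "delta_h_F": f["delta_h"].to_numpy(),
        "delta_h_M": m["delta_h"].to_numpy(),
        "gdc_F": f["gdc"].to_numpy(),
        "gdc_M": m["gdc"].to_numpy(),
        "p_gain_F": f["p_gain"].to_numpy(),
        "p_gain_M": m["p_gain"].to_numpy(),
        "rank_F": rank_f.to_numpy(),
        "rank_M": rank_m.to_numpy(),
    })
    out["final_rank"] = out["rank_F"] + out["rank_M"]
    out["_max_dh"] = out[["delta_h_F", "delta_h_M"]].max(axis=1)
    out = out.sort_values(
        ["final_rank", "_max_dh", "gene"], ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_max_dh").reset_index(drop=True)
    return out


def connectivity_rank_correlation(
    gc_sex1: pd.Series, gc_sex2: pd.Series
) -> Tuple[float, float]:
    """Spearman rank correlation of per-gene connectivity between strata."""
    common = gc_sex1.index.intersection(gc_sex2.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(common)}")
    rho, p = stats.spearmanr(gc_sex1.loc[common], gc_sex2.loc[common])
    return float(rho), float(p)
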