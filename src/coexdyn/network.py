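"""Weighted co-expression network construction and module detection.

Adjacency is soft-thresholded correlation, ``a_ij = |r_ij|^beta`` (unsigned,
the default) or ``((1+r)/2)^beta`` (signed).  The topological overlap
measure augments adjacency with shared-neighbour strength,

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,   k_i = sum_{u != i} a_iu,

and 1 - TOM is the dissimilarity for average-linkage clustering.  Module
detection uses a fixed-height cut of the dendrogram plus a minimum-size
filter, followed by merging of modules whose eigengenes are closer than
``merge_cut_height``; genes left unassigned are labelled ``grey``.  Two
soft powers are carried: one for network construction / clustering and one
for the connectivity statistics computed downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ModulePartition",
    "correlation_matrix",
    "adjacency",
    "tom",
    "pick_soft_threshold",
    "detect_modules",
    "build_reference_network",
    "MODULE_COLOR_SEQUENCE",
]

# conventional module colour sequence (size-ordered); "grey" = unassigned
MODULE_COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
]

GREY = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    """Network-construction parameters.

    ``power_network`` (default 12) soft-thresholds the adjacency used for
    clustering; ``power_connectivity`` (default 8) is the exponent used for
    the connectivity statistics.  ``tree_cut_height`` is the fixed cut on
    the 1 - TOM dendrogram; ``merge_cut_height`` merges modules whose
    eigengene dissimilarity falls below it.
    """

    power_network: float = 12.0
    power_connectivity: float = 8.0
    signed_mode: bool = False
    tree_cut_height: float = 0.9998
    merge_cut_height: float = 0.25
    min_module_size: int = 30
    max_block_size: int = 20000
    scale_free_r2_target: float = 0.80

    def __post_init__(self) -> None:
        if self.power_network < 1 or self.power_connectivity < 1:
            raise ValueError("soft powers must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if not 0 < self.tree_cut_height <= 1:
            raise ValueError("tree_cut_height must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModulePartition:
    """gene -> module label, with sizes and the dendrogram record."""

    labels: pd.Series  # index = genes, values = colour labels
    linkage_by_block: Dict[int, np.ndarray] = field(default_factory=dict)
    reference_samples: List[str] = field(default_factory=list)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def modules(self, include_grey: bool = False) -> List[str]:
        sizes = self.sizes
        mods = [m for m in sizes.index if include_grey or m != GREY]
        return sorted(mods, key=lambda m: (-sizes[m], m))

    def module_genes(self, module: str) -> List[str]:
        return self.labels.index[self.labels == module].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.labels.index, "module_label": self.labels.to_numpy()}
        )


def correlation_matrix(expr: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Gene-gene Pearson correlation (genes are rows).

    Constant genes get correlation 0 to every other gene (logged), never NaN.
    """
    vals = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, float)
    sd = vals.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    if constant.any():
        logger.warning("%d constant gene(s); their correlations set to 0", constant.sum())
    corr = np.nan_to_num(corr, nan=0.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def adjacency(
    expr: pd.DataFrame | np.ndarray,
    power: float = 8.0,
    signed_mode: bool = False,
) -> np.ndarray:
    """Soft-threshold adjacency with zero diagonal (genes are rows)."""
    corr = correlation_matrix(expr)
    return adjacency_from_correlation(corr, power, signed_mode)


def adjacency_from_correlation(
    corr: np.ndarray, power: float = 8.0, signed_mode: bool = False
) -> np.ndarray:
    """``|r|^power`` (unsigned) or ``((1+r)/2)^power`` (signed); zero diagonal.

    Accepts batched input (..., g, g).
    """
    if signed_mode:
        a = ((1.0 + corr) / 2.0) ** power
    else:
        a = np.abs(corr) ** power
    g = a.shape[-1]
    a[..., np.arange(g), np.arange(g)] = 0.0
    return a


def tom(adj: np.ndarray, include_self: bool = False) -> np.ndarray:
    """Topological overlap matrix; accepts batched adjacency (..., g, g).

    With the standard convention the shared-neighbour sum excludes u in
    {i, j}; ``include_self=True`` implements the literal all-nodes variant
    with a_ii treated as 1.  Diagonal is 1 by definition.  Isolated pairs
    (k_i = k_j = a_ij = 0) get t_ij = 0.
    """
    a = np.asarray(adj, dtype=float)
    g = a.shape[-1]
    idx = np.arange(g)
    if include_self:
        b = a.copy()
        b[..., idx, idx] = 1.0
        l = b @ b
        k = b.sum(axis=-1)
    else:
        # zero diagonal already excludes u = i and u = j from a @ a
        l = a @ a
        k = a.sum(axis=-1)
    kmin = np.minimum(k[..., :, None], k[..., None, :])
    t = (l + a) / (kmin + 1.0 - a)
    t[..., idx, idx] = 1.0
    return t


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> Tuple[float, float]:
    """Signed R^2 of the log10 p(k) vs log10 k regression (scale-free fit).

    Returns (signed_r2, slope).  R^2 is signed negative when the slope is
    positive, as in the standard topology criterion.
    """
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        kb = k[which == b]
        if kb.size == 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(kb.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (r2 if slope < 0 else -r2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: Sequence[float] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20),
    scale_free_r2_target: float = 0.80,
    signed_mode: bool = False,
    n_bins: int = 10,
) -> Tuple[float, pd.DataFrame, bool]:
    """Smallest candidate power whose scale-free fit R^2 reaches the target.

    Returns (chosen power, fit table, warning flag).  When no candidate
    reaches the target the power with maximal signed R^2 is returned with
    the warning flag set.
    """
    if expr.shape[1] < 30:
        logger.warning(
            "soft-threshold selection with %d samples (<30) may be unstable",
            expr.shape[1],
        )
    corr = correlation_matrix(expr)
    rows = []
    for p in candidate_powers:
        a = adjacency_from_correlation(corr, power=p, signed_mode=signed_mode)
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": p, "signed_r2": r2, "slope": slope, "mean_k": k.mean()})
    table = pd.DataFrame(rows)
    ok = table[table["signed_r2"] >= scale_free_r2_target]
    if len(ok):
        chosen = float(ok.iloc[0]["power"])
        return chosen, table, False
    best = table.loc[table["signed_r2"].idxmax()]
    logger.warning(
        "no candidate power reached scale-free R^2 >= %.2f; best %.2f at power %g",
        scale_free_r2_target, best["signed_r2"], best["power"],
    )
    return float(best["power"]), table, True


def _module_eigengene(expr_block: np.ndarray) -> np.ndarray:
    """First-PC score vector of a standardized genes x samples block."""
    x = expr_block - expr_block.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    # samples x genes SVD; scores = first left-singular direction of x.T
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    scores = u[:, 0] * s[0]
    load = vt[0]
    if load[np.argmax(np.abs(load))] < 0:
        scores = -scores
    return scores


def _cluster_block(
    expr: np.ndarray, config: NetworkConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Cluster one block of genes; returns (integer labels, linkage).

    Label 0 = unassigned.
    """
    a = adjacency(expr, power=config.power_network, signed_mode=config.signed_mode)
    t = tom(a)
    dissim = 1.0 - t
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    np.clip(dissim, 0.0, None, out=dissim)
    z = average(squareform(dissim, checks=False))
    labels = fcluster(z, t=config.tree_cut_height, criterion="distance")

    # merge clusters with near-identical eigengenes before the size filter,
    # so sub-branches of one module reunite rather than falling below the
    # minimum size; clusters under 3 genes have too-noisy eigengenes to merge
    while True:
        counts = pd.Series(labels).value_counts()
        mods = [m for m in counts.index if counts[m] >= 3]
        if len(mods) < 2:
            break
        scores = np.column_stack([_module_eigengene(expr[labels == m]) for m in mods])
        me_corr = np.corrcoef(scores.T)
        np.fill_diagonal(me_corr, -np.inf)
        i, j = np.unravel_index(np.argmax(me_corr), me_corr.shape)
        if 1.0 - me_corr[i, j] < config.merge_cut_height:
            labels = np.where(labels == mods[j], mods[i], labels)
        else:
            break

    counts = pd.Series(labels).value_counts()
    small = counts[counts < config.min_module_size].index
    labels = np.where(np.isin(labels, small), 0, labels)
    return labels, z


def detect_modules(
    expr: pd.DataFrame, config: NetworkConfig = NetworkConfig(), seed: int = 0
) -> ModulePartition:
    """Detect co-expression modules; genes in blocks if over max_block_size.

    Blocks are pre-partitioned by seeded k-means on standardized expression
    profiles; clustering runs independently per block and labels are
    size-ordered colours across blocks.  Fewer genes than
    ``min_module_size`` yields a single grey module.
    """
    genes = expr.index.tolist()
    n_genes = len(genes)
    if n_genes < config.min_module_size:
        return ModulePartition(labels=pd.Series(GREY, index=genes))

    vals = expr.to_numpy(dtype=float)
    if n_genes > config.max_block_size:
        from sklearn.cluster import KMeans

        n_blocks = int(np.ceil(n_genes / config.max_block_size))
        std = vals - vals.mean(axis=1, keepdims=True)
        sd = std.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        std = std / sd
        km = KMeans(n_clusters=n_blocks, random_state=seed, n_init=10)
        blocks = km.fit_predict(std)
    else:
        blocks = np.zeros(n_genes, dtype=int)

    member_sets: List[List[str]] = []
    linkages: Dict[int, np.ndarray] = {}
    for b in np.unique(blocks):
        bidx = np.where(blocks == b)[0]
        if bidx.size < config.min_module_size:
            continue
        labels, z = _cluster_block(vals[bidx], config)
        linkages[int(b)] = z
        for m in np.unique(labels):
            if m == 0:
                continue
            member_sets.append([genes[i] for i in bidx[labels == m]])

    # size-descending colour labels; ties broken by smallest member gene id
    member_sets.sort(key=lambda ms: (-len(ms), min(ms)))
    final = pd.Series(GREY, index=genes)
    for rank, members in enumerate(member_sets):
        if rank < len(MODULE_COLOR_SEQUENCE):
            name = MODULE_COLOR_SEQUENCE[rank]
        else:
            name = f"module{rank + 1}"
        final.loc[members] = name
    return ModulePartition(labels=final, linkage_by_block=linkages)


def build_reference_network(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    reference_window_day: int = 180,
    config: NetworkConfig = NetworkConfig(),
    max_offset_days: float = 100.0,
    seed: int = 0,
) -> ModulePartition:
    """Reference module partition from case samples nearest the reference day.

    The partition (and the sample list it was built from) is held fixed for
    every downstream time point.
    """
    from .cohort import window_sample_selection

    cases = samples[samples["group"] == "case"]
    sel = window_sample_selection(cases, reference_window_day, max_offset_days)
    ref_samples = [s for s in sel["sample_id"] if s in expr.columns]
    if not ref_samples:
        raise ValueError(
            f"reference window at day {reference_window_day} contains no case samples"
        )
    part = detect_modules(expr[ref_samples], config=config, seed=seed)
    part.reference_samples = ref_samples
    return part
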