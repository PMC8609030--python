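"""Module over-representation analysis against externally supplied gene sets.

Each reference-network module is tested against each gene set with a
one-sided hypergeometric (over-representation) test on the overlap, the
universe being all genes assigned in the partition; p-values are
Benjamini-Hochberg adjusted across all module x set tests of a call.
Gene sets arrive in GMT format (set name, description, members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "overrepresentation_pvalue",
    "enrich",
    "signature_expression_ratio",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus optional descriptions."""

    sets: Dict[str, set]
    descriptions: Dict[str, str] = field(default_factory=dict)

    def restrict(self, universe: set) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={name: s & universe for name, s in self.sets.items()},
            descriptions=dict(self.descriptions),
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member...)."""
    sets: Dict[str, set] = {}
    desc: Dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: malformed GMT line (needs >= 3 fields)")
        name, description, members = parts[0], parts[1], parts[2:]
        genes = {g for g in members if g}
        if not genes:
            logger.warning("%s:%d: set %r is empty, dropped", path, ln, name)
            continue
        sets[name] = genes
        desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc] + sorted(collection.sets[name])))
    Path(path).write_text("\n".join(lines) + "\n")


def overrepresentation_pvalue(overlap: int, universe: int, set_size: int,
                              module_size: int) -> float:
    """Upper-tail hypergeometric p: P(X >= overlap) for an overlap drawn
    from ``universe`` genes of which ``set_size`` are in the gene set and
    ``module_size`` are sampled into the module."""
    if overlap < 0 or set_size > universe or module_size > universe:
        raise ValueError("invalid hypergeometric configuration")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, module_size))


def enrich(
    partition,
    sets: GeneSetCollection,
    universe: Optional[set] = None,
    include_grey_in_universe: bool = True,
    probe_to_gene: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Module x gene-set over-representation table with BH q-values.

    ``partition`` is a :class:`coexdyn.network.ModulePartition`.  When a
    probe -> gene mapping is given, probes collapsing to one gene count
    once.  Gene sets are intersected with the universe before testing; an
    empty post-intersection set yields overlap 0, p = 1.
    """
    from statsmodels.stats.multitest import multipletests

    labels = partition.labels
    if probe_to_gene is not None:
        labels = labels.groupby(labels.index.map(lambda p: probe_to_gene.get(p, p))).first()
    if universe is None:
        universe = set(labels.index) if include_grey_in_universe else set(
            labels.index[labels != "grey"]
        )
    labels = labels[labels.index.isin(universe)]
    n_universe = len(universe)
    restricted = sets.restrict(universe)
    rows = []
    for module in partition.modules(include_grey=False):
        members = set(labels.index[labels == module])
        for name in sorted(restricted.sets):
            gene_set = restricted.sets[name]
            overlap = len(members & gene_set)
            if len(gene_set) == 0:
                p = 1.0
            else:
                p = overrepresentation_pvalue(
                    overlap, n_universe, len(gene_set), len(members)
                )
            rows.append({
                "module": module,
                "set": name,
                "overlap": overlap,
                "module_size": len(members),
                "set_size": len(gene_set),
                "universe_size": n_universe,
                "overlap_fraction": overlap / len(gene_set) if gene_set else 0.0,
                "p": p,
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df


def signature_expression_ratio(
    expr: pd.DataFrame,
    windows,
    gene_set: Sequence[str],
    ratio_threshold: float = 1.10,
) -> pd.DataFrame:
    """Per-gene per-window case/control expression ratio with t-test p.

    ``windows`` are matched :class:`coexdyn.cohort.WindowAssignment`
    objects.  Control means are averaged over the matched control sets.  A
    gene is flagged when its ratio deviates from 1 by more than the
    threshold in either direction.  Genes absent from the matrix are
    skipped with a warning.
    """
    genes = [g for g in gene_set if g in expr.index]
    missing = sorted(set(gene_set) - set(genes))
    if missing:
        logger.warning("signature genes absent from matrix, skipped: %s", missing[:10])
    rows = []
    for w in windows:
        if not w.case_samples or not w.control_sets:
            continue
        case_mean = expr.loc[genes, w.case_samples].mean(axis=1)
        ctrl_means = [expr.loc[genes, s].mean(axis=1) for s in w.control_sets]
        ctrl_mean = pd.concat(ctrl_means, axis=1).mean(axis=1)
        ctrl_all = sorted({s for cset in w.control_sets for s in cset})
        a = expr.loc[genes, w.case_samples].to_numpy(dtype=float)
        b = expr.loc[genes, ctrl_all].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.nan_to_num(np.asarray(t, float), nan=0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ctrl_mean.to_numpy() != 0,
                             case_mean.to_numpy() / ctrl_mean.to_numpy(), np.nan)
        dev = np.maximum(ratio, 1.0 / ratio)
        for i, g in enumerate(genes):
            rows.append({
                "window_day": w.window_day,
                "gene": g,
                "case_mean": case_mean.iloc[i],
                "control_mean": ctrl_mean.iloc[i],
                "ratio": ratio[i],
                "t": t[i],
                "p": float(p[i]),
                "exceeds_threshold": bool(dev[i] > ratio_threshold),
            })
    return pd.DataFrame(rows)
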