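"""Synthetic longitudinal case/control expression cohorts with planted modules.

The generator emulates the design of a prospective transcriptomic cohort in
which ~60 children who progress to type 1 diabetes ("cases") and ~325
non-progressors ("controls") are sampled repeatedly in the 600 days before
(pseudo-)diagnosis.  Co-expression modules are planted through a one-factor
model: for module ``m`` with per-gene loading ``lambda`` and noise SD
``sigma``, the expression of gene ``g`` in sample ``i`` is

    x_gi = lambda_g(group_i, t_i) * f_m(i) + mu_g(group_i, t_i) + eps_gi

with ``f_m(i)`` an independent standard-normal latent factor per draw,
so the population within-module correlation is lambda^2 / (lambda^2 + sigma^2).
Connectivity shifts are planted by multiplying case loadings inside a
specified pre-diagnosis time window; expression mean shifts are kept small
(<= 5% by default) to mirror the observed "connectivity without expression
change" regime.  Ground truth (module membership, per-window expected
correlations, shifted windows, designated hub genes) is returned alongside
the data so every downstream stage is testable without restricted data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PlantedModule",
    "SyntheticConfig",
    "GroundTruth",
    "loading_for_correlation",
    "generate_cohort",
    "write_fixture",
]


def loading_for_correlation(r: float, noise_sd: float = 1.0) -> float:
    """Factor loading that yields within-module correlation ``r`` in the
    one-factor model (population correlation = lambda^2/(lambda^2+sigma^2))."""
    if not 0 <= r < 1:
        raise ValueError(f"correlation must be in [0, 1), got {r}")
    return float(noise_sd * np.sqrt(r / (1.0 - r)))


@dataclass(frozen=True)
class PlantedModule:
    """A planted co-expression module driven by a latent factor.

    ``case_loading_multiplier`` scales case-sample loadings inside
    ``shift_window`` (days relative to diagnosis, both <= 0), raising
    within-module correlation for cases without touching the mean unless
    ``mean_shift_fraction`` is set.  ``sex_multipliers`` optionally replaces
    the multiplier per sex stratum.  The first ``n_hub_genes`` genes can
    carry an extra case-only loading boost, planting differential hubs.
    """

    name: str
    n_genes: int
    base_loading: float
    case_loading_multiplier: float = 1.0
    shift_window: Tuple[float, float] = (-600.0, 0.0)
    mean_shift_fraction: float = 0.0
    sex_multipliers: Optional[Dict[str, float]] = None
    n_hub_genes: int = 0
    hub_case_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"module {self.name}: n_genes must be > 0")
        if not 0 < self.base_loading:
            raise ValueError(f"module {self.name}: base_loading must be > 0")
        if self.case_loading_multiplier < 1:
            raise ValueError(
                f"module {self.name}: case_loading_multiplier must be >= 1"
            )
        lo, hi = self.shift_window
        if lo > hi:
            raise ValueError(f"module {self.name}: shift_window start > end")
        if self.mean_shift_fraction < 0:
            raise ValueError(f"module {self.name}: mean_shift_fraction < 0")
        if self.n_hub_genes < 0 or self.n_hub_genes > self.n_genes:
            raise ValueError(f"module {self.name}: invalid n_hub_genes")

    def genes(self) -> List[str]:
        return [f"{self.name}_G{i:04d}" for i in range(self.n_genes)]

    def hub_genes(self) -> List[str]:
        return self.genes()[: self.n_hub_genes]

    def multiplier_for(self, sex: str) -> float:
        if self.sex_multipliers is not None:
            return float(self.sex_multipliers.get(sex, self.case_loading_multiplier))
        return self.case_loading_multiplier

    def in_shift_window(self, offset_days: float) -> bool:
        lo, hi = self.shift_window
        return lo <= offset_days <= hi


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level design: sizes, time span, sampling cadence, noise, seed.

    Defaults mirror the emulated study: 60 cases vs 325 controls observed
    over the 600 days before diagnosis with draws roughly every 90 days.
    """

    n_cases: int = 60
    n_controls: int = 325
    n_background_genes: int = 100
    modules: Sequence[PlantedModule] = ()
    span_days: float = 600.0
    sampling_interval_days: float = 90.0
    noise_sd: float = 0.4
    diagnosis_age_range_days: Tuple[float, float] = (730.0, 1460.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [
            ("n_cases", self.n_cases),
            ("n_controls", self.n_controls),
            ("span_days", self.span_days),
            ("sampling_interval_days", self.sampling_interval_days),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError(f"module names must be unique, got {names}")
        seen: set = set()
        for m in self.modules:
            gs = set(m.genes())
            if seen & gs:
                raise ValueError(f"module gene sets overlap: {sorted(seen & gs)[:5]}")
            seen |= gs
        for m in self.modules:
            lo, hi = m.shift_window
            if lo < -self.span_days or hi > 0:
                raise ValueError(
                    f"module {m.name}: shift_window {m.shift_window} outside "
                    f"[-{self.span_days}, 0]"
                )

    def all_genes(self) -> List[str]:
        genes: List[str] = []
        for m in self.modules:
            genes.extend(m.genes())
        genes.extend(f"BG_G{i:05d}" for i in range(self.n_background_genes))
        return genes


@dataclass
class GroundTruth:
    """What was planted: membership, analytic correlations, shifted windows."""

    membership: Dict[str, str]  # gene -> module name ("background" for noise)
    expected_correlation: Dict[str, Dict[str, Dict[int, float]]]
    # module -> group ("case"/"control" or "case_F"/"case_M") -> window_day -> r
    shifted_windows: Dict[str, List[int]]  # module -> window days (days before dx)
    hub_genes: Dict[str, List[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "membership": self.membership,
            "expected_correlation": {
                m: {g: {str(w): r for w, r in wins.items()} for g, wins in grp.items()}
                for m, grp in self.expected_correlation.items()
            },
            "shifted_windows": self.shifted_windows,
            "hub_genes": self.hub_genes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            membership=dict(d["membership"]),
            expected_correlation={
                m: {g: {int(w): float(r) for w, r in wins.items()} for g, wins in grp.items()}
                for m, grp in d["expected_correlation"].items()
            },
            shifted_windows={m: [int(w) for w in ws] for m, ws in d["shifted_windows"].items()},
            hub_genes={m: list(g) for m, g in d.get("hub_genes", {}).items()},
        )


def _subject_offsets(rng: np.random.Generator, span: float, interval: float) -> np.ndarray:
    """Draw offsets (days relative to diagnosis, <= 0) on a jittered grid.

    A grid of draws every ``interval`` days with uniform jitter of half the
    interval guarantees each subject covers the whole span, so analysis
    windows are never empty by construction.
    """
    n_draws = max(1, int(round(span / interval)))
    centers = -(np.arange(n_draws) + 0.5) * interval
    jitter = rng.uniform(-interval / 2.0, interval / 2.0, size=n_draws)
    offsets = np.clip(centers + jitter, -span, 0.0)
    return np.sort(offsets)


def _expected_r(lam: float, sigma: float) -> float:
    return lam * lam / (lam * lam + sigma * sigma)


def generate_cohort(
    config: SyntheticConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression matrix, sample table, ground truth).

    Returns
    -------
    expr : DataFrame, genes x samples (log-scale intensities)
    samples : DataFrame with columns sample_id, subject_id, sex, group,
        offset_days (<= 0, days relative to diagnosis), age_days
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    genes = config.all_genes()
    n_genes = len(genes)

    # -- subjects ---------------------------------------------------------
    rows = []
    subjects = [(f"CASE{i:04d}", "case") for i in range(config.n_cases)]
    subjects += [(f"CTRL{i:04d}", "control") for i in range(config.n_controls)]
    for subj, group in subjects:
        idx = int(subj[4:])
        sex = "F" if idx % 2 == 0 else "M"  # 50/50 within each group
        diag_age = rng.uniform(*config.diagnosis_age_range_days)
        offsets = _subject_offsets(rng, config.span_days, config.sampling_interval_days)
        for k, off in enumerate(offsets):
            rows.append(
                {
                    "sample_id": f"{subj}_S{k:02d}",
                    "subject_id": subj,
                    "sex": sex,
                    "group": group,
                    "offset_days": float(off),
                    "age_days": float(diag_age + off),
                }
            )
    samples = pd.DataFrame(rows)
    n_samples = len(samples)

    # -- expression -------------------------------------------------------
    # log2-intensity scale: the gene-mean spread dominates the residual
    # noise, as on normalized arrays, so replicate samples correlate > 0.95
    baseline = rng.uniform(5.0, 15.0, size=n_genes)
    expr = np.empty((n_genes, n_samples))
    expr[:] = baseline[:, None]
    expr += rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    is_case = (samples["group"] == "case").to_numpy()
    offs = samples["offset_days"].to_numpy()
    sexes = samples["sex"].to_numpy()

    row0 = 0
    for m in config.modules:
        rows_m = slice(row0, row0 + m.n_genes)
        factors = rng.normal(0.0, 1.0, size=n_samples)  # fresh factor per draw
        lam = np.full((m.n_genes, n_samples), m.base_loading)
        in_win = np.array([m.in_shift_window(o) for o in offs])
        shifted = is_case & in_win
        if shifted.any():
            mult = np.array([m.multiplier_for(s) for s in sexes])
            lam[:, shifted] *= mult[shifted]
            if m.n_hub_genes:
                lam[: m.n_hub_genes, shifted] *= m.hub_case_multiplier
        expr[rows_m, :] += lam * factors[None, :]
        if m.mean_shift_fraction and shifted.any():
            mu = baseline[rows_m][:, None]
            expr[rows_m, :] += np.where(shifted[None, :], mu * m.mean_shift_fraction, 0.0)
        row0 += m.n_genes

    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="probe_id"),
                           columns=samples["sample_id"].tolist())

    # -- ground truth -----------------------------------------------------
    membership = {g: "background" for g in genes}
    expected: Dict[str, Dict[str, Dict[int, float]]] = {}
    shifted_windows: Dict[str, List[int]] = {}
    hubs: Dict[str, List[str]] = {}
    window_days = list(range(0, int(config.span_days) + 1, 10))
    sigma = config.noise_sd
    for m in config.modules:
        for g in m.genes():
            membership[g] = m.name
        hubs[m.name] = m.hub_genes()
        expected[m.name] = {"control": {}, "case_F": {}, "case_M": {}}
        shifted_windows[m.name] = []
        base_r = _expected_r(m.base_loading, sigma)
        for w in window_days:
            expected[m.name]["control"][w] = base_r
            in_win = m.in_shift_window(-float(w))
            for sex in ("F", "M"):
                lam = m.base_loading * (m.multiplier_for(sex) if in_win else 1.0)
                expected[m.name][f"case_{sex}"][w] = _expected_r(lam, sigma)
            if in_win and (
                m.multiplier_for("F") > 1.0 or m.multiplier_for("M") > 1.0
            ):
                shifted_windows[m.name].append(w)
    truth = GroundTruth(membership, expected, shifted_windows, hubs)
    return expr_df, samples, truth


def write_fixture(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> Dict[str, Path]:
    """Write expression TSV, sample sheet TSV and ground-truth JSON.

    Floats are written with ``repr`` precision so the files round-trip
    losslessly through :mod:`coexdyn.io`.
    """
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    cio.write_expression(expr, paths["expression"])
    cio.write_samples(samples, paths["samples"])
    paths["ground_truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
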