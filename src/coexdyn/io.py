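"""Readers/writers for the package's tab-delimited interchange formats.

Expression TSV: first column ``probe_id``, remaining columns sample IDs.
Sample sheet TSV: columns sample_id, subject_id, sex (M/F), group
(case/control), offset_days (float, <= 0 = days before diagnosis), age_days.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "subject_id", "sex", "group", "offset_days", "age_days"]


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index.name = "probe_id"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)
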