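"""Report serialization: the per-task, per-model screening metrics table.

Column layout mirrors the screening report schema (task, model, ACC, EACC,
SPC, SEN, AUC, 95% CI) plus provenance columns (feature set, fold scheme,
seed, permutation count). Numbers are rendered to three decimals in both
the CSV and JSON renderings, which therefore agree field by field.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .screening import ScreeningResults

__all__ = ["REPORT_COLUMNS", "write_report", "read_report"]

REPORT_COLUMNS = [
    "task", "model", "feature_set", "fold_scheme",
    "ACC", "EACC", "SPC", "SEN", "AUC", "CI_low", "CI_high",
    "seed", "n_perm",
]

_METRIC_COLUMNS = ["ACC", "EACC", "SPC", "SEN", "AUC", "CI_low", "CI_high"]


def _rendered(report: pd.DataFrame) -> pd.DataFrame:
    df = report.copy()
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[REPORT_COLUMNS]
    for col in _METRIC_COLUMNS:
        df[col] = df[col].map(lambda v: round(float(v), 3) if pd.notna(v) else v)
    return df


def write_report(
    report: ScreeningResults | pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
) -> None:
    """Write the screening report as CSV or JSON (3-decimal metrics)."""
    df = report.report if isinstance(report, ScreeningResults) else report
    df = _rendered(df)
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.3f")
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown report format {fmt!r} (csv or json)")


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)
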