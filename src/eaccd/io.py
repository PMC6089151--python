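"""Readers and writers for the delimited-text interfaces.

Patient tables are plain CSV with one row per patient: a time column, an
event column (0/1) and one column per categorical factor.  External
stagings are two-column CSVs mapping combination labels to group names.
All artifacts written by the pipeline are deterministic functions of the
inputs (no timestamps), so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .combinations import FactorScheme
from .exceptions import EaccdError
from .survival import KMCurve, SurvivalRecord

logger = logging.getLogger(__name__)


def read_survival_table(
    path: str | Path,
    time_col: str,
    event_col: str,
    factor_cols: Sequence[str],
) -> tuple[list[SurvivalRecord], int]:
    """Read patient records; returns (records, number of rows dropped).

    Rows with an unparsable or non-positive time, an event flag outside
    {0, 1}, or a blank/missing factor level are dropped and counted.

    Raises
    ------
    EaccdError
        If the file lacks a mapped column or no valid rows remain.
    """
    df = pd.read_csv(path, dtype=str)
    for col in [time_col, event_col, *factor_cols]:
        if col not in df.columns:
            raise EaccdError(f"column {col!r} not found in {path}")

    def to_float(series: pd.Series) -> pd.Series:
        # float() round-trips %.17g text exactly; pandas' fast parser does not
        def conv(x):
            try:
                return float(x)
            except (TypeError, ValueError):
                return float("nan")

        return series.map(conv)

    times = to_float(df[time_col])
    events = to_float(df[event_col])
    ok = times.notna() & (times > 0) & events.isin([0, 1])
    levels_cols = []
    for col in factor_cols:
        vals = df[col].fillna("").str.strip()
        ok &= vals != ""
        levels_cols.append(vals)

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_survival_table: dropped %d invalid rows", n_dropped)
    records = [
        SurvivalRecord(
            time=float(times.iloc[i]),
            event=int(events.iloc[i]),
            levels=tuple(col.iloc[i] for col in levels_cols),
        )
        for i in np.flatnonzero(ok.to_numpy())
    ]
    if not records:
        raise EaccdError(f"no valid rows in {path}")
    return records, n_dropped


def scheme_from_records(
    records: Iterable[SurvivalRecord], factor_names: Sequence[str]
) -> FactorScheme:
    """Infer a factor scheme from the observed levels (sorted, opaque labels)."""
    records = list(records)
    if not records:
        raise EaccdError("no records to infer a scheme from")
    n_factors = len(factor_names)
    level_sets: list[set[str]] = [set() for _ in range(n_factors)]
    for r in records:
        if len(r.levels) != n_factors:
            raise EaccdError("record level count does not match factor names")
        for i, lev in enumerate(r.levels):
            level_sets[i].add(lev)
    return FactorScheme(
        factor_names=tuple(factor_names),
        levels_per_factor=tuple(tuple(sorted(s)) for s in level_sets),
    )


def write_survival_table(
    records: Sequence[SurvivalRecord],
    factor_names: Sequence[str],
    path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
) -> None:
    df = pd.DataFrame(
        {
            time_col: [r.time for r in records],
            event_col: [r.event for r in records],
            **{
                name: [r.levels[i] for r in records]
                for i, name in enumerate(factor_names)
            },
        }
    )
    # %.17g guarantees exact float round-trip through the text format
    df.to_csv(path, index=False, float_format="%.17g")


def read_mapping(path: str | Path) -> dict[str, str]:
    """Two-column delimited file: combination label -> group name."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise EaccdError(f"mapping file {path} needs two columns (combination, group)")
    col_label, col_group = df.columns[:2]
    mapping = {}
    for _, row in df.iterrows():
        mapping[str(row[col_label]).strip()] = str(row[col_group]).strip()
    return mapping


def write_mapping(mapping: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        {"combination": list(mapping), "group": [mapping[k] for k in mapping]}
    )
    df.to_csv(path, index=False)


def write_groups_table(rows: Sequence[tuple[str, int]], path: str | Path) -> None:
    """Group membership table (combination label, group number)."""
    pd.DataFrame(rows, columns=["combination", "group"]).to_csv(path, index=False)


def write_curve_table(ks: Sequence[int], values: Sequence[float], path: str | Path) -> None:
    pd.DataFrame({"k": list(ks), "c_index": [f"{v:.10g}" for v in values]}).to_csv(
        path, index=False
    )


def write_km_table(km: KMCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time": km.event_times,
            "survival": [f"{v:.10g}" for v in km.survival_probs],
            "at_risk": km.at_risk,
        }
    ).to_csv(path, index=False)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
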