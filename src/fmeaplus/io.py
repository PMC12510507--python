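"""CSV and JSON input/output for panels, worksheets, surveys and results.

All files are comma-separated UTF-8 with a mandatory header row and
decimal points regardless of locale.  Expert panels travel in a long
format (one row per expert, hierarchy level and upper-triangle pair);
aggregated matrices in a wide format mirroring the published table
layout; worksheets as one row per failure mode with twelve sub-factor
rating columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrices import FuzzyComparisonMatrix, WeightVector
from .model import FailureModeRecord, FmeaTaxonomy, RiskResult, level_summary
from .validity import LikertCountTable

__all__ = [
    "read_expert_matrices",
    "write_expert_matrices",
    "read_matrix_wide",
    "write_matrix_wide",
    "read_worksheet",
    "write_worksheet",
    "write_results",
    "read_likert_counts",
    "write_likert_counts",
    "read_contingency",
    "write_contingency",
]

_LONG_COLUMNS = ["expert_id", "level", "item_i", "item_j", "l", "m", "u"]


def read_expert_matrices(path: str | Path) -> dict[str, list[FuzzyComparisonMatrix]]:
    """Read a long-format expert panel CSV.

    Columns: ``expert_id, level, item_i, item_j, l, m, u`` with one row
    per upper-triangle pair (item_i before item_j in the item order of
    first appearance).  Returns matrices grouped by hierarchy level, in
    expert order of first appearance; the lower triangle is completed by
    the reciprocal rule.
    """
    df = pd.read_csv(path)
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, list[FuzzyComparisonMatrix]] = {}
    for level, level_df in df.groupby("level", sort=False):
        # item order = order of first appearance across item_i then item_j
        items: list[str] = []
        for col in ("item_i", "item_j"):
            for name in level_df[col]:
                if name not in items:
                    items.append(name)
        mats: list[FuzzyComparisonMatrix] = []
        for expert, edf in level_df.groupby("expert_id", sort=False):
            upper = {}
            for row in edf.itertuples(index=False):
                pair = (row.item_i, row.item_j)
                if pair in upper:
                    raise ValueError(
                        f"{path}: duplicate pair {pair} for expert {expert!r} "
                        f"at level {level!r}"
                    )
                upper[pair] = (row.l, row.m, row.u)
            try:
                mats.append(FuzzyComparisonMatrix.from_upper_triangle(items, upper))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: expert {expert!r}, level {level!r}: {exc}"
                ) from exc
        out[str(level)] = mats
    return out


def write_expert_matrices(
    path: str | Path,
    panels: Mapping[str, Sequence[FuzzyComparisonMatrix]],
    expert_ids: Mapping[str, Sequence[str]] | None = None,
) -> None:
    """Write panels grouped by level to the long CSV format."""
    rows = []
    for level, mats in panels.items():
        ids = (
            list(expert_ids[level])
            if expert_ids and level in expert_ids
            else [f"E{k + 1:02d}" for k in range(len(mats))]
        )
        for eid, mat in zip(ids, mats):
            for i in range(mat.n):
                for j in range(i + 1, mat.n):
                    l, m, u = mat.values[i, j]
                    rows.append(
                        (eid, level, mat.items[i], mat.items[j], l, m, u)
                    )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def read_matrix_wide(path: str | Path, mode: str = "complete") -> FuzzyComparisonMatrix:
    """Read a wide-format aggregated matrix CSV.

    First column ``item`` holds row labels; then three columns
    ``<name>.l, <name>.m, <name>.u`` per compared item, in row order.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "item":
        raise ValueError(f"{path}: first column must be 'item'")
    items = [str(v) for v in df["item"]]
    arr = np.zeros((len(items), len(items), 3))
    for j, name in enumerate(items):
        for c, comp in enumerate("lmu"):
            col = f"{name}.{comp}"
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
            arr[:, j, c] = df[col].to_numpy(dtype=float)
    return FuzzyComparisonMatrix.from_full(items, arr, mode=mode)


def write_matrix_wide(path: str | Path, matrix: FuzzyComparisonMatrix) -> None:
    data: dict[str, list] = {"item": list(matrix.items)}
    for j, name in enumerate(matrix.items):
        for c, comp in enumerate("lmu"):
            data[f"{name}.{comp}"] = matrix.values[:, j, c].tolist()
    pd.DataFrame(data).to_csv(path, index=False)


def read_worksheet(path: str | Path, taxonomy: FmeaTaxonomy) -> list[FailureModeRecord]:
    """Read a worksheet CSV: ``mode_id, description, <12 sub-factor columns>``.

    The rating column set must match the taxonomy's sub-factors exactly;
    non-numeric cells are reported with their mode and column.
    """
    df = pd.read_csv(path, dtype={"mode_id": str})
    for col in ("mode_id", "description"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rating_cols = [c for c in df.columns if c not in ("mode_id", "description")]
    expected = set(taxonomy.sub_factors)
    if set(rating_cols) != expected:
        raise ValueError(
            f"{path}: rating columns do not match the taxonomy "
            f"(missing {sorted(expected - set(rating_cols))}, "
            f"unexpected {sorted(set(rating_cols) - expected)})"
        )
    # label-based iteration: sub-factor names contain spaces and slashes
    records = []
    for _, row in df.iterrows():
        ratings = {}
        for col in rating_cols:
            try:
                ratings[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: non-numeric rating for mode {row['mode_id']!r}, "
                    f"column {col!r}: {row[col]!r}"
                ) from exc
        rec = FailureModeRecord(
            mode_id=str(row["mode_id"]),
            description="" if pd.isna(row["description"]) else str(row["description"]),
            ratings=ratings,
        )
        rec.validate(taxonomy)
        records.append(rec)
    return records


def write_worksheet(
    path: str | Path, records: Sequence[FailureModeRecord], taxonomy: FmeaTaxonomy
) -> None:
    subs = list(taxonomy.sub_factors)
    rows = [
        {"mode_id": r.mode_id, "description": r.description, **{s: r.ratings[s] for s in subs}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["mode_id", "description", *subs]).to_csv(path, index=False)


def write_results(
    csv_path: str | Path,
    results: Sequence[RiskResult],
    summary_json_path: str | Path | None = None,
) -> None:
    """Write per-mode results (RPN to 4 decimals) and an optional summary JSON."""
    df = pd.DataFrame(
        {
            "mode_id": [r.mode_id for r in results],
            "O": [round(r.O, 4) for r in results],
            "S": [round(r.S, 4) for r in results],
            "D": [round(r.D, 4) for r in results],
            "rpn": [round(r.rpn, 4) for r in results],
            "level": [r.level for r in results],
        }
    )
    df.to_csv(csv_path, index=False)
    if summary_json_path is not None:
        with open(summary_json_path, "w", encoding="utf-8") as fh:
            json.dump(level_summary(list(results)), fh, indent=2)


def read_likert_counts(path: str | Path) -> LikertCountTable:
    """Read a Likert counts CSV: ``item, c1, c2, c3, c4, c5``."""
    df = pd.read_csv(path)
    expected = ["item", "c1", "c2", "c3", "c4", "c5"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: columns must be exactly {expected}")
    counts = df[["c1", "c2", "c3", "c4", "c5"]].to_numpy(dtype=int)
    totals = set(counts.sum(axis=1).tolist())
    if len(totals) != 1:
        raise ValueError(f"{path}: rows imply different panel sizes {sorted(totals)}")
    return LikertCountTable(tuple(df["item"].astype(str)), counts, totals.pop())


def write_likert_counts(path: str | Path, table: LikertCountTable) -> None:
    df = table.to_frame().reset_index(names="item")
    df.to_csv(path, index=False)


def read_contingency(path: str | Path) -> pd.DataFrame:
    """Read a level-by-outcome contingency CSV (first column = level)."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty contingency table")
    return df.astype(int)


def write_contingency(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index_label="level")
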