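"""Overlap and novelty statistics against reference resilience frameworks.

A membership table maps each indicator to the established frameworks that
already contain it (Community Resilience Index, PEOPLES, Sendai) plus a
novelty flag.  Statistics are pure column counts — the table is the source
of truth and is never reconciled against narrative claims; rows that are
marked both framework-present and novel are surfaced explicitly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "FRAMEWORK_COLUMNS",
    "MembershipError",
    "load_membership",
    "packaged_membership_path",
    "write_membership",
    "overlap_stats",
]

FRAMEWORK_COLUMNS = ("CRI", "PEOPLES", "Sendai")
_TRUE = {"1", "true", "yes", "✓"}
_FALSE = {"0", "false", "no", "–", "-", "—", ""}


class MembershipError(ValueError):
    pass


def packaged_membership_path() -> Path:
    """Path to the packaged indicator-framework membership fixture."""
    return Path(str(resources.files("resilmine.data").joinpath("framework_membership.csv")))


def _to_bool(value, row_label) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise MembershipError(f"row {row_label!r}: unknown membership symbol {value!r}")


def load_membership(path: str | Path | None = None) -> pd.DataFrame:
    """Read a membership CSV; checkmark/dash or 1/0 cells become booleans.

    Defaults to the packaged fixture.  Indicator names must be unique; an
    unrecognized cell symbol raises :class:`MembershipError` naming the row.
    """
    path = packaged_membership_path() if path is None else Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"indicator", "dimension", "Novel", *FRAMEWORK_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise MembershipError(f"missing columns: {sorted(missing)}")
    if df["indicator"].duplicated().any():
        dups = df.loc[df["indicator"].duplicated(), "indicator"].tolist()
        raise MembershipError(f"duplicate indicators: {dups}")
    for col in (*FRAMEWORK_COLUMNS, "Novel"):
        df[col] = [
            _to_bool(v, row) for v, row in zip(df[col], df["indicator"])
        ]
    return df


def write_membership(df: pd.DataFrame, path: str | Path) -> Path:
    out = df.copy()
    for col in (*FRAMEWORK_COLUMNS, "Novel"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    return Path(path)


def overlap_stats(table: pd.DataFrame) -> dict:
    """Column-sum overlap counts/fractions per framework, novelty counts, and
    the rows carrying both a framework checkmark and the novel flag."""
    if len(table) == 0:
        raise MembershipError("membership table is empty")
    n = len(table)
    stats: dict = {"n_indicators": int(n), "frameworks": {}, "novel": {}}
    for col in FRAMEWORK_COLUMNS:
        count = int(table[col].sum())
        stats["frameworks"][col] = {"count": count, "fraction": count / n}
    novel_count = int(table["Novel"].sum())
    stats["novel"] = {"count": novel_count, "fraction": novel_count / n}
    present_any = table[list(FRAMEWORK_COLUMNS)].any(axis=1)
    both = table.loc[present_any & table["Novel"], "indicator"].tolist()
    stats["novel_and_present"] = both  # surfaced, never reconciled away
    per_dim = table.groupby("dimension")["indicator"].count().to_dict()
    stats["per_dimension"] = {str(k): int(v) for k, v in per_dim.items()}
    return stats
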