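"""Sample locality table: sample_id, population, x, y."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ["sample_id", "population", "x", "y"]

__all__ = ["read_localities", "write_localities", "validate_localities"]


def validate_localities(
    table: pd.DataFrame, labels: tuple[str, ...] = ("N", "C", "S")
) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"locality table missing column(s) {missing}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    bad = set(table["population"]) - set(labels)
    if bad:
        raise ValueError(f"unknown population label(s) {sorted(bad)}; expected {labels}")
    return table


def read_localities(path: str | Path, labels=("N", "C", "S")) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"sample_id": str, "population": str})
    return validate_localities(table, labels)


def write_localities(table: pd.DataFrame, path: str | Path) -> None:
    validate_localities(table, tuple(sorted(set(table["population"]))))
    table.to_csv(path, index=False)
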