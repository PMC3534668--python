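"""Domain types and table I/O for study–cell-line usage corpora.

The empirical unit of analysis is a usage edge: one published study that
experimentally used one named cell line.  A corpus is a *usage table*, a
:class:`pandas.DataFrame` with one row per (study, line) edge plus study-level
metadata, and a companion *line-metadata table* with one row per line.

Cell-line names in the literature include secondary sub-lines (H9.1, H9.2,
H1-OGN, ...).  These are collapsed onto their parental line via an explicit
:class:`AliasMap`; no suffix heuristics are applied, because published
sub-line names are too irregular for any safe pattern.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a usage table, in canonical order.
USAGE_COLUMNS = ["study_id", "line_id", "pub_year", "country", "funders", "cell_class"]

#: Required columns of a line-metadata table.
META_COLUMNS = [
    "line_id",
    "first_pub_year",
    "derivation_year",
    "formerly_approved",
    "provenance_lab",
]

#: Year bounds of the emulated corpus (first hESC report through end of survey).
DEFAULT_YEAR_RANGE = (1998, 2011)


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class AliasMap:
    """Mapping from sub-line names to parental (canonical) line names.

    The map is made idempotent on construction: every canonical target maps
    to itself, and chained entries (A→B while B→C) are rejected.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        mapping = dict(mapping or {})
        for alias, parent in mapping.items():
            target = mapping.get(parent, parent)
            if target != parent:
                raise ValueError(
                    f"alias map is not idempotent: {alias!r} -> {parent!r} -> {target!r}"
                )
        self._map = mapping

    def canonical(self, name: str) -> str:
        return self._map.get(name, name)

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AliasMap) and self._map == other._map

    def apply(self, names: Iterable[str]) -> list[str]:
        return [self.canonical(n) for n in names]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasMap":
        """Read a two-column (alias, parent) TSV without header."""
        df = pd.read_csv(path, sep="\t", header=None, names=["alias", "parent"], dtype=str)
        return cls(dict(zip(df["alias"], df["parent"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self._map.items()), columns=["alias", "parent"]).to_csv(
            path, sep="\t", header=False, index=False
        )


def read_alias_map(path: str | Path) -> AliasMap:
    return AliasMap.from_tsv(path)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def _coerce_year(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    years = pd.to_numeric(df[column], errors="coerce")
    bad = years.isna() & df[column].notna()
    if bad.any():
        idx = int(bad.idxmax())
        raise SchemaError(
            f"{what}: non-numeric {column} at row {idx}: {df[column].iloc[idx]!r}"
        )
    return years.astype("Int64")


def canonicalize_usage_table(
    table: pd.DataFrame, alias_map: AliasMap | None = None
) -> pd.DataFrame:
    """Collapse sub-line names and merge the resulting duplicate edges.

    Returns a new DataFrame; the input is never modified.  Duplicate
    (study_id, line_id) rows created by the collapse carry identical study
    metadata by construction, so the first row of each group is kept.
    """
    alias_map = alias_map or AliasMap()
    out = table.copy()
    out["line_id"] = alias_map.apply(out["line_id"])
    before = len(out)
    out = out.drop_duplicates(subset=["study_id", "line_id"], keep="first")
    merged = before - len(out)
    if merged:
        logger.info("canonicalization merged %d duplicate edge(s)", merged)
    return out.reset_index(drop=True)


def validate_usage_table(
    table: pd.DataFrame, year_range: tuple[int, int] = DEFAULT_YEAR_RANGE
) -> None:
    """Raise :class:`SchemaError` if the table violates its invariants."""
    _require_columns(table, USAGE_COLUMNS, "usage table")
    dup = table.duplicated(subset=["study_id", "line_id"])
    if dup.any():
        raise SchemaError(
            f"duplicate (study_id, line_id) pairs, first at row {int(dup.idxmax())}"
        )
    if len(table):
        lo, hi = year_range
        years = table["pub_year"]
        out_of_range = (years < lo) | (years > hi)
        if out_of_range.any():
            idx = int(out_of_range.idxmax())
            raise SchemaError(
                f"pub_year {years.iloc[idx]} outside [{lo}, {hi}] at row {idx}"
            )


def read_usage_table(
    path: str | Path,
    alias_map: AliasMap | None = None,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> pd.DataFrame:
    """Read, canonicalize and validate a usage-table TSV.

    The ``funders`` column holds semicolon-separated tags (a study may carry
    several, e.g. both CIRM and NIH).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, USAGE_COLUMNS, "usage table")
    df["pub_year"] = _coerce_year(df, "pub_year", "usage table")
    logger.info("read %d usage rows from %s", len(df), path)
    df = canonicalize_usage_table(df, alias_map)
    validate_usage_table(df, year_range)
    return df


def read_line_metadata(path: str | Path, alias_map: AliasMap | None = None) -> pd.DataFrame:
    """Read a line-metadata TSV (one row per canonical line)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, META_COLUMNS, "line metadata")
    for col in ("first_pub_year", "derivation_year"):
        df[col] = _coerce_year(df, col, "line metadata")
    flag = df["formerly_approved"].astype(str).str.lower()
    bad = ~flag.isin(["0", "1", "true", "false"])
    if bad.any():
        idx = int(bad.idxmax())
        raise SchemaError(
            f"line metadata: formerly_approved must be 0/1, got "
            f"{df['formerly_approved'].iloc[idx]!r} at row {idx}"
        )
    df["formerly_approved"] = flag.isin(["1", "true"])
    if alias_map is not None:
        df = df.copy()
        df["line_id"] = alias_map.apply(df["line_id"])
        df = df.drop_duplicates(subset=["line_id"], keep="first").reset_index(drop=True)
    return df


def write_usage_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.to_csv(path, sep="\t", index=False)


def write_line_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    """Write line metadata with the 0/1 convention for formerly_approved."""
    out = meta.copy()
    out["formerly_approved"] = out["formerly_approved"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def has_funder(table: pd.DataFrame, tag: str) -> pd.Series:
    """Boolean mask: rows whose study carries the given funder tag."""
    return table["funders"].map(lambda s: tag in str(s).split(";"))


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):  # numpy scalars and arrays
        return obj.tolist()
    return obj


def write_results(obj: Any, path: str | Path) -> None:
    """Serialize a result to disk: DataFrames as TSV, everything else as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    else:
        with open(path, "w") as fh:
            json.dump(_to_jsonable(obj), fh, indent=2, sort_keys=True)
            fh.write("\n")
    logger.info("wrote %s", path)


def read_results(path: str | Path) -> Any:
    path = Path(path)
    if path.suffix in (".tsv", ".txt"):
        return pd.read_csv(path, sep="\t")
    with open(path) as fh:
        return json.load(fh)
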