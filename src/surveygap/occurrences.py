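"""Reading, cleaning, thinning, and gridding of occurrence records.

The cleaning rules follow standard specimen-database practice: flagged
records (cultivated, introduced, invasive, artificial) are removed,
infraspecific names are collapsed to the parent binomial, and exact
duplicates are dropped. Spatial thinning keeps at most one record per
species per thinning-grid cell, countering the clustering of collection
localities before distribution modelling.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSystem

__all__ = [
    "read_occurrences",
    "write_occurrences",
    "clean_records",
    "thin_records",
    "assign_to_grid",
    "BAD_FLAGS",
]

logger = logging.getLogger(__name__)

BAD_FLAGS = frozenset({"cultivated", "introduced", "invasive", "artificial"})

#: infraspecific rank markers whose token (and everything after) is stripped
_INFRA_MARKERS = {"var.", "subsp.", "ssp.", "f.", "var", "subsp", "ssp"}

_COLUMN_SYNONYMS = {
    "species": {"species", "taxon", "scientificname", "scientific_name", "name"},
    "lon": {"lon", "longitude", "long", "x", "decimallongitude"},
    "lat": {"lat", "latitude", "y", "decimallatitude"},
}


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, str] = {}
    for canon, synonyms in _COLUMN_SYNONYMS.items():
        for syn in synonyms:
            if syn in lower:
                resolved[canon] = lower[syn]
                break
        else:
            raise ValueError(f"occurrence file is missing a '{canon}' column "
                             f"(accepted headers: {sorted(synonyms)})")
    return resolved


def read_occurrences(path: str | Path, dialect: str = "csv") -> pd.DataFrame:
    """Read an occurrence table from CSV or TSV.

    Header names are matched case-insensitively against common synonyms
    (longitude/latitude/x/y ...). Rows with unparseable coordinates are
    dropped with a warning; the kept/dropped counts are logged. The result
    has columns species, lon, lat, flags, source.
    """
    if dialect not in {"csv", "tsv"}:
        raise ValueError("dialect must be 'csv' or 'tsv'")
    sep = "," if dialect == "csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(raw.columns))
    df = pd.DataFrame({
        "species": raw[cols["species"]].str.strip(),
        "lon": pd.to_numeric(raw[cols["lon"]], errors="coerce"),
        "lat": pd.to_numeric(raw[cols["lat"]], errors="coerce"),
    })
    lower = {c.lower().strip(): c for c in raw.columns}
    df["flags"] = raw[lower["flags"]].str.strip().str.lower() if "flags" in lower else ""
    df["source"] = raw[lower["source"]].str.strip() if "source" in lower else ""
    bad = df["lon"].isna() | df["lat"].isna() | ~np.isfinite(df["lon"].fillna(np.nan)) \
        | ~np.isfinite(df["lat"].fillna(np.nan))
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} record(s) with unparseable coordinates", stacklevel=2)
    df = df.loc[~bad].reset_index(drop=True)
    logger.info("read %d records (%d dropped) from %s", len(df), n_bad, path)
    return df


def write_occurrences(df: pd.DataFrame, path: str | Path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def _collapse_infraspecific(name: str) -> str:
    """Strip infraspecific rank tokens: 'Carex muliensis var. alpina' -> 'Carex muliensis'."""
    tokens = re.split(r"\s+", name.strip())
    for i, tok in enumerate(tokens):
        if i >= 2 and tok.lower() in _INFRA_MARKERS:
            return " ".join(tokens[:i])
    return " ".join(tokens)


def _flag_set(value: object) -> set[str]:
    if not isinstance(value, str) or not value.strip():
        return set()
    return {f.strip().lower() for f in re.split(r"[;,|]", value) if f.strip()}


def clean_records(df: pd.DataFrame, report: dict | None = None) -> pd.DataFrame:
    """Apply the record-cleaning rules; idempotent.

    1. remove records carrying any of the flags cultivated / introduced /
       invasive / artificial,
    2. collapse infraspecific names to the species binomial,
    3. drop records with an empty species name,
    4. collapse exact (species, lon, lat) duplicates to one record
       (first occurrence kept, stable order).

    If ``report`` (a dict) is supplied, per-rule removal counts are written
    into it.
    """
    n0 = len(df)
    flags = df.get("flags", pd.Series([""] * n0, index=df.index))
    flagged = flags.map(lambda v: bool(_flag_set(v) & BAD_FLAGS))
    out = df.loc[~flagged].copy()
    n_flagged = n0 - len(out)

    out["species"] = out["species"].map(_collapse_infraspecific)
    empty = out["species"].str.len() == 0
    n_empty = int(empty.sum())
    out = out.loc[~empty]

    before = len(out)
    out = out.drop_duplicates(subset=["species", "lon", "lat"], keep="first")
    n_dupes = before - len(out)

    if report is not None:
        report.update({
            "input": n0, "removed_flagged": n_flagged,
            "removed_empty_name": n_empty, "removed_duplicates": n_dupes,
            "kept": len(out),
        })
    if len(out) == 0:
        warnings.warn("cleaning removed every record", stacklevel=2)
    logger.info("cleaned %d -> %d records (%d flagged, %d dupes)", n0, len(out), n_flagged, n_dupes)
    return out.reset_index(drop=True)


def thin_records(df: pd.DataFrame, thin_grid: GridSystem) -> pd.DataFrame:
    """Keep at most one record per species per thinning-grid cell.

    The retained record is the first in stable input order. Records falling
    outside the thinning grid are dropped with a warning.
    """
    rows, cols, inside = thin_grid.assign(df["lon"].to_numpy(), df["lat"].to_numpy())
    if not inside.all():
        warnings.warn(f"dropped {int((~inside).sum())} record(s) outside the thinning grid",
                      stacklevel=2)
    out = df.loc[inside].copy()
    out["_cell"] = thin_grid.flat_index(rows[inside], cols[inside])
    out = out.drop_duplicates(subset=["species", "_cell"], keep="first")
    return out.drop(columns="_cell").reset_index(drop=True)


def assign_to_grid(df: pd.DataFrame, grid: GridSystem) -> dict[str, set[tuple[int, int]]]:
    """Map each species to the set of analysis-grid cells it was recorded in.

    Cells are half-open, so a point exactly on a shared boundary belongs to
    the cell on its right/top side; points outside the grid are dropped with
    a warning.
    """
    rows, cols, inside = grid.assign(df["lon"].to_numpy(), df["lat"].to_numpy())
    if not inside.all():
        warnings.warn(f"dropped {int((~inside).sum())} record(s) outside the analysis grid",
                      stacklevel=2)
    occ: dict[str, set[tuple[int, int]]] = {}
    species = df["species"].to_numpy()
    for sp, r, c, ok in zip(species, rows, cols, inside):
        if ok:
            occ.setdefault(sp, set()).add((int(r), int(c)))
    return occ
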