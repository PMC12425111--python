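"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression and count matrices are TSV with genes as rows and a header of
sample ids. Clinical tables are TSV keyed by ``sample_id``. Gene sets use the
GMT convention (name, description, tab-separated members). Protein
interactions use a STRING-style TSV with columns ``node1``, ``node2``,
``combined_score``.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from .exceptions import DataError

log = logging.getLogger(__name__)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV (first column = gene ids).

    Duplicate gene ids are collapsed by mean, with a logged count — gene
    matching downstream is by (case-sensitive) symbol.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        log.warning("collapsing %d duplicate gene ids by mean", n_dup)
        df = df.groupby(level=0).mean()
    return df


def write_expression(df: pd.DataFrame, path: str | Path, *, float_format: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table; empty fields become NaN, sample_id is the index."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError(f"clinical table {path} lacks a 'sample_id' column")
    return df.set_index("sample_id")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set_name: member set}``.

    Each line is name, description, then >=1 tab-separated members. Duplicate
    members within a line are deduplicated with a warning; empty sets are
    rejected; a fully empty file yields an empty collection with a warning.
    """
    sets: dict[str, set[str]] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}: malformed GMT line {i}: expected name, description, members")
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise DataError(f"{path}: GMT line {i} ({name!r}) has no members")
        unique = set(members)
        if len(unique) < len(members):
            warnings.warn(f"GMT set {name!r}: {len(members) - len(unique)} duplicate members removed")
        sets[name] = unique
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets")
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-style edge list (node1, node2, combined_score)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"node1", "node2", "combined_score"} - set(df.columns)
    if missing:
        raise DataError(f"edge file {path} lacks columns: {sorted(missing)}")
    return df


def write_edges(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
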