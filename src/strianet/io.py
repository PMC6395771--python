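"""Readers and writers for the package's text formats.

Counts and metadata travel as tab-separated tables, gene sets as GMT.
Round trips are exact for integer counts and good to 1e-12 for reals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
]

REQUIRED_METADATA_COLUMNS = ("group",)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV (first column = gene id,
    header row = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if df.isna().any().any():
        bad = df.isna().any(axis=1)
        lines = [int(i) + 2 for i in range(len(df)) if bad.iloc[i]][:5]
        raise ValueError(f"ragged/missing values in {path} near line(s) {lines}")
    try:
        df = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer counts in {path}: {exc}") from exc
    if (df < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sample metadata TSV indexed by ``sample_id``; when a count matrix is
    given, every counted sample must have metadata."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata {path} missing column(s): {missing_cols}")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if counts is not None:
        absent = [s for s in counts.columns if s not in df.index]
        if absent:
            raise ValueError(f"metadata {path} missing counted sample(s): {absent}")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: per line, set name, description, then gene ids,
    tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description "
                                 "and at least one gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str] | set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(map(str, genes))]) + "\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.12g", **kwargs)
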