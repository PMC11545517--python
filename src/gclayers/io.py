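"""Reading and writing the pipeline's plain-text formats.

Expression matrices travel as TSV (first column = gene id, header row of
sample ids, missing values as empty fields or "NA"); clinical tables as
TSV with ``sample_id``, ``os_months``, ``event`` and an optional
``subtype`` column; gene-annotation sets as standard GMT.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
]

_NA_VALUES = ["", "NA"]


class FormatError(ValueError):
    """Malformed input file."""


def read_expression(path) -> ExpressionMatrix:
    """Parse a genes × samples TSV into an :class:`ExpressionMatrix`.

    Raises :class:`FormatError` naming the offending line for duplicate
    gene/sample ids or ragged rows.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
            raise FormatError(f"{path}: duplicate sample id {dup!r} in header")
        seen: dict[str, int] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncol} fields, got {len(fields)}"
                )
            gid = fields[0]
            if gid in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate gene id {gid!r} "
                    f"(first seen on line {seen[gid]})"
                )
            seen[gid] = lineno
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES,
        keep_default_na=False, float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV; empty subtype fields mean "unlabeled"."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    required = {"sample_id", "os_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing clinical columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["os_months"] = df["os_months"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into name → member gene list.

    Duplicate members within a set are collapsed with a warning; sets
    with no members are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f for f in fields[2:]):
                log.warning("%s:%d: gene set %r has no members; skipped",
                            path, lineno, fields[0])
                continue
            name = fields[0]
            members: list[str] = []
            for g in fields[2:]:
                if not g:
                    continue
                if g in members:
                    log.warning("%s:%d: duplicate member %r in set %r",
                                path, lineno, g, name)
                    continue
                members.append(g)
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
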