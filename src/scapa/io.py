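"""Readers and writers for the pipeline's plain-text interchange files.

Everything is tab-separated UTF-8 with Unix newlines and no quoting, so a
write/read cycle is bit-exact.  Missing APA entries are encoded as empty
fields and come back as missing.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import APAMatrix, CellAnnotation, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_parent_table",
    "write_parent_table",
    "read_annotation",
    "write_annotation",
    "read_survival_table",
    "write_survival_table",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending row/column."""


def _read_tsv_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pandas raises several flavours
        raise ParseError(f"{path}: cannot parse TSV matrix ({exc})") from exc
    if df.index.name is None and df.shape[1] == 0:
        raise ParseError(f"{path}: malformed header")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric entry ({exc})") from exc
    return df


def read_matrix(path, kind: str):
    """Read a gene x cell matrix.

    ``kind`` is ``"dapars"`` or ``"roar"`` for an :class:`APAMatrix`
    (empty fields allowed, range-checked per dialect) or ``"expression"``
    for a complete non-negative TPM :class:`ExpressionMatrix`.
    """
    df = _read_tsv_matrix(path)
    try:
        if kind == "expression":
            return ExpressionMatrix(df)
        return APAMatrix(df, dialect=kind)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(matrix, path) -> None:
    """Write an APA/expression/enrichment matrix as TSV (NaN -> empty)."""
    df = matrix.data if hasattr(matrix, "data") else matrix
    df.to_csv(path, sep="\t", na_rep="", lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in the MSigDB GMT dialect.

    Each line: set id, description, then one or more member genes.
    Duplicate members inside a line are collapsed with a logged warning;
    an empty file yields an empty collection.
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m != ""]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if len(set(members)) != len(members):
                logger.warning(
                    "%s:%d: duplicate member genes in set %s collapsed",
                    path, lineno, name,
                )
            try:
                coll.add(name, members, desc)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sets:
            fh.write("\t".join([name, sets.description(name), *sets[name]]) + "\n")


def read_parent_table(path) -> dict[str, set[str]]:
    """Read a two-column term -> parent-term TSV into a dict of sets.

    Terms absent from the table simply have no entry; lookups should use
    ``table.get(term, set())`` (the empty-set convention makes the Jaccard
    of an unlisted term 0 against everything).
    """
    parents: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected 'term<TAB>parent'"
                )
            parents.setdefault(fields[0], set()).add(fields[1])
    return parents


def write_parent_table(parents: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(parents):
            for parent in sorted(parents[term]):
                fh.write(f"{term}\t{parent}\n")


def read_annotation(path) -> CellAnnotation:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse annotation ({exc})") from exc
    try:
        return CellAnnotation(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_annotation(annotation: CellAnnotation, path) -> None:
    tbl = annotation.table.copy()
    tbl.index.name = "cell"
    tbl.to_csv(path, sep="\t", na_rep="", lineterminator="\n")


def read_survival_table(path) -> pd.DataFrame:
    """Read a patient survival table (patient id index; ``time`` in years,
    ``event`` 0/1, remaining columns covariates)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse survival table ({exc})") from exc
    for col in ("time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: survival table lacks column {col!r}")
    if (df["time"] < 0).any():
        bad = df.index[df["time"] < 0][0]
        raise ParseError(f"{path}: negative time for patient {bad!r}")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event flags must be 0/1")
    return df


def write_survival_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "patient"
    out.to_csv(path, sep="\t", na_rep="", lineterminator="\n")


def write_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
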