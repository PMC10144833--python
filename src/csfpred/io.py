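"""Readers and writers: FASTA, TSV tables, label lists, group and mapping files.

TSV is the canonical table dialect (tab-separated, dot decimals, UTF-8, Unix
newlines); missing feature values are written as empty cells. Label files hold
one protein id per line.
"""

from __future__ import annotations

import logging
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO

from .sequence_features import FeatureMatrix, ProteinRecord, sanitize_sequence

logger = logging.getLogger(__name__)


def read_fasta(path, policy: str = "strip") -> list:
    """Read a multi-record FASTA file into sanitized :class:`ProteinRecord`s.

    Wrapped sequence lines are joined; the id is the first whitespace token of
    the header. Sequence data before the first header or duplicate ids raise.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: sequence data before first header")
            break
    else:
        logger.warning("%s: empty FASTA file", path)
        return []
    records = []
    seen = set()
    for rec in SeqIO.parse(StringIO("\n".join(lines)), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq), policy)))
    return records


def write_fasta(records: list, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a feature TSV (first column protein id, empty cells = missing)."""
    df = read_table(path)
    return FeatureMatrix.from_frame(df)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", na_rep="")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    """Generic TSV reader with ragged-row detection (row number reported)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty table")
    width = len(lines[0].split("\t"))
    for rowno, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != width:
            raise ValueError(f"{path}:{rowno}: ragged row "
                             f"({len(line.split(chr(9)))} fields, expected {width})")
    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=index_col)
    df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="")


def read_labels(path) -> list:
    """One protein id per line; blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_labels(ids: list, path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_groups(path) -> pd.Series:
    """Two-column TSV sample -> group label ('case' / 'control')."""
    df = read_table(path, index_col=0)
    return df.iloc[:, 0].astype(str)


def read_mapping(path) -> pd.DataFrame:
    """Two-column gene -> protein TSV (header row required)."""
    df = read_table(path, index_col=None)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: mapping must have exactly two columns")
    return df.astype(str)


def numeric_matrix(matrix: FeatureMatrix) -> np.ndarray:
    return matrix.values
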