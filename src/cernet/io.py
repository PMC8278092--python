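"""Readers and writers for the plain-text formats the pipeline speaks.

TSV dialect: tab-separated, header row, UTF-8, '.' decimal, no quoting.
Expression tables have feature ids in the first column and sample ids in
the header.  FASTA via Biopython, GMT as set_id <TAB> description <TAB>
gene...  All parse failures raise :class:`~cernet.errors.ParseError` with
the offending id or line number.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import GeneSet
from .errors import ParseError


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a features x samples numeric TSV (first column = feature ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # tokenizer errors carry the line number
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated feature id {dup!r}")
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        col = bad[0]
        nonnum = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        line = df.index.get_loc(nonnum.index[0]) + 2 if len(nonnum) else "?"
        raise ParseError(f"{path}: non-numeric value in column {col!r} "
                         f"(line {line})")
    if df.isna().any().any():
        feat = df.index[df.isna().any(axis=1)][0]
        line = df.index.get_loc(feat) + 2
        raise ParseError(f"{path}: missing value in row {feat!r} (line {line})")
    df.index.name = None
    df.columns.name = None
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.rename_axis("feature_id").to_csv(path, sep="\t")


def read_fasta(path) -> dict:
    """FASTA file -> {record id: sequence string}; duplicate ids raise."""
    path = Path(path)
    seqs = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ParseError(f"{path}: duplicated record id {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return seqs


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(seqs[k]), id=k, description="")
               for k in sorted(seqs)]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> list:
    """GMT file -> list of :class:`GeneSet` (line order preserved)."""
    path = Path(path)
    sets, seen = [], set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT line needs "
                                 "set id, description and >=1 gene")
            set_id, desc, genes = parts[0], parts[1], parts[2:]
            if set_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicated set id "
                                 f"{set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id, desc, frozenset(g for g in genes if g)))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, gs.description]
                               + sorted(gs.genes)) + "\n")


def read_whitelist(path) -> pd.DataFrame:
    """Interaction whitelist TSV with columns mirna_id, target_id, source."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"mirna_id", "target_id"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: whitelist needs columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = "unspecified"
    return df[["mirna_id", "target_id", "source"]]


def read_series_tsv(path, value_column: str) -> pd.Series:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if value_column not in df.columns:
        raise ParseError(f"{path}: expected a {value_column!r} column")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated id {dup!r}")
    return df[value_column]
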