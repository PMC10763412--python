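"""Readers and writers for the package's plain-text formats.

FASTA carries UTR sequences; a companion record convention ``<id>|orf``
(or a second file) supplies ORF prefixes.  Tables are TSV: tab-delimited,
'.' decimal, UTF-8, Unix newlines.  The dataset table schema is
``id, <15 feature columns>, abundance`` (column order free, matched by
header).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import GeneExpression
from .features import FEATURE_NAMES
from .model import Dataset
from .sequences import UtrSequence

ORF_SUFFIX = "|orf"


def read_fasta(path: str | Path, orf_path: str | Path | None = None) -> list[UtrSequence]:
    """Read UTRs (plus optional ORF prefixes) from FASTA.

    ORF prefixes come either from records named ``<id>|orf`` in the same
    file or from a second file matched by record id.  Duplicate ids are an
    error.  Sequences are normalised (upper case, U -> T).
    """
    utrs: dict[str, str] = {}
    orfs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        target = orfs if name.endswith(ORF_SUFFIX) else utrs
        key = name[: -len(ORF_SUFFIX)] if name.endswith(ORF_SUFFIX) else name
        if key in target:
            raise ValueError(f"duplicate record id {name!r} in {path}")
        target[key] = str(rec.seq)
    if orf_path is not None:
        for rec in SeqIO.parse(str(orf_path), "fasta"):
            if rec.id in orfs:
                raise ValueError(f"duplicate ORF record id {rec.id!r}")
            orfs[rec.id] = str(rec.seq)
    unmatched = set(orfs) - set(utrs)
    if unmatched:
        raise ValueError(f"ORF records without a UTR: {sorted(unmatched)}")
    return [UtrSequence(k, s, orfs.get(k, "")) for k, s in utrs.items()]


def write_fasta(utrs: list[UtrSequence], path: str | Path, width: int = 80) -> None:
    """Write UTRs (and any non-empty ORF prefixes as ``<id>|orf`` records)."""
    records = []
    for u in utrs:
        records.append(SeqRecord(Seq(u.seq), id=u.id, description=""))
    for u in utrs:
        if u.orf_prefix:
            records.append(
                SeqRecord(Seq(u.orf_prefix), id=u.id + ORF_SUFFIX, description="")
            )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_dataset_tsv(path: str | Path) -> Dataset:
    """Typed dataset from TSV; header-matched columns, no missing values."""
    df = pd.read_csv(path, sep="\t")
    required = ["id", *FEATURE_NAMES, "abundance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    na = df[required].isna()
    if na.any().any():
        row = int(na.any(axis=1).idxmax())
        col = na.columns[na.loc[row].to_numpy().argmax()]
        raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
    return Dataset.from_dataframe(df)


def write_dataset_tsv(dataset: Dataset, path: str | Path) -> None:
    dataset.to_dataframe().to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> list[GeneExpression]:
    """Expression table: columns gene_id and at least one of tpm / empai."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    if "tpm" not in df.columns and "empai" not in df.columns:
        raise ValueError(f"{path}: need a tpm and/or empai column")
    out = []
    for _, row in df.iterrows():
        tpm = float(row["tpm"]) if "tpm" in df.columns and pd.notna(row["tpm"]) else None
        empai = (
            float(row["empai"])
            if "empai" in df.columns and pd.notna(row["empai"])
            else None
        )
        out.append(GeneExpression(str(row["gene_id"]), tpm=tpm, empai=empai))
    return out


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
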