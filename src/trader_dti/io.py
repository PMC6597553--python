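"""Readers and writers for the pipeline's plain-text formats.

Fingerprint tables and similarity matrices travel as TSV with the first
column/row holding identifiers; interactions as two-column TSV
(drug_id, target_id); target sequences as FASTA.  Floats are written with
17 significant digits, so matrices round-trip losslessly.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .similarity import FingerprintTable, SimilarityMatrix

__all__ = [
    "read_fingerprints",
    "write_fingerprints",
    "read_similarity",
    "write_similarity",
    "read_interactions",
    "write_interactions",
    "read_fasta",
    "write_fasta",
]


def read_fingerprints(path) -> FingerprintTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return FingerprintTable.from_frame(df)


def write_fingerprints(table: FingerprintTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_similarity(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return SimilarityMatrix.from_frame(df)


def write_similarity(sm: SimilarityMatrix, path) -> None:
    sm.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_interactions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"drug_id", "target_id"}
    if not expected.issubset(df.columns):
        raise ValueError(f"interaction table must have columns {sorted(expected)}")
    return df[["drug_id", "target_id"]]


def write_interactions(pairs, path) -> None:
    df = pd.DataFrame(list(pairs), columns=["drug_id", "target_id"])
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=str(tid), description="") for tid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
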