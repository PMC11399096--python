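"""Readers/writers for the plain-text formats the pipeline exchanges.

Fragments files are tab-separated with a header line and the columns
``chrom  start  end  cell  modality  duplicate_count`` (0-based half-open
coordinates), sorted by (chrom, start, end).  Truth and report tables are
plain TSV with headers.  Sparse matrices travel as a MatrixMarket triplet:
``<prefix>.mtx`` (regions as columns), ``<prefix>.regions.bed`` and
``<prefix>.cells.tsv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FRAGMENT_COLS = ["chrom", "start", "end", "cell", "modality", "duplicate_count"]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df.columns = ["chrom", "start", "end"]
    return df


def write_fragments(records: pd.DataFrame, path) -> None:
    """Sorted fragments TSV (header line included; empty input yields a valid
    header-only file)."""
    missing = [c for c in FRAGMENT_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"fragments frame missing columns {missing}")
    out = records[FRAGMENT_COLS].sort_values(
        ["chrom", "start", "end", "cell", "modality"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "cell": str, "modality": str, "duplicate_count": np.int64},
    )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_triplet(counts, cells, regions: pd.DataFrame, prefix) -> None:
    """MatrixMarket + sidecar BED/TSV export of a cells x regions matrix."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), scipy.sparse.coo_matrix(counts))
    write_bed(regions, prefix.parent / (prefix.name + ".regions.bed"))
    pd.DataFrame({"cell": list(cells)}).to_csv(
        prefix.parent / (prefix.name + ".cells.tsv"), sep="\t", index=False
    )


def read_matrix_triplet(prefix):
    prefix = Path(prefix)
    counts = scipy.sparse.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    regions = read_bed(prefix.parent / (prefix.name + ".regions.bed"))
    cells = pd.read_csv(prefix.parent / (prefix.name + ".cells.tsv"), sep="\t")["cell"].tolist()
    return counts, cells, regions
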