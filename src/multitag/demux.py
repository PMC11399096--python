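"""Demultiplexing: barcoded FASTQ + alignments -> per-cell fragment records.

The stages mirror standard single-cell tagmentation processing: call every
barcode segment of every read against its round whitelist (exact match first,
then Hamming-distance correction within the configured radius), build a cell
whitelist from per-key read counts, join alignments keeping uniquely mapped
reads (MAPQ strictly greater than the threshold), collapse PCR duplicates per
(cell, modality, interval), and drop shallow cells.

Coordinates are 0-based half-open everywhere.  The deduplication key excludes
strand by default — Tn5 fragments are interval-defined — but strand-aware
deduplication is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .barcodes import BarcodeScheme, correct_barcode

__all__ = [
    "parse_reads",
    "build_whitelist",
    "join_alignments",
    "deduplicate",
    "filter_cells",
    "load_alignments_tsv",
    "load_alignments_sam",
    "run_demux",
]

UNASSIGNED_REASONS = ("length", "no_match", "ambiguous")


def parse_reads(
    r1_path,
    scheme: BarcodeScheme,
    radius: int | None = None,
    r2_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call every barcode segment of every read.

    Returns ``(calls, report)``.  ``calls`` has one row per read: ``read``,
    ``cell`` (the joined cell key, or NA unless every cell-role round called),
    ``modality`` (label, or NA), and ``fail_<round>`` reason columns for
    uncalled rounds.  ``report`` tabulates call/discard counts per round and
    reason.

    Both mates are accepted; only the mate(s) carrying barcode segments are
    read.  Reads shorter than the layout yield ``length`` failures for the
    truncated segments rather than aborting the run.
    """
    if radius is None:
        radius = scheme.correction_radius
    seg_specs = []
    for seg in sorted(scheme.layout, key=lambda s: (s.read, s.offset)):
        if seg.kind in ("linker", "genomic"):
            continue
        rnd = scheme.round_by_name(seg.kind)
        exact = {s: i for i, s in enumerate(rnd.sequences)}
        seg_specs.append((seg, rnd, exact))
    reads_needed = {seg.read for seg, _, _ in seg_specs}
    if "R2" in reads_needed and r2_path is None:
        raise ValueError("layout places barcodes on R2 but no R2 file given")

    names: list[str] = []
    seqs_by_read: dict[str, list[str]] = {}
    for mate, path in (("R1", r1_path), ("R2", r2_path)):
        if mate not in reads_needed:
            continue
        mate_names: list[str] = []
        seq_list: list[str] = []
        with pysam.FastxFile(str(path)) as fh:
            for i, rec in enumerate(fh):
                if rec.sequence is None:
                    raise ValueError(f"malformed FASTQ record {i} in {path}")
                mate_names.append(rec.name)
                seq_list.append(rec.sequence)
        seqs_by_read[mate] = seq_list
        if not names:
            names = mate_names
        elif len(mate_names) != len(names):
            raise ValueError("mate files differ in record count")

    n = len(names)
    round_names = [rnd.name for _, rnd, _ in seg_specs]
    idx_cols = {name: np.full(n, -1, dtype=np.int64) for name in round_names}
    reason_cols = {name: np.zeros(n, dtype="U9") for name in round_names}
    report_counts: dict[tuple[str, str], int] = {}

    for seg, rnd, exact in seg_specs:
        rsn = reason_cols[rnd.name]
        seq_list = seqs_by_read[seg.read]
        a, b = seg.offset, seg.end
        # exact-match fast path; only misses take the Hamming scan
        col = np.fromiter(
            (exact.get(s[a:b], -1) for s in seq_list), dtype=np.int64, count=n
        )
        for i in np.flatnonzero(col < 0):
            idx, reason = correct_barcode(seq_list[i][a:b], rnd, radius)
            if idx is not None:
                col[i] = idx
            else:
                rsn[i] = reason
        idx_cols[rnd.name] = col
        ok = int((col >= 0).sum())
        report_counts[(rnd.name, "called")] = ok
        for reason in UNASSIGNED_REASONS:
            cnt = int((rsn == reason).sum())
            if cnt:
                report_counts[(rnd.name, reason)] = cnt

    cell_round_names = [r.name for r in scheme.cell_rounds]
    cell_ok = np.ones(n, dtype=bool)
    for name in cell_round_names:
        cell_ok &= idx_cols[name] >= 0
    key = idx_cols[cell_round_names[0]].astype(str).astype(object)
    for name in cell_round_names[1:]:
        key = key + "-" + idx_cols[name].astype(str).astype(object)
    mod_name = scheme.modality_round.name
    mod_ok = idx_cols[mod_name] >= 0
    labels = np.array(
        [scheme.modality_label(i) for i in range(scheme.modality_round.size)],
        dtype=object,
    )
    calls = pd.DataFrame({"read": names})
    calls["cell"] = pd.array(np.where(cell_ok, key, None), dtype=object)
    calls["modality"] = pd.array(
        np.where(mod_ok, labels[np.maximum(idx_cols[mod_name], 0)], None), dtype=object
    )
    for name in round_names:
        calls[f"fail_{name}"] = reason_cols[name]
    report_counts[("all", "fully_called")] = int((cell_ok & mod_ok).sum())
    report_counts[("all", "total")] = n
    report = pd.DataFrame(
        [(rnd, reason, cnt) for (rnd, reason), cnt in sorted(report_counts.items())],
        columns=["round", "category", "count"],
    )
    return calls, report


def build_whitelist(
    counts: pd.Series | dict, method: str = "knee", n: int | None = None
) -> set[str]:
    """Cell whitelist from per-cell-key read counts.

    ``top_n`` keeps the ``n`` highest-count keys (ties broken lexicographically
    by key, so the output is deterministic and nested in n).  ``knee`` keeps
    keys ranked at or above the inflection of the log-log rank/count curve —
    the steepest point of the cliff separating real cells from barcode noise,
    located on a lightly smoothed uniform resampling of the curve.
    """
    s = pd.Series(counts)
    if s.empty:
        raise ValueError("empty count table")
    order = s.sort_values(ascending=False, kind="mergesort")
    order = order.iloc[np.lexsort((order.index.astype(str), -order.to_numpy()))]
    if method.startswith("top"):
        if n is None:
            raise ValueError("top_n method needs n")
        if n > len(order):
            import warnings

            warnings.warn(f"requested top {n} of {len(order)} keys; keeping all")
            n = len(order)
        return set(order.index[:n])
    if method != "knee":
        raise ValueError(f"unknown whitelist method {method!r}")
    if len(order) < 10:
        return set(order.index)
    x = np.log10(np.arange(1, len(order) + 1))
    y = np.log10(order.to_numpy().astype(float))
    grid = np.linspace(x[0], x[-1], 512)
    yi = np.interp(grid, x, y)
    w = 9
    ys = np.convolve(yi, np.ones(w) / w, mode="valid")
    slope = np.gradient(ys, grid[: len(ys)])
    # most negative smoothed slope = the cliff; margin avoids edge artefacts
    inner = slope[2:-2]
    cliff = int(np.argmin(inner)) + 2 + (w - 1) // 2
    cutoff_rank = max(int(np.floor(10 ** grid[min(cliff, len(grid) - 1)])), 1)
    return set(order.index[:cutoff_rank])


def load_alignments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"read", "chrom", "start", "end", "mapq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns {sorted(missing)}")
    return df


def load_alignments_sam(path) -> pd.DataFrame:
    """Fragment intervals from a (paired or single-end) SAM/BAM file: one row
    per read name, using the leftmost start and rightmost end across mates."""
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append(
                (rec.query_name, rec.reference_name, rec.reference_start,
                 rec.reference_end, rec.mapping_quality,
                 "-" if rec.is_reverse else "+")
            )
    df = pd.DataFrame(rows, columns=["read", "chrom", "start", "end", "mapq", "strand"])
    agg = df.groupby("read", sort=False).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"),
        mapq=("mapq", "min"), strand=("strand", "first"),
    )
    return agg.reset_index()


def join_alignments(
    calls: pd.DataFrame, alignments: pd.DataFrame, mapq_min: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach genomic intervals to fully-called reads.

    Keeps reads with both cell and modality calls and MAPQ strictly greater
    than ``mapq_min`` (a read at exactly the threshold is discarded).  Returns
    ``(raw_fragments, report)`` where raw fragments still contain duplicates.
    """
    called = calls[calls["cell"].notna() & calls["modality"].notna()]
    n_uncalled = len(calls) - len(called)
    merged = called.merge(alignments, on="read", how="left")
    unaligned = merged["chrom"].isna()
    low_mapq = (~unaligned) & (merged["mapq"] <= mapq_min)
    keep = merged[~unaligned & ~low_mapq]
    raw = keep[["read", "cell", "modality", "chrom", "start", "end"]].copy()
    raw["start"] = raw["start"].astype(np.int64)
    raw["end"] = raw["end"].astype(np.int64)
    report = pd.DataFrame(
        {
            "category": ["not_fully_called", "unaligned", "low_mapq", "kept"],
            "count": [n_uncalled, int(unaligned.sum()), int(low_mapq.sum()), len(raw)],
        }
    )
    return raw.reset_index(drop=True), report


def deduplicate(raw: pd.DataFrame, use_strand: bool = False) -> pd.DataFrame:
    """Collapse PCR duplicates: one record per distinct (cell, modality, chrom,
    start, end) with its multiplicity.  Idempotent: re-deduplicating sums the
    existing ``duplicate_count`` column when present."""
    key = ["cell", "modality", "chrom", "start", "end"]
    if use_strand and "strand" in raw.columns:
        key.append("strand")
    if raw.empty:
        return pd.DataFrame(columns=key + ["duplicate_count"])
    if "duplicate_count" in raw.columns:
        grouped = raw.groupby(key, sort=False)["duplicate_count"].sum()
    else:
        grouped = raw.groupby(key, sort=False).size()
    out = grouped.rename("duplicate_count").reset_index()
    return out.sort_values(["chrom", "start", "end", "cell", "modality"]).reset_index(
        drop=True
    )


def filter_cells(
    records: pd.DataFrame,
    min_unique: int = 400,
    whitelist: set[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Retain cells with strictly more than ``min_unique`` unique fragments,
    counted jointly across modalities, optionally intersected with a whitelist.

    Returns ``(retained cell keys, filtered records)``.
    """
    if records.empty:
        return [], records.copy()
    per_cell = records.groupby("cell", sort=False).size()
    keep = per_cell[per_cell > min_unique].index
    if whitelist is not None:
        keep = [c for c in keep if c in whitelist]
    keep_set = set(keep)
    return sorted(keep_set), records[records["cell"].isin(keep_set)].reset_index(drop=True)


def run_demux(
    r1_path,
    scheme: BarcodeScheme,
    alignments: pd.DataFrame,
    r2_path=None,
    radius: int | None = None,
    mapq_min: int = 30,
    min_unique: int = 0,
    whitelist_method: str | None = None,
    whitelist_n: int | None = None,
) -> dict:
    """Full demultiplexing pipeline; returns fragments plus per-stage reports.

    ``min_unique=0`` keeps every cell (useful for simulations where even
    shallow cells matter); pass 400 to reproduce the standard QC cut.  The
    whitelist, when requested, is built on cell keys pooled over modalities.
    """
    calls, parse_report = parse_reads(r1_path, scheme, radius, r2_path)
    raw, join_report = join_alignments(calls, alignments, mapq_min)
    records = deduplicate(raw)
    whitelist = None
    if whitelist_method is not None:
        counts = calls["cell"].dropna().value_counts()
        whitelist = build_whitelist(counts, whitelist_method, whitelist_n)
    cells_kept, records = filter_cells(records, min_unique, whitelist)
    return {
        "fragments": records,
        "cells": cells_kept,
        "parse_report": parse_report,
        "join_report": join_report,
        "whitelist": whitelist,
    }
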