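"""Interval sweep primitives shared by the QC and matrix layers.

All intervals are 0-based, half-open ``[start, end)``.  Region sets handed to
these helpers must be sorted and internally disjoint per chromosome (use
:func:`merge_intervals` first when in doubt); fragments need no ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome; returns sorted BED."""
    out = []
    for chrom, g in sort_intervals(df).groupby("chrom", sort=True):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLS)


def _per_chrom_arrays(regions: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """chrom -> (starts, ends, original row indices), sorted by start."""
    out = {}
    base = regions.reset_index(drop=True)
    for chrom, g in base.groupby("chrom", sort=False):
        g = g.sort_values("start")
        out[chrom] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g.index.to_numpy(),
        )
    return out


def overlaps_any(frags: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each fragment overlap (>=1 base) any region?

    Regions must be disjoint and sorted per chromosome.
    """
    hit = np.zeros(len(frags), dtype=bool)
    if regions.empty or frags.empty:
        return hit
    per_chrom = _per_chrom_arrays(regions)
    frags = frags.reset_index(drop=True)
    for chrom, g in frags.groupby("chrom", sort=False):
        arrs = per_chrom.get(chrom)
        if arrs is None:
            continue
        starts, ends, _ = arrs
        a = g["start"].to_numpy()
        b = g["end"].to_numpy()
        # first region whose end is beyond the fragment start; overlap iff it
        # also begins before the fragment end
        j = np.searchsorted(ends, a, side="right")
        ok = (j < len(starts)) & (starts[np.minimum(j, len(starts) - 1)] < b)
        hit[g.index.to_numpy()] = ok
    return hit


def region_hits(frags: pd.DataFrame, regions: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """All (fragment row, region row) overlap pairs, plus the count of
    fragments whose chromosome is absent from the region set.

    A fragment spanning several regions yields one pair per region.
    """
    if frags.empty or regions.empty:
        return np.empty(0, dtype=int), np.empty(0, dtype=int), 0
    per_chrom = _per_chrom_arrays(regions)
    frags = frags.reset_index(drop=True)
    f_idx, r_idx = [], []
    unknown = 0
    for chrom, g in frags.groupby("chrom", sort=False):
        arrs = per_chrom.get(chrom)
        if arrs is None:
            unknown += len(g)
            continue
        starts, ends, rows = arrs
        a = g["start"].to_numpy()
        b = g["end"].to_numpy()
        j0 = np.searchsorted(ends, a, side="right")
        j1 = np.searchsorted(starts, b, side="left")
        n = np.maximum(j1 - j0, 0)
        total = int(n.sum())
        if total == 0:
            continue
        frag_rows = np.repeat(g.index.to_numpy(), n)
        # enumerate j0..j1-1 per fragment
        offsets = np.concatenate([np.arange(k) for k in n if k > 0]) if total else np.empty(0, int)
        region_rows = rows[np.repeat(j0, n) + offsets]
        f_idx.append(frag_rows)
        r_idx.append(region_rows)
    if not f_idx:
        return np.empty(0, dtype=int), np.empty(0, dtype=int), unknown
    return np.concatenate(f_idx), np.concatenate(r_idx), unknown
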