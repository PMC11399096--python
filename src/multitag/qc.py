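"""Quality metrics: barnyard species mixing, FRiP, duplication, downsampling.

Species assignment works on deduplicated fragments (duplicates would bias the
per-cell species fractions), classifying a cell as a species only when
strictly more than 95% of its fragments map there; anything at or below the
threshold is a collision.  Note the observational unit after demultiplexing
is a *barcode* (cell key): two colliding cells are one barcode.  The analytic
collision expectation is a per-cell probability, so
:func:`estimate_cell_collision_rate` converts the observed barcode-level
mixed fraction to the cell scale using the standard barnyard correction for
undetected same-species merges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, overlaps_any, sort_intervals

__all__ = [
    "species_fractions",
    "species_mix_classify",
    "collision_rate",
    "estimate_cell_collision_rate",
    "frip",
    "frip_per_cell",
    "duplication_rate",
    "downsample",
    "qc_report",
    "lower_median",
]


def default_species_of_chrom(chrom: str) -> str:
    """Species prefix embedded in the chromosome name (``hs_chr1`` -> ``hs``)."""
    return chrom.split("_", 1)[0]


def species_fractions(fragments: pd.DataFrame, species_of=None) -> pd.DataFrame:
    """Per-cell fraction of unique fragments per species (rows sum to 1)."""
    if species_of is None:
        species_of = default_species_of_chrom
    df = fragments[["cell", "chrom"]].copy()
    df["species"] = df["chrom"].map(species_of)
    tab = df.groupby(["cell", "species"]).size().unstack(fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0)


def species_mix_classify(fractions: pd.DataFrame, threshold: float = 0.95) -> pd.Series:
    """Classify each cell: the species holding strictly more than ``threshold``
    of its fragments, else ``"collision"`` (a cell at exactly the threshold is
    a collision).  Cells with zero fragments never appear in ``fractions`` and
    are thereby excluded."""
    best = fractions.max(axis=1)
    winner = fractions.idxmax(axis=1)
    return pd.Series(
        np.where(best > threshold, winner, "collision"), index=fractions.index,
        name="species_class",
    )


def collision_rate(classes: pd.Series) -> float:
    """Fraction of classified barcodes labelled collision."""
    if len(classes) == 0:
        raise ValueError("no classified cells")
    return float((classes == "collision").mean())


def estimate_cell_collision_rate(classes: pd.Series) -> float:
    """Per-cell detected collision rate estimated from barcode-level classes.

    A merged pair appears as one barcode, and same-species merges are invisible
    to a species-mixing readout.  With M mixed barcodes among T classified
    barcodes, the expected number of merges of any kind is M / p_mixed where
    p_mixed = 1 - sum_s f_s^2 (species fractions estimated from the pure
    barcodes), each merge hides one extra cell, and every detected merge
    involves two cells:

        cells ~= T + M / p_mixed,   rate = 2 M / cells.

    This matches the analytic per-cell expectation up to merges of three or
    more cells.
    """
    if len(classes) == 0:
        raise ValueError("no classified cells")
    M = int((classes == "collision").sum())
    T = len(classes)
    pure = classes[classes != "collision"]
    if pure.empty:
        raise ValueError("no pure barcodes to estimate species fractions from")
    f = pure.value_counts(normalize=True).to_numpy()
    p_mixed = 1.0 - float((f**2).sum())
    if p_mixed <= 0:
        raise ValueError("species mixture is degenerate (single species)")
    return 2.0 * M / (T + M / p_mixed)


def frip(fragments: pd.DataFrame, peaks: pd.DataFrame) -> float:
    """Fraction of fragments overlapping any peak by >= 1 base, to 4 significant
    figures.  Peaks are merged if not already disjoint.  Raises on zero
    fragments (undefined)."""
    if len(fragments) == 0:
        raise ValueError("FRiP undefined for zero fragments")
    if peaks.empty:
        return 0.0
    peaks = merge_intervals(peaks)
    frac = float(overlaps_any(fragments, peaks).mean())
    return float(f"{frac:.4g}")


def frip_per_cell(fragments: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """FRiP per cell over one modality's fragments; zero-fragment cells are
    absent by construction."""
    if fragments.empty:
        return pd.Series(dtype=float, name="frip")
    peaks = merge_intervals(peaks) if not peaks.empty else peaks
    hit = (
        overlaps_any(fragments, peaks)
        if not peaks.empty
        else np.zeros(len(fragments), dtype=bool)
    )
    df = pd.DataFrame({"cell": fragments["cell"].to_numpy(), "hit": hit})
    out = df.groupby("cell")["hit"].mean().round(6)
    out.name = "frip"
    return out


def duplication_rate(raw_reads: int, unique_fragments: int) -> float:
    """(raw - unique) / raw."""
    if raw_reads == 0:
        raise ValueError("duplication rate undefined for zero reads")
    if not raw_reads >= unique_fragments >= 0:
        raise ValueError("need raw >= unique >= 0")
    return (raw_reads - unique_fragments) / raw_reads


def downsample(df: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Keep each record independently with probability ``rate`` (deterministic
    per seed; ``rate=1`` returns the input unchanged)."""
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must be in (0, 1]")
    if rate == 1.0:
        return df.copy()
    rng = np.random.default_rng(seed)
    return df[rng.random(len(df)) < rate].reset_index(drop=True)


def lower_median(values) -> float:
    """Lower median: the n//2-th order statistic for even n (documented
    convention; identical to the usual median for odd n)."""
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("empty")
    return float(arr[(arr.size - 1) // 2])


def qc_report(
    fragments: pd.DataFrame,
    peaks_by_modality: dict[str, pd.DataFrame] | None = None,
    species_of=None,
    threshold: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and per-modality QC tables from deduplicated fragments.

    Per cell: unique fragments (total and per modality), total raw reads,
    duplicate fraction, species fractions and class, FRiP per modality (when
    peak sets are supplied).  Per modality: cell count, lower-median unique
    fragments and FRiP.
    """
    frac = species_fractions(fragments, species_of)
    classes = species_mix_classify(frac, threshold)
    per_cell = pd.DataFrame(index=frac.index)
    uniq = fragments.groupby(["cell", "modality"]).size().unstack(fill_value=0)
    per_cell["unique_fragments"] = uniq.sum(axis=1)
    for mod in uniq.columns:
        per_cell[f"unique_{mod}"] = uniq[mod]
    raw = fragments.groupby("cell")["duplicate_count"].sum()
    per_cell["raw_reads"] = raw
    per_cell["duplicate_fraction"] = (raw - per_cell["unique_fragments"]) / raw
    for sp in frac.columns:
        per_cell[f"frac_{sp}"] = frac[sp]
    per_cell["species_class"] = classes

    frips = {}
    if peaks_by_modality:
        for mod, peaks in peaks_by_modality.items():
            sub = fragments[fragments["modality"] == mod]
            frips[mod] = frip_per_cell(sub, peaks)
            per_cell[f"frip_{mod}"] = frips[mod]

    mod_rows = []
    for mod in uniq.columns:
        nz = uniq[mod][uniq[mod] > 0]
        row = {
            "modality": mod,
            "n_cells": int((uniq[mod] > 0).sum()),
            "median_unique_fragments": lower_median(nz) if len(nz) else np.nan,
        }
        if mod in frips and len(frips[mod]):
            row["median_frip"] = lower_median(frips[mod].to_numpy())
        mod_rows.append(row)
    per_modality = pd.DataFrame(mod_rows)
    return per_cell.reset_index(names="cell"), per_modality
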