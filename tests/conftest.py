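import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from multitag import simulate as sim
from multitag.barcodes import build_scheme

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scheme():
    """Compact scheme (2 T5, 2 modalities, 4x4 ligation, 4 PCR wells) with the
    production code-distance properties."""
    return build_scheme(
        round_sizes={"t5": 2, "r1": 4, "r2": 4, "pcr": 4},
        modality_labels=["drug", "mark"],
        barcode_lengths={"t5": 8, "t7": 8, "r1": 8, "r2": 8, "pcr": 8},
        genomic_length=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_genome():
    return sim.make_toy_genome(
        5, {"hs": {"chr1": 200_000}, "mm": {"chr1": 200_000}}
    )


def brute_overlaps(frag_row, region_row) -> bool:
    """All-pairs overlap oracle: half-open intervals share >= 1 base."""
    return (
        frag_row["chrom"] == region_row["chrom"]
        and frag_row["start"] < region_row["end"]
        and region_row["start"] < frag_row["end"]
    )


def random_intervals(rng, n, chroms=("hs_chr1", "mm_chr1"), span=10_000, max_len=400):
    starts = rng.integers(0, span, size=n)
    lens = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lens,
        }
    )


def disjoint_regions(rng, n, chroms=("hs_chr1", "mm_chr1"), width=200, gap=150):
    """Sorted disjoint region set spread over the chromosomes."""
    rows = []
    for i in range(n):
        chrom = chroms[i % len(chroms)]
        base = (i // len(chroms)) * (width + gap) + int(rng.integers(0, gap // 2))
        rows.append((chrom, base, base + width))
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


@pytest.fixture(scope="session")
def big_scheme():
    """Production-scale scheme: 6 T5 x 96 x 96 ligation rounds, 96 PCR wells."""
    return build_scheme(modality_labels=["drug", "mark"], seed=1)


@pytest.fixture(scope="session")
def two_type_sim(big_scheme, tiny_genome):
    """Two well-separated cell types with disjoint peak sets on one species:
    the workhorse for clustering/embedding recovery checks.

    Returns dict with cells, fragments, per-type peak frames and truth labels.
    """
    rng = np.random.default_rng(42)
    cfg = sim.SimConfig(
        cell_groups=[
            sim.CellGroup("hs", "typeA", 160),
            sim.CellGroup("hs", "typeB", 160),
        ],
        n_per_well=80,
        n_wells=4,
        seed=42,
    )
    cells = sim.simulate_split_pool(cfg, big_scheme, rng)
    sizes = tiny_genome.sizes_for("hs")
    peaks_a = sim.sample_peaks(sizes, 60, width_median=600, min_gap=800, rng=rng)
    peaks_b = sim.sample_peaks(sizes, 60, width_median=600, min_gap=800, rng=rng)
    profiles = {
        ("drug", "typeA"): sim.SignalProfile(peaks_a, phi=0.8, nb_mean=150),
        ("drug", "typeB"): sim.SignalProfile(peaks_b, phi=0.8, nb_mean=150),
    }
    frags = sim.simulate_fragments(cells, profiles, tiny_genome, rng)
    frags = frags.merge(cells[["cell_id", "cell_key", "cell_type"]], on="cell_id")
    frags = frags.rename(columns={"cell_key": "cell"})
    truth = cells.set_index("cell_key")["cell_type"]
    return {
        "cells": cells,
        "fragments": frags,
        "peaks_a": peaks_a,
        "peaks_b": peaks_b,
        "truth_types": truth,
    }
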