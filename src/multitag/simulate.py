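"""Synthetic data generator for split-pool barcoded multimodal tagmentation.

Everything downstream (demultiplexing, QC, co-enrichment, trajectory
statistics) is validated against data produced here, because ground truth is
known exactly: which cell each read came from, which modality, where its
fragment lies, and which reads are PCR duplicates of which.

The generative model, per cell and modality:

* a two-species toy genome (random sequence at a configurable GC fraction)
  stands in for a real human/mouse reference;
* each (modality, cell type) has a peak set, a fraction-in-peaks phi, a
  negative-binomial fragment-count law and a log-normal fragment-length law;
* a fragment lands inside a uniformly chosen peak with probability phi,
  otherwise uniformly on the cell's species genome;
* cells draw their (T5, round1, round2) barcodes independently and uniformly
  and are partitioned into PCR wells of exactly ``n_per_well`` cells whose
  index is the PCR barcode — barcode collisions are *emergent*, never
  injected;
* every fragment is sequenced once plus Geometric extra PCR-duplicate reads
  (so the expected duplicate fraction equals ``duplication_rate``), and
  barcode bases are substituted independently at ``barcode_error_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .barcodes import BarcodeScheme, InfeasibleBarcodeSet

__all__ = [
    "ToyGenome",
    "SignalProfile",
    "CellGroup",
    "SimConfig",
    "make_toy_genome",
    "sample_peaks",
    "simulate_split_pool",
    "detected_collision_fraction",
    "simulate_fragments",
    "emit_reads",
]


@dataclass
class ToyGenome:
    """Random reference sequences for one or more species.

    Chromosome names embed the species prefix (``hs_chr1``) so that a
    fragment's species is recoverable from its chromosome alone, mirroring a
    concatenated two-species alignment index.
    """

    sequences: dict[str, str]
    species_of: dict[str, str]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def species(self) -> list[str]:
        seen = []
        for sp in self.species_of.values():
            if sp not in seen:
                seen.append(sp)
        return seen

    def chroms_for(self, species: str) -> list[str]:
        return [c for c, sp in self.species_of.items() if sp == species]

    def sizes_for(self, species: str) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chroms_for(species)}

    def write_fasta(self, path) -> None:
        io.write_fasta(self.sequences, path)


def make_toy_genome(
    seed: int, sizes: dict[str, dict[str, int]], gc: float = 0.41
) -> ToyGenome:
    """Generate random chromosomes; ``sizes`` maps species -> chrom -> length.

    Base draws are i.i.d. with P(G)+P(C)=gc, so the realised GC content is
    binomial around ``gc``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    sequences, species_of = {}, {}
    for species, chroms in sizes.items():
        for chrom, length in chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: length must be positive")
            name = f"{species}_{chrom}"
            sequences[name] = "".join(bases[rng.choice(4, size=length, p=p)])
            species_of[name] = species
    return ToyGenome(sequences, species_of)


def sample_peaks(
    chrom_sizes: dict[str, int],
    n_peaks: int,
    width_median: int = 1000,
    width_sigma: float = 0.25,
    min_gap: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Disjoint, sorted peak intervals with log-normal widths and pairwise
    gaps >= ``min_gap``.

    Peaks are allotted to chromosomes proportionally to length, then placed by
    distributing the residual slack uniformly among the inter-peak gaps, which
    guarantees the gap constraint by construction.  Raises ``ValueError`` when
    the peaks cannot be packed.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_peaks == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n_peaks, lengths / lengths.sum())
    rows = []
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        widths = np.maximum(
            50, rng.lognormal(np.log(width_median), width_sigma, size=k).astype(int)
        )
        L = chrom_sizes[chrom]
        slack = L - int(widths.sum()) - (k - 1) * min_gap
        if slack < 0:
            raise ValueError(
                f"cannot pack {k} peaks (total {widths.sum()} b) with gap "
                f"{min_gap} on {chrom} ({L} b)"
            )
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = extra[0]
        for i in range(k):
            rows.append((chrom, pos, pos + widths[i]))
            pos += widths[i] + (min_gap if i < k - 1 else 0) + extra[i + 1]
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class SignalProfile:
    """Signal model for one (modality, cell type): where fragments go and how
    many there are.

    phi is the probability a fragment falls inside a peak (drives FRiP);
    fragment counts per cell are NB(mean, dispersion); lengths are log-normal
    around ``frag_len_median``.
    """

    peaks: pd.DataFrame
    phi: float
    nb_mean: float
    nb_dispersion: float = 10.0
    frag_len_median: int = 300
    frag_len_sigma: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")


@dataclass
class CellGroup:
    species: str
    cell_type: str
    n_cells: int


@dataclass
class SimConfig:
    """Study design: who is in the pool and how the physical process behaves."""

    cell_groups: list[CellGroup]
    n_per_well: int
    n_wells: int
    duplication_rate: float = 0.0
    barcode_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(g.n_cells for g in self.cell_groups)
        if total != self.n_per_well * self.n_wells:
            raise ValueError(
                f"total cells {total} != n_wells*n_per_well "
                f"{self.n_wells * self.n_per_well}"
            )
        if not 0.0 <= self.duplication_rate < 1.0:
            raise ValueError("duplication_rate must be in [0, 1)")
        if not 0.0 <= self.barcode_error_rate < 1.0:
            raise ValueError("barcode_error_rate must be in [0, 1)")


def simulate_split_pool(
    config: SimConfig, scheme: BarcodeScheme, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Put cells through the physical split-pool process.

    Each cell independently and uniformly draws one barcode per non-PCR cell
    round; cells are then randomly partitioned into wells of exactly
    ``n_per_well`` and inherit the well's PCR index.  Returns one row per cell
    with columns ``cell_id, species, cell_type, well, <round columns>, cell_key``.
    Collisions (two cells sharing a full ``cell_key``) arise only by chance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_total = config.n_per_well * config.n_wells
    pcr_round = scheme.round_by_name(scheme.pcr_round)
    if config.n_wells > pcr_round.size:
        raise ValueError("more wells than PCR indices")

    species = np.concatenate(
        [np.full(g.n_cells, g.species, dtype=object) for g in config.cell_groups]
    )
    ctype = np.concatenate(
        [np.full(g.n_cells, g.cell_type, dtype=object) for g in config.cell_groups]
    )
    order = rng.permutation(n_total)
    species, ctype = species[order], ctype[order]

    cols = {"cell_id": np.arange(n_total), "species": species, "cell_type": ctype}
    cols["well"] = np.repeat(np.arange(config.n_wells), config.n_per_well)
    for rnd in scheme.cell_rounds:
        if rnd.name == scheme.pcr_round:
            cols[rnd.name] = cols["well"]
        else:
            cols[rnd.name] = rng.integers(0, rnd.size, size=n_total)
    cells = pd.DataFrame(cols)
    key_parts = [cells[r.name].astype(str) for r in scheme.cell_rounds]
    key = key_parts[0]
    for part in key_parts[1:]:
        key = key + "-" + part
    cells["cell_key"] = key
    return cells


def detected_collision_fraction(cells: pd.DataFrame) -> float:
    """Fraction of cells sharing their full barcode key with at least one cell
    of a *different* species — the Monte-Carlo counterpart of the analytic
    ``theoretical_collision_rate`` (both are per-cell probabilities)."""
    n_species = cells.groupby("cell_key")["species"].transform("nunique")
    return float((n_species > 1).mean())


def simulate_fragments(
    cells: pd.DataFrame,
    profiles: dict[tuple[str, str], SignalProfile],
    genome: ToyGenome,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw genomic fragments for every cell and profiled modality.

    Returns columns ``cell_id, modality, chrom, start, end``.  Peak placement
    keeps the whole fragment inside the chosen peak whenever the peak is wide
    enough; background fragments land uniformly on the cell's species genome
    (chromosome chosen proportionally to length).
    """
    out = []
    for (modality, cell_type), prof in profiles.items():
        sub = cells[cells["cell_type"] == cell_type]
        if sub.empty:
            continue
        species = sub["species"].iloc[0]
        chroms = genome.chroms_for(species)
        chrom_len = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
        p_nb = prof.nb_dispersion / (prof.nb_dispersion + prof.nb_mean)
        counts = rng.negative_binomial(prof.nb_dispersion, p_nb, size=len(sub))
        total = int(counts.sum())
        if total == 0:
            continue
        cell_ids = np.repeat(sub["cell_id"].to_numpy(), counts)
        lens = np.maximum(
            30, rng.lognormal(np.log(prof.frag_len_median), prof.frag_len_sigma, total)
        ).astype(np.int64)
        in_peak = rng.random(total) < prof.phi
        chrom_arr = np.empty(total, dtype=object)
        start_arr = np.empty(total, dtype=np.int64)

        n_pk = int(in_peak.sum())
        if n_pk and not prof.peaks.empty:
            pk = prof.peaks
            pick = rng.integers(0, len(pk), size=n_pk)
            ps = pk["start"].to_numpy()[pick]
            pe = pk["end"].to_numpy()[pick]
            room = np.maximum(pe - ps - lens[in_peak], 0)
            start_arr[in_peak] = ps + (rng.random(n_pk) * (room + 1)).astype(np.int64)
            chrom_arr[in_peak] = pk["chrom"].to_numpy()[pick]
        elif n_pk:
            in_peak[:] = False  # no peaks to target: everything is background

        bg = ~in_peak
        n_bg = int(bg.sum())
        if n_bg:
            ci = rng.choice(len(chroms), size=n_bg, p=chrom_len / chrom_len.sum())
            room = np.maximum(chrom_len[ci].astype(np.int64) - lens[bg], 1)
            chrom_arr[bg] = np.array(chroms, dtype=object)[ci]
            start_arr[bg] = (rng.random(n_bg) * room).astype(np.int64)

        df = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "modality": modality,
                "chrom": chrom_arr,
                "start": start_arr,
                "end": start_arr + lens,
            }
        )
        # clamp to chromosome bounds
        sizes = genome.chrom_sizes
        cmax = df["chrom"].map(sizes).to_numpy()
        df["end"] = np.minimum(df["end"], cmax)
        out.append(df)
    if not out:
        return pd.DataFrame(columns=["cell_id", "modality", "chrom", "start", "end"])
    return pd.concat(out, ignore_index=True)


def _apply_barcode_errors(
    seqs: list[str], positions: np.ndarray, error_rate: float, rng: np.random.Generator
) -> None:
    """In-place per-base substitution of the barcode positions of R1 strings."""
    if error_rate <= 0:
        return
    n_err = rng.binomial(len(positions), error_rate, size=len(seqs))
    hit = np.flatnonzero(n_err)
    bases = "ACGT"
    for i in hit:
        s = list(seqs[i])
        for pos in rng.choice(positions, size=n_err[i], replace=False):
            old = s[pos]
            s[pos] = bases[(bases.index(old) + rng.integers(1, 4)) % 4] if old in bases else "N"
        seqs[i] = "".join(s)


def emit_reads(
    fragments: pd.DataFrame,
    cells: pd.DataFrame,
    scheme: BarcodeScheme,
    genome: ToyGenome,
    out_dir,
    error_rate: float = 0.0,
    duplication_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    mapq: int = 60,
) -> dict:
    """Write paired FASTQ plus exact truth tables for a fragment table.

    Each fragment is emitted once plus ``Geometric`` extra duplicate reads
    parameterised so the expected duplicate fraction equals
    ``duplication_rate``.  Duplicates receive fresh read names; only the truth
    table links them (column ``duplicate_of``).  R1 carries the barcode
    segments (with substitution errors at ``error_rate`` per barcode base),
    R2 the genomic sequence at the fragment start.

    Returns paths of ``r1``, ``r2``, ``truth_reads`` (read name -> true cell,
    modality, interval, duplicate_of) and ``alignments`` (read name -> chrom,
    start, end, strand, mapq), plus the two truth DataFrames.
    """
    if rng is None:
        rng = np.random.default_rng()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_frag = len(fragments)

    if duplication_rate > 0:
        copies = rng.geometric(1.0 - duplication_rate, size=n_frag)
    else:
        copies = np.ones(n_frag, dtype=np.int64)
    frag_of_read = np.repeat(np.arange(n_frag), copies)
    n_reads = len(frag_of_read)
    first_read_of_frag = np.zeros(n_frag, dtype=np.int64)
    first_read_of_frag[1:] = np.cumsum(copies)[:-1]
    is_dup = np.ones(n_reads, dtype=bool)
    is_dup[first_read_of_frag] = False

    names = np.array([f"r{i:08d}" for i in range(n_reads)])
    dup_of = np.where(is_dup, names[first_read_of_frag[frag_of_read]], "")

    cell_by_id = cells.set_index("cell_id")
    frag_cells = cell_by_id.loc[fragments["cell_id"].to_numpy()]
    mod_round = scheme.modality_round
    label_to_t7 = {scheme.modality_label(i): i for i in range(mod_round.size)}
    t7_idx = fragments["modality"].map(label_to_t7).to_numpy()

    # assemble R1 per layout order; record barcode base positions for the
    # error model (linker bases stay error-free)
    r1_segs = sorted((s for s in scheme.layout if s.read == "R1"), key=lambda s: s.offset)
    parts = []
    bc_positions = []
    for seg in r1_segs:
        if seg.kind == "linker":
            parts.append(np.full(n_frag, seg.sequence, dtype=object))
            continue
        bc_positions.extend(range(seg.offset, seg.end))
        rnd = scheme.round_by_name(seg.kind)
        seq_arr = np.array(rnd.sequences, dtype=object)
        if seg.kind == mod_round.name:
            idx = t7_idx
        else:
            idx = frag_cells[seg.kind].to_numpy()
        parts.append(seq_arr[idx])
    r1_frag = parts[0]
    for p in parts[1:]:
        r1_frag = r1_frag + p
    r1 = list(r1_frag[frag_of_read])
    _apply_barcode_errors(r1, np.array(bc_positions), error_rate, rng)

    gseg = next(s for s in scheme.layout if s.kind == "genomic")
    strands = np.where(rng.random(n_frag) < 0.5, "+", "-")
    chrom_list = fragments["chrom"].tolist()
    start_list = fragments["start"].tolist()
    seqs = genome.sequences
    r2_frag = [
        (seqs[c][s : s + gseg.length]).ljust(gseg.length, "A")
        for c, s in zip(chrom_list, start_list)
    ]
    r2 = [r2_frag[f] for f in frag_of_read]

    r1_path, r2_path = out_dir / "reads_R1.fastq", out_dir / "reads_R2.fastq"
    for path, seq_list in ((r1_path, r1), (r2_path, r2)):
        with open(path, "w") as fh:
            chunk = []
            for name, seq in zip(names, seq_list):
                chunk.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
                if len(chunk) >= 100_000:
                    fh.write("".join(chunk))
                    chunk = []
            fh.write("".join(chunk))

    truth_reads = pd.DataFrame(
        {
            "read": names,
            "cell_id": fragments["cell_id"].to_numpy()[frag_of_read],
            "cell_key": frag_cells["cell_key"].to_numpy()[frag_of_read],
            "modality": fragments["modality"].to_numpy()[frag_of_read],
            "chrom": fragments["chrom"].to_numpy()[frag_of_read],
            "start": fragments["start"].to_numpy()[frag_of_read],
            "end": fragments["end"].to_numpy()[frag_of_read],
            "strand": strands[frag_of_read],
            "duplicate_of": dup_of,
        }
    )
    alignments = truth_reads[["read", "chrom", "start", "end", "strand"]].copy()
    alignments["mapq"] = mapq
    truth_path = out_dir / "truth_reads.tsv"
    aln_path = out_dir / "alignments.tsv"
    io.write_table(truth_reads, truth_path)
    io.write_table(alignments, aln_path)
    return {
        "r1": r1_path,
        "r2": r2_path,
        "truth_reads_path": truth_path,
        "alignments_path": aln_path,
        "truth_reads": truth_reads,
        "alignments": alignments,
    }
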