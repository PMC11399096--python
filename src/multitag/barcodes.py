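"""Split-pool barcode architecture.

Cells pass through several barcoding rounds: six barcoded Tn5 adaptors (T5)
in the tagmentation step, two 96-well ligation rounds, and a final indexed
PCR round of up to 96 wells.  The combination (T5, round1, round2, PCR index)
uniquely identifies a cell; a separate T7 adaptor barcode identifies the
modality (which antibody-directed signal a fragment came from).  This module
models that architecture: whitelist generation under a minimum pairwise
Hamming-distance constraint, single-barcode error correction, scheme
(de)serialisation, and the analytic expectation for barcode collisions in a
two-species mixing experiment.

Coordinates and offsets are 0-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

BASES = "ACGT"

__all__ = [
    "BarcodeRound",
    "LayoutSegment",
    "BarcodeScheme",
    "InfeasibleBarcodeSet",
    "hamming",
    "generate_barcodes",
    "correct_barcode",
    "theoretical_collision_rate",
    "build_scheme",
]


class InfeasibleBarcodeSet(ValueError):
    """Requested barcode set cannot satisfy the length/distance constraint."""


def hamming(a: str, b: str) -> int:
    """Hamming distance; any non-ACGT character (e.g. N) counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x not in BASES)


def generate_barcodes(
    n: int, length: int, min_dist: int, rng: np.random.Generator, max_tries: int = 200_000
) -> list[str]:
    """Draw ``n`` random barcodes of ``length`` bases with pairwise Hamming
    distance >= ``min_dist`` by rejection sampling.

    Raises :class:`InfeasibleBarcodeSet` when the request is infeasible by the
    coarse bound ``length >= ceil(log4 n) + min_dist`` or when rejection
    sampling exhausts its budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < math.ceil(math.log(n, 4) if n > 1 else 0) + min_dist:
        raise InfeasibleBarcodeSet(
            f"cannot fit {n} barcodes of length {length} at min distance {min_dist}"
        )
    chosen: list[str] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise InfeasibleBarcodeSet(
                f"gave up after {max_tries} draws with {len(chosen)}/{n} barcodes "
                f"(length {length}, min distance {min_dist})"
            )
        cand = "".join(rng.choice(list(BASES), size=length))
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
    return chosen


@dataclass
class BarcodeRound:
    """One barcoding round: a named, ordered whitelist of equal-length sequences.

    ``role`` is ``"cell"`` for rounds that contribute to cell identity and
    ``"modality"`` for the T7 round that tags which assay a fragment belongs to.
    ``labels`` optionally names each barcode (modality rounds carry assay names).
    """

    name: str
    role: str
    sequences: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.role not in ("cell", "modality"):
            raise ValueError(f"round {self.name}: role must be 'cell' or 'modality'")
        if not self.sequences:
            raise ValueError(f"round {self.name}: empty whitelist")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError(f"round {self.name}: sequences have unequal lengths")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError(f"round {self.name}: duplicate sequences")
        if self.labels is not None and len(self.labels) != len(self.sequences):
            raise ValueError(f"round {self.name}: labels/sequences length mismatch")
        self._index = {s: i for i, s in enumerate(self.sequences)}

    @property
    def size(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def min_pairwise_hamming(self) -> int:
        """Minimum pairwise Hamming distance (inf-like large value for size 1)."""
        if self.size == 1:
            return self.length  # vacuous
        return min(
            hamming(a, b)
            for i, a in enumerate(self.sequences)
            for b in self.sequences[i + 1 :]
        )

    def exact_index(self, seq: str) -> int | None:
        return self._index.get(seq)


def correct_barcode(
    observed: str, rnd: BarcodeRound, radius: int = 1
) -> tuple[int | None, str]:
    """Assign an observed sequence to a whitelist entry within ``radius`` errors.

    Returns ``(index, "ok")`` on a unique assignment, otherwise ``(None, reason)``
    with reason one of ``"length"`` (observed length differs from the round's),
    ``"no_match"`` (no whitelist entry within radius) or ``"ambiguous"`` (two or
    more entries tie at the minimum distance within radius; ambiguity is never
    broken arbitrarily).
    """
    if len(observed) != rnd.length:
        return None, "length"
    idx = rnd.exact_index(observed)
    if idx is not None:
        return idx, "ok"
    best, best_d, tie = None, radius + 1, False
    for i, seq in enumerate(rnd.sequences):
        d = hamming(observed, seq)
        if d < best_d:
            best, best_d, tie = i, d, False
        elif d == best_d:
            tie = True
    if best is None or best_d > radius:
        return None, "no_match"
    if tie:
        return None, "ambiguous"
    return best, "ok"


def theoretical_collision_rate(
    n_per_well: int, K: int, species_fractions: Sequence[float]
) -> float:
    """Analytic detected cross-species collision rate for split-pool barcoding.

    In one PCR well of ``n_per_well`` cells, each cell independently draws one
    of ``K`` equally likely within-well barcode combinations.  A cell is merged
    when at least one other cell in the well drew the same combination,

        p_merge = 1 - (1 - 1/K)**(n_per_well - 1),

    and a merge is *detected* in a species-mixing experiment only when the
    partners differ in species,

        p_mixed = 1 - sum_s f_s**2.

    The product ``p_merge * p_mixed`` is the probability that a given cell is
    part of a detected collision.  This pairwise-merge approximation ignores
    merges of three or more cells, which are negligible at realistic n/K
    (the Monte-Carlo split-pool simulation agrees within sampling error).
    """
    if n_per_well < 1:
        raise ValueError("n_per_well must be >= 1")
    if K < 1:
        raise ValueError("K must be >= 1")
    fractions = np.asarray(species_fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"species fractions sum to {fractions.sum()!r}, not 1")
    p_merge = 1.0 - (1.0 - 1.0 / K) ** (n_per_well - 1)
    p_mixed = 1.0 - float((fractions**2).sum())
    return p_merge * p_mixed


@dataclass
class LayoutSegment:
    """One slice of a sequencing read: which mate, where, how long, and what it
    encodes (a barcode round name, ``"linker"`` with a fixed sequence, or
    ``"genomic"``)."""

    read: str  # "R1" | "R2"
    offset: int
    length: int
    kind: str
    sequence: str | None = None  # fixed sequence for linkers

    def __post_init__(self) -> None:
        if self.read not in ("R1", "R2"):
            raise ValueError("segment read must be 'R1' or 'R2'")
        if self.offset < 0 or self.length < 1:
            raise ValueError("segment offset/length out of range")
        if self.kind == "linker" and (
            self.sequence is None or len(self.sequence) != self.length
        ):
            raise ValueError("linker segment needs a fixed sequence of its length")

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class BarcodeScheme:
    """The full barcode architecture plus the read layout that carries it.

    ``rounds`` is ordered; cell identity is the tuple of indices of all
    cell-role rounds in that order.  The round named ``pcr_round`` is the
    indexed-PCR round: it is shared by every cell in a well and therefore does
    not contribute to the *within-well* barcode space ``K``.
    """

    rounds: list[BarcodeRound]
    layout: list[LayoutSegment]
    correction_radius: int = 1
    pcr_round: str = "pcr"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        names = [r.name for r in self.rounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate round names")
        by_read: dict[str, list[LayoutSegment]] = {"R1": [], "R2": []}
        for seg in self.layout:
            by_read[seg.read].append(seg)
        for read, segs in by_read.items():
            segs.sort(key=lambda s: s.offset)
            for a, b in zip(segs, segs[1:]):
                if a.end > b.offset:
                    raise ValueError(f"overlapping layout segments on {read}")
        seg_rounds = [s.kind for s in self.layout if s.kind not in ("linker", "genomic")]
        if sorted(seg_rounds) != sorted(names):
            raise ValueError("every barcode round must appear in exactly one segment")
        if sum(1 for s in self.layout if s.kind == "genomic") != 1:
            raise ValueError("exactly one genomic segment required")
        for seg in self.layout:
            if seg.kind not in ("linker", "genomic"):
                if seg.length != self.round_by_name(seg.kind).length:
                    raise ValueError(f"segment length mismatch for round {seg.kind}")
        for rnd in self.rounds:
            if rnd.size > 1 and rnd.min_pairwise_hamming < 2 * self.correction_radius + 1:
                raise ValueError(
                    f"round {rnd.name}: min pairwise Hamming "
                    f"{rnd.min_pairwise_hamming} < 2*radius+1"
                )
        if not any(r.name == self.pcr_round for r in self.rounds):
            raise ValueError(f"no round named {self.pcr_round!r}")

    def round_by_name(self, name: str) -> BarcodeRound:
        for r in self.rounds:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def cell_rounds(self) -> list[BarcodeRound]:
        return [r for r in self.rounds if r.role == "cell"]

    @property
    def modality_round(self) -> BarcodeRound:
        mods = [r for r in self.rounds if r.role == "modality"]
        if len(mods) != 1:
            raise ValueError("scheme must have exactly one modality round")
        return mods[0]

    @property
    def K(self) -> int:
        """Within-well cell-barcode space: product of cell-round sizes excluding
        the PCR index round (all cells in one well share their PCR index)."""
        k = 1
        for r in self.cell_rounds:
            if r.name != self.pcr_round:
                k *= r.size
        return k

    def cell_key(self, indices: dict[str, int]) -> str:
        """Canonical cell-key string from per-round indices, e.g. '3-17-42-0'."""
        return "-".join(str(indices[r.name]) for r in self.cell_rounds)

    def modality_label(self, t7_index: int) -> str:
        rnd = self.modality_round
        if rnd.labels is not None:
            return rnd.labels[t7_index]
        return f"mod{t7_index}"

    def read_length(self, read: str) -> int:
        return max((s.end for s in self.layout if s.read == read), default=0)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "correction_radius": self.correction_radius,
            "pcr_round": self.pcr_round,
            "rounds": [
                {
                    "name": r.name,
                    "role": r.role,
                    "sequences": list(r.sequences),
                    **({"labels": list(r.labels)} if r.labels is not None else {}),
                }
                for r in self.rounds
            ],
            "layout": [
                {
                    "read": s.read,
                    "offset": s.offset,
                    "length": s.length,
                    "kind": s.kind,
                    **({"sequence": s.sequence} if s.sequence is not None else {}),
                }
                for s in self.layout
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BarcodeScheme":
        rounds = [
            BarcodeRound(r["name"], r["role"], list(r["sequences"]), r.get("labels"))
            for r in d["rounds"]
        ]
        layout = [
            LayoutSegment(s["read"], s["offset"], s["length"], s["kind"], s.get("sequence"))
            for s in d["layout"]
        ]
        return cls(rounds, layout, d.get("correction_radius", 1), d.get("pcr_round", "pcr"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "BarcodeScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def export_whitelist(self, round_name: str, path) -> None:
        """Plain-text whitelist, one sequence per line."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.round_by_name(round_name).sequences) + "\n")


def load_whitelist(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


DEFAULT_ROUND_SIZES = {"t5": 6, "t7": 1, "r1": 96, "r2": 96, "pcr": 96}
LINKER = "TCAG"


def build_scheme(
    round_sizes: dict[str, int] | None = None,
    modality_labels: Sequence[str] | None = None,
    barcode_lengths: dict[str, int] | None = None,
    min_dist: int = 3,
    correction_radius: int = 1,
    genomic_length: int = 40,
    seed: int = 0,
) -> BarcodeScheme:
    """Construct a scheme with generated, distance-constrained whitelists.

    Defaults mirror the assay architecture: 6 T5 tagmentation barcodes, one T7
    modality barcode per assayed modality, two 96-well ligation rounds and 96
    indexed-PCR wells.  All barcode segments sit on R1 in round order with a
    fixed 4-base linker after the T7 segment; R2 is genomic.  Deterministic for
    a fixed seed.
    """
    sizes = dict(DEFAULT_ROUND_SIZES)
    if round_sizes:
        sizes.update(round_sizes)
    if modality_labels is not None:
        sizes["t7"] = len(modality_labels)
    lengths = {"t5": 8, "t7": 8, "r1": 10, "r2": 10, "pcr": 10}
    if barcode_lengths:
        lengths.update(barcode_lengths)
    rng = np.random.default_rng(seed)
    rounds = []
    for name in ("t5", "t7", "r1", "r2", "pcr"):
        try:
            seqs = generate_barcodes(sizes[name], lengths[name], min_dist, rng)
        except InfeasibleBarcodeSet as e:
            raise InfeasibleBarcodeSet(f"round {name}: {e}") from e
        role = "modality" if name == "t7" else "cell"
        labels = list(modality_labels) if (name == "t7" and modality_labels) else None
        rounds.append(BarcodeRound(name, role, seqs, labels))

    layout, off = [], 0
    for name in ("t5", "t7"):
        layout.append(LayoutSegment("R1", off, lengths[name], name))
        off += lengths[name]
    layout.append(LayoutSegment("R1", off, len(LINKER), "linker", LINKER))
    off += len(LINKER)
    for name in ("r1", "r2", "pcr"):
        layout.append(LayoutSegment("R1", off, lengths[name], name))
        off += lengths[name]
    layout.append(LayoutSegment("R2", 0, genomic_length, "genomic"))
    return BarcodeScheme(rounds, layout, correction_radius)
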