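# multitag

Toolkit for **split-pool barcoded multimodal single-cell tagmentation data**:
simulation with exact ground truth, demultiplexing, barnyard quality control,
and the statistics used to analyse co-assayed chromatin modalities (drug
binding sites, histone marks, accessibility) in the same single cells.

## The problem

In split-pool combinatorial barcoding, cells pass through successive rounds of
barcoded reactions — here six barcoded Tn5 adaptors (T5), two 96-well ligation
rounds and a 96-well indexed PCR — so that each cell's barcode combination
`(T5, round1, round2, PCR)` identifies it without physical isolation. A
separate T7 adaptor barcode marks which antibody-directed modality a fragment
came from. Two cells occasionally draw the same combination and merge into one
pseudo-cell (a *collision*). For `n` cells per PCR well drawing uniformly from
`K` within-well combinations, a cell is merged with probability

```
p_merge = 1 − (1 − 1/K)^(n−1)
```

and the merge is *detected* in a two-species mixing experiment only when the
partners differ in species, with probability `p_mixed = 1 − Σ_s f_s²`. At the
production design point (`K = 6·96·96 = 55,296`, `n = 1,000`, 1:1
human:mouse) the detected per-cell collision expectation is
`p_merge · p_mixed = 0.00895 ≈ 0.9%`.

Downstream, the package implements the standard single-cell chromatin
statistics: per-cell FRiP (fraction of fragments in peaks), TF-IDF/LSI
embedding of binarised cell × region matrices, cluster error rate (misgrouped
fraction minimised over label permutations), per-cell **Cramér's V**
co-enrichment between two modalities' region occupancy
(`V = |ad − bc| / √((a+b)(c+d)(a+c)(b+d))` on the per-cell 2×2
presence/absence table, with a matched random-region null), and pseudotime
metacell trajectories with region-dynamics clustering.

## Worked example

A full in-silico barnyard experiment — 20 PCR wells × 1,000 cells, half
human-like and half mouse-like, 20% PCR duplication — simulated to FASTQ,
demultiplexed, deduplicated and classified:

```python
import numpy as np
from multitag import simulate as sim, demux, qc
from multitag.barcodes import build_scheme, theoretical_collision_rate

rate = theoretical_collision_rate(1000, 6 * 96 * 96, [0.5, 0.5])
# 0.00895  (0.9%)

scheme = build_scheme(modality_labels=["drug"], seed=1)
cfg = sim.SimConfig(
    cell_groups=[sim.CellGroup("hs", "K562", 10_000),
                 sim.CellGroup("mm", "mES", 10_000)],
    n_per_well=1000, n_wells=20, duplication_rate=0.2, seed=7)
rng = np.random.default_rng(cfg.seed)
genome = sim.make_toy_genome(8, {"hs": {"chr1": 1_000_000},
                                 "mm": {"chr1": 1_000_000}})
cells = sim.simulate_split_pool(cfg, scheme, rng)
peaks = {sp: sim.sample_peaks(genome.sizes_for(sp), 50, width_median=600,
                              min_gap=2000, rng=rng) for sp in ("hs", "mm")}
profiles = {("drug", "K562"): sim.SignalProfile(peaks["hs"], 0.6, 20),
            ("drug", "mES"):  sim.SignalProfile(peaks["mm"], 0.6, 20)}
frags = sim.simulate_fragments(cells, profiles, genome, rng)
reads = sim.emit_reads(frags, cells, scheme, genome, "out/",
                       duplication_rate=0.2, rng=rng)

calls, _ = demux.parse_reads(reads["r1"], scheme)
raw, _ = demux.join_alignments(calls, reads["alignments"])   # MAPQ > 30
records = demux.deduplicate(raw)
classes = qc.species_mix_classify(qc.species_fractions(records))  # >95% rule
```

This prints (seed 7):

```
reads emitted: 499508, unique fragments: 399947
duplication rate: 0.199
classified barcodes: 19792
barcode-level collision rate: 0.00475
per-cell collision estimate:  0.00941
human cells: 9846, median FRiP: 0.6200
```

Reading the numbers: the recovered duplication rate matches the simulated 20%;
the *barcode-level* mixed fraction (0.48%) is roughly half the per-cell
expectation because a merged pair collapses into a single barcode and
same-species merges are invisible — `qc.estimate_cell_collision_rate` applies
the standard barnyard correction and lands on 0.94%, within sampling error of
the analytic 0.9%; and the median FRiP of human cells recovers the simulated
fraction-in-peaks (φ = 0.6) plus a small background-overlap excess.

A command-line interface mirrors the library
(`multitag scheme / demux / qc / matrix / coenrich / peaks / dynamics`);
see `multitag --help`.

## Layout

| module | contents |
| --- | --- |
| `multitag.barcodes` | barcode rounds, whitelist generation, Hamming correction, collision model, scheme (de)serialisation |
| `multitag.simulate` | toy genomes, peak sampling, split-pool process, fragment and read emission with truth tables |
| `multitag.demux` | barcode calling, whitelisting (knee / top-n), alignment join, deduplication, cell filtering |
| `multitag.qc` | species mixing, collision rates, FRiP, duplication, downsampling, QC reports |
| `multitag.multimodal` | cell × region matrices, TF-IDF/LSI, clustering + error rate, normalized signal, Cramér's V, random regions, peak partitioning, naive peak caller |
| `multitag.dynamics` | centroid-axis pseudotime, 50-cell metacells, smoothing, region-trajectory clustering |
| `multitag.io` | FASTA/BED/fragments-TSV/MatrixMarket readers and writers |
| `multitag.cli` | thin click CLI over all of the above |
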