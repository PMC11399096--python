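# Methods

This note documents the models, conventions and design choices behind
`multitag`, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the genuinely open choices were resolved.

## Barcode architecture and error correction

A scheme is an ordered list of barcode rounds plus a read layout. Cell
identity is the tuple of indices over the cell-role rounds — by default
`(T5, round1, round2, PCR index)` with sizes 6 × 96 × 96 × 96 — and the T7
round encodes only the modality. The six T5 adaptors are treated as a
cell-splitting round (split usage), which makes the within-well barcode space
`K = |T5|·|round1|·|round2| = 55,296`; the PCR index is shared by every cell
in a well and therefore contributes to global identity but not to `K`.

Whitelists are generated by seeded rejection sampling under a minimum pairwise
Hamming distance of 3 (lengths 8–10 bp), rather than copied from any
particular oligo set; real-data users can load plain-text whitelists instead.
Correction radius defaults to 1: with distance ≥ 2r+1 every read with at most
r errors per segment decodes to its true barcode, which is tested by
exhaustive perturbation. Equidistant hits within the radius are left
unassigned — zero cross-cell contamination is prioritised over yield. `N`
bases count as mismatches.

## The collision model and its units

For `n` cells per PCR well drawing independently and uniformly from `K`
combinations, the per-cell merge probability is
`p_merge = 1 − (1 − 1/K)^(n−1)` and a merge is detected in a species-mixing
experiment with probability `p_mixed = 1 − Σ f_s²`. The product is the
**per-cell** probability of a detected collision (pairwise-merge
approximation; merges of three or more cells are negligible at the default
n/K and are covered by the Monte-Carlo check in `simulate`). At
`n = 1,000`, `K = 55,296`, `f = (½, ½)` this gives 0.00895, i.e. 0.9%.

One unit subtlety matters and is handled explicitly. After demultiplexing,
the observable unit is a *barcode* (cell key): a merged pair appears as one
barcode, and same-species merges are invisible to the species readout. The
observed mixed-barcode fraction is therefore roughly half the per-cell rate
at a 1:1 mixture. `qc.collision_rate` reports the plain barcode-level
fraction; `qc.estimate_cell_collision_rate` converts it to the per-cell scale
using the standard barnyard correction (estimate species fractions from pure
barcodes, inflate the mixed count by `1/p_mixed` to account for hidden
same-species merges, count two cells per merge). The end-to-end agreement
tests compare this cell-level estimate — and the simulator's truth-level
per-cell fraction — against the analytic formula; both land within 3 binomial
standard errors at 10,000–20,000 simulated cells.

## The synthetic-data generator

The generator emulates a two-species ("barnyard") multimodal experiment:

* **Genome** — random sequence at GC 0.41, species prefix embedded in
  chromosome names (`hs_chr1`), standing in for a concatenated two-species
  index. Default test scale: 1 Mb per species.
* **Peaks** — disjoint intervals with log-normal widths (median 600–1,000 bp)
  and a minimum gap, allotted to chromosomes by length.
* **Cells** — default barnyard design: 20 PCR wells × 1,000 cells, 1:1
  human-like:mouse-like, matching the production loading of 1,000–3,000
  cells/well at its lower end (the value consistent with the 0.9%
  expectation). Cells draw (T5, r1, r2) uniformly; wells are exact
  partitions; collisions are emergent, never injected.
* **Fragments** — per cell and modality, counts are negative binomial
  (dispersion 10; mean 20 in the barnyard runs, higher where embeddings need
  depth), lengths log-normal (median 300 bp, σ 0.35, floor 30 bp); a fragment
  falls inside a uniformly chosen peak with probability φ, else uniformly on
  the cell's species genome. φ directly drives FRiP.
* **Reads** — each fragment is sequenced once plus `Geometric(1 − d)` − 1
  duplicate reads, so the expected duplicate fraction equals `d` (default
  0.2 in tests; deep production libraries reach ~0.83). Duplicates get fresh
  read names; only the truth table links them, so deduplication is tested
  without name hints. Barcode bases substitute independently at the
  configured error rate; linker and genomic bases are left clean.
* **Truth** — per-read tables (true cell, modality, interval, duplicate-of)
  and an exact alignment table (MAPQ 60), so alignment itself stays a
  pluggable external stage.

What the generator does **not** model: base-call quality, mappability and
alignment error, chromatin-state spatial autocorrelation beyond peak
membership, doublets from cell clumping (distinct from barcode collisions),
and batch effects. Passing tests therefore demonstrate correctness of the
computational pipeline under its stated generative assumptions, not
robustness to every artefact of real libraries.

## Demultiplexing conventions

* Coordinates are 0-based half-open everywhere (BED convention).
* MAPQ filtering is strict: a read at exactly the threshold (30) is
  discarded.
* Deduplication keys on (cell, modality, chrom, start, end); strand is
  excluded by default because Tn5 fragments are interval-defined (flag
  available). Deduplication is per (cell, modality) — modality is orthogonal
  to cell identity by design.
* The cell-depth filter keeps cells with strictly more than 400 unique
  fragments, counted jointly across modalities (per-modality thresholds are a
  config away; the joint count is the default because the assay's cell QC is
  a property of the cell, not of one modality).
* The knee whitelist takes the inflection (steepest smoothed log-log slope)
  of the rank/count curve — the cliff between real cells and barcode noise —
  rather than a maximum-curvature point, which on negative-binomial count
  plateaus tends to cut into the real-cell tail. Ties in `top_n` break
  lexicographically by key; the output is nested in n.
* "Cross-cell misassignment" is defined as a read decoded to a *different
  real cell's* key. With distance-3 codes at radius 1, a 2-error segment can
  in principle decode to a wrong codeword, but the wrong full key virtually
  never coincides with another real cell in a sparsely occupied key space;
  the noisy-demux test asserts zero such events and checks the fully-correct
  call fraction against the closed form Π_seg P(≤ 1 error in segment).

## QC conventions

Species classification uses deduplicated fragments (duplicates would bias
fractions) and a strict >95% rule: a cell at exactly 95% is a collision.
FRiP counts ≥ 1 base of overlap on half-open intervals (midpoint mode by
flag) and is reported to 4 significant figures; zero-fragment cells are
excluded rather than given 0. Duplication rate is `(raw − unique)/raw`.
Medians use the lower-median convention for even counts. Downsampling keeps
records i.i.d. with the given probability, seeded.

## Multimodal statistics

**TF-IDF/LSI.** The matrix is binarised; `TF` is entry over cell total,
`IDF` is cells over region occupancy, combined as `ln(1 + 10⁴·TF·IDF)`;
rank-d truncated SVD (ARPACK, fixed starting state) with a deterministic sign
convention (largest-magnitude region loading positive). Each component's
Pearson correlation with log depth is reported and the first component is
dropped by default when |r| > 0.9, as is standard for binarised chromatin
matrices. The dialect is fixed here because the technique's name alone does
not pin it down.

**Cramér's V.** The co-enrichment statistic is computed per cell from
presence/absence indicators over a reference region set: `a` regions hit by
both modalities, `b` by A only, `c` by B only, `d` by neither, and
`V = |ad − bc| / √((a+b)(c+d)(a+c)(b+d))` — the 2×2 form of `√(χ²/N)`. The
region set defaults to the union of both modalities' peaks; any BED may be
supplied. Cells with a degenerate margin are excluded and counted, not
assigned 0. The null control regenerates the region set with the same count
and width multiset placed uniformly (non-overlapping) on the genome; under
independence the median V tends to 0 as regions grow.

**Cluster error rate** is the misassigned fraction minimised over label
permutations (Hungarian assignment on the confusion matrix), hence invariant
to relabelling.

**Peak partitioning** classifies peaks as shared on ≥ 1 base of overlap,
reported in each set's own coordinates so counts are conserved per set. The
naive peak caller (fixed 500-bp bins, one-sided Poisson test against the
genome-wide mean, Benjamini–Hochberg at q < 0.01, adjacent significant bins
merged) is plumbing for self-contained runs, not a substitute for a real
caller.

## Pseudotime and region dynamics

The assayed trajectories are single root→terminal transitions, so pseudotime
is the scalar projection of each cell onto the axis joining the root and
terminal cluster centroids in LSI space, min-max scaled to [0, 1]; a graph
learner would add nothing for this geometry, and an externally computed
pseudotime vector can be substituted. Ties in t break by cell key for
determinism. Metacells aggregate 50 consecutive cells in pseudotime order
(the trailing partial block is kept and flagged); columns are normalised to
counts per million, rows z-scored (zero-variance rows stay 0) — the
normalisation applied before clustering had to be fixed here, and CPM +
row-z is the conventional choice for trajectory heatmaps. Smoothing is a
centred moving average with half-width 1 by default, truncated at the edges.
Region clusters (k-means seeded, or Ward) are renumbered by the pseudotime
position of each cluster's mean-curve maximum, a stable naming; defaults for
k (6, 3, 4) mirror the analyses the toolkit targets and are config-exposed.

## Problem sizes and determinism

The test suite runs the full pipeline at 20 wells × 1,000 cells (plus
20 × 500 and 10 × 2,000) with ~20 fragments per cell for collision
statistics; 320-cell two-type simulations at ~150 fragments per cell for
embedding and clustering recovery; 400-cell gradient simulations for
pseudotime; 10⁴ regions for the Cramér's V null; and 1,000 random instances
for the brute-force overlap oracles. These sizes give 3-standard-error
margins comfortably below the effects being measured. All randomness flows
through `numpy.random.Generator` objects seeded explicitly; every simulation
and embedding is bit-reproducible for a fixed seed.

## Known limitations

* The pairwise-merge collision approximation degrades when `n/K` approaches
  1 (heavily overloaded wells); the split-pool simulator remains exact there.
* The per-cell collision estimator assumes merges of exactly two cells and a
  stable species mixture across wells.
* The naive peak caller has no local background model and will merge nearby
  peaks at high depth.
* The centroid-axis pseudotime assumes an approximately linear transition in
  embedding space; branched topologies need an external trajectory method.
* Real-data headline numbers from the assay this toolkit models (cell
  counts, peak counts, per-modality medians) depend on restricted-access
  raw data and are not reproduced here; the simulation-based property checks
  stand in for them.
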