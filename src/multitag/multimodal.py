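"""Cell x region matrices and the multimodal co-assay statistics.

Covers matrix construction from fragments (peaks or fixed genomic bins),
TF-IDF/LSI embedding of the binarised matrix, cell clustering with a
permutation-minimised error rate, z-scored normalized signal over a reference
peak set, per-cell Cramér's V co-enrichment between two modalities with a
matched random-region control, specific/shared peak partitioning, and a naive
Poisson bin peak caller used as plumbing where an external caller would
normally run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import TruncatedSVD

from ._intervals import merge_intervals, region_hits, sort_intervals

__all__ = [
    "FeatureMatrix",
    "Embedding",
    "make_bins",
    "build_matrix",
    "tfidf_lsi",
    "cluster_cells",
    "cluster_error_rate",
    "normalized_signal",
    "cramers_v",
    "random_regions",
    "specific_shared_peaks",
    "PeakPartition",
    "naive_peak_call",
]


@dataclass
class FeatureMatrix:
    """Sparse cells x regions count matrix for one modality."""

    cells: list[str]
    regions: pd.DataFrame  # chrom, start, end; sorted, non-overlapping
    counts: scipy.sparse.csr_matrix
    modality: str = ""
    n_unknown_chrom: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cells), len(self.regions)):
            raise ValueError("counts shape inconsistent with cells/regions")

    @property
    def depth(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def make_bins(chrom_sizes: dict[str, int], width: int = 5000) -> pd.DataFrame:
    """Fixed non-overlapping genomic bins tiling every chromosome."""
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        edges = np.arange(0, size + width, width)
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append((chrom, int(a), min(int(b), size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_matrix(
    fragments: pd.DataFrame,
    features: pd.DataFrame,
    cells: list[str] | None = None,
    modality: str = "",
) -> FeatureMatrix:
    """Count fragment/region overlaps per cell.

    A fragment overlapping several regions (e.g. spanning a bin boundary) is
    counted once in *each* of them.  Fragments on chromosomes absent from the
    feature set are counted in ``n_unknown_chrom`` and skipped.  ``cells``
    fixes the row order (and admits empty rows); by default rows are the
    sorted cells present.
    """
    features = sort_intervals(features)
    if cells is None:
        cells = sorted(fragments["cell"].unique())
    cell_index = {c: i for i, c in enumerate(cells)}
    frags = fragments[fragments["cell"].isin(cell_index)].reset_index(drop=True)
    f_idx, r_idx, unknown = region_hits(frags, features)
    rows = frags["cell"].map(cell_index).to_numpy()[f_idx] if len(f_idx) else []
    counts = scipy.sparse.coo_matrix(
        (np.ones(len(f_idx)), (rows, r_idx)),
        shape=(len(cells), len(features)),
    ).tocsr()
    return FeatureMatrix(list(cells), features, counts, modality, unknown)


@dataclass
class Embedding:
    """LSI embedding: per-cell coordinates plus diagnostics."""

    cells: list[str]
    coords: np.ndarray
    singular_values: np.ndarray
    depth_correlation: np.ndarray  # per retained component, vs log depth
    dropped_first: bool = False


def tfidf_lsi(
    fm: FeatureMatrix,
    d: int = 30,
    binarize: bool = True,
    drop_depth_component: bool = True,
    depth_corr_threshold: float = 0.9,
    random_state: int = 0,
) -> Embedding:
    """TF-IDF normalisation followed by truncated SVD (latent semantic
    indexing), the standard embedding for sparse binary chromatin matrices.

    TF is the entry over the cell total, IDF the number of cells over the
    number of cells hitting the region, combined as ``ln(1 + 1e4 * TF * IDF)``.
    Component signs follow a deterministic convention (largest-magnitude
    region loading positive).  Each component's Pearson correlation with log
    depth is reported, and the first component is dropped by default when
    |correlation| exceeds ``depth_corr_threshold`` — in binarised chromatin
    data it typically tracks sequencing depth rather than cell state.
    """
    X = fm.counts.copy().astype(float)
    if binarize:
        X.data = np.ones_like(X.data)
    depth = np.asarray(X.sum(axis=1)).ravel()
    if depth.sum() == 0:
        raise ValueError("all-zero matrix")
    keep_cells = depth > 0
    if not keep_cells.all():
        raise ValueError("cells with zero counts; filter before embedding")
    n_cells, n_regions = X.shape
    if min(n_cells, n_regions) <= d:
        raise ValueError(f"need more than d={d} cells and regions")
    tf = scipy.sparse.diags(1.0 / depth) @ X
    region_cells = np.asarray(X.sum(axis=0)).ravel()
    idf = np.zeros(n_regions)
    nz = region_cells > 0
    idf[nz] = n_cells / region_cells[nz]
    mat = tf @ scipy.sparse.diags(idf)
    mat.data = np.log1p(1e4 * mat.data)

    svd = TruncatedSVD(n_components=d, algorithm="arpack", random_state=random_state)
    coords = svd.fit_transform(mat)
    # deterministic sign: largest-|loading| region positive per component
    for k in range(d):
        j = int(np.argmax(np.abs(svd.components_[k])))
        if svd.components_[k, j] < 0:
            coords[:, k] *= -1.0
    logd = np.log(depth)
    if np.std(logd) > 0:
        corr = np.array(
            [
                scipy.stats.pearsonr(coords[:, k], logd)[0]
                if np.std(coords[:, k]) > 0
                else 0.0
                for k in range(d)
            ]
        )
    else:
        corr = np.zeros(d)
    dropped = False
    if drop_depth_component and abs(corr[0]) > depth_corr_threshold:
        coords, corr = coords[:, 1:], corr[1:]
        sv = svd.singular_values_[1:]
        dropped = True
    else:
        sv = svd.singular_values_
    return Embedding(list(fm.cells), coords, sv, corr, dropped)


def cluster_cells(
    coords: np.ndarray, k: int = 2, method: str = "hierarchical", seed: int = 0
) -> np.ndarray:
    """Cluster cells in embedding space into labels 0..k-1, deterministically.

    ``hierarchical`` is Ward agglomeration; ``kmeans`` is seeded k-means.
    Identical points with k > 1 yield an arbitrary but deterministic split.
    """
    if k > len(coords):
        raise ValueError("k exceeds number of cells")
    if k == 1:
        return np.zeros(len(coords), dtype=int)
    if method == "hierarchical":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(coords)
    if method == "kmeans":
        return KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(coords)
    raise ValueError(f"unknown method {method!r}")


def cluster_error_rate(labels, truth) -> float:
    """Misassigned fraction minimised over all label permutations (for k=2 this
    is min(err, 1-err)); invariant under relabelling of the predictions."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    pred_ids = np.unique(labels)
    true_ids = np.unique(truth)
    conf = np.zeros((len(pred_ids), len(true_ids)), dtype=int)
    for i, p in enumerate(pred_ids):
        for j, t in enumerate(true_ids):
            conf[i, j] = int(((labels == p) & (truth == t)).sum())
    rows, cols = linear_sum_assignment(-conf)
    return 1.0 - conf[rows, cols].sum() / len(labels)


def normalized_signal(
    fragments_by_modality: dict[str, pd.DataFrame],
    reference_peaks: pd.DataFrame,
    cells: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell, per-modality z-scored fraction of fragments in a reference
    peak set (the 'normalized signal' readout over e.g. a target protein's
    peaks).  Zero-depth cells are excluded (NaN)."""
    reference_peaks = merge_intervals(reference_peaks)
    if cells is None:
        shared = None
        for frags in fragments_by_modality.values():
            s = set(frags["cell"])
            shared = s if shared is None else shared & s
        cells = sorted(shared or [])
    index = list(cells)
    cols = {}
    for mod, frags in fragments_by_modality.items():
        mat = build_matrix(frags, reference_peaks, cells=cells, modality=mod)
        in_peaks = mat.depth  # counts within reference peaks
        total = frags.groupby("cell").size().reindex(mat.cells).fillna(0).to_numpy()
        frac = np.where(total > 0, in_peaks / np.maximum(total, 1), np.nan)
        mu, sd = np.nanmean(frac), np.nanstd(frac)
        cols[mod] = (frac - mu) / sd if sd > 0 else frac - mu
    return pd.DataFrame(cols, index=index)


def cramers_v(
    fragments_a: pd.DataFrame,
    fragments_b: pd.DataFrame,
    regions: pd.DataFrame,
    cells: list[str] | None = None,
) -> tuple[pd.Series, dict]:
    """Per-cell Cramér's V between two modalities' region occupancy.

    For each cell, every region contributes a (hit in A, hit in B) indicator
    pair; the resulting 2x2 table (a = both, b = A only, c = B only, d =
    neither) gives V = |ad - bc| / sqrt((a+b)(c+d)(a+c)(b+d)), the 2x2 form of
    sqrt(chi2/N).  Cells with a degenerate margin (a modality hitting no
    region, or every region) have undefined V; they are excluded and counted.

    Returns the per-cell series plus a summary dict with the median over
    defined cells and the exclusion count.
    """
    regions = merge_intervals(regions)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    if cells is None:
        cells = sorted(set(fragments_a["cell"]) & set(fragments_b["cell"]))
    xa = build_matrix(fragments_a, regions, cells=cells).counts
    xb = build_matrix(fragments_b, regions, cells=cells).counts
    A = (xa > 0).toarray()
    B = (xb > 0).toarray()
    n = A.shape[1]
    a = (A & B).sum(axis=1).astype(float)
    b = (A & ~B).sum(axis=1).astype(float)
    c = (~A & B).sum(axis=1).astype(float)
    d = n - a - b - c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.abs(a * d - b * c) / np.sqrt(denom)
    v[denom == 0] = np.nan
    series = pd.Series(v, index=cells, name="cramers_v")
    defined = series.dropna()
    summary = {
        "median": float(defined.median()) if len(defined) else float("nan"),
        "n_cells": len(defined),
        "n_excluded": int(series.isna().sum()),
    }
    return series, summary


def random_regions(
    chrom_sizes: dict[str, int],
    template: pd.DataFrame,
    seed: int,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Non-overlapping random regions matching the template's count and width
    multiset, placed uniformly on the genome — the null control for
    co-enrichment statistics."""
    if template.empty:
        raise ValueError("template region set is empty")
    rng = np.random.default_rng(seed)
    widths = template["end"].to_numpy() - template["start"].to_numpy()
    widths = widths[rng.permutation(len(widths))]
    chroms = sorted(chrom_sizes)
    lens = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for w in widths:
        ok = False
        for _ in range(max_tries):
            ci = rng.choice(len(chroms), p=lens / lens.sum())
            chrom = chroms[ci]
            room = chrom_sizes[chrom] - int(w)
            if room <= 0:
                continue
            start = int(rng.integers(0, room + 1))
            end = start + int(w)
            if all(e <= start or s >= end for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                rows.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise ValueError("could not place random regions without overlap")
    return sort_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@dataclass
class PeakPartition:
    """Specific/shared partition of two peak sets; shared peaks are reported in
    each set's own coordinates, so |A| = |a_specific| + |a_shared| and
    likewise for B."""

    a_specific: pd.DataFrame
    a_shared: pd.DataFrame
    b_specific: pd.DataFrame
    b_shared: pd.DataFrame


def specific_shared_peaks(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> PeakPartition:
    """Partition two internally disjoint peak sets by >= 1 base overlap."""
    from ._intervals import overlaps_any

    a = sort_intervals(peaks_a)
    b = sort_intervals(peaks_b)
    if len(b):
        a_hit = overlaps_any(a, b)
    else:
        a_hit = np.zeros(len(a), dtype=bool)
    if len(a):
        b_hit = overlaps_any(b, a)
    else:
        b_hit = np.zeros(len(b), dtype=bool)
    return PeakPartition(
        a_specific=a[~a_hit].reset_index(drop=True),
        a_shared=a[a_hit].reset_index(drop=True),
        b_specific=b[~b_hit].reset_index(drop=True),
        b_shared=b[b_hit].reset_index(drop=True),
    )


def naive_peak_call(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_width: int = 500,
    q: float = 0.01,
) -> pd.DataFrame:
    """Naive fixed-bin Poisson peak caller (plumbing, not a MACS replacement).

    Fragment midpoints are binned genome-wide; each bin count is tested
    against Poisson(global mean) one-sided, Benjamini–Hochberg corrected
    across bins, and significant adjacent bins are merged into peaks.
    """
    if fragments.empty:
        raise ValueError("no fragments")
    bins = make_bins(chrom_sizes, bin_width)
    mid = (fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2
    counts = np.zeros(len(bins), dtype=np.int64)
    offsets = {}
    pos = 0
    for chrom in sorted(chrom_sizes):
        nb = int(np.ceil(chrom_sizes[chrom] / bin_width))
        offsets[chrom] = pos
        pos += nb
    for chrom, g in fragments.groupby("chrom"):
        if chrom not in offsets:
            continue
        m = (g["start"].to_numpy() + g["end"].to_numpy()) // 2
        b = np.clip(m // bin_width, 0, int(np.ceil(chrom_sizes[chrom] / bin_width)) - 1)
        np.add.at(counts, offsets[chrom] + b, 1)
    lam = counts.mean()
    pvals = scipy.stats.poisson.sf(counts - 1, lam)  # P(X >= count)
    qvals = scipy.stats.false_discovery_control(pvals)
    sig = qvals < q
    bins = bins.assign(sig=sig)
    peaks = []
    for chrom, g in bins.groupby("chrom", sort=True):
        g = g.sort_values("start")
        cur = None
        for _, row in g[g["sig"]].iterrows():
            if cur is not None and row["start"] == cur[2]:
                cur[2] = row["end"]
            else:
                if cur is not None:
                    peaks.append(tuple(cur))
                cur = [chrom, row["start"], row["end"]]
        if cur is not None:
            peaks.append(tuple(cur))
    return pd.DataFrame(peaks, columns=["chrom", "start", "end"])
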