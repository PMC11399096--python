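"""Pseudotime ordering, metacell aggregation and region-trajectory clustering.

The pseudotime here is deliberately simple: the assayed transitions are a
single root-to-terminal progression (e.g. epithelial to intermediate-EMT), so
each cell is scored by its scalar projection onto the axis joining the root
and terminal cluster centroids in embedding space, rescaled to [0, 1].  An
externally computed pseudotime vector can be substituted anywhere a
:class:`Trajectory` is accepted.

Metacells aggregate a fixed number of pseudotime-adjacent cells (default 50)
to stabilise sparse per-cell signal; columns are depth-normalised to counts
per million and rows z-scored before smoothing and clustering region
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .multimodal import FeatureMatrix

__all__ = [
    "Trajectory",
    "MetacellMatrix",
    "pseudotime",
    "make_metacells",
    "smooth",
    "cluster_regions",
    "RegionClusters",
]


@dataclass
class Trajectory:
    cells: list[str]
    t: np.ndarray  # in [0, 1]
    root_label: int | str | None = None
    terminal_label: int | str | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell": self.cells, "t": self.t})


def pseudotime(
    coords: np.ndarray,
    cells: list[str],
    labels,
    root_label,
    terminal_label,
) -> Trajectory:
    """Centroid-axis pseudotime: scalar projection of every cell onto the unit
    vector from the root cluster centroid to the terminal cluster centroid,
    min-max rescaled to [0, 1].  Swapping root and terminal maps t -> 1 - t.
    """
    labels = np.asarray(labels)
    root = coords[labels == root_label]
    term = coords[labels == terminal_label]
    if len(root) == 0 or len(term) == 0:
        raise ValueError("root or terminal label absent")
    axis = term.mean(axis=0) - root.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("root and terminal centroids coincide")
    proj = coords @ (axis / norm)
    t = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-300)
    return Trajectory(list(cells), t, root_label, terminal_label)


@dataclass
class MetacellMatrix:
    """Regions x metacells matrix: raw sums, CPM + row-z normalised values,
    per-metacell mean pseudotime and sizes.  The trailing metacell may hold
    fewer than m cells; ``last_partial`` flags it."""

    regions: pd.DataFrame
    raw: np.ndarray  # regions x metacells, raw summed counts
    z: np.ndarray  # CPM + row z-score
    mean_t: np.ndarray
    sizes: np.ndarray
    last_partial: bool


def make_metacells(
    fm: FeatureMatrix, trajectory: Trajectory, m: int = 50
) -> MetacellMatrix:
    """Aggregate consecutive pseudotime-ordered cells into metacells of m cells.

    Cells are sorted by (t, cell key) — the key breaks ties deterministically —
    then summed in consecutive blocks of m.  Columns are normalised to counts
    per million and rows z-scored (zero-variance rows stay 0).
    """
    if m > len(fm.cells):
        raise ValueError(f"metacell size {m} exceeds {len(fm.cells)} cells")
    order_frame = pd.DataFrame(
        {"cell": trajectory.cells, "t": trajectory.t}
    ).sort_values(["t", "cell"], kind="mergesort")
    cell_row = {c: i for i, c in enumerate(fm.cells)}
    rows = order_frame["cell"].map(cell_row)
    if rows.isna().any():
        raise ValueError("trajectory contains cells absent from the matrix")
    rows = rows.to_numpy(dtype=int)
    t_sorted = order_frame["t"].to_numpy()
    X = fm.counts[rows].toarray().T  # regions x cells, in pseudotime order
    n = X.shape[1]
    n_meta = int(np.ceil(n / m))
    raw = np.zeros((X.shape[0], n_meta))
    mean_t = np.zeros(n_meta)
    sizes = np.zeros(n_meta, dtype=int)
    for j in range(n_meta):
        sl = slice(j * m, min((j + 1) * m, n))
        raw[:, j] = X[:, sl].sum(axis=1)
        mean_t[j] = t_sorted[sl].mean()
        sizes[j] = sl.stop - sl.start
    col_tot = raw.sum(axis=0)
    cpm = raw / np.maximum(col_tot, 1) * 1e6
    mu = cpm.mean(axis=1, keepdims=True)
    sd = cpm.std(axis=1, keepdims=True)
    z = np.divide(cpm - mu, sd, out=np.zeros_like(cpm), where=sd > 0)
    return MetacellMatrix(fm.regions, raw, z, mean_t, sizes, bool(n % m))


def smooth(matrix: np.ndarray, window: int = 1) -> np.ndarray:
    """Centred moving average over columns with half-width ``window``; edge
    columns average over whatever neighbours exist.  ``window=0`` is the
    identity; constant rows are unchanged for any window."""
    if window < 0:
        raise ValueError("window must be >= 0")
    if window == 0:
        return matrix.copy()
    n = matrix.shape[1]
    out = np.empty_like(matrix, dtype=float)
    for j in range(n):
        a, b = max(0, j - window), min(n, j + window + 1)
        out[:, j] = matrix[:, a:b].mean(axis=1)
    return out


@dataclass
class RegionClusters:
    labels: np.ndarray  # per region, renumbered by peak position along t
    mean_curves: np.ndarray  # k x metacells
    sd_curves: np.ndarray
    fractions: np.ndarray  # per cluster, sums to 1


def cluster_regions(
    z: np.ndarray,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
) -> RegionClusters:
    """Cluster region trajectories (rows of a z-scored regions x metacells
    matrix) into k groups.

    Cluster IDs are renumbered by the pseudotime position of each cluster's
    mean-curve maximum, so cluster 0 peaks earliest — a stable naming
    independent of the clusterer's arbitrary label order.
    """
    if k > z.shape[0]:
        raise ValueError("k exceeds number of regions")
    if method == "kmeans":
        raw_labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(z)
    elif method == "hierarchical":
        raw_labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(z)
    else:
        raise ValueError(f"unknown method {method!r}")
    means = np.vstack([z[raw_labels == c].mean(axis=0) for c in range(k)])
    order = np.argsort([np.argmax(means[c]) for c in range(k)], kind="stable")
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw_labels])
    mean_curves = means[order]
    sd_curves = np.vstack([z[labels == c].std(axis=0) for c in range(k)])
    fractions = np.array([(labels == c).mean() for c in range(k)])
    return RegionClusters(labels, mean_curves, sd_curves, fractions)
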