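"""Spatial single-cell analysis: transcript assignment, clustering, annotation.

Transcripts are assigned to segmented cells by label-mask lookup with a
bounded nearest-label expansion (default 8 px, mirroring the segmentation's
cell-expansion setting): a transcript landing on a labeled pixel belongs to
that cell; one in the background goes to the nearest labeled pixel within
the expansion radius (ties broken toward the lowest label), else it stays
unassigned.  No cell is dropped by transcript count.

Clustering follows the panel workflow: per-cell log normalization, the 10
most variable transcripts, PCA to 5 components, k-means with the number of
clusters chosen by mean silhouette.  Clusters are annotated by marker-set
mean z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io_formats import GeneSet, LabelMask, SpatialTranscriptTable

__all__ = [
    "CellTable",
    "log_normalize_cells",
    "assign_transcripts",
    "cluster_cells",
    "annotate_clusters",
]


@dataclass
class CellTable:
    """Per-cell panel counts plus annotations.

    ``counts``: cells x genes integer frame indexed by mask label.
    ``meta``: per-cell centroid, total_count and, once computed, cluster,
    cell_type, condition and class.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    unassigned: int = 0
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the cell index")
        if not self.genes:
            self.genes = list(self.counts.columns)
        tot = self.counts.sum(axis=1)
        if "total_count" not in self.meta.columns:
            self.meta["total_count"] = tot
        elif not np.array_equal(self.meta["total_count"].to_numpy(), tot.to_numpy()):
            raise ValueError("meta total_count inconsistent with counts")

    @property
    def n_cells(self) -> int:
        return len(self.counts)


def log_normalize_cells(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Per-cell depth normalization: log2(1 + scale * count / total)."""
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    totals[totals == 0] = 1.0
    return np.log2(1.0 + scale * counts.div(totals, axis=0))


def assign_transcripts(
    t: SpatialTranscriptTable,
    mask: LabelMask,
    expansion_px: float = 8.0,
) -> CellTable:
    """Count transcripts per segmented cell.

    Every mask label becomes a cell (zero-count cells included); centroids
    are label-pixel means.  Out-of-bounds transcripts are unassigned with a
    warning.  The returned table satisfies assigned + unassigned == len(t).
    """
    labels_all = mask.labels()
    if labels_all.size == 0:
        raise ValueError("label mask contains no cells")
    h, w = mask.shape
    x = t.data["x"].to_numpy(dtype=float)
    y = t.data["y"].to_numpy(dtype=float)
    gene = t.data["gene"].to_numpy()
    col = np.floor(x).astype(int)
    row = np.floor(y).astype(int)
    in_bounds = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    if not in_bounds.all():
        warnings.warn(
            f"{int((~in_bounds).sum())} transcripts outside the mask bounds "
            "left unassigned",
            stacklevel=2,
        )
    assigned = np.zeros(len(t), dtype=np.int64)
    assigned[in_bounds] = mask.grid[row[in_bounds], col[in_bounds]]

    todo = in_bounds & (assigned == 0)
    if expansion_px > 0 and todo.any():
        lab_r, lab_c = np.nonzero(mask.grid)
        lab_val = mask.grid[lab_r, lab_c]
        tree = scipy.spatial.cKDTree(np.column_stack([lab_r, lab_c]))
        pts = np.column_stack([row[todo], col[todo]]).astype(float)
        k = int(min(16, len(lab_r)))
        dist, idx = tree.query(pts, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        # among neighbours tied at the minimal distance, take the lowest label
        dmin = dist[:, 0]
        within = dist <= np.minimum(dmin, expansion_px)[:, None] + 1e-9
        within &= dist <= expansion_px + 1e-9
        cand = np.where(within, lab_val[idx], np.iinfo(np.int64).max)
        best = cand.min(axis=1)
        best[dmin > expansion_px + 1e-9] = 0
        best[best == np.iinfo(np.int64).max] = 0
        assigned[np.flatnonzero(todo)] = best

    genes = sorted(pd.unique(gene))
    counts = np.zeros((labels_all.size, len(genes)), dtype=np.int64)
    hit = assigned > 0
    if hit.any():
        li = np.searchsorted(labels_all, assigned[hit])
        gi = pd.Categorical(gene[hit], categories=genes).codes
        np.add.at(counts, (li, gi), 1)
    unassigned = int((~hit).sum())

    rr, cc = np.nonzero(mask.grid)
    vals = mask.grid[rr, cc]
    npix = np.bincount(vals)[labels_all]
    cx = np.bincount(vals, weights=cc)[labels_all] / npix + 0.5
    cy = np.bincount(vals, weights=rr)[labels_all] / npix + 0.5
    cents = np.column_stack([cx, cy])  # (x, y)
    counts_df = pd.DataFrame(counts, index=pd.Index(labels_all, name="cell_id"),
                             columns=genes)
    meta = pd.DataFrame(
        {"x": cents[:, 0], "y": cents[:, 1]},
        index=counts_df.index,
    )
    return CellTable(counts=counts_df, meta=meta, unassigned=unassigned, genes=genes)


def cluster_cells(
    ct: CellTable,
    n_var_genes: int = 10,
    n_pcs: int = 5,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
) -> pd.Series:
    """K-means cluster ids on PCA of the most variable transcripts.

    Cells are depth log-normalized; the ``n_var_genes`` highest-variance
    genes feed a ``n_pcs``-component PCA; k is chosen over ``k_range`` by
    maximal mean silhouette (ties toward smaller k).  Deterministic given
    ``seed``.  Stores the result in ``ct.meta['cluster']`` and returns it.
    """
    if ct.n_cells < k_range[0]:
        raise ValueError(f"need at least {k_range[0]} cells to cluster")
    lognorm = log_normalize_cells(ct.counts)
    variances = lognorm.var(axis=0)
    if len(variances) < n_var_genes:
        warnings.warn(
            f"only {len(variances)} genes available; using all of them", stacklevel=2
        )
        n_var_genes = len(variances)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_var_genes]
    X = lognorm[sorted(top)].to_numpy()
    n_pcs_eff = int(min(n_pcs, X.shape[1], max(1, ct.n_cells - 1)))
    pcs = PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(X)
    best: tuple[float, int, np.ndarray] | None = None
    for k in range(k_range[0], min(k_range[1], ct.n_cells - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(pcs)
        if len(np.unique(lab)) < 2:
            continue
        score = silhouette_score(pcs, lab)
        if best is None or score > best[0] + 1e-12:
            best = (score, k, lab)
    if best is None:
        raise ValueError("clustering failed for every k in range")
    out = pd.Series(best[2], index=ct.counts.index, name="cluster")
    ct.meta["cluster"] = out
    return out


def annotate_clusters(
    ct: CellTable,
    marker_sets: list[GeneSet],
    min_margin: float = 0.1,
) -> pd.Series:
    """Assign each cluster the cell type whose markers score highest.

    Per cluster the score of a type is the mean (over its panel-resident
    markers and the cluster's cells) z-scored log-normalized expression; a
    winning margin below ``min_margin`` yields type "unknown".  Stores the
    per-cell types in ``ct.meta['cell_type']`` and returns them.
    """
    if "cluster" not in ct.meta.columns:
        raise ValueError("run cluster_cells before annotate_clusters")
    lognorm = log_normalize_cells(ct.counts)
    sd = lognorm.std(axis=0).replace(0.0, 1.0)
    z = (lognorm - lognorm.mean(axis=0)) / sd
    usable: dict[str, list[str]] = {}
    for s in marker_sets:
        present = [g for g in s.members if g in z.columns]
        if not present:
            warnings.warn(
                f"marker set '{s.name}' shares no genes with the panel; "
                "type unavailable",
                stacklevel=2,
            )
            continue
        usable[s.name] = present
    if not usable:
        raise ValueError("no marker set overlaps the panel")
    clusters = ct.meta["cluster"]
    type_per_cluster: dict[int, str] = {}
    for cl in sorted(clusters.unique()):
        cells = clusters.index[clusters == cl]
        scores = pd.Series(
            {t: float(z.loc[cells, genes].to_numpy().mean()) for t, genes in usable.items()}
        ).sort_values(ascending=False)
        if len(scores) > 1 and scores.iloc[0] - scores.iloc[1] < min_margin:
            type_per_cluster[cl] = "unknown"
        else:
            type_per_cluster[cl] = scores.index[0]
    out = clusters.map(type_per_cluster).rename("cell_type")
    ct.meta["cell_type"] = out
    return out
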