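"""Minimal lineage ordering, pseudotime binning, and expression-wave statistics.

Given a precomputed 2D embedding and cluster labels, cells are ordered along
the unique path between a start and an end cluster in the minimum spanning
tree of cluster centroids; each cell on the path's clusters is projected onto
the piecewise-linear centroid polyline and its arc-length position rescaled
to [0, 1].  Downstream, gene expression along pseudotime is LOESS-fitted
(local linear, tricube weights), evaluated at the midpoints of 30 pseudotime
bins per developmental stage, and normalized per gene to a global maximum of
1 across all stages.  The wave-order statistic then asks whether the early
(Onecut), intermediate (Pou2f2/Zfhx), and late (Nfi/Neurod) TF groups peak in
strictly increasing pseudotime bins at every stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "LineagePath",
    "order_cells",
    "loess_smooth",
    "bin_and_normalize",
    "wave_order",
    "WaveOrderResult",
    "DEFAULT_GENE_GROUPS",
    "bin_midpoints",
]

N_BINS_DEFAULT = 30

DEFAULT_GENE_GROUPS: dict[str, tuple[str, ...]] = {
    "early": ("Onecut2",),
    "intermediate": ("Pou2f2", "Zfhx3"),
    "late": ("Nfia", "Nfib", "Neurod2"),
}


@dataclass
class LineagePath:
    """One ordered lineage: cluster sequence, per-cell pseudotime in [0, 1]."""

    name: str
    cluster_sequence: list
    pseudotime: pd.Series  # indexed by cell id, cells on path clusters only
    excluded: bool = False
    exclusion_reason: str = ""
    self_intersecting: bool = False


def bin_midpoints(n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Midpoints of ``n_bins`` equal pseudotime bins on [0, 1]."""
    return (np.arange(n_bins) + 0.5) / n_bins


def _mst_path(centroids: np.ndarray, start: int, end: int) -> list[int]:
    """Unique path from start to end in the Euclidean MST of the centroids."""
    d = cdist(centroids, centroids)
    mst = minimum_spanning_tree(d).toarray()
    adj = (mst > 0) | (mst.T > 0)
    if not adj.any() and len(centroids) > 1:
        raise ValueError("could not build a spanning tree over cluster centroids")
    # BFS from start recording parents
    parent = {start: None}
    queue = [start]
    while queue:
        node = queue.pop(0)
        for nxt in np.where(adj[node])[0]:
            if nxt not in parent:
                parent[int(nxt)] = node
                queue.append(int(nxt))
    if end not in parent:
        raise ValueError(
            f"clusters {start} and {end} fall in disconnected embedding components"
        )
    path = [end]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _polyline_self_intersects(points: np.ndarray) -> bool:
    n = len(points) - 1
    for i in range(n):
        for j in range(i + 2, n):  # skip adjacent segments sharing a vertex
            if _segments_intersect(points[i], points[i + 1], points[j], points[j + 1]):
                return True
    return False


def order_cells(
    embedding: pd.DataFrame,
    clusters: pd.Series,
    start_cluster,
    end_cluster=None,
    exclusion_list: tuple[str, ...] = (),
    name: str | None = None,
) -> LineagePath:
    """Order cells along the MST path between two cluster centroids.

    ``embedding`` is cells x (x, y); ``clusters`` assigns every cell to a
    cluster.  When ``end_cluster`` is omitted, the cluster whose centroid is
    farthest from the start centroid is used.  Cells belonging to clusters on
    the path are projected onto the piecewise-linear centroid path; their
    arc-length positions are rescaled to [0, 1].  Paths whose name appears in
    ``exclusion_list`` are marked excluded (skipped downstream).  A
    self-intersection of the centroid polyline is advisory only: it sets
    ``self_intersecting`` and warns, but never auto-excludes.
    """
    if not embedding.index.equals(clusters.index):
        clusters = clusters.reindex(embedding.index)
    if clusters.isna().any():
        raise ValueError("clusters must cover all cells in the embedding")
    labels = sorted(pd.unique(clusters))
    if start_cluster not in labels:
        raise KeyError(f"unknown start cluster {start_cluster!r}")
    centroids = np.vstack(
        [embedding[clusters == lab].mean(axis=0).to_numpy() for lab in labels]
    )
    s = labels.index(start_cluster)
    if end_cluster is None:
        dists = np.linalg.norm(centroids - centroids[s], axis=1)
        e = int(np.argmax(dists))
        end_cluster = labels[e]
    else:
        if end_cluster not in labels:
            raise KeyError(f"unknown end cluster {end_cluster!r}")
        e = labels.index(end_cluster)
    if s == e:
        raise ValueError("start and end cluster must differ")

    path_idx = _mst_path(centroids, s, e)
    seq = [labels[i] for i in path_idx]
    pts = centroids[path_idx]
    path_name = name or f"{start_cluster}->{end_cluster}"

    if _polyline_self_intersects(pts):
        warnings.warn(
            f"lineage path {path_name} self-intersects in the embedding; "
            "inspect before trusting downstream ordering",
            stacklevel=2,
        )
        self_x = True
    else:
        self_x = False

    seg_vec = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    on_path = clusters.isin(seq)
    cells = embedding[on_path].to_numpy(dtype=float)

    # project every cell onto its nearest polyline segment
    arc = np.empty(len(cells))
    for i, p in enumerate(cells):
        best_d, best_a = np.inf, 0.0
        for k in range(len(seg_vec)):
            v = seg_vec[k]
            L2 = seg_len[k] ** 2
            tt = 0.0 if L2 == 0 else np.clip(np.dot(p - pts[k], v) / L2, 0.0, 1.0)
            proj = pts[k] + tt * v
            d = np.linalg.norm(p - proj)
            if d < best_d:
                best_d, best_a = d, cum[k] + tt * seg_len[k]
        arc[i] = best_a
    ptime = arc / total if total > 0 else np.zeros_like(arc)

    path = LineagePath(
        name=path_name,
        cluster_sequence=seq,
        pseudotime=pd.Series(ptime, index=embedding.index[on_path], name="pseudotime"),
        self_intersecting=self_x,
    )
    if path_name in exclusion_list:
        path.excluded = True
        path.exclusion_reason = "listed in exclusion_list"
    return path


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    grid: np.ndarray | None = None,
    n_bins: int = N_BINS_DEFAULT,
) -> np.ndarray:
    """LOESS fit (local linear, tricube weights) evaluated at bin midpoints.

    ``span`` is the fraction of points in each local window.  With too few
    points for a meaningful local window (< 4 in the window) the fit falls
    back to a global linear least-squares line (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("loess_smooth needs >= 10 points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if grid is None:
        grid = bin_midpoints(n_bins) * (x.max() - x.min()) + x.min()
    if span * len(x) < 4:
        logger.warning("loess window too small (span*n < 4); global linear fallback")
        coef = np.polyfit(x, y, 1)
        return np.polyval(coef, grid)
    fitted = lowess(y, x, frac=span, it=0, xvals=grid)
    return np.asarray(fitted, dtype=float)


def bin_and_normalize(
    paths_per_stage: dict[str, LineagePath],
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    n_bins: int = N_BINS_DEFAULT,
    span: float = 0.75,
) -> dict[str, pd.DataFrame]:
    """Per-stage binned expression, normalized per gene across all stages.

    For each stage's (non-excluded) lineage, every gene's expression is
    LOESS-fitted against pseudotime and evaluated at the ``n_bins`` bin
    midpoints; fits are floored at 0.  Each gene row is then divided by its
    maximum over all stages' bins, so the global per-gene maximum is exactly
    1 (all-zero genes stay zero, flagged in the log).
    """
    usable = {s: p for s, p in paths_per_stage.items() if not p.excluded}
    if not usable:
        raise ValueError("no non-excluded lineage path available")
    genes = list(genes) if genes is not None else list(expr.index)
    binned: dict[str, np.ndarray] = {}
    for stage, path in usable.items():
        cells = [c for c in path.pseudotime.index if c in expr.columns]
        pt = path.pseudotime.loc[cells].to_numpy()
        grid = bin_midpoints(n_bins)
        mat = np.empty((len(genes), n_bins))
        for i, g in enumerate(genes):
            mat[i] = loess_smooth(pt, expr.loc[g, cells].to_numpy(), span=span, grid=grid)
        binned[stage] = np.clip(mat, 0.0, None)
    gmax = np.max(np.stack(list(binned.values())), axis=(0, 2))
    zero = gmax == 0
    if zero.any():
        logger.warning("bin_and_normalize: %d all-zero genes", int(zero.sum()))
    gmax[zero] = 1.0
    return {
        stage: pd.DataFrame(
            mat / gmax[:, None], index=genes, columns=[f"bin{b:02d}" for b in range(n_bins)]
        )
        for stage, mat in binned.items()
    }


@dataclass
class WaveOrderResult:
    """Outcome of the early < intermediate < late peak-order test."""

    verdict: bool
    peak_table: pd.DataFrame  # stage x group median peak bins
    per_stage: dict[str, bool | None] = field(default_factory=dict)
    flagged_stages: list[str] = field(default_factory=list)


def wave_order(
    binned: dict[str, pd.DataFrame],
    gene_groups: dict[str, tuple[str, ...]] | None = None,
) -> WaveOrderResult:
    """Test whether TF groups peak in strictly increasing pseudotime order.

    Per stage, each group's peak is the median argmax bin over its expressed
    genes (row max > 0).  The stage verdict is True iff the group peaks are
    strictly increasing in the given group order; stages where some group has
    no expressed gene are flagged and do not contribute.  The overall verdict
    is True iff every contributing stage passes (and at least one does).
    """
    groups = gene_groups or DEFAULT_GENE_GROUPS
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("every gene group must be nonempty")
    rows = []
    per_stage: dict[str, bool | None] = {}
    flagged = []
    for stage, mat in binned.items():
        peaks: dict[str, float] = {}
        ok = True
        for gname, members in groups.items():
            present = [g for g in members if g in mat.index]
            expressed = [g for g in present if mat.loc[g].max() > 0]
            if not expressed:
                ok = False
                peaks[gname] = np.nan
                continue
            peaks[gname] = float(
                np.median([int(np.argmax(mat.loc[g].to_numpy())) for g in expressed])
            )
        rows.append({"stage": stage, **peaks})
        if not ok:
            per_stage[stage] = None
            flagged.append(stage)
            continue
        vals = [peaks[g] for g in groups]
        per_stage[stage] = all(a < b for a, b in zip(vals, vals[1:]))
    contributing = [v for v in per_stage.values() if v is not None]
    verdict = bool(contributing) and all(contributing)
    return WaveOrderResult(
        verdict=verdict,
        peak_table=pd.DataFrame(rows).set_index("stage"),
        per_stage=per_stage,
        flagged_stages=flagged,
    )
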