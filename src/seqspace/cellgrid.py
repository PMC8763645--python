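"""Cell-level quantification: spot assignment, QC, normalization, graphs.

Decoded mRNA spots are counted per segmented cell, segments that look like
empty space are removed (over-large square-root area, one-sided Z test with
Benjamini-Hochberg control), low-content cells are dropped, counts are
log2-normalized with unit-mean size factors, and the polygon-expansion
neighborhood graph is built per (embryo, z-slice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import shapely
from scipy.stats import norm
from shapely.geometry import Polygon
from shapely.strtree import STRtree
from statsmodels.stats.multitest import multipletests

from .segmentation import SegmentationSet

__all__ = ["assign_spots", "qc_filter", "normalize", "build_graph", "NeighborhoodGraph"]


def assign_spots(spots: pd.DataFrame, cells: SegmentationSet, genes=None) -> ad.AnnData:
    """Count decoded spots per segmented cell.

    A spot is counted for the unique cell whose polygon covers it (the
    boundary counts as inside; a boundary tie goes to the lower cell_id).
    Spots outside all polygons are discarded and tallied in
    ``uns['n_discarded']``.

    Parameters
    ----------
    spots
        Decoded spot table with columns ``gene, x, y, z_slice, fov, embryo``.
    genes
        Column order of the returned matrix; defaults to the sorted genes
        present in ``spots``.
    """
    if genes is None:
        genes = sorted(spots["gene"].unique())
    gene_idx = {g: i for i, g in enumerate(genes)}
    cell_fovs = {key for key, _ in cells.fovs()}
    if len(spots):
        spot_fovs = {
            tuple(k) for k in spots[["embryo", "z_slice", "fov"]].drop_duplicates().itertuples(index=False)
        }
        orphans = sorted(spot_fovs - cell_fovs)
        if orphans:
            raise ValueError(f"spots reference FOVs with no segmentation: {orphans}")

    order = [c.cell_id for c in cells]
    row_of = {cid: i for i, cid in enumerate(order)}
    X = np.zeros((len(order), len(genes)), dtype=np.int64)
    n_discarded = 0
    for key, fov_cells in cells.fovs():
        mask = (
            (spots["embryo"] == key[0])
            & (spots["z_slice"] == key[1])
            & (spots["fov"] == key[2])
        )
        sub = spots[mask]
        if not len(sub):
            continue
        polys = [c.polygon for c in fov_cells]
        ids = [c.cell_id for c in fov_cells]
        tree = STRtree(polys)
        xs = sub["x"].to_numpy()
        ys = sub["y"].to_numpy()
        gs = sub["gene"].to_numpy()
        pts = shapely.points(xs, ys)
        hit_poly, hit_pt = {}, {}
        cand = tree.query(pts, predicate="intersects")
        # cand: 2 x m array of (point index, polygon index)
        for pi, ci in zip(*cand):
            prev = hit_poly.get(pi)
            if prev is None or ids[ci] < prev:
                hit_poly[pi] = ids[ci]
        for si in range(len(sub)):
            cid = hit_poly.get(si)
            g = gs[si]
            if cid is None or g not in gene_idx:
                n_discarded += 1
                continue
            X[row_of[cid], gene_idx[g]] += 1

    meta = cells.to_frame().loc[order].astype({"z_slice": int, "fov": int})
    meta.index = meta.index.map(str)
    adata = ad.AnnData(
        X=X,
        obs=meta,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["n_discarded"] = int(n_discarded)
    return adata


def qc_filter(
    cells: SegmentationSet,
    counts: ad.AnnData,
    area_fdr: float = 0.01,
    min_spots: int = 10,
    min_genes: int = 5,
):
    """Remove empty-space segments and low-content cells.

    First, segments whose square-root area is significantly larger than the
    per-(embryo, z-slice) mean (one-sided upper-tail Z test, BH-adjusted at
    ``area_fdr`` across all segments) are removed as likely empty space.
    Then cells with fewer than ``min_spots`` molecules or ``min_genes``
    distinct genes are dropped.

    Returns the filtered ``(SegmentationSet, AnnData)``.
    """
    seg_ids = [c.cell_id for c in cells]
    pvals = pd.Series(1.0, index=seg_ids)
    for (embryo, z), stratum in cells.strata():
        if len(stratum) < 3:
            warnings.warn(
                f"fewer than 3 segments in stratum ({embryo}, z={z}); area test skipped"
            )
            continue
        s = np.sqrt([c.area for c in stratum])
        sd = s.std(ddof=1)
        if sd == 0:
            continue
        zscores = (s - s.mean()) / sd
        p = norm.sf(zscores)
        for c, pv in zip(stratum, p):
            pvals[c.cell_id] = pv
    reject, *_ = multipletests(pvals.to_numpy(), alpha=area_fdr, method="fdr_bh")[:1]
    flagged = {cid for cid, r in zip(pvals.index, reject) if r}

    keep_ids = [cid for cid in seg_ids if cid not in flagged]
    obs_ids = [str(cid) for cid in keep_ids]
    sub = counts[obs_ids]
    totals = np.asarray(sub.X).sum(axis=1)
    n_genes = (np.asarray(sub.X) > 0).sum(axis=1)
    ok = (totals >= min_spots) & (n_genes >= min_genes)
    final_ids = [cid for cid, k in zip(keep_ids, ok) if k]
    filtered = counts[[str(cid) for cid in final_ids]].copy()
    filtered.uns["n_flagged_area"] = len(flagged)
    filtered.uns["n_low_content"] = int((~ok).sum())
    return cells.subset(final_ids), filtered


def normalize(counts: ad.AnnData, exclude_genes=()) -> ad.AnnData:
    """Log2-normalize counts with unit-mean size factors.

    Size factors are proportional to each cell's total molecule count over
    the non-excluded genes (the sex-specific gene is excluded upstream of
    cell typing), rescaled to unit mean.  Values are
    ``log2(count / size_factor + 1)``; excluded genes are still normalized
    with the same size factors.
    """
    X = np.asarray(counts.X, dtype=float)
    keep = ~counts.var_names.isin(list(exclude_genes))
    totals = X[:, keep].sum(axis=1)
    if (totals <= 0).any():
        bad = counts.obs_names[totals <= 0].tolist()
        raise ValueError(
            f"cells with zero total over non-excluded genes (run qc_filter first): {bad[:5]}"
        )
    sf = totals / totals.mean()
    out = counts.copy()
    out.obs["size_factor"] = sf
    out.layers["lognorm"] = np.log2(X / sf[:, None] + 1.0)
    return out


@dataclass
class NeighborhoodGraph:
    """Per-(embryo, z-slice) undirected cell adjacency with path lengths."""

    graphs: dict = field(default_factory=dict)  # (embryo, z) -> nx.Graph

    def graph(self, embryo, z_slice) -> nx.Graph:
        return self.graphs[(embryo, z_slice)]

    def distance(self, embryo, z_slice, j, k):
        """Shortest-path length D(j, k); None when unreachable."""
        try:
            return nx.shortest_path_length(self.graphs[(embryo, z_slice)], j, k)
        except nx.NetworkXNoPath:
            return None

    def distances_from(self, embryo, z_slice, source) -> dict:
        return nx.single_source_shortest_path_length(self.graphs[(embryo, z_slice)], source)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"embryo": e, "z_slice": z, "cell_a": min(a, b), "cell_b": max(a, b)}
            for (e, z), g in sorted(self.graphs.items())
            for a, b in g.edges
        ]
        return pd.DataFrame(rows, columns=["embryo", "z_slice", "cell_a", "cell_b"])


def _expand_polygon(vertices: np.ndarray, expansion: float) -> Polygon:
    center = vertices.mean(axis=0)
    return Polygon(center + expansion * (vertices - center))


def build_graph(cells: SegmentationSet, expansion: float = 1.3) -> NeighborhoodGraph:
    """Polygon-expansion neighborhood graph, per (embryo, z-slice).

    Each cell's polygon is expanded by moving every vertex away from the
    polygon center (arithmetic mean of the vertices) along the center-vertex
    ray by ``expansion``.  Cells j and k are adjacent iff any original
    vertex of one lies inside the other's expanded polygon (either
    direction suffices, so the graph is undirected).
    """
    if expansion < 1:
        raise ValueError("expansion must be >= 1")
    result = NeighborhoodGraph()
    for (embryo, z), stratum in cells.strata():
        usable = []
        for c in stratum:
            if len(c.vertices) < 3:
                warnings.warn(f"cell {c.cell_id} has a degenerate polygon; skipped")
                continue
            usable.append(c)
        g = nx.Graph()
        g.add_nodes_from(c.cell_id for c in usable)
        expanded = [_expand_polygon(c.vertices, expansion) for c in usable]
        tree = STRtree(expanded)
        for i, c in enumerate(usable):
            pts = shapely.points(c.vertices[:, 0], c.vertices[:, 1])
            cand = tree.query(pts, predicate="intersects")
            for _, j in zip(*cand):
                if j == i:
                    continue
                g.add_edge(c.cell_id, usable[j].cell_id)
        result.graphs[(embryo, z)] = g
    return result
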