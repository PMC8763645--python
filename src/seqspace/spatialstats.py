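"""Spatial statistics on the cell neighborhood graph.

Contact maps quantify whether pairs of cell types touch more or less often
than a random relabeling of the tissue would suggest; the spatial
heterogeneity test asks, per gene and cell type, whether a cell's
expression is predicted by a path-length-weighted average of its
same-type neighbors' expression after adjusting for embryo and z-slice;
virtual dissection selects cells by a drawn boundary; differential
expression is a per-gene Welch t-test with Benjamini-Hochberg control; and
the anterior-posterior ranking orders cells by arc length along a fitted
principal curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import LineString, Point, Polygon
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cellgrid import NeighborhoodGraph

__all__ = [
    "ContactMap",
    "contact_map",
    "spatial_heterogeneity",
    "virtual_dissect",
    "differential_expression",
    "ap_rank",
    "PrincipalCurveRanking",
]


@dataclass
class ContactMap:
    """Permutation probabilities of cell-type contact, per stratum and mean.

    ``mean.loc[a, b]`` is the average over strata of
    P(permuted edge count >= observed edge count) for the label pair (a, b);
    small values mean segregation, large values integration.
    """

    labels: list
    mean: pd.DataFrame
    per_stratum: dict
    n_permutations: int


def _pair_edge_counts(codes_a, codes_b, n_labels: int) -> np.ndarray:
    """Symmetric label-pair edge count matrix from edge endpoint codes."""
    lo = np.minimum(codes_a, codes_b)
    hi = np.maximum(codes_a, codes_b)
    flat = np.bincount(lo * n_labels + hi, minlength=n_labels * n_labels)
    m = flat.reshape(n_labels, n_labels)
    return m + np.triu(m, 1).T


def contact_map(
    graph: NeighborhoodGraph,
    labels: pd.Series,
    n_perm: int = 500,
    seed: int = 0,
) -> ContactMap:
    """Permutation cell-cell contact map.

    Per (embryo, z-slice) stratum, the observed number of edges joining
    each pair of labels is compared with ``n_perm`` random reassignments of
    the labels (sampling without replacement within the stratum); the entry
    is the proportion of permutations with at least the observed count.
    Strata are then averaged element-wise; a pair is excluded from the mean
    in strata where either label is absent.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    all_labels = sorted(pd.unique(labels).astype(str))
    lab_code = {l: i for i, l in enumerate(all_labels)}
    L = len(all_labels)
    per_stratum = {}
    ss = np.random.SeedSequence(seed)
    for (key, g), child in zip(sorted(graph.graphs.items()), ss.spawn(len(graph.graphs))):
        rng = np.random.default_rng(child)
        nodes = [n for n in g.nodes if n in labels.index]
        codes = np.array([lab_code[str(labels[n])] for n in nodes])
        node_pos = {n: i for i, n in enumerate(nodes)}
        edges = np.array(
            [(node_pos[a], node_pos[b]) for a, b in g.edges if a in node_pos and b in node_pos]
        )
        mat = np.full((L, L), np.nan)
        present = np.zeros(L, dtype=bool)
        present[np.unique(codes)] = True
        if len(edges):
            obs = _pair_edge_counts(codes[edges[:, 0]], codes[edges[:, 1]], L)
            tally = np.zeros((L, L))
            for _ in range(n_perm):
                perm = rng.permutation(codes)
                cnt = _pair_edge_counts(perm[edges[:, 0]], perm[edges[:, 1]], L)
                tally += cnt >= obs
            prob = tally / n_perm
            for i in range(L):
                for j in range(L):
                    if present[i] and present[j]:
                        mat[i, j] = prob[i, j]
        per_stratum[key] = pd.DataFrame(mat, index=all_labels, columns=all_labels)
    stack = np.stack([m.to_numpy() for m in per_stratum.values()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        mean = np.nanmean(stack, axis=0)
    return ContactMap(
        labels=all_labels,
        mean=pd.DataFrame(mean, index=all_labels, columns=all_labels),
        per_stratum=per_stratum,
        n_permutations=n_perm,
    )


def spatial_heterogeneity(
    expr: pd.DataFrame,
    graph: NeighborhoodGraph,
    cell_meta: pd.DataFrame,
    cell_type: str,
    genes=None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Neighbor-weighted spatial heterogeneity regression, per gene.

    For cells j of the given type, the spatial covariate is
    ``x*_j = sum_k x_k / D(j, k)`` over the *other* same-type cells k of the
    same stratum, with D the shortest-path length in the neighborhood graph
    (unreachable cells contribute nothing).  Each gene's log-normalized
    expression is regressed on x* with embryo, z-slice and their interaction
    as categorical covariates; the t-statistic of the x* coefficient
    measures spatial heterogeneity.

    Parameters
    ----------
    expr
        Cells x genes log-normalized matrix, indexed by cell_id.
    cell_meta
        Per-cell table with ``embryo``, ``z_slice`` and ``cell_type``,
        indexed by cell_id.

    Returns a table (gene, beta_spatial, t_statistic, p_value, n_cells, reason).
    """
    if genes is None:
        genes = list(expr.columns)
    sel = cell_meta[cell_meta["cell_type"].astype(str) == str(cell_type)]
    sel = sel[sel.index.isin(expr.index)]
    if len(sel) < min_cells:
        raise ValueError(
            f"only {len(sel)} cells of type {cell_type!r}; at least {min_cells} required"
        )

    # inverse path-length weights between same-type cells, per stratum
    cells = list(sel.index)
    pos = {c: i for i, c in enumerate(cells)}
    Wd = np.zeros((len(cells), len(cells)))
    for (embryo, z), g in sorted(graph.graphs.items()):
        members = [c for c in cells
                   if sel.loc[c, "embryo"] == embryo and sel.loc[c, "z_slice"] == z
                   and c in g]
        for c in members:
            dists = nx.single_source_shortest_path_length(g, c)
            for k in members:
                if k == c:
                    continue
                d = dists.get(k)
                if d:
                    Wd[pos[c], pos[k]] = 1.0 / d

    X = expr.loc[cells, genes].to_numpy(dtype=float)
    Xstar = Wd @ X

    # embryo / z-slice design with interaction; degenerate levels dropped
    emb = sel["embryo"].astype(str)
    zsl = sel["z_slice"].astype(str)
    covars = pd.DataFrame(index=sel.index)
    if emb.nunique() > 1:
        covars = covars.join(pd.get_dummies(emb, prefix="e", drop_first=True, dtype=float))
    if zsl.nunique() > 1:
        covars = covars.join(pd.get_dummies(zsl, prefix="z", drop_first=True, dtype=float))
    if emb.nunique() > 1 and zsl.nunique() > 1:
        inter = emb + ":" + zsl
        if inter.nunique() > emb.nunique() + zsl.nunique() - 1:
            covars = covars.join(pd.get_dummies(inter, prefix="ez", drop_first=True, dtype=float))
    C = covars.to_numpy(dtype=float) if covars.shape[1] else np.empty((len(cells), 0))

    rows = []
    for gi, gene in enumerate(genes):
        y = X[:, gi]
        xs = Xstar[:, gi]
        if np.var(y) == 0 or np.var(xs) == 0:
            which = "expression" if np.var(y) == 0 else "spatial covariate"
            rows.append({"gene": gene, "beta_spatial": np.nan, "t_statistic": np.nan,
                         "p_value": np.nan, "n_cells": len(cells),
                         "reason": f"zero variance in {which}"})
            continue
        design = sm.add_constant(np.column_stack([xs, C]))
        fit = sm.OLS(y, design).fit()
        rows.append({"gene": gene, "beta_spatial": fit.params[1],
                     "t_statistic": fit.tvalues[1], "p_value": fit.pvalues[1],
                     "n_cells": len(cells), "reason": ""})
    return pd.DataFrame(rows).set_index("gene")


def virtual_dissect(cell_meta: pd.DataFrame, boundary, names=("region_a", "region_b")) -> pd.Series:
    """Split cells into two regions by a drawn boundary.

    ``boundary`` may be a shapely Polygon (inside vs outside by centroid
    containment) or a LineString / (n, 2) polyline (side of the line by the
    sign of the cross product at the nearest segment).  Returns a Series of
    region labels indexed by cell_id.
    """
    pts = cell_meta[["x", "y"]].to_numpy(dtype=float)
    if isinstance(boundary, Polygon):
        inside = shapely.contains_xy(boundary, pts[:, 0], pts[:, 1]) | shapely.intersects(
            boundary.exterior, shapely.points(pts[:, 0], pts[:, 1])
        )
        labels = np.where(inside, names[0], names[1])
    else:
        line = boundary if isinstance(boundary, LineString) else LineString(np.asarray(boundary))
        coords = np.asarray(line.coords)
        labels = np.empty(len(pts), dtype=object)
        for i, p in enumerate(pts):
            pt = Point(p)
            # nearest segment of the polyline
            best, seg = None, None
            for a, b in zip(coords[:-1], coords[1:]):
                d = LineString([a, b]).distance(pt)
                if best is None or d < best:
                    best, seg = d, (a, b)
            a, b = seg
            cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            labels[i] = names[0] if cross < 0 else names[1]
    out = pd.Series(labels, index=cell_meta.index, name="region")
    for name in names:
        if not (out == name).any():
            warnings.warn(f"region {name!r} is empty; boundary may not intersect the cells")
    return out


def differential_expression(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    lfc_threshold: float = 0.2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test on log-normalized values.

    ``lfc`` is mean(A) - mean(B) (log2 values, so a log fold change);
    p-values are Benjamini-Hochberg adjusted and a gene is significant iff
    ``p_adj < fdr`` and ``|lfc| > lfc_threshold``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    if list(group_a.columns) != list(group_b.columns):
        raise ValueError("groups must share the same gene columns")
    A = group_a.to_numpy(dtype=float)
    B = group_b.to_numpy(dtype=float)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # constant genes trigger a precision warning; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    lfc = A.mean(axis=0) - B.mean(axis=0)
    # both groups constant: equal means -> no evidence, unequal -> infinite t
    degenerate = np.isnan(t)
    t = np.where(degenerate & (lfc == 0), 0.0, t)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(np.isnan(t), np.sign(lfc) * np.inf, t)
    p = np.where(np.isnan(p), 0.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "lfc": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": (p_adj < fdr) & (np.abs(lfc) > lfc_threshold),
        },
        index=group_a.columns,
    )


@dataclass
class PrincipalCurveRanking:
    """Arc-length positions and ranks along a fitted principal curve."""

    arc_length: np.ndarray
    rank: np.ndarray  # permutation of 1..n
    curve: np.ndarray  # ordered polyline
    anchor: np.ndarray


def _project_to_polyline(points: np.ndarray, curve: np.ndarray):
    """Arc-length parameter and squared distance of each point's projection."""
    seg_a = curve[:-1]
    seg_v = curve[1:] - curve[:-1]
    seg_len = np.linalg.norm(seg_v, axis=1)
    seg_len[seg_len == 0] = 1e-12
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    diff = points[:, None, :] - seg_a[None, :, :]
    t = np.clip((diff * seg_v[None, :, :]).sum(-1) / (seg_len**2)[None, :], 0.0, 1.0)
    proj = seg_a[None, :, :] + t[:, :, None] * seg_v[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(-1)
    best = np.argmin(d2, axis=1)
    n = len(points)
    lam = cum[best] + t[np.arange(n), best] * seg_len[best]
    return lam, d2[np.arange(n), best]


def _running_mean(values: np.ndarray, window: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(values, size=window, axis=0, mode="nearest")


def ap_rank(
    coords: np.ndarray,
    anchor,
    span: float = 0.3,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> PrincipalCurveRanking:
    """Rank cells along an anatomical axis with a principal curve.

    The curve is initialized from the first principal component and refined
    by alternating projection (points onto the current polyline) and
    smoothing (running mean of the coordinates against arc-length order,
    window = ``span`` x n).  The curve is oriented so the end nearest
    ``anchor`` (the anterior point) has arc length 0; ranks are the order
    of fitted arc lengths.
    """
    coords = np.asarray(coords, dtype=float)
    anchor = np.asarray(anchor, dtype=float)
    n = len(coords)
    if n < 10:
        raise ValueError("at least 10 cells are required")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    center = coords.mean(axis=0)
    Xc = coords - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    lam = Xc @ vt[0]
    window = max(3, int(round(span * n)))
    collinear = len(s) < 2 or s[1] <= 1e-10 * s[0]
    if collinear:
        order = np.argsort(lam, kind="stable")
        curve = coords[order]
    else:
        prev_loss = None
        for _ in range(max_iter):
            order = np.argsort(lam, kind="stable")
            curve = _running_mean(coords[order], window)
            lam, d2 = _project_to_polyline(coords, curve)
            loss = float(d2.sum())
            if prev_loss is not None and abs(prev_loss - loss) <= tol * max(prev_loss, 1e-12):
                break
            prev_loss = loss
    lam, _ = _project_to_polyline(coords, curve)
    # orient: arc length 0 at the end nearest the anterior anchor
    if np.linalg.norm(curve[0] - anchor) > np.linalg.norm(curve[-1] - anchor):
        lam = lam.max() - lam
        curve = curve[::-1]
    order = np.argsort(lam, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    return PrincipalCurveRanking(arc_length=lam, rank=rank, curve=curve, anchor=anchor)
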