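"""Paired synthetic reference-atlas and spatial-section data with ground truth.

The generator emulates the study design every downstream stage assumes: a
dissociated scRNA-seq "atlas" (full gene set, several sequencing batches,
labeled cell types with planted markers) and sagittal embryo sections (2-3
embryos, 2 z-slices, several FOVs) carrying polygonal cell segmentations,
spatially contiguous cell-type domains, and per-round fluorescent dots
emitted under a pseudocolor codebook with dropout, jitter and background
noise.

Counts follow a negative-binomial model with gene-level dispersion; the
spatial modality applies an extra binomial thinning relative to the
reference to mimic platform sensitivity differences.  Batch effects are
additive shifts in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .codebook import Codebook
from .segmentation import SegmentationSet, SegmentedCell

__all__ = ["SimConfig", "GroundTruth", "generate_reference", "generate_section", "emit_round_spots"]


@dataclass
class SimConfig:
    """Parameters of one paired simulation.

    The defaults describe the study conditions the pipeline targets:
    two embryos with two z-slices each (parallel section planes), a
    ~2,000-gene reference atlas over several sequencing batches, and a
    ~100-gene spatial panel sharing its genes with the reference.
    """

    n_cell_types: int = 3
    n_genes_total: int = 2000
    n_genes_panel: int = 100
    n_ref_batches: int = 4
    n_ref_cells: int = 2000
    n_embryos: int = 2
    n_z_slices: int = 2
    fovs_per_embryo: int = 2
    cells_per_fov: int = 125
    marker_effect_lfc: float = 2.0  # log2 units
    dropout_rate_spatial: float = 0.1  # per round, per molecule
    spot_jitter_sd: float = 0.5  # pixels
    false_spot_rate: float = 2e-6  # false dots per px^2 per round
    seed: int = 0
    # plumbing parameters behind the stated noise model
    n_markers_per_type: int = 5
    spatial_detection_rate: float = 0.6  # binomial thinning vs the reference
    fov_size: float = 1000.0  # pixels, square FOV
    # lognormal gene base means sized so a ~100-gene panel yields on the
    # order of 200 detected transcripts per spatial cell after thinning
    base_mean_log: float = 0.65
    base_mean_sd: float = 1.0
    batch_lfc_sd: float = 0.15  # additive batch shifts in log2 space
    dispersion: float = 0.3  # NB dispersion (1/size), shared gene prior scale
    boundary_frac: float = 0.1  # fraction of a domain's width forming the mixed band

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_cell_types": self.n_cell_types,
            "n_genes_total": self.n_genes_total,
            "n_genes_panel": self.n_genes_panel,
            "n_ref_batches": self.n_ref_batches,
            "n_ref_cells": self.n_ref_cells,
            "n_embryos": self.n_embryos,
            "n_z_slices": self.n_z_slices,
            "fovs_per_embryo": self.fovs_per_embryo,
            "cells_per_fov": self.cells_per_fov,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_genes_panel > self.n_genes_total:
            raise ValueError("n_genes_panel exceeds n_genes_total")
        for name in ("dropout_rate_spatial", "spatial_detection_rate", "boundary_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        for name in ("marker_effect_lfc", "spot_jitter_sd", "false_spot_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the simulation stages."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cells: pd.DataFrame  # cell_id, embryo, z_slice, fov, cell_type, x, y
    rates: pd.DataFrame  # cells x panel genes, expected molecule counts
    molecules: pd.DataFrame  # mol_id, gene, cell_id, x, y, embryo, z_slice, fov
    domains: dict  # (embryo, z_slice, fov) -> list of (cell_type, vertex array)
    panel: list = field(default_factory=list)


def _nb_draw(rng, mean, dispersion):
    """Negative-binomial counts with mean `mean` and dispersion 1/size."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_reference(config: SimConfig) -> ad.AnnData:
    """Simulate the dissociated single-cell reference atlas.

    Returns an AnnData with integer counts in ``X``, ``obs['batch']``,
    ``obs['cell_type']``, ``obs['stage']``, log2-normalized values in
    ``layers['lognorm']`` (unit-mean size factors, pseudocount 1), and
    ground-truth structure (type means, marker table, panel) in ``uns``.
    """
    if config.n_cell_types < 2:
        raise ValueError("n_cell_types must be at least 2")
    per_cell = config.n_ref_cells // (config.n_ref_batches * config.n_cell_types)
    if per_cell < 25:
        raise ValueError(
            "n_ref_cells too small: fewer than 25 cells per cell type per batch "
            f"({per_cell} with n_ref_cells={config.n_ref_cells}, "
            f"n_ref_batches={config.n_ref_batches}, n_cell_types={config.n_cell_types})"
        )
    rng = config.rng(0)
    genes = np.array([f"g{i:04d}" for i in range(config.n_genes_total)])
    types = np.array([f"type{t}" for t in range(config.n_cell_types)])
    batches = np.array([f"batch{b}" for b in range(config.n_ref_batches)])

    base_mean = rng.lognormal(config.base_mean_log, config.base_mean_sd, size=config.n_genes_total)
    # planted markers: disjoint blocks of genes boosted for one type each
    markers = []
    type_lfc = np.zeros((config.n_cell_types, config.n_genes_total))
    for t in range(config.n_cell_types):
        lo = t * config.n_markers_per_type
        hi = lo + config.n_markers_per_type
        type_lfc[t, lo:hi] = config.marker_effect_lfc
        for g in range(lo, hi):
            markers.append({"gene": genes[g], "cell_type": types[t], "lfc": config.marker_effect_lfc})
    type_means = base_mean[None, :] * 2.0 ** type_lfc  # types x genes

    batch_shift = rng.normal(0.0, config.batch_lfc_sd, size=(config.n_ref_batches, config.n_genes_total))
    dispersion = config.dispersion

    obs_batch, obs_type, rows = [], [], []
    for b in range(config.n_ref_batches):
        for t in range(config.n_cell_types):
            mean = type_means[t] * 2.0 ** batch_shift[b]
            for _ in range(per_cell):
                rows.append(_nb_draw(rng, mean, dispersion))
                obs_batch.append(batches[b])
                obs_type.append(types[t])
    X = np.vstack(rows)

    # spatial gene panel: all planted markers plus a seeded random fill
    n_marker_genes = config.n_cell_types * config.n_markers_per_type
    if config.n_genes_panel < n_marker_genes:
        panel_idx = np.arange(config.n_genes_panel)
    else:
        rest = rng.choice(
            np.arange(n_marker_genes, config.n_genes_total),
            size=config.n_genes_panel - n_marker_genes,
            replace=False,
        )
        panel_idx = np.concatenate([np.arange(n_marker_genes), np.sort(rest)])
    panel = genes[panel_idx].tolist()

    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {
                "batch": pd.Categorical(obs_batch),
                "cell_type": pd.Categorical(obs_type),
                "stage": "E8.5",
            },
            index=[f"ref{i}" for i in range(len(rows))],
        ),
        var=pd.DataFrame(index=genes),
    )
    adata.uns["type_means"] = pd.DataFrame(type_means, index=types, columns=genes)
    adata.uns["markers"] = pd.DataFrame(markers)
    adata.uns["panel"] = panel
    adata.uns["dispersion"] = dispersion

    # unit-mean size-factor log2 normalization (same convention as cellgrid)
    totals = X.sum(axis=1).astype(float)
    sf = totals / totals.mean()
    adata.obs["size_factor"] = sf
    adata.layers["lognorm"] = np.log2(X / sf[:, None] + 1.0)
    return adata


def _bounded_voronoi(points: np.ndarray, bounds: Polygon):
    """Voronoi polygons for `points`, clipped to `bounds`, in point order."""
    diagram = voronoi_diagram(MultiPoint([tuple(p) for p in points]), envelope=bounds)
    polys = [g.intersection(bounds) for g in diagram.geoms]
    tree = STRtree(polys)
    out = [None] * len(points)
    for i, p in enumerate(points):
        pt = Point(p)
        for j in tree.query(pt):
            if polys[j].covers(pt):
                out[i] = polys[j]
                break
        if out[i] is None:  # numerical edge case: fall back to nearest polygon
            j = min(range(len(polys)), key=lambda j: polys[j].distance(pt))
            out[i] = polys[j]
    return out


def generate_section(config: SimConfig, reference: ad.AnnData):
    """Simulate spatial sections matched to a reference atlas.

    Cells sit on a jittered grid; polygons come from a bounded Voronoi
    tessellation clipped to the FOV.  Cell types occupy contiguous vertical
    domains (cells in the narrow band between two domains draw either
    adjacent type with probability 0.5).  Per-cell expected molecule counts
    are the reference profile of the cell's type restricted to the panel,
    binomially thinned by ``spatial_detection_rate``.

    Returns ``(SegmentationSet, GroundTruth)``.
    """
    min_cell_area = 25.0  # px^2; below this the tessellation degenerates
    if config.fov_size**2 / config.cells_per_fov < min_cell_area:
        raise ValueError(
            f"cells_per_fov={config.cells_per_fov} too large for a "
            f"{config.fov_size:.0f}px FOV (mean cell area would fall below {min_cell_area} px^2)"
        )
    rng = config.rng(1)
    genes = reference.var_names.to_numpy()
    panel = list(reference.uns["panel"])
    type_means = reference.uns["type_means"]
    types = list(type_means.index)
    n_types = len(types)
    dispersion = float(reference.uns.get("dispersion", 0.0))
    panel_means = type_means[panel].to_numpy()  # types x panel genes

    W = H = config.fov_size
    fov_box = box(0.0, 0.0, W, H)
    band_w = W / n_types
    bw = config.boundary_frac * band_w / 2.0  # half-width of each mixed band

    n_side = math.ceil(math.sqrt(config.cells_per_fov))
    spacing = W / n_side

    seg_cells = []
    cell_rows = []
    rate_rows = []
    mol_rows = []
    domains = {}
    cell_id = 0
    mol_id = 0
    for e in range(config.n_embryos):
        embryo = f"embryo{e + 1}"
        for z in range(1, config.n_z_slices + 1):
            for fov in range(1, config.fovs_per_embryo + 1):
                # jittered grid positions, truncated to the FOV interior
                grid = [
                    ((i + 0.5) * spacing, (j + 0.5) * spacing)
                    for j in range(n_side)
                    for i in range(n_side)
                ][: config.cells_per_fov]
                pts = np.asarray(grid) + rng.normal(0, 0.18 * spacing, size=(len(grid), 2))
                pts = np.clip(pts, 1.0, W - 1.0)
                polys = _bounded_voronoi(pts, fov_box)

                domains[(embryo, z, fov)] = [
                    (types[t], np.array([[t * band_w, 0.0], [(t + 1) * band_w, 0.0],
                                          [(t + 1) * band_w, H], [t * band_w, H]]))
                    for t in range(n_types)
                ]

                for p_xy, poly in zip(pts, polys):
                    verts = np.asarray(poly.exterior.coords)[:-1]
                    cx, cy = p_xy
                    band = min(int(cx // band_w), n_types - 1)
                    # mixed band around internal domain edges
                    edge_lo, edge_hi = band * band_w, (band + 1) * band_w
                    if band > 0 and cx - edge_lo < bw:
                        t_idx = band - int(rng.random() < 0.5)
                    elif band < n_types - 1 and edge_hi - cx < bw:
                        t_idx = band + int(rng.random() < 0.5)
                    else:
                        t_idx = band
                    ctype = types[t_idx]

                    lam = panel_means[t_idx] * config.spatial_detection_rate
                    counts = _nb_draw(rng, lam, dispersion)
                    n_mol = int(counts.sum())
                    if n_mol:
                        xy = _sample_in_polygon(rng, poly, n_mol)
                        gene_idx = np.repeat(np.arange(len(panel)), counts)
                        for g_i, (mx, my) in zip(gene_idx, xy):
                            mol_rows.append(
                                (mol_id, panel[g_i], cell_id, mx, my, embryo, z, fov)
                            )
                            mol_id += 1

                    seg_cells.append(
                        SegmentedCell(cell_id, embryo, z, fov, verts)
                    )
                    cell_rows.append(
                        {
                            "cell_id": cell_id,
                            "embryo": embryo,
                            "z_slice": z,
                            "fov": fov,
                            "cell_type": ctype,
                            "x": cx,
                            "y": cy,
                        }
                    )
                    rate_rows.append(lam)
                    cell_id += 1

    cells_df = pd.DataFrame(cell_rows).set_index("cell_id")
    rates = pd.DataFrame(np.asarray(rate_rows), index=cells_df.index, columns=panel)
    molecules = pd.DataFrame(
        mol_rows,
        columns=["mol_id", "gene", "cell_id", "x", "y", "embryo", "z_slice", "fov"],
    )
    truth = GroundTruth(cells=cells_df, rates=rates, molecules=molecules, domains=domains, panel=panel)
    return SegmentationSet(seg_cells), truth


def _sample_in_polygon(rng, poly: Polygon, n: int) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        sel = cand[keep][: n - got]
        out[got : got + len(sel)] = sel
        got += len(sel)
    return out


def emit_round_spots(truth: GroundTruth, codebook: Codebook, config: SimConfig) -> pd.DataFrame:
    """Emit per-hybridization-round fluorescent dots for the true molecules.

    Each molecule produces one dot per round at its position plus Gaussian
    jitter, colored by its gene's codeword pseudocolor for that round; each
    round's dot is independently omitted with ``dropout_rate_spatial``.
    False dots appear at ``false_spot_rate`` per px^2 per round with uniform
    position and pseudocolor.
    """
    missing = set(truth.panel) - set(codebook.genes)
    if missing:
        raise ValueError(f"panel genes absent from codebook: {sorted(missing)[:5]}")
    rng = config.rng(2)
    n_rounds = codebook.n_rounds
    cw = {g: codebook.codewords[g] for g in truth.panel}

    rows = []
    spot_id = 0
    mols = truth.molecules
    fov_area = config.fov_size**2
    groups = mols.groupby(["embryo", "z_slice", "fov"], sort=True) if len(mols) else []
    seen = set()
    for (embryo, z, fov), sub in groups:
        seen.add((embryo, z, fov))
        n = len(sub)
        gene_cw = np.array([cw[g] for g in sub["gene"]])
        base = sub[["x", "y"]].to_numpy()
        for r in range(1, n_rounds + 1):
            jitter = rng.normal(0.0, config.spot_jitter_sd, size=(n, 2))
            keep = rng.random(n) >= config.dropout_rate_spatial
            xy = base + jitter
            for i in np.nonzero(keep)[0]:
                rows.append(
                    (spot_id, r, int(gene_cw[i, r - 1]), xy[i, 0], xy[i, 1], z, fov, embryo)
                )
                spot_id += 1
    # background dots across every imaged FOV
    for (embryo, z, fov) in sorted(seen | set(truth.domains)):
        for r in range(1, n_rounds + 1):
            n_false = rng.poisson(config.false_spot_rate * fov_area)
            for _ in range(n_false):
                rows.append(
                    (
                        spot_id,
                        r,
                        int(rng.integers(1, codebook.n_pseudocolors + 1)),
                        rng.uniform(0, config.fov_size),
                        rng.uniform(0, config.fov_size),
                        z,
                        fov,
                        embryo,
                    )
                )
                spot_id += 1
    return pd.DataFrame(
        rows,
        columns=["spot_id", "round", "pseudocolor", "x", "y", "z_slice", "fov", "embryo"],
    )
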