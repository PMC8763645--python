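"""Spot-to-cell assignment, QC filtering, normalization, neighborhood graph."""

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.stats import norm
from shapely.geometry import Point, Polygon

from seqspace import cellgrid as cg
from seqspace.segmentation import SegmentationSet, SegmentedCell


def square(cell_id, x0, y0, side=10.0, embryo="e1", z=1, fov=1):
    v = np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])
    return SegmentedCell(cell_id, embryo, z, fov, v)


def spot_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "x", "y", "embryo", "z_slice", "fov"])


class TestAssignSpots:
    def test_interior_spots_counted(self):
        cells = SegmentationSet([square(0, 0, 0), square(1, 10, 0)])
        spots = spot_frame(
            [("gA", 5, 5, "e1", 1, 1), ("gA", 15, 5, "e1", 1, 1), ("gB", 4, 4, "e1", 1, 1)]
        )
        out = cg.assign_spots(spots, cells)
        assert list(out.var_names) == ["gA", "gB"]
        assert out.X.tolist() == [[1, 1], [1, 0]]
        assert out.uns["n_discarded"] == 0

    def test_outside_spot_discarded(self):
        cells = SegmentationSet([square(0, 0, 0)])
        spots = spot_frame([("gA", 50, 50, "e1", 1, 1)])
        out = cg.assign_spots(spots, cells)
        assert out.X.sum() == 0
        assert out.uns["n_discarded"] == 1

    def test_boundary_tie_goes_to_lower_id(self):
        cells = SegmentationSet([square(7, 0, 0), square(3, 10, 0)])
        spots = spot_frame([("gA", 10.0, 5.0, "e1", 1, 1)])  # shared edge
        out = cg.assign_spots(spots, cells)
        assert out["3"].X.sum() == 1
        assert out["7"].X.sum() == 0

    def test_orphan_fov_rejected(self):
        cells = SegmentationSet([square(0, 0, 0)])
        spots = spot_frame([("gA", 5, 5, "e1", 1, 2)])
        with pytest.raises(ValueError, match="no segmentation"):
            cg.assign_spots(spots, cells)

    def test_matches_exhaustive_scan_oracle(self, small_section):
        """Counts equal a per-spot shapely covers() scan over all polygons."""
        cells, truth = small_section
        spots = truth.molecules.sample(400, random_state=0)
        out = cg.assign_spots(spots, cells, genes=truth.panel)
        # oracle: exhaustive containment scan
        oracle = {}
        n_out = 0
        for _, m in spots.iterrows():
            pt = Point(m["x"], m["y"])
            hits = [
                c.cell_id
                for c in cells
                if (c.embryo, c.z_slice, c.fov) == (m["embryo"], m["z_slice"], m["fov"])
                and c.polygon.covers(pt)
            ]
            if hits:
                oracle[(min(hits), m["gene"])] = oracle.get((min(hits), m["gene"]), 0) + 1
            else:
                n_out += 1
        assert out.uns["n_discarded"] == n_out
        gi = {g: i for i, g in enumerate(out.var_names)}
        ri = {int(c): i for i, c in enumerate(out.obs_names)}
        total = 0
        for (cid, g), n in oracle.items():
            assert out.X[ri[cid], gi[g]] == n
            total += n
        assert out.X.sum() == total  # conservation: nothing counted twice

    def test_conservation(self, small_section):
        cells, truth = small_section
        out = cg.assign_spots(truth.molecules, cells, genes=truth.panel)
        assert out.X.sum() + out.uns["n_discarded"] == len(truth.molecules)


def counts_adata(X, genes=None, ids=None):
    import anndata as ad

    X = np.asarray(X)
    ids = ids if ids is not None else list(range(X.shape[0]))
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    obs = pd.DataFrame({"cell_id": ids}, index=[str(i) for i in ids])
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=pd.DataFrame(index=genes))


class TestQcFilter:
    def _cells_with_areas(self, side_lengths):
        cells = []
        x = 0.0
        for i, s in enumerate(side_lengths):
            cells.append(square(i, x, 0.0, side=s))
            x += s
        return SegmentationSet(cells)

    def test_low_content_thresholds(self):
        """Exactly the stated >=10 spots / >=5 genes thresholds."""
        sides = [10.0] * 4
        cells = self._cells_with_areas(sides)
        X = np.zeros((4, 6), dtype=int)
        X[0, :5] = [2, 2, 2, 2, 2]      # 10 spots, 5 genes -> keep
        X[1, :4] = [3, 3, 3, 3]         # 12 spots, 4 genes -> drop
        X[2, :5] = [2, 2, 2, 2, 1]      # 9 spots, 5 genes -> drop
        X[3, :6] = [2, 2, 2, 2, 2, 2]   # 12 spots, 6 genes -> keep
        kept_cells, kept = cg.qc_filter(cells, counts_adata(X), min_spots=10, min_genes=5)
        assert sorted(int(c) for c in kept.obs["cell_id"]) == [0, 3]
        assert kept.uns["n_low_content"] == 2

    def test_area_outliers_removed_bh_oracle(self):
        """Planted large segments flagged; matches a from-scratch BH check."""
        rng = np.random.default_rng(0)
        n, n_big = 200, 5
        sqrt_areas = np.concatenate([rng.normal(10, 1, n - n_big), np.full(n_big, 25.0)])
        cells = SegmentationSet(
            [square(i, 30.0 * i, 0.0, side=s) for i, s in enumerate(sqrt_areas)]
        )
        X = np.full((n, 6), 3, dtype=int)  # everyone passes the content filter
        kept_cells, kept = cg.qc_filter(cells, counts_adata(X), area_fdr=0.01)
        kept_ids = {int(c) for c in kept.obs["cell_id"]}
        # oracle: one-sided Z on sqrt-area, BH at 0.01
        s = np.sqrt([c.area for c in cells])
        z = (s - s.mean()) / s.std(ddof=1)
        p = norm.sf(z)
        order = np.argsort(p)
        m = len(p)
        thresh = 0.01 * (np.arange(1, m + 1)) / m
        below = np.nonzero(np.sort(p) <= thresh)[0]
        k = below.max() + 1 if len(below) else 0
        flagged = set(order[:k])
        assert set(range(n)) - kept_ids == flagged
        assert flagged >= set(range(n - n_big, n))  # all planted outliers caught

    def test_tiny_stratum_skipped_with_warning(self):
        cells = SegmentationSet([square(0, 0, 0), square(1, 10, 0)])
        X = np.full((2, 6), 3, dtype=int)
        with pytest.warns(UserWarning, match="fewer than 3 segments"):
            kept_cells, kept = cg.qc_filter(cells, counts_adata(X))
        assert kept.n_obs == 2


class TestNormalize:
    def test_worked_example(self):
        X = np.array([[2, 2], [6, 6]])
        out = cg.normalize(counts_adata(X))
        # totals 4 and 12, mean 8 -> size factors 0.5 and 1.5
        assert np.allclose(out.obs["size_factor"], [0.5, 1.5])
        assert np.allclose(out.layers["lognorm"], np.log2(X / np.array([[0.5], [1.5]]) + 1))

    def test_excluded_gene_ignored_for_size_factor_but_normalized(self):
        X = np.array([[4, 100], [4, 0]])
        out = cg.normalize(counts_adata(X, genes=["gA", "gX"]), exclude_genes=["gX"])
        assert np.allclose(out.obs["size_factor"], [1.0, 1.0])
        assert out.layers["lognorm"][0, 1] == pytest.approx(np.log2(101))

    def test_scale_invariance(self):
        """Multiplying every cell's counts by the same factor is absorbed."""
        rng = np.random.default_rng(1)
        X = rng.poisson(5.0, size=(20, 10)) + 1
        a = cg.normalize(counts_adata(X))
        b = cg.normalize(counts_adata(3 * X))
        assert np.allclose(
            2.0 ** a.layers["lognorm"] - 1, (2.0 ** b.layers["lognorm"] - 1) / 3
        )

    def test_zero_total_rejected(self):
        X = np.array([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="zero total"):
            cg.normalize(counts_adata(X))


class TestBuildGraph:
    def test_adjacent_unit_squares_connected(self):
        cells = SegmentationSet([square(0, 0, 0, side=1), square(1, 1, 0, side=1), square(2, 5, 0, side=1)])
        g = cg.build_graph(cells, expansion=1.3).graph("e1", 1)
        assert g.has_edge(0, 1)
        assert not g.has_edge(0, 2) and not g.has_edge(1, 2)

    def test_expansion_one_keeps_touching_squares(self):
        """At expansion 1 the shared corner vertex still lies on both squares."""
        cells = SegmentationSet([square(0, 0, 0, side=1), square(1, 1, 0, side=1)])
        g = cg.build_graph(cells, expansion=1.0).graph("e1", 1)
        assert g.has_edge(0, 1)

    def test_gap_closed_only_by_sufficient_expansion(self):
        # gap of 0.5 between unit squares: expansion 1.3 moves each vertex
        # 0.15 outward -> still 0.2 short; expansion 2.2 bridges it
        cells = SegmentationSet([square(0, 0, 0, side=1), square(1, 1.5, 0, side=1)])
        assert not cg.build_graph(cells, expansion=1.3).graph("e1", 1).has_edge(0, 1)
        assert cg.build_graph(cells, expansion=2.2).graph("e1", 1).has_edge(0, 1)

    def test_strata_not_mixed(self):
        cells = SegmentationSet([square(0, 0, 0, z=1), square(1, 1, 0, z=2)])
        g = cg.build_graph(cells)
        assert list(g.graph("e1", 1).nodes) == [0]
        assert list(g.graph("e1", 2).nodes) == [1]

    def test_matches_all_pairs_oracle(self, small_section):
        """Edges equal an O(n^2) vertex-in-expanded-polygon scan."""
        cells, _ = small_section
        (key, stratum) = cells.strata()[0]
        sub = SegmentationSet(stratum[:60])
        g = cg.build_graph(sub, expansion=1.3).graph(*key)
        expanded = {
            c.cell_id: Polygon(
                c.vertices.mean(0) + 1.3 * (c.vertices - c.vertices.mean(0))
            )
            for c in sub
        }
        oracle = set()
        cl = list(sub)
        for i in range(len(cl)):
            for j in range(i + 1, len(cl)):
                a, b = cl[i], cl[j]
                ab = any(expanded[b.cell_id].covers(Point(v)) for v in a.vertices)
                ba = any(expanded[a.cell_id].covers(Point(v)) for v in b.vertices)
                if ab or ba:
                    oracle.add((min(a.cell_id, b.cell_id), max(a.cell_id, b.cell_id)))
        got = {(min(a, b), max(a, b)) for a, b in g.edges}
        assert got == oracle

    def test_path_distance(self):
        cells = SegmentationSet(
            [square(i, float(i), 0, side=1) for i in range(5)]
        )
        g = cg.build_graph(cells, expansion=1.3)
        assert g.distance("e1", 1, 0, 4) == 4
        assert g.distances_from("e1", 1, 0)[2] == 2

    def test_invalid_expansion_rejected(self):
        cells = SegmentationSet([square(0, 0, 0)])
        with pytest.raises(ValueError, match="expansion"):
            cg.build_graph(cells, expansion=0.5)
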