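"""Contact maps, spatial heterogeneity, dissection, DE, axis ranking."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import LineString, Polygon

from seqspace import spatialstats as sps
from seqspace.cellgrid import NeighborhoodGraph


def chain_graph(n, key=("e1", 1)):
    g = nx.path_graph(n)
    return NeighborhoodGraph(graphs={key: g})


def two_block_graph(key=("e1", 1)):
    """Two internally connected blocks of 6, one bridging edge."""
    g = nx.Graph()
    for off in (0, 6):
        for i in range(6):
            for j in range(i + 1, 6):
                g.add_edge(off + i, off + j)
    g.add_edge(5, 6)
    return NeighborhoodGraph(graphs={key: g})


class TestContactMap:
    def test_single_permutation_bounds(self):
        graph = chain_graph(6)
        labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=range(6))
        cm = sps.contact_map(graph, labels, n_perm=1, seed=0)
        vals = cm.mean.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        assert cm.n_permutations == 1

    def test_segregated_types_scored_correctly(self):
        """Fully segregated blocks: same-type contact is maximal (entry ~0),
        cross-type contact minimal (entry ~1)."""
        graph = two_block_graph()
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=range(12))
        cm = sps.contact_map(graph, labels, n_perm=300, seed=1)
        assert cm.mean.loc["a", "a"] <= 0.05
        assert cm.mean.loc["b", "b"] <= 0.05
        assert cm.mean.loc["a", "b"] >= 0.95

    def test_symmetric(self):
        graph = two_block_graph()
        rng = np.random.default_rng(2)
        labels = pd.Series(rng.choice(["a", "b", "c"], 12), index=range(12))
        cm = sps.contact_map(graph, labels, n_perm=50, seed=0)
        m = cm.mean.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)

    def test_label_name_invariance(self):
        """Renaming the labels permutes rows/columns but not the values."""
        graph = two_block_graph()
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=range(12))
        swapped = labels.map({"a": "b", "b": "a"})
        cm1 = sps.contact_map(graph, labels, n_perm=200, seed=3)
        cm2 = sps.contact_map(graph, swapped, n_perm=200, seed=3)
        assert cm1.mean.loc["a", "a"] == cm2.mean.loc["b", "b"]
        assert cm1.mean.loc["a", "b"] == cm2.mean.loc["b", "a"]

    def test_absent_pair_is_nan_within_stratum(self):
        graph = NeighborhoodGraph(
            graphs={("e1", 1): nx.path_graph(4), ("e1", 2): nx.path_graph([4, 5, 6, 7])}
        )
        labels = pd.Series(["a", "a", "b", "b"] + ["a", "a", "a", "a"], index=range(8))
        cm = sps.contact_map(graph, labels, n_perm=20, seed=0)
        s2 = cm.per_stratum[("e1", 2)]
        assert np.isnan(s2.loc["a", "b"])
        assert not np.isnan(s2.loc["a", "a"])
        # the mean over strata still has the pair, from stratum 1 alone
        assert not np.isnan(cm.mean.loc["a", "b"])

    def test_seed_determinism(self):
        graph = two_block_graph()
        rng = np.random.default_rng(4)
        labels = pd.Series(rng.choice(["a", "b"], 12), index=range(12))
        a = sps.contact_map(graph, labels, n_perm=50, seed=9).mean
        b = sps.contact_map(graph, labels, n_perm=50, seed=9).mean
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError, match="n_perm"):
            sps.contact_map(chain_graph(3), pd.Series(["a", "b", "a"]), n_perm=0)


def meta_frame(n, embryo="e1", z=1, cell_type="t", xs=None, ys=None):
    return pd.DataFrame(
        {
            "embryo": embryo,
            "z_slice": z,
            "cell_type": cell_type,
            "x": xs if xs is not None else np.arange(n, dtype=float),
            "y": ys if ys is not None else np.zeros(n),
        },
        index=range(n),
    )


class TestSpatialHeterogeneity:
    def test_constant_gene_flagged(self):
        n = 20
        graph = chain_graph(n)
        meta = meta_frame(n)
        expr = pd.DataFrame({"gflat": np.ones(n), "gvar": np.random.default_rng(0).random(n)},
                            index=range(n))
        out = sps.spatial_heterogeneity(expr, graph, meta, "t")
        assert out.loc["gflat", "reason"] == "zero variance in expression"
        assert np.isnan(out.loc["gflat", "t_statistic"])
        assert out.loc["gvar", "reason"] == ""

    def test_gradient_detected_against_noise(self):
        """A smooth spatial gradient gets a far larger |t| than iid noise."""
        rng = np.random.default_rng(1)
        n = 60
        graph = chain_graph(n)
        meta = meta_frame(n)
        grad = np.linspace(0, 4, n) + rng.normal(0, 0.3, n)
        noise = rng.normal(0, 1, n)
        expr = pd.DataFrame({"g_grad": grad, "g_noise": noise}, index=range(n))
        out = sps.spatial_heterogeneity(expr, graph, meta, "t")
        assert abs(out.loc["g_grad", "t_statistic"]) > 3 * abs(out.loc["g_noise", "t_statistic"])
        assert out.loc["g_grad", "p_value"] < 1e-6

    def test_matches_ols_oracle_two_embryos(self):
        """beta, t and p equal a from-scratch inverse-path-distance OLS."""
        rng = np.random.default_rng(2)
        n = 40
        g1 = nx.path_graph(range(0, n // 2))
        g2 = nx.path_graph(range(n // 2, n))
        graph = NeighborhoodGraph(graphs={("e1", 1): g1, ("e2", 1): g2})
        meta = pd.DataFrame(
            {
                "embryo": ["e1"] * (n // 2) + ["e2"] * (n // 2),
                "z_slice": 1,
                "cell_type": "t",
                "x": 0.0,
                "y": 0.0,
            },
            index=range(n),
        )
        y = rng.normal(0, 1, n) + np.linspace(0, 2, n)
        out = sps.spatial_heterogeneity(pd.DataFrame({"g": y}, index=range(n)), graph, meta, "t")
        # oracle: path distances on a chain are |i - j| within each embryo
        xstar = np.zeros(n)
        for lo, hi in ((0, n // 2), (n // 2, n)):
            for j in range(lo, hi):
                xstar[j] = sum(y[k] / abs(k - j) for k in range(lo, hi) if k != j)
        D = np.column_stack([np.ones(n), xstar, (np.arange(n) >= n // 2).astype(float)])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        dof = n - D.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(D.T @ D)
        t = beta[1] / np.sqrt(cov[1, 1])
        p = 2 * stats.t.sf(abs(t), dof)
        assert out.loc["g", "beta_spatial"] == pytest.approx(beta[1], abs=1e-8)
        assert out.loc["g", "t_statistic"] == pytest.approx(t, abs=1e-8)
        assert out.loc["g", "p_value"] == pytest.approx(p, abs=1e-10)

    def test_too_few_cells_rejected(self):
        graph = chain_graph(4)
        meta = meta_frame(4)
        expr = pd.DataFrame({"g": np.arange(4.0)}, index=range(4))
        with pytest.raises(ValueError, match="at least 10"):
            sps.spatial_heterogeneity(expr, graph, meta, "t")

    def test_other_types_ignored(self):
        n = 30
        graph = chain_graph(n)
        meta = meta_frame(n)
        meta.loc[15:, "cell_type"] = "other"
        expr = pd.DataFrame({"g": np.random.default_rng(3).random(n)}, index=range(n))
        out = sps.spatial_heterogeneity(expr, graph, meta, "t")
        assert out.loc["g", "n_cells"] == 15


class TestVirtualDissect:
    def test_polygon_split(self):
        meta = meta_frame(4, xs=np.array([1.0, 2.0, 8.0, 9.0]), ys=np.zeros(4) + 1.0)
        region = Polygon([(0, 0), (5, 0), (5, 5), (0, 5)])
        out = sps.virtual_dissect(meta, region, names=("in", "out"))
        assert out.tolist() == ["in", "in", "out", "out"]

    def test_vertical_line_split(self):
        meta = meta_frame(4, xs=np.array([1.0, 2.0, 8.0, 9.0]), ys=np.zeros(4))
        out = sps.virtual_dissect(meta, LineString([(5, -10), (5, 10)]))
        assert len(set(out[:2])) == 1 and len(set(out[2:])) == 1
        assert out.iloc[0] != out.iloc[2]

    def test_polyline_array_accepted(self):
        meta = meta_frame(2, xs=np.array([0.0, 10.0]), ys=np.array([0.0, 0.0]))
        out = sps.virtual_dissect(meta, np.array([[5.0, -1.0], [5.0, 1.0]]))
        assert out.iloc[0] != out.iloc[1]

    def test_empty_region_warns(self):
        meta = meta_frame(3)
        far = Polygon([(100, 100), (101, 100), (101, 101), (100, 101)])
        with pytest.warns(UserWarning, match="empty"):
            out = sps.virtual_dissect(meta, far, names=("a", "b"))
        assert (out == "b").all()


class TestDifferentialExpression:
    def test_matches_welch_hand_formula(self):
        """t and p equal the textbook Welch formula to 1e-10."""
        rng = np.random.default_rng(5)
        A = pd.DataFrame(rng.normal(1.0, 1.0, size=(15, 4)), columns=list("wxyz"))
        B = pd.DataFrame(rng.normal(0.0, 2.0, size=(25, 4)), columns=list("wxyz"))
        out = sps.differential_expression(A, B)
        for g in "wxyz":
            a, b = A[g].to_numpy(), B[g].to_numpy()
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            p = 2 * stats.t.sf(abs(t), df)
            assert out.loc[g, "t"] == pytest.approx(t, abs=1e-10)
            assert out.loc[g, "p"] == pytest.approx(p, abs=1e-10)
            assert out.loc[g, "lfc"] == pytest.approx(a.mean() - b.mean())

    def test_swap_negates_lfc_and_t(self):
        rng = np.random.default_rng(6)
        A = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        B = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        ab = sps.differential_expression(A, B)
        ba = sps.differential_expression(B, A)
        assert np.allclose(ab["lfc"], -ba["lfc"])
        assert np.allclose(ab["t"], -ba["t"])
        assert np.allclose(ab["p_adj"], ba["p_adj"])

    def test_significance_requires_both_criteria(self):
        rng = np.random.default_rng(7)
        n = 200
        # g_big: large shift; g_small: significant but below the lfc gate;
        # g_null: no shift
        A = pd.DataFrame(
            {
                "g_big": rng.normal(1.0, 0.5, n),
                "g_small": rng.normal(0.1, 0.1, n),
                "g_null": rng.normal(0.0, 1.0, n),
            }
        )
        B = pd.DataFrame(
            {
                "g_big": rng.normal(0.0, 0.5, n),
                "g_small": rng.normal(0.0, 0.1, n),
                "g_null": rng.normal(0.0, 1.0, n),
            }
        )
        out = sps.differential_expression(A, B, lfc_threshold=0.2, fdr=0.05)
        assert out.loc["g_big", "significant"]
        assert not out.loc["g_small", "significant"]  # |lfc| ~ 0.1 < 0.2
        assert out.loc["g_small", "p_adj"] < 0.05
        assert not out.loc["g_null", "significant"]

    def test_constant_equal_groups_not_significant(self):
        A = pd.DataFrame({"g": np.ones(5)})
        B = pd.DataFrame({"g": np.ones(6)})
        out = sps.differential_expression(A, B)
        assert out.loc["g", "t"] == 0.0
        assert out.loc["g", "p"] == 1.0

    def test_constant_unequal_groups_certain(self):
        A = pd.DataFrame({"g": np.ones(5)})
        B = pd.DataFrame({"g": np.zeros(6)})
        out = sps.differential_expression(A, B)
        assert np.isinf(out.loc["g", "t"]) and out.loc["g", "t"] > 0
        assert out.loc["g", "p"] == 0.0

    def test_mismatched_columns_rejected(self):
        A = pd.DataFrame({"g1": np.ones(3)})
        B = pd.DataFrame({"g2": np.ones(3)})
        with pytest.raises(ValueError, match="same gene columns"):
            sps.differential_expression(A, B)


class TestApRank:
    def test_straight_line_exact_order(self):
        xs = np.linspace(0, 10, 30)
        coords = np.column_stack([xs, np.zeros(30)])
        out = sps.ap_rank(coords, anchor=(0.0, 0.0))
        assert out.rank.tolist() == list(range(1, 31))

    def test_anchor_at_far_end_reverses(self):
        xs = np.linspace(0, 10, 30)
        coords = np.column_stack([xs, np.zeros(30)])
        fwd = sps.ap_rank(coords, anchor=(0.0, 0.0))
        rev = sps.ap_rank(coords, anchor=(10.0, 0.0))
        assert rev.rank.tolist() == fwd.rank[::-1].tolist()

    def test_rank_is_permutation(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, np.pi, 80))
        coords = np.column_stack([np.cos(t), np.sin(t)]) * 10 + rng.normal(0, 0.3, (80, 2))
        out = sps.ap_rank(coords, anchor=(10.0, 0.0))
        assert sorted(out.rank.tolist()) == list(range(1, 81))

    def test_noisy_semicircle_recovers_order(self):
        """Spearman correlation with the generating parameter is near 1."""
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, np.pi, 120))
        coords = np.column_stack([np.cos(t), np.sin(t)]) * 10 + rng.normal(0, 0.4, (120, 2))
        out = sps.ap_rank(coords, anchor=(10.0, 0.0))
        rho = stats.spearmanr(out.rank, np.arange(len(t))).statistic
        assert rho > 0.95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            sps.ap_rank(np.zeros((5, 2)), anchor=(0, 0))

    def test_bad_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            sps.ap_rank(np.zeros((12, 2)), anchor=(0, 0), span=0.0)
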