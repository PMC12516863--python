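"""Spatial graph, neighborhoods, patches, and interaction testing."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sgctme.spatial import (assign_neighborhoods, build_knn_graph,
                            detect_patches, distance_to_border,
                            neighbor_fractions, summarize_interactions)
from sgctme.spatial import test_interactions as interaction_test

from conftest import toy_roi


def brute_force_knn(coords, ids, k):
    """Oracle: O(n^2) exact search with (distance, id) ordering."""
    n = len(coords)
    out = []
    for i in range(n):
        cand = [(np.hypot(*(coords[j] - coords[i])), ids[j], j)
                for j in range(n) if j != i]
        cand.sort()
        out.append([j for _, _, j in cand[: min(k, n - 1)]])
    return np.array(out)


class TestKnnGraph:
    def test_collinear_example(self):
        cells = toy_roi([(0, 0), (1, 0), (3, 0)], ["a"] * 3)
        g = build_knn_graph(cells, k=1)
        # 0 -> 1, 1 -> 0, 3 -> 1
        assert g.indices.ravel().tolist() == [1, 0, 1]

    def test_matches_brute_force_on_random_rois(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = int(rng.integers(5, 120))
            coords = rng.uniform(0, 100, (n, 2))
            cells = toy_roi(coords, ["a"] * n)
            g = build_knn_graph(cells, k=7)
            oracle = brute_force_knn(coords, cells["cell_id"].to_numpy(), 7)
            assert (g.indices == oracle).all()

    def test_large_roi_path_matches_brute_force(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 500, (3000, 2))  # beyond the cdist cutoff
        cells = toy_roi(coords, ["a"] * 3000)
        g = build_knn_graph(cells, k=5)
        sample = rng.choice(3000, 40, replace=False)
        oracle = brute_force_knn(coords, cells["cell_id"].to_numpy(), 5)
        assert (g.indices[sample] == oracle[sample]).all()

    def test_k_capped_at_n_minus_1(self):
        cells = toy_roi([(0, 0), (1, 1), (2, 0)], ["a"] * 3)
        g = build_knn_graph(cells, k=20)
        assert g.indices.shape == (3, 2)

    def test_tie_broken_by_lower_cell_id(self):
        # two neighbors exactly 1.0 away from the origin cell
        cells = toy_roi([(0, 0), (1, 0), (-1, 0)], ["a"] * 3)
        g = build_knn_graph(cells, k=1)
        assert g.indices[0, 0] == 1  # c001 < c002

    def test_errors(self):
        cells = toy_roi([(0, 0), (1, 0)], ["a"] * 2)
        with pytest.raises(ValueError):
            build_knn_graph(cells, k=0)
        with pytest.raises(ValueError):
            build_knn_graph(cells.iloc[:1], k=1)


class TestNeighborFractions:
    def test_hand_count(self):
        # cell 0 at origin; 12 tumor, 5 mCAF, 3 CD8 T neighbors around it
        labels = (["other immune"] + ["tumor"] * 12 + ["mCAF"] * 5
                  + ["CD8 T"] * 3)
        theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        coords = [(0, 0)] + [(np.cos(t), np.sin(t)) for t in theta]
        cells = toy_roi(coords, labels)
        g = build_knn_graph(cells, k=20)
        nf = neighbor_fractions(g, pd.Series(labels, index=cells["cell_id"]))
        row = nf.iloc[0]
        assert row["tumor"] == pytest.approx(0.60)
        assert row["mCAF"] == pytest.approx(0.25)
        assert row["CD8 T"] == pytest.approx(0.15)

    def test_rows_sum_to_one(self, roi_cells):
        cells, truth = roi_cells
        g = build_knn_graph(cells, k=20)
        nf = neighbor_fractions(g, truth.cell_types.loc[g.cell_ids])
        assert np.allclose(nf.sum(axis=1), 1.0, atol=1e-9)
        assert ((nf >= 0) & (nf <= 1)).all().all()

    def test_unlabeled_cell_rejected(self):
        cells = toy_roi([(0, 0), (1, 0), (2, 0)], ["tumor", None, "tumor"])
        g = build_knn_graph(cells, k=1)
        with pytest.raises(ValueError, match="label"):
            neighbor_fractions(g, cells.set_index("cell_id")["label_final"])


def _two_niche_roi(n=600, seed=0):
    """Spatially segregated pure-tumor and pure-lymphocyte halves."""
    rng = np.random.default_rng(seed)
    left = np.column_stack([rng.uniform(0, 200, n // 2),
                            rng.uniform(0, 500, n // 2)])
    right = np.column_stack([rng.uniform(300, 500, n // 2),
                             rng.uniform(0, 500, n // 2)])
    labels = ["tumor"] * (n // 2) + ["CD8 T"] * (n // 2)
    return toy_roi(np.concatenate([left, right]), labels), np.array(
        [0] * (n // 2) + [1] * (n // 2))


class TestNeighborhoods:
    def test_two_planted_niches_recovered(self):
        cells, planted = _two_niche_roi()
        g = build_knn_graph(cells, k=20)
        nf = neighbor_fractions(g, cells.set_index("cell_id")["label_final"])
        model = assign_neighborhoods(nf, n_neighborhoods=2, seed=0)
        assert adjusted_rand_score(planted, model.cn_of_cell) >= 0.95

    def test_deterministic_under_seed(self):
        cells, _ = _two_niche_roi(seed=3)
        g = build_knn_graph(cells, k=20)
        nf = neighbor_fractions(g, cells.set_index("cell_id")["label_final"])
        a = assign_neighborhoods(nf, 3, seed=5)
        b = assign_neighborhoods(nf, 3, seed=5)
        assert (a.cn_of_cell == b.cn_of_cell).all()

    def test_single_cluster(self):
        cells, _ = _two_niche_roi(seed=4)
        g = build_knn_graph(cells, k=20)
        nf = neighbor_fractions(g, cells.set_index("cell_id")["label_final"])
        model = assign_neighborhoods(nf, 1, seed=0)
        assert set(model.cn_of_cell) == {1}

    def test_more_clusters_than_cells_rejected(self):
        cells, _ = _two_niche_roi(n=10, seed=5)
        g = build_knn_graph(cells, k=5)
        nf = neighbor_fractions(g, cells.set_index("cell_id")["label_final"])
        with pytest.raises(ValueError):
            assign_neighborhoods(nf, 50, seed=0)


def flood_fill_patches(graph, tumor_mask, min_size):
    """Oracle: BFS connected components on the symmetrized tumor subgraph."""
    n = graph.n_cells
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in graph.indices[i]:
            if tumor_mask[i] and tumor_mask[j]:
                adj[i].add(int(j))
                adj[int(j)].add(i)
    seen, comps = set(), []
    for start in np.flatnonzero(tumor_mask):
        if start in seen:
            continue
        stack, comp = [int(start)], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in adj[u] if v not in comp)
        seen |= comp
        if len(comp) >= min_size:
            comps.append(frozenset(comp))
    return set(comps)


class TestPatches:
    def test_chain_of_ten_is_one_patch(self):
        coords = [(i * 5.0, 0.0) for i in range(10)]
        cells = toy_roi(coords, ["tumor"] * 10)
        g = build_knn_graph(cells, k=3)
        ps = detect_patches(g, cells.set_index("cell_id")["label_final"], 10)
        assert len(ps.patches) == 1
        assert len(ps.patches[1]) == 10

    def test_nine_cells_never_a_patch(self):
        coords = [(i * 5.0, 0.0) for i in range(9)]
        cells = toy_roi(coords, ["tumor"] * 9)
        g = build_knn_graph(cells, k=3)
        ps = detect_patches(g, cells.set_index("cell_id")["label_final"], 10)
        assert len(ps.patches) == 0

    def test_two_disjoint_components(self):
        coords = ([(i * 4.0, 0.0) for i in range(15)]
                  + [(i * 4.0, 400.0) for i in range(15)])
        cells = toy_roi(coords, ["tumor"] * 30)
        g = build_knn_graph(cells, k=3)
        labels = cells.set_index("cell_id")["label_final"]
        ps = detect_patches(g, labels, 10)
        oracle = flood_fill_patches(g, np.ones(30, bool), 10)
        got = {frozenset(int(i) for i in m) for m in ps.patches.values()}
        assert got == oracle
        assert len(ps.patches) == 2

    def test_matches_flood_fill_on_random_rois(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(50, 400))
            coords = rng.uniform(0, 300, (n, 2))
            labels = rng.choice(["tumor", "mCAF"], size=n, p=[0.6, 0.4])
            cells = toy_roi(coords, labels)
            g = build_knn_graph(cells, k=8)
            ps = detect_patches(g, cells.set_index("cell_id")["label_final"],
                                10)
            oracle = flood_fill_patches(g, labels == "tumor", 10)
            got = {frozenset(int(i) for i in m)
                   for m in ps.patches.values()}
            assert got == oracle

    def test_no_tumor_cells(self):
        cells = toy_roi([(0, 0), (1, 0), (2, 0)], ["mCAF"] * 3)
        g = build_knn_graph(cells, k=1)
        ps = detect_patches(g, cells.set_index("cell_id")["label_final"], 10)
        assert ps.patches == {}


class TestDistanceToBorder:
    def _patchy(self):
        # 11-cell tumor grid plus TME cells around / inside it
        tumor = [(x * 10.0, y * 10.0) for x in range(4) for y in range(3)]
        tme = [(0.0, 0.0), (33.0, 24.0), (15.0, 10.0)]
        labels = ["tumor"] * len(tumor) + ["mCAF", "CD8 T", "mCAF"]
        cells = toy_roi(tumor + tme, labels)
        g = build_knn_graph(cells, k=4)
        lab = cells.set_index("cell_id")["label_final"]
        return cells, g, lab, detect_patches(g, lab, 10)

    def test_coincident_cell_distance_zero(self):
        cells, g, lab, ps = self._patchy()
        d = distance_to_border(cells.set_index("cell_id"), ps, lab)
        assert abs(d["dist_to_tumor_border"].iloc[len(cells) - 3]) == 0.0

    def test_pythagorean_distance(self):
        cells, g, lab, ps = self._patchy()
        d = distance_to_border(cells.set_index("cell_id"), ps, lab)
        # TME cell at (33, 24), nearest patch cell (30, 20) -> 5 um outside
        assert d["dist_to_tumor_border"].iloc[len(cells) - 2] == \
            pytest.approx(5.0)
        assert not d["infiltrating"].iloc[len(cells) - 2]

    def test_enclosed_cell_negative_and_infiltrating(self):
        cells, g, lab, ps = self._patchy()
        d = distance_to_border(cells.set_index("cell_id"), ps, lab)
        row = d.iloc[len(cells) - 1]
        assert row["dist_to_tumor_border"] <= 0.0
        assert row["infiltrating"]

    def test_empty_patch_set(self):
        cells = toy_roi([(0, 0), (5, 0), (9, 0)], ["mCAF"] * 3)
        g = build_knn_graph(cells, k=1)
        lab = cells.set_index("cell_id")["label_final"]
        ps = detect_patches(g, lab, 10)
        d = distance_to_border(cells.set_index("cell_id"), ps, lab)
        assert d["dist_to_tumor_border"].isna().all()
        assert not d["infiltrating"].any()


class TestInteractions:
    def test_single_label_roi(self):
        rng = np.random.default_rng(0)
        cells = toy_roi(rng.uniform(0, 100, (30, 2)), ["tumor"] * 30)
        g = build_knn_graph(cells, k=20)
        t = interaction_test(g, cells.set_index("cell_id")["label_final"],
                              n_perm=50, seed=1)
        assert len(t) == 1
        row = t.iloc[0]
        assert row["ct"] == min(20, 29)
        assert row["p_gt"] == 1.0 and row["p_lt"] == 1.0

    def test_segregated_blocks_avoid(self):
        cells, _ = _two_niche_roi(n=300, seed=9)
        g = build_knn_graph(cells, k=20)
        t = interaction_test(g, cells.set_index("cell_id")["label_final"],
                              n_perm=500, alpha=0.01, seed=2)
        cross = t[(t.from_label == "tumor") & (t.to_label == "CD8 T")]
        assert cross["p_lt"].iloc[0] <= 0.01
        assert cross["sig"].iloc[0] == -1

    def test_pvalues_never_zero_and_bounded(self):
        cells, _ = _two_niche_roi(n=200, seed=10)
        g = build_knn_graph(cells, k=10)
        t = interaction_test(g, cells.set_index("cell_id")["label_final"],
                              n_perm=99, seed=3)
        assert (t["p_gt"] >= 1 / 100).all() and (t["p_gt"] <= 1).all()
        assert (t["p_lt"] >= 1 / 100).all() and (t["p_lt"] <= 1).all()

    def test_invalid_permutation_count(self):
        cells, _ = _two_niche_roi(n=100, seed=11)
        g = build_knn_graph(cells, k=5)
        with pytest.raises(ValueError):
            interaction_test(g, cells.set_index("cell_id")["label_final"],
                              n_perm=0)


class TestSummary:
    def test_empty(self):
        out = summarize_interactions([])
        assert len(out) == 0

    def test_hand_count(self):
        rows = []
        for roi, sig in (("r1", 1), ("r2", 1), ("r3", -1)):
            rows.append(pd.DataFrame([{
                "roi_id": roi, "from_label": "A", "to_label": "B",
                "ct": 1.0, "p_gt": 0.5, "p_lt": 0.5, "sig": sig}]))
        out = summarize_interactions(rows).set_index(
            ["from_label", "to_label"])
        assert out.loc[("A", "B"), "n_pos"] == 2
        assert out.loc[("A", "B"), "n_neg"] == 1
        assert out.loc[("A", "B"), "net"] == 1

    def test_directed_pairs_tallied_independently(self):
        t = pd.DataFrame([
            {"roi_id": "r", "from_label": "A", "to_label": "B", "ct": 1.0,
             "p_gt": 0.001, "p_lt": 1.0, "sig": 1},
            {"roi_id": "r", "from_label": "B", "to_label": "A", "ct": 1.0,
             "p_gt": 1.0, "p_lt": 0.001, "sig": -1},
        ])
        out = summarize_interactions([t]).set_index(
            ["from_label", "to_label"])
        assert out.loc[("A", "B"), "net"] == 1
        assert out.loc[("B", "A"), "net"] == -1
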