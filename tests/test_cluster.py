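"""Clustering, ranking, threshold selection and specificity calls."""

import numpy as np
import pandas as pd
import pytest

import dck
from dck.cluster import ClusterInputMatrix, UsnCluster

from conftest import run_pipeline


def make_matrix(values, cluster_ids, dan_ids, dan_types, members=None):
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=cluster_ids, columns=dan_ids)
    members = members or {c: (i,) for i, c in enumerate(cluster_ids)}
    return ClusterInputMatrix(values=vals, dan_types=pd.Series(dan_types), members=members)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


class TestClusterByType:
    def test_group_by_label(self):
        usns = pd.DataFrame({"neuron_id": [1, 2, 3], "type_label": ["A", "A", "B"]})
        clusters = {c.cluster_id: c.member_ids for c in dck.cluster_by_type(usns)}
        assert clusters == {"A": (1, 2), "B": (3,)}

    def test_empty_labels_become_singletons(self):
        usns = pd.DataFrame({"neuron_id": [7, 8], "type_label": ["", ""]})
        clusters = dck.cluster_by_type(usns)
        assert sorted(c.member_ids for c in clusters) == [(7,), (8,)]

    def test_sez_neurons_are_left_for_morphology_clustering(self):
        usns = pd.DataFrame({"neuron_id": [1, 2], "type_label": ["A", "A"],
                             "sez_associated": [False, True]})
        clusters = dck.cluster_by_type(usns)
        assert [c.member_ids for c in clusters] == [(1,)]


class TestClusterByMorphology:
    def test_identical_vectors_merge_at_any_positive_cut(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=[5, 6])
        clusters = dck.cluster_by_morphology(X, cut=0.5, max_cluster_size=None)
        assert [c.member_ids for c in clusters] == [(5, 6)]

    def test_hand_dendrogram_on_the_line(self):
        # L1 positions 0, 1, 10, 11: average linkage merges {0,1} and {10,11}
        # at height 1, then both at height 10; a cut at 2 yields two pairs.
        X = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]}, index=[1, 2, 3, 4])
        clusters = dck.cluster_by_morphology(X, cut=2.0, max_cluster_size=None)
        assert sorted(c.member_ids for c in clusters) == [(1, 2), (3, 4)]

    def test_mirrored_left_hemisphere_reproduces_right_clusters(self):
        rng = np.random.default_rng(0)
        right = rng.normal(size=(6, 3))
        Xr = pd.DataFrame(right, index=range(6))
        ref = dck.cluster_by_morphology(Xr, cut=2.0, max_cluster_size=None)
        left = right.copy()
        left[:, 0] *= -1  # mediolateral flip
        Xl = pd.DataFrame(left, index=range(6))
        hemi = pd.Series(["left"] * 6, index=Xl.index)
        mirrored = dck.cluster_by_morphology(
            Xl, cut=2.0, hemisphere=hemi, mirror_axis=0, max_cluster_size=None
        )
        assert sorted(c.member_ids for c in ref) == sorted(c.member_ids for c in mirrored)

    def test_unequal_vector_lengths_error(self):
        with pytest.raises(ValueError):
            dck.cluster_by_morphology(pd.DataFrame([[1, 2], [3, None]]).astype(object), cut=1.0)


# ---------------------------------------------------------------------------
# matrix, ranking, overlap
# ---------------------------------------------------------------------------


class TestBuildMatrix:
    def test_hand_sum_and_singleton_identity(self, toy_neurons, toy_edges):
        catalog = dck.DanTypeCatalog.from_neurons(toy_neurons)
        usns = dck.identify_usns(toy_edges, toy_neurons, catalog)
        frac = dck.input_fractions(toy_edges, catalog, usns)
        singles = [UsnCluster(f"c{u}", (u,), "by_type") for u in sorted(usns)]
        m1 = dck.build_matrix(frac, singles, catalog)
        assert np.allclose(sorted(m1.values[1]), [25.0, 75.0])
        merged = [UsnCluster("both", tuple(sorted(usns)), "by_type")]
        m2 = dck.build_matrix(frac, merged, catalog)
        assert m2.values.loc["both", 1] == pytest.approx(100.0)

    def test_column_sums_conserved_on_synthetic_data(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        sums = pipe["matrix"].values.sum(axis=0)
        assert np.allclose(sums[sums > 0], 100.0, rtol=1e-9)

    def test_unclustered_usn_is_an_error(self, toy_neurons, toy_edges):
        catalog = dck.DanTypeCatalog.from_neurons(toy_neurons)
        usns = dck.identify_usns(toy_edges, toy_neurons, catalog)
        frac = dck.input_fractions(toy_edges, catalog, usns)
        with pytest.raises(ValueError, match="absent from every cluster"):
            dck.build_matrix(frac, [UsnCluster("c3", (3,), "by_type")], catalog)


class TestRankTop:
    def setup_method(self):
        self.matrix = make_matrix(
            [[5.0, 0.0], [3.0, 0.0], [3.0, 0.0]],
            ["c1", "c2", "c3"],
            [101, 102],
            {101: "PAM08", 102: "PAM01"},
            members={"c1": (1, 2), "c2": (3,), "c3": (4, 5)},
        )

    def test_no_truncation_when_n_exceeds_clusters(self):
        ranked = dck.rank_top(self.matrix, ["PAM08"], n=10)
        assert len(ranked.table) == 3

    def test_ties_break_by_ascending_cluster_id(self):
        ranked = dck.rank_top(self.matrix, ["PAM08"], n=2)
        assert ranked.cluster_ids == ["c1", "c2"]

    def test_nonpositive_n_is_an_error(self):
        with pytest.raises(ValueError):
            dck.rank_top(self.matrix, ["PAM08"], n=0)

    def test_ranking_invariant_under_synapse_rescaling(self, noise_free_connectome):
        neurons, edges, _ = noise_free_connectome
        a = run_pipeline(neurons, edges)
        b = run_pipeline(neurons, edges.assign(synapse_count=edges["synapse_count"] * 7))
        ra = dck.rank_top(a["matrix"], dck.SELECTIONS["all7"], 50)
        rb = dck.rank_top(b["matrix"], dck.SELECTIONS["all7"], 50)
        assert ra.cluster_ids == rb.cluster_ids


class TestCompareTopsets:
    def test_identical_rankings_share_everything(self):
        m = make_matrix([[5.0], [3.0]], ["c1", "c2"], [101], {101: "PAM08"},
                        members={"c1": (1,), "c2": (2, 3)})
        r = dck.rank_top(m, ["PAM08"], 2)
        rep = dck.compare_topsets(r, r)
        assert rep["shared_clusters"] == 2 and rep["shared_usns"] == 3
        assert rep["unique_clusters_a"] == rep["unique_clusters_b"] == 0

    def test_set_arithmetic_on_partly_overlapping_rankings(self):
        m = make_matrix([[5.0, 0.0], [3.0, 3.0], [0.0, 4.0]],
                        ["c1", "c2", "c3"], [101, 102],
                        {101: "PAM08", 102: "PAM01"},
                        members={"c1": (1,), "c2": (2,), "c3": (3, 4)})
        a = dck.rank_top(m, ["PAM08"], 2)   # c1, c2
        b = dck.rank_top(m, ["PAM01"], 2)   # c3, c2
        rep = dck.compare_topsets(a, b)
        assert rep["shared_clusters"] == 1 and rep["shared_usns"] == 1
        assert rep["unique_clusters_a"] == 1 and rep["unique_usns_a"] == 1
        assert rep["unique_clusters_b"] == 1 and rep["unique_usns_b"] == 2


# ---------------------------------------------------------------------------
# thresholding and specificity
# ---------------------------------------------------------------------------


class TestEdgeThreshold:
    def test_boundary_is_inclusive(self):
        m = make_matrix([[0.39, 0.40, 0.41]], ["c1"], [1, 2, 3],
                        {1: "PAM08", 2: "PAM08", 3: "PAM08"})
        out = dck.apply_edge_threshold(m, 0.4)
        assert len(out) == 2 and out["percent"].min() == pytest.approx(0.40)

    def test_zero_threshold_keeps_all_nonzero_entries(self):
        m = make_matrix([[0.0, 1.0], [2.0, 0.0]], ["c1", "c2"], [1, 2],
                        {1: "PAM08", 2: "PAM01"})
        assert len(dck.apply_edge_threshold(m, 0.0)) == 2

    def test_edge_count_nonincreasing_in_tau(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        counts = [len(dck.apply_edge_threshold(pipe["matrix"], tau))
                  for tau in (0.0, 0.2, 0.4, 1.0, 2.0, 5.0)]
        assert counts == sorted(counts, reverse=True)


class TestClassifyTypeConnectivity:
    def test_saturated_single_type_is_exclusive(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        catalog = pipe["catalog"]
        dans = catalog.members["PAM08"]
        edges = pd.DataFrame({"cluster_id": "c1", "dan_id": list(dans),
                              "dan_type": "PAM08", "percent": 1.0})
        calls = dck.classify_type_connectivity(edges, catalog)
        row = calls.iloc[0]
        assert row["exclusivity"] == "exclusive_to_one_type" and row["exclusive_to"] == "g4"

    def test_twenty_percent_coverage_boundary_inclusive(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        catalog = pipe["catalog"]
        dans = list(catalog.members["PAM05"])  # 10 members: 2 connect, 1 does not
        for n_cov, expect in [(2, True), (1, False)]:
            edges = pd.DataFrame({"cluster_id": "c1", "dan_id": dans[:n_cov],
                                  "dan_type": "PAM05", "percent": 1.0})
            calls = dck.classify_type_connectivity(edges, catalog)
            assert bool(calls.iloc[0]["bp2"]) is expect

    def test_unknown_dan_type_is_an_error(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        edges = pd.DataFrame({"cluster_id": ["c1"], "dan_id": [1],
                              "dan_type": ["PAM99"], "percent": [1.0]})
        with pytest.raises(ValueError, match="PAM99"):
            dck.classify_type_connectivity(edges, pipe["catalog"])

    def test_planted_specificity_classes_recovered_exactly_noise_free(self, noise_free_pipeline):
        pipe, truth = noise_free_pipeline
        assert dck.class_recovery(pipe["calls"], truth, check_flag=True) == 1.0

    def test_no_connection_gained_as_tau_rises(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        catalog, matrix = pipe["catalog"], pipe["matrix"]
        prev = None
        for tau in (0.4, 1.0, 2.0):
            calls = dck.classify_type_connectivity(
                dck.apply_edge_threshold(matrix, tau), catalog)
            conn = {(r["cluster_id"], g) for _, r in calls.iterrows()
                    for g in ("bp2", "g4", "g5") if r[g]}
            if prev is not None:
                assert conn <= prev
            prev = conn


# ---------------------------------------------------------------------------
# silhouette threshold scan
# ---------------------------------------------------------------------------


def brute_silhouette(X, labels):
    """Direct mean silhouette under Manhattan distance (singletons score 0)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    scores = []
    for i in range(n):
        same = (labels == labels[i])
        if same.sum() == 1:
            scores.append(0.0)
            continue
        a = D[i, same & (np.arange(n) != i)].mean()
        b = min(D[i, labels == lab].mean() for lab in set(labels) if lab != labels[i])
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


def brute_scan(matrix, grid):
    """Exhaustive grid evaluation, independent of the library scorer."""
    labels = matrix.dan_types.reindex(matrix.values.columns).to_numpy()
    V = matrix.values.to_numpy()
    scores = [brute_silhouette((V >= tau).T.astype(float), labels) for tau in grid]
    best = max(scores)
    return grid[int(np.argmax(np.asarray(scores) >= best - 1e-12))], scores


class TestSilhouetteScan:
    def test_perfect_block_structure_scores_one_and_selects_smallest(self):
        # two DAN types receive disjoint cluster inputs, all above 2%
        vals = np.zeros((4, 6))
        vals[:2, :3] = 3.0
        vals[2:, 3:] = 4.0
        m = make_matrix(vals, ["c1", "c2", "c3", "c4"], list(range(6)),
                        {i: ("PAM08" if i < 3 else "PAM01") for i in range(6)})
        res = dck.silhouette_threshold_scan(m)
        below = res.table.loc[res.table["tau"] <= 2.9, "score"]
        assert np.allclose(below, 1.0)
        assert res.selected_threshold == pytest.approx(0.1)

    def test_scan_matches_brute_force_oracle_on_planted_noisy_matrix(self):
        rng = np.random.default_rng(42)
        n_c, n_d = 15, 12
        vals = np.zeros((n_c, n_d))
        vals[:8, :6] = 1.5
        vals[7:, 6:] = 2.5
        vals += rng.uniform(0, 1.2, size=vals.shape)  # additive noise
        types = {i: ("PAM08" if i < 6 else "PAM01") for i in range(n_d)}
        m = make_matrix(vals, [f"c{i:02d}" for i in range(n_c)], list(range(n_d)), types)
        res = dck.silhouette_threshold_scan(m)
        grid = res.table["tau"].to_numpy()
        expected_tau, expected_scores = brute_scan(m, grid)
        assert res.selected_threshold == pytest.approx(expected_tau)
        assert np.allclose(res.table["score"], expected_scores, atol=1e-9)

    def test_all_zero_profiles_are_flagged(self):
        m = make_matrix([[0.2, 0.2, 5.0, 5.0], [0.2, 0.3, 4.0, 5.0]],
                        ["c1", "c2"], [1, 2, 3, 4],
                        {1: "PAM08", 2: "PAM08", 3: "PAM01", 4: "PAM01"})
        res = dck.silhouette_threshold_scan(m)
        flagged = res.table.loc[res.table["tau"] > 0.3, "flagged"]
        assert flagged.all()

    def test_single_type_label_is_an_error(self):
        m = make_matrix([[1.0, 2.0]], ["c1"], [1, 2], {1: "PAM08", 2: "PAM08"})
        with pytest.raises(ValueError):
            dck.silhouette_threshold_scan(m)


# ---------------------------------------------------------------------------
# heat map and styling
# ---------------------------------------------------------------------------


class TestHeatmapSpec:
    def test_rows_normalise_to_one(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        spec = dck.heatmap_spec(pipe["matrix"])
        sums = spec.values.sum(axis=1)
        assert np.allclose(sums, 1.0, rtol=1e-9)

    def test_three_row_leaf_order_matches_hand_ward(self):
        # after row normalisation: r1=(1,0), r2=(0.9,0.1), r3=(0,1)
        # L1 distances: d(r1,r2)=0.2, d(r1,r3)=2, d(r2,r3)=1.8 -> r1,r2 merge first
        m = make_matrix([[10.0, 0.0], [9.0, 1.0], [0.0, 5.0]],
                        ["r1", "r2", "r3"], [1, 2], {1: "PAM08", 2: "PAM01"})
        spec = dck.heatmap_spec(m)
        order = list(spec.row_order)
        assert order.index("r3") in (0, 2)
        pair = {order[1], order[0] if order.index("r3") == 2 else order[2]}
        assert pair == {"r1", "r2"}

    def test_all_zero_row_left_unnormalised_and_flagged(self):
        m = make_matrix([[0.0, 0.0], [1.0, 3.0]], ["z", "a"], [1, 2],
                        {1: "PAM08", 2: "PAM01"})
        spec = dck.heatmap_spec(m)
        assert spec.flagged_rows == ("z",)
        assert spec.values.loc["z"].sum() == 0.0

    def test_columns_sorted_by_dan_type(self, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        spec = dck.heatmap_spec(pipe["matrix"])
        types = [pipe["matrix"].dan_types[d] for d in spec.col_order]
        order = {t: k for k, t in enumerate(dck.DAN_TYPE_INFO)}
        assert [order[t] for t in types] == sorted(order[t] for t in types)


class TestEdgeStyle:
    @pytest.mark.parametrize("percent,expected", [(0.1, 49.0), (12.17, 149.0), (6.135, 99.0)])
    def test_affine_anchors_and_midpoint(self, percent, expected):
        assert dck.edge_style(percent)["transparency"] == pytest.approx(expected)

    def test_clamped_outside_the_anchor_range(self):
        assert dck.edge_style(0.0)["transparency"] == 49.0
        assert dck.edge_style(50.0)["transparency"] == 149.0

    def test_weight_is_passthrough(self):
        assert dck.edge_style(3.7)["weight"] == pytest.approx(3.7)


class TestExportNetwork:
    def test_round_trip_preserves_edges_and_attributes(self, tmp_path, noise_free_pipeline):
        import networkx as nx

        pipe, _ = noise_free_pipeline
        edges = pipe["edges_t"].head(40)
        path = tmp_path / "net.graphml"
        dck.export_network(edges, pipe["catalog"], path, calls=pipe["calls"])
        G = nx.read_graphml(path)
        assert G.number_of_edges() == len(edges)
        for _, _, d in G.edges(data=True):
            assert 49.0 <= d["transparency"] <= 149.0
            assert d["weight"] == pytest.approx(d["percent"])

    def test_empty_edge_list_still_writes_nodes(self, tmp_path, noise_free_pipeline):
        import networkx as nx

        pipe, _ = noise_free_pipeline
        path = tmp_path / "empty.graphml"
        empty = pipe["edges_t"].iloc[0:0]
        dck.export_network(empty, pipe["catalog"], path)
        G = nx.read_graphml(path)
        assert G.number_of_nodes() == 86 and G.number_of_edges() == 0

    def test_byte_stable_for_fixed_input(self, tmp_path, noise_free_pipeline):
        pipe, _ = noise_free_pipeline
        edges = pipe["edges_t"].head(20)
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        dck.export_network(edges, pipe["catalog"], p1)
        dck.export_network(edges, pipe["catalog"], p2)
        assert p1.read_bytes() == p2.read_bytes()
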