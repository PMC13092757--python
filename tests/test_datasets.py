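"""Labeling, response-graph assembly, similarity edges and omics I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drpgraph.datasets import (OmicsProfileSet, ResponseRecord, VIEW_NAMES,
                               build_response_graph, compute_similarity_edges,
                               label_responses, read_omics_tables,
                               write_edge_list)


def make_records(values):
    return [ResponseRecord(f"c{i}", f"d{i}", v) for i, v in enumerate(values)]


class TestLabeling:
    @pytest.mark.parametrize("value,expected", [
        (-4.0, "sensitive"), (5.0, "resistant"), (0.0, "uncorrelated"),
        (-3.0, "uncorrelated"), (3.0, "uncorrelated"),  # thresholds are strict
    ])
    def test_threshold_labels(self, value, expected):
        summary = label_responses(make_records([value]), -3.0, 3.0)
        assert summary.records[0].label == expected

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_label_partition_sums_to_input(self, values):
        summary = label_responses(make_records(values), -3.0, 3.0)
        assert sum(summary.counts.values()) == len(values)
        assert len(summary.records) == len(values)

    def test_nonfinite_ic50_reported_not_dropped(self):
        summary = label_responses(make_records([1.0, np.nan, -5.0]))
        assert len(summary.rejected) == 1
        assert summary.rejected[0].cell_id == "c1"
        assert summary.counts == {"sensitive": 1, "resistant": 0, "uncorrelated": 1}

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            label_responses(make_records([0.0]), 3.0, -3.0)


class TestGraphAssembly:
    def test_one_edge_per_record(self):
        records = [ResponseRecord("c0", "d0", -4.0, "sensitive"),
                   ResponseRecord("c1", "d1", 4.0, "resistant")]
        g = build_response_graph(["c0", "c1"], ["d0", "d1"], records)
        assert g.relations["sensitive"].sum() == 1
        assert g.relations["resistant"].sum() == 1
        assert g.relations["sensitive_inv"].sum() == 1

    def test_zero_records_gives_empty_adjacencies(self):
        g = build_response_graph(["c0"], ["d0"], [])
        assert all(adj.nnz == 0 for adj in g.relations.values())

    def test_synthetic_scale_edge_count(self):
        # 3,001 planted sensitive records -> adjacency sum 3,001 by construction
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(192)]
        drugs = [f"d{i}" for i in range(352)]
        pairs = {(cells[rng.integers(192)], drugs[rng.integers(352)])
                 for _ in range(40000)}
        pairs = sorted(pairs)[:29697]
        records = [ResponseRecord(c, d, -4.0, "sensitive") for c, d in pairs[:3001]]
        records += [ResponseRecord(c, d, 4.0, "resistant") for c, d in pairs[3001:]]
        g = build_response_graph(cells, drugs, records)
        assert g.relations["sensitive"].sum() == 3001
        assert g.relations["resistant"].sum() == 26696

    def test_adjacency_disjointness_and_direction(self, tiny_graph):
        s = tiny_graph.relations["sensitive"].toarray()
        r = tiny_graph.relations["resistant"].toarray()
        assert (s * r).sum() == 0
        nc = tiny_graph.n_cells
        assert s[:, :nc].sum() == 0 and s[nc:, :].sum() == 0  # cell-row x drug-col only
        assert r[:, :nc].sum() == 0 and r[nc:, :].sum() == 0

    def test_conflicting_labels_error_names_pair(self):
        records = [ResponseRecord("c0", "d0", -4.0, "sensitive"),
                   ResponseRecord("c0", "d0", 4.0, "resistant")]
        with pytest.raises(ValueError, match="c0.*d0"):
            build_response_graph(["c0"], ["d0"], records)

    def test_uncorrelated_records_excluded(self):
        records = [ResponseRecord("c0", "d0", 0.0, "uncorrelated")]
        g = build_response_graph(["c0"], ["d0"], records)
        assert g.relations["sensitive"].nnz == 0
        assert g.relations["resistant"].nnz == 0

    def test_edge_list_export(self, tiny_graph, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_list(tiny_graph, path)
        df = pd.read_csv(path, sep="\t")
        assert set(df.columns) == {"src", "dst", "relation"}
        assert len(df) == 8  # 4 records x (forward + inverse)


def brute_force_knn(features, k, metric):
    """O(n^2) pairwise similarity + top-k union, independent of the implementation."""
    n = len(features)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = features[i], features[j]
            if metric == "cosine":
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                sim[i, j] = 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))
            else:
                ab, aa, bb = ((a > 0) & (b > 0)).sum(), (a > 0).sum(), (b > 0).sum()
                union = aa + bb - ab
                sim[i, j] = 0.0 if union == 0 else ab / union
    edges = set()
    for i in range(n):
        order = sorted(range(n), key=lambda j: (-sim[i, j], j))
        for j in [j for j in order if j != i][:k]:
            edges.add((i, j))
            edges.add((j, i))
    return sim, edges


class TestSimilarity:
    def test_identical_rows_always_linked(self):
        feats = np.array([[1.0, 2.0], [1.0, 2.0], [0.5, -1.0]])
        out = compute_similarity_edges(feats, k=1, metric="cosine")
        assert out.adjacency[0, 1] == 1 and out.adjacency[1, 0] == 1
        assert out.scores[(0, 1)] == pytest.approx(1.0)

    def test_orthogonal_rows_similarity_zero(self):
        feats = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = compute_similarity_edges(feats, k=2, metric="cosine")
        assert out.scores[(0, 1)] == pytest.approx(0.0)

    @pytest.mark.parametrize("metric", ["cosine", "tanimoto"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, metric, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        if metric == "cosine":
            feats = rng.standard_normal((n, 5))
        else:
            feats = (rng.random((n, 12)) < 0.4).astype(float)
        k = int(rng.integers(1, 4))
        out = compute_similarity_edges(feats, k=k, metric=metric)
        sim, expected = brute_force_knn(feats, k, metric)
        got = {(int(i), int(j)) for i, j in zip(*out.adjacency.nonzero())}
        # ties among equal similarities may resolve differently: compare scores
        for (i, j) in got ^ expected:
            tied = np.isclose(sorted(sim[i])[::-1][k - 1], sim[i, j]) or \
                   np.isclose(sorted(sim[j])[::-1][k - 1], sim[j, i])
            assert tied, f"edge ({i},{j}) differs from oracle and is not a tie"

    def test_symmetry_and_degree_bounds(self):
        rng = np.random.default_rng(3)
        feats = rng.standard_normal((5, 4))
        out = compute_similarity_edges(feats, k=2, metric="cosine")
        adj = out.adjacency.toarray()
        np.testing.assert_array_equal(adj, adj.T)
        assert np.diag(adj).sum() == 0
        assert 10 <= adj.sum() <= 20  # between n*k and 2*n*k directed entries

    def test_zero_row_warns(self):
        feats = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            compute_similarity_edges(feats, k=1, metric="cosine")

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            compute_similarity_edges(np.eye(3), k=3, metric="cosine")


class TestOmicsIO:
    def _write_views(self, tmp_path, cell_sets):
        paths = {}
        for view, cells in zip(VIEW_NAMES, cell_sets):
            df = pd.DataFrame(np.arange(len(cells) * 8, dtype=float).reshape(len(cells), 8),
                              index=cells, columns=[f"f{j}" for j in range(8)])
            p = tmp_path / f"{view}.csv"
            df.to_csv(p)
            paths[view] = p
        return paths

    def test_shared_cells_intersected(self, tmp_path):
        paths = self._write_views(tmp_path, [["a", "b", "c"]] * 6)
        profile, dropped = read_omics_tables(paths)
        assert profile.n_cells == 3 and dropped == []

    def test_missing_cell_dropped_everywhere(self, tmp_path):
        sets = [["a", "b", "c"]] * 5 + [["a", "b"]]
        paths = self._write_views(tmp_path, sets)
        profile, dropped = read_omics_tables(paths)
        assert profile.cell_ids == ["a", "b"] and dropped == ["c"]

    def test_median_imputation_before_standardization(self, tmp_path):
        paths = self._write_views(tmp_path, [["a", "b", "c"]] * 6)
        df = pd.read_csv(paths["transcriptomics"], index_col=0)
        df.iloc[:, 0] = [1.0, 2.0, np.nan]
        df.to_csv(paths["transcriptomics"])
        profile, _ = read_omics_tables(paths)
        col = profile.views["transcriptomics"][:, 0]
        # imputed value is median(1, 2) = 1.5, then z-scored with the column
        raw = np.array([1.0, 2.0, 1.5])
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(col, expected)

    def test_empty_intersection_reports_counts(self, tmp_path):
        sets = [["a"], ["b"]] + [["a", "b"]] * 4
        paths = self._write_views(tmp_path, sets)
        with pytest.raises(ValueError, match="per-view counts"):
            read_omics_tables(paths)


def test_profile_set_rejects_misaligned_views():
    with pytest.raises(ValueError, match="rows"):
        OmicsProfileSet(views={"transcriptomics": np.zeros((2, 3))}, cell_ids=["a"])
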