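import numpy as np
import pandas as pd
import pytest

from csdnet.network import (
    EdgeSet,
    build_network,
    edges_from_importance,
    node_table,
    read_edge_list,
    select_top,
    write_network,
)


def _score_frame(scores, genes=None):
    n = len(scores)
    if genes is None:
        genes = [(f"G{i:04d}", f"H{i:04d}") for i in range(n)]
    ga, gb = zip(*genes)
    return pd.DataFrame({
        "gene_a": ga, "gene_b": gb,
        "rho1": np.linspace(-1, 1, n), "rho2": np.linspace(1, -1, n),
        "var1": 0.01, "var2": 0.01,
        "c_score": scores, "s_score": scores, "d_score": scores,
    })


class TestEdgesFromImportance:
    def test_all_pairs_at_level_one(self):
        assert edges_from_importance(3, 1.0) == 3

    def test_floor_with_minimum_one(self):
        assert edges_from_importance(10, 1e-6) == 1  # floor would be 0

    def test_invalid_level(self):
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="importance level"):
                edges_from_importance(100, p)
        with pytest.raises(ValueError, match="2 genes"):
            edges_from_importance(1, 0.5)


class TestSelectTop:
    def test_picks_largest(self):
        frame = _score_frame([5.0, 3.0, 9.0, 1.0])
        top = select_top(frame, "C", 2)
        assert top["score"].tolist() == [9.0, 5.0]

    def test_k_exceeding_pairs_returns_all_descending(self, caplog):
        frame = _score_frame([5.0, 3.0, 9.0, 1.0])
        top = select_top(frame, "S", 10)
        assert top["score"].tolist() == [9.0, 5.0, 3.0, 1.0]
        assert "only 4 scored pairs" in caplog.text

    def test_matches_full_sort_oracle_with_duplicates(self, rng):
        n, k = 10_000, 137
        scores = rng.integers(0, 500, size=n).astype(float)  # many duplicates
        frame = _score_frame(scores)
        top = select_top(frame, "D", k)
        oracle = frame.sort_values(
            ["d_score", "gene_a", "gene_b"], ascending=[False, True, True]
        ).head(k)
        assert top["gene_a"].tolist() == oracle["gene_a"].tolist()
        assert top["score"].tolist() == oracle["d_score"].tolist()

    def test_boundary_ties_broken_lexicographically(self):
        frame = _score_frame([2.0, 2.0, 2.0, 5.0],
                             genes=[("B", "Z"), ("A", "Y"), ("A", "X"), ("C", "W")])
        top = select_top(frame, "C", 2)
        assert list(zip(top.gene_a, top.gene_b)) == [("C", "W"), ("A", "X")]

    def test_monotone_in_k(self, rng):
        frame = _score_frame(rng.uniform(size=300))
        smaller = select_top(frame, "C", 20)
        larger = select_top(frame, "C", 50)
        small_pairs = set(zip(smaller.gene_a, smaller.gene_b))
        large_pairs = set(zip(larger.gene_a, larger.gene_b))
        assert small_pairs <= large_pairs

    def test_nan_scores_excluded_and_all_nan_errors(self):
        frame = _score_frame([1.0, np.nan, 3.0, np.nan])
        top = select_top(frame, "C", 3)
        assert top["score"].tolist() == [3.0, 1.0]
        with pytest.raises(ValueError, match="no scored pairs"):
            select_top(_score_frame([np.nan, np.nan]), "C", 1)


class TestBuildAndWrite:
    def test_exclusive_sizing_arguments(self):
        frame = _score_frame([1.0, 2.0])
        with pytest.raises(ValueError, match="exactly one"):
            build_network(frame)
        with pytest.raises(ValueError, match="exactly one"):
            build_network(frame, n_edges=1, importance_level=0.5)

    def test_independent_per_type_selection(self):
        frame = _score_frame([1.0, 2.0, 3.0])
        es = build_network(frame, n_edges=2)
        assert set(es.edges) == {"C", "S", "D"}
        # identical score columns here, so all three selections coincide
        for lt in ("S", "D"):
            assert es.edges[lt]["gene_a"].tolist() == es.edges["C"]["gene_a"].tolist()

    def test_round_trip_and_empty_type(self, tmp_path):
        frame = _score_frame([4.0, 2.0, 7.0])
        es = build_network(frame, n_edges=2)
        es.edges["D"] = es.edges["D"].iloc[0:0]  # emulate an empty D network
        paths = write_network(es, tmp_path / "net")
        back_c = read_edge_list(tmp_path / "net_C.tsv")
        pd.testing.assert_frame_equal(back_c, es.edges["C"], atol=1e-12)
        back_d = read_edge_list(tmp_path / "net_D.tsv")
        assert back_d.empty and list(back_d.columns) == [
            "gene_a", "gene_b", "score", "rho1", "rho2"]
        combined = read_edge_list(tmp_path / "net_CSD.tsv")
        assert sorted(combined["link_type"].unique()) == ["C", "S"]
        assert len(paths) == 4

    def test_self_loop_rejected(self):
        df = pd.DataFrame({"gene_a": ["A"], "gene_b": ["A"], "score": [1.0],
                           "rho1": [0.5], "rho2": [0.5]})
        with pytest.raises(ValueError, match="self-loop"):
            EdgeSet(edges={"C": df}, n_requested=1)

    def test_node_table_degrees(self):
        frame = _score_frame([3.0, 2.0, 1.0],
                             genes=[("A", "B"), ("A", "C"), ("B", "C")])
        es = build_network(frame, n_edges=2)
        nodes = node_table(es)
        a = nodes.set_index("gene").loc["A"]
        assert a["degree_C"] == 2 and a["degree_D"] == 2

    def test_to_networkx_multigraph(self):
        frame = _score_frame([3.0, 1.0], genes=[("A", "B"), ("B", "C")])
        g = build_network(frame, n_edges=1).to_networkx()
        assert g.number_of_edges() == 3  # same pair under C, S and D
        assert set(g.nodes) == {"A", "B"}
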