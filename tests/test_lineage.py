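import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devconnectome.io import NeuronTable
from devconnectome.lineage import (LineageNameError, build_lineage_tree,
                                   chrono_dendrogram_export,
                                   ganglion_lineage_stats, lineage_distance,
                                   max_lineage_distance, rung_of)

lineage_names = st.builds(
    lambda letters: "AB" + "".join(letters),
    st.lists(st.sampled_from("aplr"), min_size=1, max_size=10))


class TestRung:
    @pytest.mark.parametrize("name, rung", [
        ("P0", 0),
        ("AB", 1),
        ("ABa", 2),
        ("ABprpapaap", 9),   # AB counts as a single letter
        ("MS", 3),           # founder depth from standard embryology
        ("MSaap", 6),
    ])
    def test_rung_examples(self, name, rung):
        assert rung_of(name) == rung

    @pytest.mark.parametrize("bad", ["", "XY", "ABq", "ABpzr"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(LineageNameError):
            rung_of(bad)


class TestLineageDistance:
    def test_identity(self):
        assert lineage_distance("ABplp", "ABplp") == 0

    def test_siblings_share_one_division(self):
        assert lineage_distance("ABa", "ABp") == 1
        assert lineage_distance("ABpl", "ABpr") == 1

    def test_mirror_cousins(self):
        # progenitor ABp at rung 2; three divisions on each side, the
        # shared one counted once: 3 + 3 - 1
        assert lineage_distance("ABplaa", "ABpraa") == 5

    @given(a=lineage_names, b=lineage_names)
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_identity_axioms(self, a, b):
        d = lineage_distance(a, b)
        assert d == lineage_distance(b, a)
        assert (d == 0) == (a == b)

    @given(a=lineage_names, b=lineage_names, c=lineage_names)
    @settings(max_examples=200, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        assert lineage_distance(a, c) <= (lineage_distance(a, b)
                                          + lineage_distance(b, c))

    @given(st.integers(2, 12), st.data())
    @settings(max_examples=100, deadline=None)
    def test_same_rung_distances_are_odd(self, rung, data):
        letters = st.lists(st.sampled_from("ap"), min_size=rung - 1,
                           max_size=rung - 1)
        a = "AB" + "".join(data.draw(letters))
        b = "AB" + "".join(data.draw(letters))
        if a != b:
            assert lineage_distance(a, b) % 2 == 1


class TestMaxLineageDistance:
    def test_degenerate_rung_one(self):
        assert max_lineage_distance(1, 1) is None

    def test_children_of_the_first_division(self):
        assert max_lineage_distance(2, 2) == 1

    def test_empirical_maximum_at_rung_14(self):
        assert max_lineage_distance(14, 14) == 25

    def test_rejects_rung_below_one(self):
        with pytest.raises(ValueError):
            max_lineage_distance(0, 3)

    @given(st.integers(2, 14), st.integers(2, 14))
    @settings(max_examples=50, deadline=None)
    def test_bounds_realized_distances(self, r1, r2):
        # deepest split: progenitor at rung 1 on two pure-'a'/'p' paths
        a = "AB" + "a" * (r1 - 1)
        b = "AB" + "p" * (r2 - 1)
        assert lineage_distance(a, b) == max_lineage_distance(r1, r2)


def _table_from_leaves(leaves, times=None):
    times = times or {l: 100.0 + 10 * i for i, l in enumerate(leaves)}
    return NeuronTable(pd.DataFrame({
        "name": [f"n{i}" for i in range(len(leaves))],
        "x_ap": np.linspace(0, 1, len(leaves)),
        "y_dv": 0.0,
        "proc_cat": "S",
        "birth_time": [times[l] for l in leaves],
        "birth_stage": "Embryo",
        "lineage_name": leaves,
    }))


class TestBuildLineageTree:
    def test_two_leaves_make_three_nodes_plus_root(self):
        tree = build_lineage_tree(_table_from_leaves(["ABa", "ABp"]))
        assert set(tree.nodes) == {"P0", "AB", "ABa", "ABp"}
        assert tree.nodes["ABa"].parent == "AB"
        assert tree.rung("ABa") == 2

    def test_rung_equals_depth(self, small_worm):
        table, _, tree, _ = small_worm
        for name, node in tree.nodes.items():
            depth = 0
            cur = node
            while cur.parent is not None:
                cur = tree.nodes[cur.parent]
                depth += 1
            assert depth == node.rung

    def test_duplicate_lineage_names_rejected(self):
        table = _table_from_leaves(["ABaa", "ABap"])
        table.df.loc[1, "lineage_name"] = "ABaa"
        with pytest.raises(ValueError, match="share lineage"):
            build_lineage_tree(table)

    def test_distance_matrix_matches_graph_path_oracle(self):
        leaves = ["ABaaa", "ABaap", "ABapa", "ABplp", "ABprppa"]
        tree = build_lineage_tree(_table_from_leaves(leaves))
        g = nx.Graph()
        for name, node in tree.nodes.items():
            if node.parent is not None:
                g.add_edge(node.parent, name)
        d, names = tree.distance_matrix(leaves)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i == j:
                    continue
                # dividing progenitors on the path = edges - 1
                expect = nx.shortest_path_length(g, a, b) - 1
                assert d[i, j] == expect

    def test_internal_times_interpolated_and_flagged(self):
        tree = build_lineage_tree(_table_from_leaves(
            ["ABaa", "ABap"], times={"ABaa": 300.0, "ABap": 330.0}))
        ab = tree.nodes["AB"]
        assert ab.time_imputed
        assert ab.time == pytest.approx(100.0)  # 300 * (1/3)

    def test_supplied_division_times_are_used_verbatim(self):
        tree = build_lineage_tree(
            _table_from_leaves(["ABaa", "ABap"], times={"ABaa": 300.0,
                                                        "ABap": 330.0}),
            division_times={"AB": 40.0, "ABa": 120.0})
        assert tree.nodes["AB"].time == 40.0
        assert not tree.nodes["AB"].time_imputed

    def test_newick_round_trips_through_dendropy(self, small_worm):
        _, _, tree, _ = small_worm
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        taxa = {l.taxon.label if l.taxon else None
                for l in parsed.leaf_node_iter()}
        assert len(taxa - {None}) == len(tree.leaves)


class TestGanglionLineageStats:
    def _stats(self, leaves, ganglia, **kw):
        table = _table_from_leaves(leaves)
        table.df["ganglion"] = ganglia
        tree = build_lineage_tree(table)
        return ganglion_lineage_stats(tree, table, **kw)

    def test_single_ganglion_covering_all_leaves_has_zero_z(self):
        leaves = ["ABaa", "ABap", "ABpa", "ABpp"]
        res = self._stats(leaves, ["G1"] * 4, n_real=30, n_swaps=50, seed=1)
        # permuting leaves cannot change a statistic over all of them
        assert res.z_mean.loc["G1", "G1"] == pytest.approx(0.0, abs=1e-12) \
            or np.isnan(res.z_mean.loc["G1", "G1"])

    def test_clade_ganglion_is_strongly_under_dispersed(self):
        # G1 is exactly the ABa clade: intra distances far below null
        leaves = (["ABa" + s for s in ("aa", "ap", "pa", "pp")]
                  + ["ABp" + "".join(p) for p in
                     [("a", "a", "a"), ("a", "a", "p"), ("a", "p", "a"),
                      ("p", "a", "a"), ("p", "a", "p"), ("p", "p", "a")]])
        ganglia = ["G1"] * 4 + ["G2"] * 6
        res = self._stats(leaves, ganglia, n_real=200, n_swaps=100, seed=2)
        assert res.z_mean.loc["G1", "G1"] < -2.0

    def test_null_preserves_distance_multiset_and_centers_z(self, small_worm):
        table, _, tree, _ = small_worm
        res = ganglion_lineage_stats(tree, table, n_real=60, n_swaps=200,
                                     seed=3)
        vals = res.z_mean.values[np.isfinite(res.z_mean.values)]
        # across many ganglion pairs the null z should be centered near 0
        assert abs(np.mean(vals)) < 1.5

    def test_tiny_ganglion_reported_missing(self):
        leaves = ["ABaa", "ABap", "ABpa"]
        res = self._stats(leaves, ["G1", "G2", "G2"], n_real=10, n_swaps=20,
                          seed=0)
        assert np.isnan(res.mean_l.loc["G1", "G1"])


class TestChronoDendrogram:
    def test_rows_and_parent_pointers(self):
        tree = build_lineage_tree(_table_from_leaves(["ABa", "ABp"]))
        out = chrono_dendrogram_export(tree)
        assert len(out) == 4
        assert set(out["parent"].dropna()) <= set(out["name"])

    def test_highlight_flags_exactly_the_subset(self, small_worm):
        table, _, tree, _ = small_worm
        g1 = list(table.df.loc[table.df["ganglion"] == "G1", "lineage_name"])
        out = chrono_dendrogram_export(tree, highlight=g1)
        assert out["highlighted"].sum() == len(g1)

    def test_late_branch_leaves_have_larval_times(self, small_worm):
        table, _, tree, _ = small_worm
        out = chrono_dendrogram_export(tree).set_index("name")
        late = table.df.loc[table.df["cohort"] == "late", "lineage_name"]
        t_hatch = 800.0
        assert (out.loc[late, "time"] > t_hatch).all()
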