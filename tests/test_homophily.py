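import numpy as np
import pandas as pd
import pytest

from devconnectome.homophily import (birth_cohort_analysis,
                                     class_pair_modularity,
                                     constrained_rewire_surrogate,
                                     homophily_report, homophily_zscore,
                                     modularity, shuffle_attribute_surrogate)
from devconnectome.io import Connectome, NeuronTable

from conftest import random_connectome


def modularity_oracle(a, labels):
    """Literal double-loop evaluation of the modularity sum."""
    a = np.asarray(a, dtype=float)
    L = a.sum()
    k_in = a.sum(axis=1)
    k_out = a.sum(axis=0)
    q = 0.0
    for i in range(len(a)):
        for j in range(len(a)):
            if labels[i] == labels[j]:
                q += a[i, j] - k_in[i] * k_out[j] / L
    return q / L


def pair_modularity_oracle(a, labels, x, y):
    a = np.asarray(a, dtype=float)
    L = a.sum()
    k_in = a.sum(axis=1)
    k_out = a.sum(axis=0)
    q = 0.0
    for i in range(len(a)):
        for j in range(len(a)):
            if labels[i] == y and labels[j] == x:
                q += a[i, j] - k_in[i] * k_out[j] / L
    return q / L


class TestModularity:
    def test_two_nodes_one_edge_singletons(self):
        syn = np.array([[0, 1], [0, 0]], dtype=np.int8)
        c = Connectome(["a", "b"], syn, np.zeros((2, 2), np.int8))
        assert modularity(c, ["c1", "c2"]) == pytest.approx(0.0)

    @pytest.mark.parametrize("n, seed", [(5, 0), (8, 1), (10, 2), (12, 3)])
    @pytest.mark.parametrize("graph", ["syn", "gap"])
    def test_matches_double_loop_oracle(self, n, seed, graph):
        c = random_connectome(n, seed=seed)
        rng = np.random.default_rng(seed + 100)
        labels = rng.choice(["x", "y", "z"], size=n)
        got = modularity(c, labels, graph=graph)
        assert got == pytest.approx(
            modularity_oracle(c.matrix(graph), labels), abs=1e-12)

    def test_single_community(self):
        c = random_connectome(6, seed=4)
        q = modularity(c, ["m"] * 6)
        assert q == pytest.approx(modularity_oracle(c.syn, ["m"] * 6), abs=1e-12)

    def test_empty_graph_raises(self):
        c = Connectome(["a", "b"], np.zeros((2, 2), np.int8),
                       np.zeros((2, 2), np.int8))
        with pytest.raises(ValueError, match="no links"):
            modularity(c, ["x", "y"])

    def test_unlabeled_neurons_excluded(self):
        c = random_connectome(6, seed=5)
        full = modularity(c, ["x", "x", "y", "y", "x", "y"])
        labels = pd.Series(["x", "x", "y", "y", "x", "y"], index=c.neurons)
        labels.iloc[5] = np.nan
        reduced = modularity(c, labels)
        assert reduced != pytest.approx(full)  # computed on the subnetwork


class TestClassPairModularity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_and_diagonal_sums_to_q(self, seed):
        c = random_connectome(8, seed=seed)
        rng = np.random.default_rng(seed)
        labels = rng.choice(["a", "b", "c"], size=8)
        qxy = class_pair_modularity(c, labels)
        for x in "abc":
            for y in "abc":
                assert qxy.loc[x, y] == pytest.approx(
                    pair_modularity_oracle(c.syn, labels, x, y), abs=1e-12)
        q = modularity(c, labels)
        assert np.trace(qxy.values) == pytest.approx(q, abs=1e-12)

    def test_one_community_single_entry_equals_q(self):
        c = random_connectome(5, seed=7)
        qxy = class_pair_modularity(c, ["m"] * 5)
        assert qxy.shape == (1, 1)
        assert qxy.iloc[0, 0] == pytest.approx(modularity(c, ["m"] * 5))


class TestShuffleSurrogate:
    def test_class_sizes_preserved_every_realization(self):
        labels = np.array(["S"] * 5 + ["M"] * 3 + ["L"] * 2, dtype=object)
        for perm in shuffle_attribute_surrogate(labels, 50, seed=0):
            assert sorted(perm) == sorted(labels)

    def test_needs_two_realizations(self):
        with pytest.raises(ValueError):
            list(shuffle_attribute_surrogate(["a", "b"], 1))

    def test_surrogate_q_converges_to_analytic_expectation(self):
        # under a uniform label shuffle E[Q] is slightly negative (the
        # familiar finite-size bias): diagonal null-model terms always
        # count as same-label, off-diagonal terms with probability
        # sum n_x (n_x - 1) / (N (N - 1))
        c = random_connectome(20, p_syn=0.2, seed=8)
        n = 20
        labels = np.array(["x"] * 10 + ["y"] * 10, dtype=object)
        qs = [modularity(c, perm)
              for perm in shuffle_attribute_surrogate(labels, 500, seed=1)]
        a = c.syn.astype(float)
        L = a.sum()
        b = a - np.outer(a.sum(axis=1), a.sum(axis=0)) / L
        p_same = 2 * (10 * 9) / (n * (n - 1))
        expect = (np.trace(b) + p_same * (b.sum() - np.trace(b))) / L
        se = np.std(qs) / np.sqrt(len(qs))
        assert abs(np.mean(qs) - expect) < 4 * se
        assert abs(np.mean(qs)) < 0.05  # small on an absolute scale too

    def test_planted_assortative_graph_beats_every_surrogate(self):
        n = 16
        labels = np.array(["x"] * 8 + ["y"] * 8, dtype=object)
        syn = np.zeros((n, n), dtype=np.int8)
        rng = np.random.default_rng(2)
        for i in range(n):
            for j in range(n):
                if i != j and labels[i] == labels[j] and rng.random() < 0.8:
                    syn[i, j] = 1
        c = Connectome([f"n{i}" for i in range(n)], syn, np.zeros((n, n), np.int8))
        q_emp = modularity(c, labels)
        qs = [modularity(c, perm)
              for perm in shuffle_attribute_surrogate(labels, 100, seed=3)]
        assert q_emp > max(qs)


class TestZScore:
    def test_equal_to_mean_gives_zero(self):
        assert homophily_zscore(1.5, [1.0, 2.0]) == pytest.approx(0.0)

    def test_hand_arithmetic_population_sd(self):
        # samples {0, 2}: mean 1, population sd 1; x = 3 -> z = 2
        assert homophily_zscore(3.0, [0.0, 2.0]) == pytest.approx(2.0)

    def test_zero_variance_reported_undefined(self):
        assert np.isnan(homophily_zscore(1.0, [2.0, 2.0]))


class TestConstrainedRewiring:
    def test_invariants_on_every_realization(self, small_worm):
        table, conn, _, _ = small_worm
        rng = np.random.default_rng(0)
        Lb = table.body_length
        pos = table.positions()
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        for sur in constrained_rewire_surrogate(conn, table, n_swaps=3000,
                                                n_real=5, seed=42):
            np.testing.assert_array_equal(sur.k_in, conn.k_in)
            np.testing.assert_array_equal(sur.k_out, conn.k_out)
            np.testing.assert_array_equal(sur.k_gap, conn.k_gap)
            assert not np.diag(sur.syn).any()
            assert sur.syn.max() <= 1  # no multi-edges by construction
            # every rewired edge could at least have been reached by the
            # loosest possible draw: two full-body processes
            post, pre = np.nonzero(sur.syn)
            assert (dist[post, pre] <= 2 * Lb).all()

    def test_reach_constraint_respected_with_recorded_lengths(self, small_worm):
        # rerun one realization with the identical RNG stream to recover
        # the drawn lengths, then check no rewired edge exceeds the reach
        from devconnectome.homophily import draw_process_lengths
        table, conn, _, _ = small_worm
        seed = 7
        rng = np.random.default_rng(seed)
        lengths = draw_process_lengths(table, rng).reindex(conn.neurons)
        sur = next(constrained_rewire_surrogate(conn, table, n_swaps=3000,
                                                n_real=1, seed=seed))
        pos = table.positions()
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        reach = lengths.to_numpy()
        new_edges = (sur.syn == 1) & (conn.syn == 0)
        post, pre = np.nonzero(new_edges)
        assert (dist[post, pre] <= reach[post] + reach[pre] + 1e-12).all()

    def test_rewiring_moves_edges(self, small_worm):
        table, conn, _, _ = small_worm
        sur = next(constrained_rewire_surrogate(conn, table, n_swaps=5000,
                                                n_real=1, seed=1))
        assert (sur.syn != conn.syn).sum() > 0


class TestHomophilyReport:
    def test_planted_process_class_homophily_detected(self, small_worm):
        table, conn, _, _ = small_worm
        res = homophily_report(conn, table.column("proc_cat"), graph="syn",
                               n_real=60, seed=5)
        assert res.z > 2.0
        assert np.trace(res.Q_pairs.values) == pytest.approx(res.Q, abs=1e-12)

    def test_same_class_entries_dominate_cross_class(self, default_worm):
        table, conn, _, _ = default_worm
        res = homophily_report(conn, table.column("proc_cat"), graph="syn",
                               n_real=40, seed=6)
        qp = res.Q_pairs
        diag = np.diag(qp.values).mean()
        off = qp.values[~np.eye(len(qp), dtype=bool)].mean()
        assert diag > off


class TestBirthCohortAnalysis:
    def test_planted_short_range_homophily_flagged_only_there(self):
        # neurons on a line; same-cohort links only between close pairs,
        # cross-cohort links at long range keep degrees comparable
        rng = np.random.default_rng(0)
        n = 60
        x = rng.uniform(0, 1.0, n)
        cohort = np.where(np.arange(n) % 2 == 0, "early", "late")
        stage = np.where(cohort == "early", "Embryo", "L1")
        df = pd.DataFrame({
            "name": [f"n{i}" for i in range(n)], "x_ap": x, "y_dv": 0.0,
            "proc_cat": "L", "birth_time": np.where(cohort == "early", 300, 1200),
            "birth_stage": stage, "lineage_name": [None] * n,
        })
        df["lineage_name"] = ["AB" + format(i, "06b").replace(
            "0", "a").replace("1", "p") for i in range(n)]
        table = NeuronTable(df)
        dist = np.abs(x[:, None] - x[None, :])
        syn = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                short = dist[i, j] < table.body_length / 3
                same = cohort[i] == cohort[j]
                p = 0.5 if (short and same) else 0.02
                if rng.random() < p:
                    syn[i, j] = 1
        conn = Connectome(list(df["name"]), syn, np.zeros((n, n), np.int8))
        res = birth_cohort_analysis(conn, table, n_real=8, n_swaps=4000, seed=1)
        by_stratum = {r.stratum: r for r in res}
        assert by_stratum["short (d < L/3)"].homophily_flag

    def test_single_cohort_shows_nothing(self, small_worm):
        table, conn, _, _ = small_worm
        mono = NeuronTable(table.df.assign(cohort="early",
                                           birth_stage="Embryo",
                                           birth_time=300.0))
        res = birth_cohort_analysis(conn, mono, n_real=4, n_swaps=500, seed=2)
        for r in res:
            assert r.counts.get("early-late", 0) == 0
            assert r.counts.get("late-late", 0) == 0
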