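"""Graph metrics against brute-force oracles and hand-computed cases."""

import numpy as np
import pytest

from eegspan import (DEFAULT_DENSITIES, Montage, Partition,
                     characteristic_path_length, clustering_coefficient,
                     density_sweep, global_efficiency, louvain_partitions,
                     metrics_for_subject, modular_span, modularity, nmi,
                     nmi_matrix, participation_coefficients,
                     participation_sd, threshold_proportional,
                     MetricsConfig)
from eegspan.graph import ThresholdedGraph
from eegspan.synth import planted_partition_matrix


# ---------------------------------------------------------------------------
# brute-force oracles (naive loops; independent of the implementation)

def brute_clustering(w):
    wmax = w.max()
    if wmax <= 0:
        return 0.0
    n = len(w)
    cs = []
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            cs.append(0.0)
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += ((w[i, j] / wmax) * (w[i, h] / wmax)
                          * (w[j, h] / wmax)) ** (1 / 3)
        cs.append(total / (k * (k - 1)))
    return float(np.mean(cs))


def brute_dijkstra(w):
    n = len(w)
    dist = np.full((n, n), np.inf)
    for src in range(n):
        d = np.full(n, np.inf)
        d[src] = 0.0
        visited = np.zeros(n, bool)
        for _ in range(n):
            u = -1
            best = np.inf
            for v in range(n):
                if not visited[v] and d[v] < best:
                    best, u = d[v], v
            if u < 0:
                break
            visited[u] = True
            for v in range(n):
                if w[u, v] > 0 and d[u] + 1.0 / w[u, v] < d[v]:
                    d[v] = d[u] + 1.0 / w[u, v]
        dist[src] = d
    return dist


def brute_path_and_efficiency(w):
    d = brute_dijkstra(w)
    n = len(w)
    finite, inv = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                finite.append(d[i, j])
            inv.append(1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0
                       else 0.0)
    return float(np.mean(finite)), float(np.mean(inv))


def brute_participation(w, labels):
    n = len(w)
    p = []
    for i in range(n):
        k_i = sum(w[i, j] for j in range(n))
        if k_i == 0:
            p.append(0.0)
            continue
        acc = 0.0
        for mod in set(labels):
            k_im = sum(w[i, j] for j in range(n) if labels[j] == mod)
            acc += (k_im / k_i) ** 2
        p.append(1.0 - acc)
    return np.array(p)


def brute_nmi(a, b):
    n = len(a)
    mi = 0.0
    for la in set(a):
        for lb in set(b):
            p_ab = sum(1 for i in range(n) if a[i] == la and b[i] == lb) / n
            p_a = sum(1 for i in range(n) if a[i] == la) / n
            p_b = sum(1 for i in range(n) if b[i] == lb) / n
            if p_ab > 0:
                mi += p_ab * np.log(p_ab / (p_a * p_b))
    ha = -sum((np.count_nonzero(np.asarray(a) == la) / n)
              * np.log(np.count_nonzero(np.asarray(a) == la) / n)
              for la in set(a))
    hb = -sum((np.count_nonzero(np.asarray(b) == lb) / n)
              * np.log(np.count_nonzero(np.asarray(b) == lb) / n)
              for lb in set(b))
    if (ha + hb) == 0:
        return 1.0 if list(a) == list(b) else 0.0
    return mi / ((ha + hb) / 2.0)


def brute_modular_span(w, d, labels):
    spans = {}
    for mod in set(labels):
        nodes = [i for i in range(len(w)) if labels[i] == mod]
        if len(nodes) < 2:
            continue
        s = 0.0
        for i in nodes:
            for j in nodes:
                if j > i and w[i, j] > 0:
                    s += w[i, j] * d[i, j]
        spans[mod] = s / len(nodes)
    return spans


def random_weighted_graph(rng, n, p=0.4):
    w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < p), k=1)
    return ThresholdedGraph(w + w.T, density=p, retained_edges=int((w > 0).sum()))


# ---------------------------------------------------------------------------

class TestThresholding:
    def test_full_density_keeps_everything(self, rng):
        w = np.abs(rng.standard_normal((6, 6)))
        w = np.triu(w, 1) + np.triu(w, 1).T
        g = threshold_proportional(w, 1.0)
        assert np.allclose(g.adjacency, w)

    def test_ninety_one_channels_at_ten_percent(self, rng):
        w = rng.random((91, 91))
        w = np.triu(w, 1) + np.triu(w, 1).T
        g = threshold_proportional(w, 0.10)
        # 0.10 × 4095 = 409.5 rounds half-up to 410
        assert g.retained_edges == 410
        assert (np.triu(g.adjacency, 1) > 0).sum() == 410

    def test_top_three_of_six(self):
        w = np.zeros((4, 4))
        vals = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        iu = np.triu_indices(4, 1)
        w[iu] = vals
        w = w + w.T
        g = threshold_proportional(w, 0.5)
        kept = sorted(g.adjacency[iu][g.adjacency[iu] > 0], reverse=True)
        assert kept == [0.9, 0.8, 0.7]

    def test_sweep_is_nested_and_monotone(self, rng):
        w = rng.random((20, 20))
        w = np.triu(w, 1) + np.triu(w, 1).T
        sweep = density_sweep(w)
        assert len(sweep) == 17
        counts = [g.retained_edges for g in sweep]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        first = set(zip(*np.nonzero(np.triu(sweep[0].adjacency, 1))))
        last = set(zip(*np.nonzero(np.triu(sweep[-1].adjacency, 1))))
        assert last <= first

    def test_densities_grid(self):
        assert len(DEFAULT_DENSITIES) == 17
        assert DEFAULT_DENSITIES[0] == 0.50
        assert DEFAULT_DENSITIES[-1] == 0.10


class TestClustering:
    def test_complete_graph_unit_weights(self):
        w = np.ones((5, 5)) - np.eye(5)
        g = ThresholdedGraph(w, 1.0, 10)
        assert clustering_coefficient(g) == pytest.approx(1.0)

    def test_star_graph(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        g = ThresholdedGraph(w, 0.4, 4)
        assert clustering_coefficient(g) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            g = random_weighted_graph(rng, 10)
            assert clustering_coefficient(g) == pytest.approx(
                brute_clustering(g.adjacency), abs=1e-12)


class TestPathsAndEfficiency:
    def test_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        g = ThresholdedGraph(w, 1.0, 3)
        assert characteristic_path_length(g) == pytest.approx(1.0)
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        g = ThresholdedGraph(w, 2 / 3, 2)
        assert characteristic_path_length(g) == pytest.approx(4 / 3)
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_disconnected_dyads(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        g = ThresholdedGraph(w, 1 / 3, 2)
        assert characteristic_path_length(g) == pytest.approx(1.0)
        assert global_efficiency(g) == pytest.approx(1 / 3)

    def test_match_brute_force(self, rng):
        for _ in range(5):
            g = random_weighted_graph(rng, 12, p=0.3)
            l_ref, e_ref = brute_path_and_efficiency(g.adjacency)
            assert characteristic_path_length(g) == pytest.approx(l_ref, abs=1e-10)
            assert global_efficiency(g) == pytest.approx(e_ref, abs=1e-10)


class TestLouvain:
    def test_two_cliques(self):
        w = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        g = ThresholdedGraph(w, 0.4, 6)
        parts, q = louvain_partitions(g, n_reps=10, seed=0)
        # hand value: Q = 2 × (6/12 − (6/12)²) = 0.5
        assert q == pytest.approx(0.5)
        for p in parts:
            assert p.n_modules == 2
            assert len(set(p.assignment[:3])) == 1
            assert len(set(p.assignment[3:])) == 1

    def test_determinism(self, rng):
        g = random_weighted_graph(rng, 25)
        a = louvain_partitions(g, n_reps=8, seed=42)
        b = louvain_partitions(g, n_reps=8, seed=42)
        assert a[1] == b[1]
        for pa, pb in zip(a[0], b[0]):
            assert np.array_equal(pa.assignment, pb.assignment)

    def test_planted_partition_recovery_quick(self):
        hits = 0
        for seed in range(10):
            adj, truth = planted_partition_matrix(seed=seed)
            g = ThresholdedGraph(adj, 1.0, int(adj.sum() // 2))
            parts, _ = louvain_partitions(g, n_reps=1, seed=seed)
            if nmi(parts[0].assignment, truth) >= 0.9:
                hits += 1
        assert hits >= 9

    def test_empty_graph_trivial_partition(self):
        g = ThresholdedGraph(np.zeros((5, 5)), 0.1, 0)
        parts, q = louvain_partitions(g, n_reps=3, seed=0)
        assert q == 0.0
        assert all(p.n_modules == 1 for p in parts)


class TestParticipation:
    def test_all_intra_modular(self):
        w = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 0.7
        g = ThresholdedGraph(w, 0.4, 6)
        p = Partition(np.array([1, 1, 1, 2, 2, 2]))
        assert participation_sd(g, p) == 0.0
        assert np.allclose(participation_coefficients(g, p), 0.0)

    def test_equal_split_half(self):
        # node 0's weight split equally between two modules → P = 0.5
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        g = ThresholdedGraph(w, 2 / 3, 2)
        p = Partition(np.array([1, 1, 2]))
        assert participation_coefficients(g, p)[0] == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            g = random_weighted_graph(rng, 12)
            labels = rng.integers(1, 4, 12)
            ours = participation_coefficients(g, Partition(labels))
            ref = brute_participation(g.adjacency, Partition(labels).assignment)
            assert np.allclose(ours, ref, atol=1e-12)


class TestNmi:
    def test_identical_partitions(self, rng):
        a = rng.integers(1, 5, 40)
        assert nmi(a, a) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = rng.integers(1, 5, 30)
            b = rng.integers(1, 4, 30)
            assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)

    def test_independent_partitions_low(self, rng):
        vals = [nmi(rng.integers(1, 5, 91), rng.integers(1, 5, 91))
                for _ in range(100)]
        assert np.mean(vals) < 0.15

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import normalized_mutual_info_score
        for _ in range(10):
            a = rng.integers(1, 6, 25)
            b = rng.integers(1, 4, 25)
            assert nmi(a, b) == pytest.approx(brute_nmi(a, b), abs=1e-10)
            assert nmi(a, b) == pytest.approx(
                normalized_mutual_info_score(a, b,
                                             average_method="arithmetic"),
                abs=1e-10)

    def test_trivial_partition_conventions(self):
        ones = np.ones(10, dtype=int)
        assert nmi(ones, ones) == 1.0
        assert nmi(ones, np.arange(10)) == 0.0


class TestModularSpan:
    def _montage(self, positions):
        return Montage(tuple(f"E{i}" for i in range(len(positions))),
                       np.asarray(positions, float))

    def test_two_node_module(self):
        mont = self._montage([[0, 0, 0], [1, 0, 0]])
        w = np.array([[0, 1.0], [1.0, 0]])
        g = ThresholdedGraph(w, 1.0, 1)
        spans, largest = modular_span(g, Partition(np.array([1, 1])), mont)
        assert largest == pytest.approx(0.5)  # (1/2) × w·d = 0.5

    def test_three_node_hand_case(self):
        # module edges (w, d): (0.5, 0.2), (0.5, 0.2), (1.0, 0.4)
        # → S = (0.1 + 0.1 + 0.4) / 3 = 0.2
        # the fourth electrode only sets the normalization (d_max = 1)
        pos = [[0, 0, 0], [0.2, 0, 0], [0.4, 0, 0], [1.0, 0, 0]]
        mont = Montage(("a", "b", "c", "far"), np.asarray(pos, float))
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 1.0
        g = ThresholdedGraph(w, 0.5, 3)
        part = Partition(np.array([1, 1, 1, 2]))
        spans, largest = modular_span(g, part, mont)
        assert largest == pytest.approx(0.2, abs=1e-12)
        ref = brute_modular_span(w, mont.distances, part.assignment)
        assert ref[1] == pytest.approx(0.2, abs=1e-12)

    def test_linear_in_weights(self, rng, montage_small):
        g = random_weighted_graph(rng, 12)
        labels = rng.integers(1, 3, 12)
        _, s1 = modular_span(g, Partition(labels), montage_small)
        g2 = ThresholdedGraph(g.adjacency * 2, g.density, g.retained_edges)
        _, s2 = modular_span(g2, Partition(labels), montage_small)
        assert s2 == pytest.approx(2 * s1)

    def test_matches_brute_force(self, rng, montage_small):
        for _ in range(5):
            g = random_weighted_graph(rng, 12)
            labels = rng.integers(1, 4, 12)
            part = Partition(labels)
            spans, _ = modular_span(g, part, montage_small)
            ref = brute_modular_span(g.adjacency, montage_small.distances,
                                     part.assignment)
            for mod, val in ref.items():
                assert spans[mod] == pytest.approx(val, abs=1e-12)

    def test_degenerate_modules_excluded(self, montage_small, rng):
        g = random_weighted_graph(rng, 12)
        labels = np.r_[np.ones(11, int), [2]]  # one singleton module
        spans, _ = modular_span(g, Partition(labels), montage_small)
        assert set(spans) == {1}


class TestModularity:
    def test_two_cliques_hand_value(self):
        w = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        assert modularity(w, np.array([1, 1, 1, 2, 2, 2])) == pytest.approx(0.5)


class TestSubjectMetrics:
    def test_constant_matrix_deterministic_tie_break(self, montage_small):
        # all-equal weights exercise the tie-break: the sweep must be
        # reproducible, and at full density the graph is complete with
        # max-normalized unit weights, so clustering is exactly 1
        w = np.full((12, 12), 0.5)
        np.fill_diagonal(w, 0)
        cfg = MetricsConfig(densities=(1.0, 0.5, 0.3), n_reps=3, seed=0)
        res1 = metrics_for_subject(w, montage_small, config=cfg)
        res2 = metrics_for_subject(w, montage_small, config=cfg)
        assert res1.clustering[0] == pytest.approx(1.0)
        assert np.array_equal(res1.clustering, res2.clustering)
        assert np.array_equal(res1.modular_span, res2.modular_span)

    def test_determinism(self, rng, montage_small):
        w = rng.random((12, 12))
        w = np.triu(w, 1) + np.triu(w, 1).T
        cfg = MetricsConfig(densities=(0.4, 0.2), n_reps=4, seed=9)
        a = metrics_for_subject(w, montage_small, config=cfg)
        b = metrics_for_subject(w, montage_small, config=cfg)
        for attr in ("clustering", "path_length", "efficiency",
                     "modularity_q", "participation_sd", "modular_span"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
        for pa, pb in zip(a.partitions, b.partitions):
            assert np.array_equal(pa, pb)


class TestNmiMatrix:
    def test_identical_subjects(self, rng):
        memb = rng.integers(1, 4, size=(5, 20))
        subject = [memb, memb]  # two densities
        out = nmi_matrix([subject, subject, subject])
        assert np.allclose(out, 1.0)

    def test_symmetry_unit_diagonal(self, rng):
        subs = [[rng.integers(1, 4, size=(3, 20)) for _ in range(2)]
                for _ in range(4)]
        out = nmi_matrix(subs)
        assert np.allclose(out, out.T)
        assert np.allclose(np.diag(out), 1.0)
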