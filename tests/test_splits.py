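import numpy as np
import networkx as nx
import pytest

from hybriscope.errors import AnalysisError
from hybriscope.io_model import MarkerMatrix
from hybriscope.splits import (
    SplitSystem,
    circular_splits,
    group_cohesion,
    jaccard_distance,
    neighbor_net,
    neighbor_net_cycle,
)


def _matrix(rows):
    rows = np.asarray(rows)
    return MarkerMatrix(
        [f"s{i}" for i in range(rows.shape[0])],
        [f"L{j}" for j in range(rows.shape[1])],
        rows,
    )


def random_tree_distances(n, rng):
    """Random binary additive tree; returns (distance matrix, nontrivial
    splits as canonical label-sets with branch-length weights)."""
    g = nx.Graph()
    g.add_edge(0, 1, w=rng.uniform(0.1, 1.0))
    nxt = n
    for leaf in range(2, n):
        u, v, data = list(g.edges(data=True))[rng.integers(len(g.edges))]
        g.remove_edge(u, v)
        mid = nxt
        nxt += 1
        f = rng.uniform(0.2, 0.8)
        g.add_edge(u, mid, w=data["w"] * f)
        g.add_edge(mid, v, w=data["w"] * (1 - f))
        g.add_edge(mid, leaf, w=rng.uniform(0.1, 1.0))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    d = np.array([[lengths[i][j] for j in range(n)] for i in range(n)])
    tsplits = {}
    for u, v, data in g.edges(data=True):
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(str(x) for x in nx.node_connected_component(h, u) if x < n)
        if 1 < len(side) < n - 1:
            other = frozenset(str(x) for x in range(n)) - side
            key = min(side, other, key=lambda s: (len(s), sorted(s)))
            tsplits[key] = tsplits.get(key, 0.0) + data["w"]
    return d, tsplits


def _weights_by_labels(ss: SplitSystem):
    out = {}
    for side, w in ss.nontrivial_splits():
        labels = frozenset(ss.taxa[i] for i in side)
        other = frozenset(ss.taxa) - labels
        out[min(labels, other, key=lambda s: (len(s), sorted(s)))] = w
    return out


class TestJaccard:
    def test_identical_rows_distance_zero(self):
        d = jaccard_distance(_matrix([[1, 1, 0], [1, 1, 0]]))
        assert d[0, 1] == 0.0

    def test_hand_counted_example(self):
        d = jaccard_distance(_matrix([[1, 1, 0], [0, 1, 1]]))
        assert d[0, 1] == pytest.approx(1 - 1 / 3)

    def test_matches_set_oracle(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(0, 2, (12, 40)) | (rng.random((12, 40)) < 0.05))
        d = jaccard_distance(m)
        for i in range(12):
            for j in range(12):
                a = set(np.flatnonzero(m.values[i]))
                b = set(np.flatnonzero(m.values[j]))
                expect = 0.0 if i == j else 1 - len(a & b) / len(a | b)
                assert d[i, j] == pytest.approx(expect)

    def test_all_absent_pair_rejected(self):
        with pytest.raises(AnalysisError, match="undefined"):
            jaccard_distance(_matrix([[0, 0, 0], [0, 0, 0]]))


class TestNeighborNet:
    def test_recovers_additive_tree_splits(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d, tsplits = random_tree_distances(7, rng)
            ss = neighbor_net(d, taxa=[str(i) for i in range(7)])
            got = _weights_by_labels(ss)
            assert set(got) == set(tsplits)
            for k, w in tsplits.items():
                assert got[k] == pytest.approx(w, abs=1e-6)
            # induced split distance reproduces the input metric
            assert np.abs(ss.induced_distance() - d).max() < 1e-6

    def test_four_taxon_circular_metric_weights(self):
        cycle = [0, 1, 2, 3]
        sides = circular_splits(cycle)
        rng = np.random.default_rng(1)
        weights = {s: float(rng.uniform(0.1, 1.0)) for s in sides}
        d = np.zeros((4, 4))
        for s, w in weights.items():
            for i in range(4):
                for j in range(4):
                    if (i in s) != (j in s):
                        d[i, j] += w
        ss = neighbor_net(d)
        got = dict(ss.splits)
        for s, w in weights.items():
            matched = got.get(s) or got.get(frozenset(range(4)) - s)
            assert matched == pytest.approx(w, abs=1e-8)

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(3)
        d, _ = random_tree_distances(6, rng)
        taxa = [str(i) for i in range(6)]
        base = _weights_by_labels(neighbor_net(d, taxa=taxa))
        perm = rng.permutation(6)
        d2 = d[np.ix_(perm, perm)]
        permuted = _weights_by_labels(neighbor_net(d2, taxa=[taxa[i] for i in perm]))
        assert set(base) == set(permuted)
        for k in base:
            assert base[k] == pytest.approx(permuted[k], abs=1e-8)

    def test_equal_distances_symmetric_weights(self):
        d = np.ones((5, 5)) - np.eye(5)
        ss = neighbor_net(d)
        weights = {w for _, w in ss.splits}
        # all retained splits carry the same weight by exchangeability
        assert max(weights) - min(weights) < 1e-9

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(AnalysisError):
            neighbor_net_cycle(d)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(AnalysisError):
            neighbor_net(np.zeros((3, 3)))


class TestGroupCohesion:
    def test_two_separated_clusters_isolated_by_splits(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, (4, 60))
        left = np.hstack([a, np.zeros((4, 60), dtype=int), np.ones((4, 5), dtype=int)])
        right = np.hstack([np.zeros((4, 60), dtype=int), a, np.ones((4, 5), dtype=int)])
        m = _matrix(np.vstack([left, right]))
        d = jaccard_distance(m)
        ss = neighbor_net(d, taxa=m.sample_ids)
        groups = {"L": m.sample_ids[:4], "R": m.sample_ids[4:]}
        rep = group_cohesion(groups, splits=ss, d=d, sample_ids=m.sample_ids)
        for g in groups:
            assert rep[g]["isolated"]
            assert rep[g]["mean_within"] < rep[g]["mean_between"]

    def test_single_group_reports_no_between(self):
        d = np.zeros((4, 4))
        rep = group_cohesion({"only": ["a", "b", "c", "d"]}, d=d, sample_ids=list("abcd"))
        assert rep["only"]["mean_between"] is None

    def test_unknown_member_rejected(self):
        ss = SplitSystem(["a", "b", "c", "d"], [0, 1, 2, 3], [(frozenset({1}), 1.0)])
        with pytest.raises(AnalysisError):
            group_cohesion({"g": ["ghost"]}, splits=ss)

    def test_scenario_taxon_groups_separate(self, dataset):
        parents = [
            r.sample_id
            for r in dataset.meta.non_excluded()
            if r.replicate_of is None and r.taxon in ("P. argentea", "P. pusilla")
        ]
        m = dataset.matrix.subset(parents)
        d = jaccard_distance(m)
        groups = {}
        for s in parents:
            rec = dataset.meta.get(s)
            key = f"{rec.taxon} {rec.cytotype}x"
            groups.setdefault(key, []).append(s)
        rep = group_cohesion(groups, d=d, sample_ids=parents)
        for g, entry in rep.items():
            assert entry["mean_within"] < entry["mean_between"]
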