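import networkx as nx
import numpy as np
import pytest

from pgcna import (
    Partition,
    cluster_ensemble,
    louvain_run,
    modularity,
    select_partition,
)
from pgcna.io import SignatureDatabase

from oracles import best_modularity_exhaustive, modularity_reference, random_sparse_graph


class TestModularity:
    def test_two_triangles_partition_scores_half(self, two_triangles):
        part = {"a": "M1", "b": "M1", "c": "M1", "x": "M2", "y": "M2", "z": "M2"}
        assert modularity(two_triangles, part) == pytest.approx(0.5)

    def test_single_module_scores_zero(self, two_triangles):
        part = dict.fromkeys(two_triangles.nodes, "M1")
        assert modularity(two_triangles, part) == pytest.approx(0.0)

    def test_any_split_of_complete_graph_is_negative(self):
        k4 = nx.complete_graph(4)
        whole = modularity(k4, dict.fromkeys(k4.nodes, "M1"))
        assert whole == pytest.approx(0.0)
        split = modularity(k4, {0: "M1", 1: "M1", 2: "M2", 3: "M2"})
        assert split < 0

    def test_agrees_with_networkx_and_matrix_reference(self, rng):
        for _ in range(10):
            g = random_sparse_graph(rng, 7)
            part = louvain_run(g, seed=int(rng.integers(1e6)))
            comms = {}
            for node, label in part.assignment.items():
                comms.setdefault(label, set()).add(node)
            q_nx = nx.community.modularity(g, comms.values(), weight="weight")
            q_ref = modularity_reference(g, part.assignment)
            assert part.modularity == pytest.approx(q_nx, abs=1e-12)
            assert part.modularity == pytest.approx(q_ref, abs=1e-12)

    def test_zero_weight_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="zero total"):
            modularity(g, {"a": "M1", "b": "M1"})


class TestLouvainRun:
    def test_recovers_disjoint_triangles_exactly(self, two_triangles):
        part = louvain_run(two_triangles, seed=0)
        assert len(part) == 2
        assert part.modularity == pytest.approx(0.5)
        assert part.assignment["a"] == part.assignment["b"] == part.assignment["c"]
        assert part.assignment["x"] == part.assignment["y"] == part.assignment["z"]

    def test_isolated_node_becomes_singleton(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_node("lonely")
        part = louvain_run(g, seed=1)
        assert part.assignment["lonely"] not in (part.assignment["a"], part.assignment["b"])

    def test_deterministic_for_fixed_seed(self, two_triangles):
        assert louvain_run(two_triangles, seed=5).assignment == louvain_run(two_triangles, seed=5).assignment

    def test_labels_ordered_by_module_size(self, rng):
        g = nx.Graph()
        g.add_edges_from(nx.complete_graph(5).edges)
        g.add_edges_from([(f"b{i}", f"b{j}") for i in range(3) for j in range(i + 1, 3)])
        part = louvain_run(g, seed=3)
        sizes = [len(m) for _, m in sorted(part.modules().items(), key=lambda kv: int(kv[0][1:]))]
        assert sizes == sorted(sizes, reverse=True)
        assert part.labels()[0] == "M1"


class TestEnsemble:
    def test_q_non_increasing_and_kept_count(self, two_triangles):
        result = cluster_ensemble(two_triangles, n_runs=10, keep=3, base_seed=0)
        qs = [p.modularity for p in result.partitions]
        assert len(qs) == 3
        assert qs == sorted(qs, reverse=True)

    def test_reproducible_from_base_seed(self, two_triangles):
        a = cluster_ensemble(two_triangles, n_runs=8, keep=2, base_seed=11)
        b = cluster_ensemble(two_triangles, n_runs=8, keep=2, base_seed=11)
        assert [p.assignment for p in a.partitions] == [p.assignment for p in b.partitions]
        assert [p.seed for p in a.partitions] == [p.seed for p in b.partitions]

    def test_best_q_non_decreasing_in_runs(self, rng):
        g = random_sparse_graph(rng, 12)
        small = cluster_ensemble(g, n_runs=10, keep=1, base_seed=7)
        large = cluster_ensemble(g, n_runs=100, keep=1, base_seed=7)
        assert large.best.modularity >= small.best.modularity

    def test_stored_q_equals_recomputed_q(self, rng):
        g = random_sparse_graph(rng, 15)
        for part in cluster_ensemble(g, n_runs=20, keep=5, base_seed=1).partitions:
            assert modularity(g, part.assignment) == pytest.approx(part.modularity, abs=1e-12)

    def test_keep_larger_than_runs_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            cluster_ensemble(two_triangles, n_runs=2, keep=3)

    def test_matches_exhaustive_optimum_on_small_graphs(self, rng):
        hits = total = 0
        for _ in range(30):
            n = int(rng.integers(5, 9))
            g = random_sparse_graph(rng, n)
            best_q = cluster_ensemble(g, n_runs=100, keep=1, base_seed=3).best.modularity
            exact = best_modularity_exhaustive(g)
            total += 1
            hits += best_q >= exact - 1e-9
        assert hits / total >= 0.95


class TestSelectPartition:
    def test_max_modularity_returns_top(self, two_triangles):
        result = cluster_ensemble(two_triangles, n_runs=5, keep=3, base_seed=0)
        assert select_partition(result) is result.partitions[0]

    def test_enrichment_requires_signatures(self, two_triangles):
        result = cluster_ensemble(two_triangles, n_runs=3, keep=1, base_seed=0)
        with pytest.raises(ValueError, match="signatures"):
            select_partition(result, strategy="enrichment")

    def test_empty_ensemble_rejected(self):
        from pgcna.clustering import EnsembleResult

        with pytest.raises(ValueError):
            select_partition(EnsembleResult(partitions=[], n_runs=0))

    def test_enrichment_prefers_planted_split_over_coarse_merge(self):
        # Three 6-cliques; cliques A and B are densely bridged so that Q
        # genuinely favors merging them, but exact signatures for A and B
        # make the enrichment score prefer the planted three-way split.
        g = nx.Graph()
        blocks = {
            name: [f"{name}{i}" for i in range(6)] for name in ("A", "B", "C")
        }
        for members in blocks.values():
            for i in range(6):
                for j in range(i + 1, 6):
                    g.add_edge(members[i], members[j], weight=1.0)
        for a in blocks["A"]:
            for b in blocks["B"]:
                g.add_edge(a, b, weight=1.0)
        planted = {}
        for label, members in blocks.items():
            planted.update(dict.fromkeys(members, f"M_{label}"))
        coarse = {
            **dict.fromkeys(blocks["A"] + blocks["B"], "M_AB"),
            **dict.fromkeys(blocks["C"], "M_C"),
        }
        q_planted = modularity(g, planted)
        q_coarse = modularity(g, coarse)
        assert q_coarse > q_planted  # premise: modularity favors the merge
        from pgcna.clustering import EnsembleResult

        ensemble = EnsembleResult(
            partitions=[
                Partition(assignment=coarse, modularity=q_coarse),
                Partition(assignment=planted, modularity=q_planted),
            ],
            n_runs=2,
        )
        assert select_partition(ensemble).assignment == coarse
        signatures = SignatureDatabase(
            sets={name: frozenset(members) for name, members in blocks.items()}
        )
        chosen = select_partition(
            ensemble, strategy="enrichment", signatures=signatures,
            population=set(planted),
        )
        assert chosen.assignment == planted
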