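"""Min-label propagation vs the union-find oracle."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semascaf.clustering import (
    cluster_edges,
    oracle_components,
    propagate_once,
    relabel_consecutive,
)
from semascaf.edge_filter import EdgeTable
from semascaf.synthetic_data import GeneratorParams, generate

from conftest import make_edge


def table_of(edges):
    return EdgeTable.from_raw(list(edges))


def partition_from_assignment(assignment):
    """Clusters as frozensets of vertex ids (fragments and proteins mixed)."""
    groups = {}
    for vertex, label in assignment.fragment_clusters.items():
        groups.setdefault(label, set()).add(vertex)
    for vertex, label in assignment.protein_clusters.items():
        groups.setdefault(label, set()).add(vertex)
    return {frozenset(g) for g in groups.values()}


class TestPropagateOnce:
    def test_shared_vertex_takes_smaller_label(self):
        """An edge pair sharing a protein vertex converges on the smaller
        of the two labels within a single sweep (labels 45 and 328 → 45)."""
        edges = [make_edge(f"c{i}", f"p{i}") for i in range(1, 329)]
        edges[327] = make_edge("c328", "p45")  # edge 328 shares p45 with edge 45
        labels = {i: i for i in range(1, 329)}
        new_labels, changed = propagate_once(labels, edges)
        assert changed
        assert new_labels[45] == 45
        assert new_labels[328] == 45
        untouched = [i for i in range(1, 329) if i not in (45, 328)]
        assert all(new_labels[i] == i for i in untouched)

    def test_disjoint_edges_are_fixed_point(self):
        edges = [make_edge("c1", "p1"), make_edge("c2", "p2")]
        labels = {1: 1, 2: 2}
        new_labels, changed = propagate_once(labels, edges)
        assert new_labels == labels
        assert not changed

    def test_path_sweep(self):
        # e1–e2 share p1, e2–e3 share c2; e1 and e3 are disjoint
        edges = [make_edge("c1", "p1"), make_edge("c2", "p1"), make_edge("c2", "p2")]
        labels = {1: 1, 2: 2, 3: 3}
        new_labels, _ = propagate_once(labels, edges)
        assert new_labels[2] == 1
        assert new_labels[3] <= 2

    def test_labels_never_increase(self):
        edges = [make_edge("c1", "p1"), make_edge("c2", "p1"), make_edge("c2", "p2")]
        labels = {1: 3, 2: 1, 3: 2}
        new_labels, _ = propagate_once(labels, edges)
        assert all(new_labels[i] <= labels[i] for i in labels)


class TestClusterEdges:
    def test_chain_of_shared_vertices_is_one_cluster(self):
        table = table_of([
            make_edge("c1", "p1"), make_edge("c2", "p1"),
            make_edge("c2", "p2"), make_edge("c3", "p2"),
        ])
        assignment = cluster_edges(table)
        assert assignment.n_clusters == 1
        assert partition_from_assignment(assignment) == {
            frozenset({"c1", "c2", "c3", "p1", "p2"})
        }

    def test_disconnected_edges_are_separate_clusters(self):
        table = table_of([make_edge("c1", "p1"), make_edge("c2", "p2")])
        assignment = cluster_edges(table)
        assert assignment.n_clusters == 2

    def test_empty_table(self):
        assignment = cluster_edges(table_of([]))
        assert assignment.n_clusters == 0
        assert assignment.labels == {}
        assert assignment.fragment_clusters == {}

    def test_planted_components_recovered(self):
        instance = generate(GeneratorParams(n_components=10, seed=11))
        table = EdgeTable.from_raw(list(instance.edges))
        assignment = cluster_edges(table)
        assert assignment.n_clusters == 10
        recovered = {}
        for fragment, label in assignment.fragment_clusters.items():
            recovered.setdefault(label, set()).add(fragment)
        truth = {}
        for fragment, comp in instance.true_partition.items():
            truth.setdefault(comp, set()).add(fragment)
        assert {frozenset(v) for v in recovered.values()} == {
            frozenset(v) for v in truth.values()
        }

    def test_labels_consecutive_from_one(self):
        instance = generate(GeneratorParams(n_components=7, seed=5))
        assignment = cluster_edges(EdgeTable.from_raw(list(instance.edges)))
        labels = set(assignment.labels.values())
        assert labels == set(range(1, len(labels) + 1))


class TestRelabelConsecutive:
    def test_ranks_by_converged_label(self):
        edges = [make_edge(f"c{i}", f"p{i}") for i in range(1, 6)]
        from semascaf.clustering import ClusterAssignment

        raw = ClusterAssignment(
            labels={1: 45, 2: 45, 3: 2, 4: 2, 5: 97},
            n_iterations=3,
            fragment_clusters={},
            protein_clusters={},
        )
        relabeled = relabel_consecutive(raw, edges)
        assert relabeled.labels == {1: 2, 2: 2, 3: 1, 4: 1, 5: 3}

    def test_single_cluster_all_ones(self):
        edges = [make_edge("c1", "p1"), make_edge("c1", "p2")]
        assignment = cluster_edges(table_of(edges))
        assert set(assignment.labels.values()) == {1}


class TestOracle:
    def test_chain_is_one_component(self):
        components = oracle_components([
            make_edge("c1", "p1"), make_edge("c2", "p1"),
            make_edge("c2", "p2"), make_edge("c3", "p2"),
        ])
        assert components == [frozenset({"c1", "c2", "c3", "p1", "p2"})]

    def test_two_disjoint_edges(self):
        components = oracle_components([make_edge("c1", "p1"), make_edge("c2", "p2")])
        assert len(components) == 2

    def test_oracle_agrees_with_networkx(self):
        """Independent cross-check of the oracle itself on a random instance."""
        instance = generate(GeneratorParams(n_components=8, seed=13,
                                            merge_noise_rate=0.05))
        table = EdgeTable.from_raw(list(instance.edges))
        graph = nx.Graph((e.query_id, e.subject_id) for e in table)
        expected = {frozenset(c) for c in nx.connected_components(graph)}
        assert {frozenset(c) for c in oracle_components(table)} == expected


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("merge_noise", [0.0, 0.08])
def test_propagation_equals_oracle(seed, merge_noise):
    """The label-propagation partition equals union-find connected
    components on random instances with duplicate and noise edges."""
    instance = generate(GeneratorParams(
        n_components=6 + seed, seed=100 + seed, merge_noise_rate=merge_noise,
        n_orphan_fragments=2,
    ))
    table = EdgeTable.from_raw(list(instance.edges))
    assignment = cluster_edges(table)
    assert partition_from_assignment(assignment) == set(oracle_components(table))


@given(
    st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 5)),
        min_size=1, max_size=30,
    )
)
def test_propagation_equals_oracle_on_arbitrary_graphs(pairs):
    table = table_of([make_edge(f"c{q}", f"p{s}") for q, s in pairs])
    assignment = cluster_edges(table)
    assert partition_from_assignment(assignment) == set(oracle_components(table))


def test_row_permutation_leaves_partition_unchanged():
    instance = generate(GeneratorParams(n_components=9, seed=21))
    edges = list(instance.edges)
    base = partition_from_assignment(cluster_edges(EdgeTable.from_raw(edges)))
    reversed_part = partition_from_assignment(
        cluster_edges(EdgeTable.from_raw(edges[::-1]))
    )
    assert base == reversed_part


@pytest.mark.parametrize("workers", [2, 3, 8])
def test_worker_partitioning_is_invariant(workers):
    """Splitting the sweep across W equal shares changes nothing: labels,
    iteration count and partition all match the single-worker run."""
    instance = generate(GeneratorParams(n_components=12, seed=31))
    table = EdgeTable.from_raw(list(instance.edges))
    single = cluster_edges(table, workers=1)
    multi = cluster_edges(table, workers=workers)
    assert multi.labels == single.labels
    assert multi.n_iterations == single.n_iterations
    assert partition_from_assignment(multi) == partition_from_assignment(single)


def test_iteration_count_grows_with_path_length():
    """An adversarial path needs more sweeps the longer it is; the count
    is data-dependent, not a constant of the algorithm."""
    def path_table(n_links):
        edges = []
        for i in range(n_links):
            edges.append(make_edge(f"c{i}", f"p{i}"))
            edges.append(make_edge(f"c{i + 1}", f"p{i}"))
        # adversarial: smallest label at one end, reached link by link
        return table_of(edges[::-1])

    short = cluster_edges(path_table(4))
    long = cluster_edges(path_table(32))
    assert short.n_clusters == long.n_clusters == 1
    assert long.n_iterations > short.n_iterations
    assert long.n_iterations <= 2 * 32 + 1  # bounded by edge count
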