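import numpy as np
import pytest

from grnwalker.gcen import CoexpressionNetwork, build_network
from grnwalker.walker import (
    SamplerConfig,
    collect_neighborhood,
    enumerate_inference_subgraphs,
    sample_training_subgraph,
)


def _net_from_edges(nodes, edges, threshold=0.0):
    net = CoexpressionNetwork(nodes, threshold)
    for u, v in edges:
        net._add_edge(u, v, 0.5)
    return net


def _random_net(rng, n=25, p=0.15):
    nodes = [f"g{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return _net_from_edges(nodes, edges)


class TestCollectNeighborhood:
    def test_star_reaches_target_at_hop_one(self):
        nodes = ["hub"] + [f"n{i}" for i in range(300)]
        net = _net_from_edges(nodes, [("hub", n) for n in nodes[1:]])
        nbrs, hop, exhausted = collect_neighborhood(net, "hub", 99)
        assert len(nbrs) == 300  # the whole hop is collected
        assert hop == 1
        assert not exhausted

    def test_path_graph_expands_hop_by_hop(self):
        nodes = ["anchor"] + [f"g{i}" for i in range(120)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(120)]
        net = _net_from_edges(nodes, edges)
        nbrs, hop, exhausted = collect_neighborhood(net, "anchor", 99)
        assert len(nbrs) == 99
        assert hop == 99  # one new node per hop on a path
        assert not exhausted

    def test_small_component_exhausts(self):
        nodes = [f"g{i}" for i in range(40)]
        edges = [(nodes[0], n) for n in nodes[1:]]
        net = _net_from_edges(nodes + ["far"], edges)
        nbrs, hop, exhausted = collect_neighborhood(net, "g0", 99)
        assert len(nbrs) == 39
        assert exhausted

    def test_unknown_anchor_rejected(self, tiny_gcen):
        with pytest.raises(KeyError):
            collect_neighborhood(tiny_gcen, "not-a-gene", 10)


class TestTrainingSampler:
    def test_rich_neighbourhood_gives_exact_size(self):
        nodes = ["tf"] + [f"n{i}" for i in range(300)]
        net = _net_from_edges(nodes, [("tf", n) for n in nodes[1:]])
        sg = sample_training_subgraph(net, "tf", SamplerConfig(subgraph_size=100, seed=0))
        assert sg.n_nodes == 100
        assert sg.node_ids[0] == "tf"

    def test_boundary_neighbourhood_included_fully(self):
        nodes = ["tf"] + [f"n{i}" for i in range(99)]
        net = _net_from_edges(nodes, [("tf", n) for n in nodes[1:]])
        sg = sample_training_subgraph(net, "tf", SamplerConfig(subgraph_size=100, seed=0))
        assert sg.n_nodes == 100
        assert set(sg.node_ids) == set(nodes)

    def test_seeded_determinism(self, tiny_gcen, tiny_dataset):
        cfg = SamplerConfig(subgraph_size=10, seed=42)
        tf = tiny_dataset.tf_ids[0]
        a = sample_training_subgraph(tiny_gcen, tf, cfg)
        b = sample_training_subgraph(tiny_gcen, tf, cfg)
        assert a.node_ids == b.node_ids
        assert a.edges == b.edges

    def test_isolated_anchor_skipped(self, caplog):
        net = _net_from_edges(["tf", "a", "b"], [("a", "b")])
        with caplog.at_level("INFO"):
            assert sample_training_subgraph(net, "tf", SamplerConfig(seed=0)) is None
        assert any("isolated" in r.message for r in caplog.records)

    def test_small_component_emitted_not_discarded(self):
        net = _net_from_edges(["tf", "a", "b"], [("tf", "a"), ("a", "b")])
        sg = sample_training_subgraph(net, "tf", SamplerConfig(subgraph_size=100, seed=0))
        assert sg.n_nodes == 3
        assert sg.exhausted

    def test_induced_edge_completeness_on_random_graphs(self, rng):
        """Brute force: edge in subgraph iff edge in network, for node pairs."""
        for trial in range(50):
            net = _random_net(np.random.default_rng(trial), n=20, p=0.2)
            anchors = [g for g in net.gene_ids if net.degree(g) > 0][:3]
            for anchor in anchors:
                sg = sample_training_subgraph(
                    net, anchor, SamplerConfig(subgraph_size=8, seed=trial)
                )
                if sg is None:
                    continue
                have = {frozenset((u, v)) for u, v, _ in sg.edges}
                expect = {
                    frozenset((a, b))
                    for i, a in enumerate(sg.node_ids)
                    for b in sg.node_ids[i + 1 :]
                    if net.has_edge(a, b)
                }
                assert have == expect


class TestInferenceSampler:
    def test_chunking_covers_large_neighbourhood(self):
        nodes = ["tf"] + [f"n{i:03d}" for i in range(250)]
        net = _net_from_edges(nodes, [("tf", n) for n in nodes[1:]])
        cfg = SamplerConfig(subgraph_size=100, mode="infer")
        sgs = list(enumerate_inference_subgraphs(net, ["tf"], cfg))
        assert len(sgs) == 3  # ceil(250 / 99)
        assert all(sg.node_ids[0] == "tf" for sg in sgs)
        covered = set().union(*(set(sg.node_ids) for sg in sgs)) - {"tf"}
        assert covered == set(nodes[1:])

    def test_small_neighbourhood_single_subgraph(self):
        nodes = ["tf"] + [f"n{i}" for i in range(10)]
        net = _net_from_edges(nodes, [("tf", n) for n in nodes[1:]])
        sgs = list(enumerate_inference_subgraphs(net, ["tf"]))
        assert len(sgs) == 1
        assert sgs[0].n_nodes == 11

    def test_empty_tf_list_gives_empty_sequence(self, tiny_gcen):
        assert list(enumerate_inference_subgraphs(tiny_gcen, [])) == []

    def test_coverage_matches_collect_neighborhood(self, rng):
        for trial in range(50):
            net = _random_net(np.random.default_rng(100 + trial), n=20, p=0.2)
            cfg = SamplerConfig(subgraph_size=6, mode="infer")
            anchors = [g for g in net.gene_ids if net.degree(g) > 0][:2]
            for anchor in anchors:
                expected, _, _ = collect_neighborhood(net, anchor, cfg.subgraph_size - 1)
                sgs = list(enumerate_inference_subgraphs(net, [anchor], cfg))
                covered = set().union(*(set(s.node_ids) for s in sgs)) - {anchor}
                assert covered == set(expected)

    def test_deterministic_across_runs(self, tiny_gcen, tiny_dataset):
        cfg = SamplerConfig(subgraph_size=12, mode="infer")
        a = [s.node_ids for s in enumerate_inference_subgraphs(tiny_gcen, tiny_dataset.tf_ids, cfg)]
        b = [s.node_ids for s in enumerate_inference_subgraphs(tiny_gcen, tiny_dataset.tf_ids, cfg)]
        assert a == b


def test_train_mode_requires_seed():
    with pytest.raises(ValueError, match="seed"):
        SamplerConfig(mode="train", seed=None)
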