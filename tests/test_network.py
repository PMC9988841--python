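import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from readermap import (ChromosomeDomains, GenomicInterval, MarkSpec, PeakSet,
                       ReaderSpec, SyntheticConfig, build_network,
                       louvain_partition, modularity, pairwise_overlap_stats,
                       simulate_genome, simulate_marks, simulate_reader)
from readermap.network import ColocEdge


def two_triangles_bridge() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


def all_partitions(items):
    """Every set partition (Bell number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield smaller + [[first]]


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def test_modularity_single_community_is_zero():
    g = two_triangles_bridge()
    assert modularity(g, {n: 0 for n in g}) == pytest.approx(0.0, abs=1e-15)


def test_modularity_triangle_partition_hand_value():
    g = two_triangles_bridge()
    part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    assert modularity(g, part) == pytest.approx(5 / 14, abs=1e-12)
    # relabeling communities leaves Q unchanged
    relabeled = {n: {0: "x", 1: "y"}[c] for n, c in part.items()}
    assert modularity(g, relabeled) == pytest.approx(5 / 14, abs=1e-12)


def test_modularity_matches_networkx():
    g = two_triangles_bridge()
    for part in [{n: 0 for n in g}, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1},
                 {0: 0, 1: 0, 2: 1, 3: 1, 4: 2, 5: 2}]:
        comms = {}
        for n, c in part.items():
            comms.setdefault(c, set()).add(n)
        expected = nx.community.modularity(g, comms.values())
        assert modularity(g, part) == pytest.approx(expected, abs=1e-12)


def test_modularity_zero_weight_graph_errors():
    g = nx.Graph()
    g.add_nodes_from([0, 1])
    with pytest.raises(ValueError):
        modularity(g, {0: 0, 1: 1})


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def test_louvain_recovers_bruteforce_optimum():
    g = two_triangles_bridge()
    best_q, best_part = -1.0, None
    n_parts = 0
    for blocks in all_partitions(list(g.nodes)):
        n_parts += 1
        part = {n: i for i, block in enumerate(blocks) for n in block}
        q = modularity(g, part)
        if q > best_q:
            best_q, best_part = q, part
    assert n_parts == 203  # Bell(6)
    comm, q = louvain_partition(g, seed=0)
    assert q == pytest.approx(best_q, abs=1e-12)
    assert q == pytest.approx(5 / 14, abs=1e-12)
    groups = {}
    for n, c in comm.items():
        groups.setdefault(c, set()).add(n)
    assert set(map(frozenset, groups.values())) == {frozenset({0, 1, 2}),
                                                    frozenset({3, 4, 5})}
    # reported Q equals an independent recomputation
    assert modularity(g, comm) == pytest.approx(q, abs=1e-15)


def test_louvain_single_clique_one_community():
    g = nx.complete_graph(5)
    comm, _ = louvain_partition(g, seed=0)
    assert len(set(comm.values())) == 1


def test_louvain_deterministic_under_seed():
    rng = np.random.default_rng(4)
    g = nx.gnp_random_graph(30, 0.2, seed=4)
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.random())
    c1, q1 = louvain_partition(g, seed=3)
    c2, q2 = louvain_partition(g, seed=3)
    assert c1 == c2 and q1 == q2


def test_louvain_zero_edge_graph():
    g = nx.Graph()
    g.add_nodes_from("abc")
    comm, q = louvain_partition(g, seed=0)
    assert q is None
    assert len(set(comm.values())) == 3


# ---------------------------------------------------------------------------
# tiers and pairwise stats
# ---------------------------------------------------------------------------

def test_build_network_tiers():
    edges = [ColocEdge("a", "b", 0.7, 0.6, 0.6),
             ColocEdge("a", "c", 0.3, 0.4, 0.3),
             ColocEdge("b", "c", 0.1, 0.2, 0.1)]
    g = build_network(edges)
    assert g["a"]["b"]["tier"] == "strong"
    assert g["a"]["c"]["tier"] == "moderate"
    assert not g.has_edge("b", "c")
    assert set(g.nodes) == {"a", "b", "c"}  # isolated node kept


def test_build_network_empty_edges_keeps_isolated_nodes():
    g = build_network([ColocEdge("a", "b", 0.0, 0.0, 0.0)])
    assert g.number_of_edges() == 0 and set(g.nodes) == {"a", "b"}


def test_pairwise_identical_sparse_sets_full_weight():
    domains = ChromosomeDomains({"chrI": (10_000, 30_000, 40_000)})
    ivs = [GenomicInterval("chrI", s, s + 20) for s in (5000, 15_000, 35_000)]
    a = PeakSet("A", ivs)
    b = PeakSet("B", list(ivs))
    (edge,) = pairwise_overlap_stats([a, b], domains)
    assert edge.overlap_ab == 1.0 and edge.overlap_ba == 1.0
    assert edge.weight == 1.0


def test_pairwise_far_apart_sets_no_edge():
    # two singleton sets at opposite ends of a large domain: enumeration gives
    # p = (fraction of placements within the observed large distance) ~ 1
    domains = ChromosomeDomains({"chrI": (100_000, 300_000, 400_000)})
    a = PeakSet("A", [GenomicInterval("chrI", 1000, 1020)])
    b = PeakSet("B", [GenomicInterval("chrI", 98_000, 98_020)])
    (edge,) = pairwise_overlap_stats([a, b], domains)
    assert edge.weight == 0.0
    g = build_network([edge])
    assert g.number_of_edges() == 0


def test_pairwise_weight_symmetric():
    domains = ChromosomeDomains({"chrI": (10_000, 30_000, 40_000)})
    a = PeakSet("A", [GenomicInterval("chrI", s, s + 30) for s in range(1000, 5000, 500)])
    b = PeakSet("B", [GenomicInterval("chrI", s + 10, s + 40) for s in range(1000, 3000, 500)])
    (e1,) = pairwise_overlap_stats([a, b], domains)
    (e2,) = pairwise_overlap_stats([b, a], domains)
    assert e1.weight == pytest.approx(e2.weight)


# ---------------------------------------------------------------------------
# community recovery on synthetic groups
# ---------------------------------------------------------------------------

def test_community_recovery_on_grouped_readers():
    """Three reader groups coupled to three distinct heterochromatin marks
    are recovered as three network communities (high adjusted Rand index)."""
    marks = [MarkSpec(name, kind="het") for name in ("mA", "mB", "mC")]
    scores = []
    for seed in range(20):
        readers = [ReaderSpec(f"g{gi}_r{ri}", f"m{'ABC'[gi]}", 0.9, 80)
                   for gi in range(3) for ri in range(3)]
        cfg = SyntheticConfig(seed=seed,
                              chrom_lengths={"chrI": 1_000_000, "chrII": 1_000_000},
                              marks=marks, readers=readers, n_genes=50,
                              repeats_per_family=10)
        genome = simulate_genome(cfg)
        mark_data = simulate_marks(genome, cfg)
        peak_sets = [simulate_reader(genome, mark_data, spec, cfg).peaks
                     for spec in readers]
        edges = pairwise_overlap_stats(peak_sets, genome.domains)
        g = build_network(edges, moderate=0.25, strong=0.5)
        comm, _ = louvain_partition(g, seed=0)
        truth = [name.split("_")[0] for name in sorted(comm)]
        found = [comm[name] for name in sorted(comm)]
        scores.append(adjusted_rand_score(truth, found))
    assert np.mean(scores) >= 0.9
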