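"""Colocalization network: pairwise significant-overlap statistics, tiered
edges and modularity-based (Louvain) community detection.

Edge weight between two factors is the smaller of the two directional
significant-overlap fractions, which penalizes asymmetric engulfment of a
small peak set by a large one.  Communities are found by greedy modularity
optimization (local moves plus graph aggregation); modularity per pass is
asserted non-decreasing.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass

import networkx as nx

from .core import ChromosomeDomains, PeakSet
from .proximity import significant_fraction

logger = logging.getLogger("readermap")

TIER_STRONG = 0.5
TIER_MODERATE = 0.25


@dataclass
class ColocEdge:
    factor_a: str
    factor_b: str
    overlap_ab: float  # fraction of A peaks significantly overlapping B
    overlap_ba: float
    weight: float      # min of the two directional fractions
    tier: str = "none"


def pairwise_overlap_stats(peak_sets: list[PeakSet], domains: ChromosomeDomains,
                           alpha: float = 0.05, domain_class: str = "whole"
                           ) -> list[ColocEdge]:
    """Directional significant-overlap fractions for every unordered pair."""
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    edges = []
    for a, b in itertools.combinations(peak_sets, 2):
        f_ab, _ = significant_fraction(a, b, domains, alpha, domain_class)
        f_ba, _ = significant_fraction(b, a, domains, alpha, domain_class)
        edges.append(ColocEdge(a.sample, b.sample, f_ab, f_ba, min(f_ab, f_ba)))
    return edges


def build_network(candidates: list[ColocEdge],
                  roles: dict[str, str] | None = None,
                  strong: float = TIER_STRONG, moderate: float = TIER_MODERATE
                  ) -> nx.Graph:
    """Keep edges reaching the moderate tier; isolated nodes are retained."""
    if not strong > moderate:
        raise ValueError("tier thresholds must satisfy strong > moderate")
    g = nx.Graph()
    for e in candidates:
        for node in (e.factor_a, e.factor_b):
            g.add_node(node, role=(roles or {}).get(node, "factor"))
        if e.weight >= strong:
            e.tier = "strong"
        elif e.weight >= moderate:
            e.tier = "moderate"
        else:
            e.tier = "none"
            continue
        g.add_edge(e.factor_a, e.factor_b, weight=e.weight, tier=e.tier,
                   overlap_ab=e.overlap_ab, overlap_ba=e.overlap_ba)
    return g


def _degrees(g: nx.Graph) -> dict:
    # weighted degree with self-loops counted twice (modularity convention)
    deg = {}
    for n in g.nodes:
        d = 0.0
        for m, data in g[n].items():
            w = data.get("weight", 1.0)
            d += 2 * w if m == n else w
        deg[n] = d
    return deg


def modularity(g: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = sum_c [ W_c/W - (S_c / 2W)^2 ] on edge weights."""
    w_total = sum(data.get("weight", 1.0) for _, _, data in g.edges(data=True))
    if w_total <= 0:
        raise ValueError("graph has zero total edge weight")
    deg = _degrees(g)
    comms: dict = {}
    for node, c in partition.items():
        comms.setdefault(c, set()).add(node)
    q = 0.0
    for members in comms.values():
        w_in = sum(data.get("weight", 1.0) for u, v, data in g.edges(members, data=True)
                   if u in members and v in members)
        s = sum(deg[n] for n in members)
        q += w_in / w_total - (s / (2 * w_total)) ** 2
    return q


def _one_louvain_pass(g: nx.Graph, seed: int) -> tuple[dict, bool]:
    """Local-move phase: each node greedily joins the neighbor community with
    the largest modularity gain.  Nodes are visited in sorted order; the seed
    breaks exact gain ties."""
    rng = random.Random(seed)
    w_total = sum(data.get("weight", 1.0) for _, _, data in g.edges(data=True))
    deg = _degrees(g)
    comm = {n: n for n in sorted(g.nodes)}
    comm_deg = dict(deg)
    improved = False
    moved = True
    while moved:
        moved = False
        for node in sorted(g.nodes):
            cur = comm[node]
            k = deg[node]
            # link weight from node to each neighboring community (self-loops excluded)
            links: dict = {}
            for nb, data in g[node].items():
                if nb == node:
                    continue
                links[comm[nb]] = links.get(comm[nb], 0.0) + data.get("weight", 1.0)
            comm_deg[cur] -= k
            best_c, best_gain = cur, links.get(cur, 0.0) / w_total - comm_deg[cur] * k / (2 * w_total ** 2)
            candidates = []
            for c, l in sorted(links.items(), key=lambda kv: str(kv[0])):
                gain = l / w_total - comm_deg[c] * k / (2 * w_total ** 2)
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
                    candidates = [c]
                elif abs(gain - best_gain) <= 1e-12 and c != best_c:
                    candidates.append(c)
            if len(candidates) > 1:
                best_c = rng.choice(candidates)
            comm_deg[best_c] = comm_deg.get(best_c, 0.0) + k
            if best_c != cur:
                comm[node] = best_c
                moved = improved = True
    return comm, improved


def louvain_partition(g: nx.Graph, seed: int = 0) -> tuple[dict, float | None]:
    """Community detection by greedy modularity optimization.

    Returns (node -> community id, Q).  A graph without edges yields each
    node in its own community and Q = None (not applicable).
    """
    if g.number_of_edges() == 0:
        logger.warning("zero-edge graph: singleton communities, Q undefined")
        return {n: i for i, n in enumerate(sorted(g.nodes))}, None
    mapping = {n: n for n in g.nodes}
    work = g.copy()
    prev_q = modularity(g, mapping)
    while True:
        comm, improved = _one_louvain_pass(work, seed)
        if not improved:
            break
        mapping = {n: comm[mapping[n]] for n in mapping}
        q = modularity(g, mapping)
        assert q >= prev_q - 1e-12, "modularity decreased across a Louvain pass"
        prev_q = q
        # aggregation phase: one node per community
        agg = nx.Graph()
        agg.add_nodes_from(set(comm.values()))
        for u, v, data in work.edges(data=True):
            cu, cv = comm[u], comm[v]
            w = data.get("weight", 1.0)
            if agg.has_edge(cu, cv):
                agg[cu][cv]["weight"] += w
            else:
                agg.add_edge(cu, cv, weight=w)
        if agg.number_of_nodes() == work.number_of_nodes():
            break
        work = agg
    # relabel communities 0..k-1 in order of smallest member
    groups: dict = {}
    for node, c in mapping.items():
        groups.setdefault(c, []).append(node)
    final = {}
    for i, (_, members) in enumerate(sorted(groups.items(), key=lambda kv: str(min(kv[1])))):
        for n in members:
            final[n] = i
    return final, modularity(g, final)


def write_edges_tsv(edges: list[ColocEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("factor_a\tfactor_b\toverlap_ab\toverlap_ba\tweight\ttier\n")
        for e in edges:
            fh.write(f"{e.factor_a}\t{e.factor_b}\t{e.overlap_ab:.4f}\t"
                     f"{e.overlap_ba:.4f}\t{e.weight:.4f}\t{e.tier}\n")


def write_graphml(g: nx.Graph, communities: dict, path) -> None:
    out = g.copy()
    for n in out.nodes:
        out.nodes[n]["community"] = int(communities.get(n, -1))
    nx.write_graphml(out, path)
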