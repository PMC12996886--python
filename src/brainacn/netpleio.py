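"""Molecular-network pleiotropy statistics.

Given gene networks (directed transcriptional regulatory networks, undirected
PPI or co-expression graphs) and gene sets (brain-age-associated genes,
disorder risk genes), this module extracts seed-anchored subnetworks, scores
per-node connectivity into a subset (connectivity score, Cs), measures
between-subnetwork enrichment with a node-set Jaccard index, ranks hub
transcription factors by out-degree, and computes the fraction of
seed-interacting risk genes shared by two or more disorders (pleiotropy).

Note on naming: the enrichment index is the standard Jaccard *similarity*
|A∩B| / |A∪B| (higher = more similar), although the literature this follows
calls it a "Jaccard distance index".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols."""

    name: str
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class GeneNetwork:
    """A gene network: node set, edge list, directedness flag.

    Undirected edges are stored canonically (lexicographically ordered pair);
    self-loops are disallowed and every edge endpoint is a node.
    """

    nodes: FrozenSet[str]
    edges: Tuple[Tuple[str, str], ...]
    directed: bool = False
    kind: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) has endpoint outside node set")
            if not self.directed and u > v:
                raise ValueError(f"undirected edge ({u}, {v}) not canonically ordered")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        directed: bool = False,
        kind: str = "",
        extra_nodes: Iterable[str] = (),
        return_duplicate_count: bool = False,
    ):
        """Build a network, canonicalising undirected edges and dropping duplicates."""
        seen: Set[Tuple[str, str]] = set()
        ordered: List[Tuple[str, str]] = []
        n_dupes = 0
        for u, v in edges:
            e = (u, v) if directed or u <= v else (v, u)
            if e in seen:
                n_dupes += 1
                continue
            seen.add(e)
            ordered.append(e)
        nodes = {n for e in ordered for n in e} | set(extra_nodes)
        net = cls(nodes=frozenset(nodes), edges=tuple(ordered), directed=directed, kind=kind)
        if return_duplicate_count:
            return net, n_dupes
        return net

    def to_networkx(self) -> nx.Graph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def degree(self, node: str) -> int:
        """Number of connections of a node; directed networks use in + out."""
        return sum(1 for u, v in self.edges if node in (u, v))


def extract_subnetwork(network: GeneNetwork, seeds: GeneSet) -> GeneNetwork:
    """Seed-anchored subnetwork: keep edges with >= 1 endpoint in the seeds,
    then return the largest connected component (direction ignored for
    connectivity; size ties broken by smallest lexicographic node label)."""
    if not seeds.members:
        raise ValueError("seed set is empty")
    kept = [(u, v) for u, v in network.edges if u in seeds.members or v in seeds.members]
    if not kept:
        warnings.warn(f"no seed from {seeds.name!r} touches any edge; returning empty network", stacklevel=2)
        return GeneNetwork(nodes=frozenset(), edges=(), directed=network.directed, kind=network.kind)
    und = nx.Graph()
    und.add_edges_from(kept)
    components = sorted(nx.connected_components(und), key=lambda c: (-len(c), min(c)))
    biggest = components[0]
    sub_edges = tuple((u, v) for u, v in kept if u in biggest and v in biggest)
    return GeneNetwork(nodes=frozenset(biggest), edges=sub_edges,
                       directed=network.directed, kind=network.kind)


def connectivity_score(network: GeneNetwork, subset: GeneSet, node: str) -> float:
    """Cs = (C_i / C_o) / (N_i / N_o).

    C_i: the node's connections to subset members; C_o: all its connections;
    N_i: subset size; N_o: network size.  Cs > 1 means the node connects into
    the subset more than the subset's share of the network would predict.
    Isolated nodes score 0 by convention.
    """
    if node not in network.nodes:
        raise ValueError(f"node {node!r} not in network")
    if not subset.members:
        raise ValueError("subset is empty")
    c_i = c_o = 0
    for u, v in network.edges:
        if node == u:
            c_o += 1
            c_i += v in subset.members
        elif node == v:
            c_o += 1
            c_i += u in subset.members
    if c_o == 0:
        return 0.0
    n_i = len(subset.members)
    n_o = len(network.nodes)
    return (c_i / c_o) / (n_i / n_o)


def mean_connectivity(
    network: GeneNetwork, query_set: GeneSet, subset: GeneSet
) -> Tuple[float, float]:
    """Mean Cs over query genes present in the network, and the background
    mean over all other nodes (the "compared to other genes" contrast)."""
    present = sorted(query_set.members & network.nodes)
    if not present:
        raise ValueError(f"no member of {query_set.name!r} is in the network")
    q_mean = sum(connectivity_score(network, subset, n) for n in present) / len(present)
    others = sorted(network.nodes - query_set.members)
    bg_mean = (
        sum(connectivity_score(network, subset, n) for n in others) / len(others)
        if others else float("nan")
    )
    return q_mean, bg_mean


def jaccard_enrichment(a: GeneSet, b: GeneSet) -> float:
    """Node-set Jaccard similarity |A∩B| / |A∪B|; higher = more similar."""
    if not a.members and not b.members:
        raise ValueError("both gene sets are empty")
    union = a.members | b.members
    return len(a.members & b.members) / len(union)


def rank_hub_tfs(trn: GeneNetwork, seeds: GeneSet, k: int) -> List[Tuple[str, int]]:
    """Top-k seed transcription factors by out-degree in the seed subnetwork.

    A TF is a node with outgoing edges in the extracted subnetwork; ties in
    out-degree are broken lexicographically.
    """
    if not trn.directed:
        raise ValueError("hub-TF ranking requires a directed network")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = extract_subnetwork(trn, seeds)
    out_deg: Dict[str, int] = {}
    for u, _v in sub.edges:
        if u in seeds.members:
            out_deg[u] = out_deg.get(u, 0) + 1
    ranked = sorted(out_deg.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def pleiotropy_fraction(
    network: GeneNetwork,
    seeds: GeneSet,
    disorder_sets: Sequence[GeneSet],
) -> Tuple[float, Dict[str, List[str]]]:
    """Fraction of seed-interacting risk genes involved in >= 2 disorders.

    Risk genes are the union of the disorder sets; a risk gene "interacts"
    when it shares an edge with a seed gene.  Also returns the per-gene
    disorder-membership table for downstream annotation.
    """
    if len(disorder_sets) < 2:
        raise ValueError("need >= 2 disorder sets")
    risk = set().union(*(d.members for d in disorder_sets))
    interacting: Set[str] = set()
    for u, v in network.edges:
        if u in seeds.members and v in risk:
            interacting.add(v)
        if v in seeds.members and u in risk:
            interacting.add(u)
    if not interacting:
        warnings.warn("no risk gene interacts with any seed gene; fraction undefined", stacklevel=2)
        return float("nan"), {}
    membership = {
        g: sorted(d.name for d in disorder_sets if g in d.members)
        for g in sorted(interacting)
    }
    n_pleio = sum(1 for m in membership.values() if len(m) >= 2)
    return n_pleio / len(interacting), membership
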