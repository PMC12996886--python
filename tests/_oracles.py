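"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain scalar loops / enumeration, deliberately
avoiding the vectorised code paths (and, for the normal CDF, scipy) so that
agreement is a genuine two-route check.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np


def normal_cdf(x: float, mu: float, sigma: float) -> float:
    return 0.5 * (1.0 + math.erf((x - mu) / (sigma * math.sqrt(2.0))))


def soft_label_oracle(age: float, sigma: float) -> np.ndarray:
    """Per-bin normal mass over integer ages 5..94, renormalised."""
    probs = []
    for c in range(5, 95):
        probs.append(normal_cdf(c + 0.5, age, sigma) - normal_cdf(c - 0.5, age, sigma))
    total = sum(probs)
    return np.array([p / total for p in probs])


def age_loss_oracle(true_ages: Sequence[float], q: np.ndarray, sigma: float,
                    floor: float = 1e-12) -> float:
    """Scalar-loop L1 + KL age loss."""
    total = 0.0
    for i, y in enumerate(true_ages):
        p = soft_label_oracle(float(y), sigma)
        yhat = 0.0
        for j in range(90):
            yhat += q[i, j] * (5 + j)
        kl = 0.0
        for j in range(90):
            if p[j] > 0:
                kl += p[j] * math.log(max(p[j], floor)) - p[j] * math.log(max(q[i, j], floor))
        total += abs(y - yhat) + kl
    return total


def confound_loss_oracle(labels: Mapping[str, Sequence[int]],
                         probs: Mapping[str, np.ndarray],
                         floor: float = 1e-12) -> float:
    """Scalar-loop summed per-factor mean cross-entropy."""
    total = 0.0
    for name in labels:
        d = probs[name]
        n = len(labels[name])
        s = 0.0
        for j, c in enumerate(labels[name]):
            s += -math.log(max(d[j, c], floor))
        total += s / n
    return total


# ------------------------------------------------------------------- graphs

Edge = Tuple[str, str]


def connectivity_score_oracle(nodes: Set[str], edges: Sequence[Edge],
                              subset: Set[str], node: str) -> float:
    c_i = c_o = 0
    for u, v in edges:
        if node == u:
            c_o += 1
            if v in subset:
                c_i += 1
        elif node == v:
            c_o += 1
            if u in subset:
                c_i += 1
    if c_o == 0:
        return 0.0
    return (c_i / c_o) / (len(subset) / len(nodes))


def _components(nodes: Set[str], edges: Sequence[Edge]) -> List[Set[str]]:
    adj: Dict[str, Set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: Set[str] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    stack.append(nxt)
        comps.append(comp)
    return comps


def extract_subnetwork_oracle(edges: Sequence[Edge], seeds: Set[str]) -> Tuple[Set[str], Set[Edge]]:
    """Seed-touching edges, then largest component (ties: smallest min label)."""
    kept = [(u, v) for u, v in edges if u in seeds or v in seeds]
    if not kept:
        return set(), set()
    nodes = {n for e in kept for n in e}
    comps = _components(nodes, kept)
    comps.sort(key=lambda c: (-len(c), min(c)))
    best = comps[0]
    return best, {(u, v) for u, v in kept if u in best and v in best}


def jaccard_oracle(a: Set[str], b: Set[str]) -> float:
    return len(a & b) / len(a | b)


def pleiotropy_oracle(edges: Sequence[Edge], seeds: Set[str],
                      disorder_sets: Sequence[Set[str]]) -> float:
    risk = set().union(*disorder_sets)
    interacting = set()
    for u, v in edges:
        if u in seeds and v in risk:
            interacting.add(v)
        if v in seeds and u in risk:
            interacting.add(u)
    if not interacting:
        return float("nan")
    pleio = sum(1 for g in interacting if sum(g in d for d in disorder_sets) >= 2)
    return pleio / len(interacting)


def erdos_renyi_edges(n: int, p: float, rng: np.random.Generator) -> List[Edge]:
    names = [f"g{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j]))
    return edges
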