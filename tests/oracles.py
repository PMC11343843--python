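"""Independent oracles: brute-force / closed-form reference computations.

These deliberately avoid the package's own code paths: the ILP oracle
enumerates every state assignment and edge subset, the hypergeometric
oracle sums binomial coefficients, and the enrichment oracle evaluates
the NES formula directly from sorted ranks.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence


def brute_force_optimize(edges: Sequence[tuple[str, str, int]],
                         measured: Mapping[str, int],
                         sources: Mapping[str, int],
                         beta: float,
                         weights: Mapping[str, float] | None = None) -> float:
    """Exhaustive minimum of the sign-coherent subnetwork objective.

    Enumerates all node-state assignments in {-1, 0, +1} and, per
    assignment, all subsets of the state-coherent edges, keeping only
    subsets that support every nonzero non-source node and are acyclic.
    """
    weights = weights or {}
    nodes = sorted({u for u, _, _ in edges} | {v for _, v, _ in edges}
                   | set(measured) | set(sources))
    free = [n for n in nodes if n not in sources]
    best = math.inf
    for assignment in itertools.product((-1, 0, 1), repeat=len(free)):
        state = dict(sources)
        state.update(zip(free, assignment))
        mismatch = sum(weights.get(n, 1.0) * abs(m - state[n])
                       for n, m in measured.items())
        if mismatch >= best:
            continue
        coherent = [k for k, (u, v, s) in enumerate(edges)
                    if state[u] != 0 and state[v] == s * state[u]]
        need_support = [n for n in nodes
                        if state[n] != 0 and n not in sources]
        for mask in range(1 << len(coherent)):
            chosen = [edges[coherent[k]] for k in range(len(coherent))
                      if mask >> k & 1]
            cost = mismatch + beta * len(chosen)
            if cost >= best:
                continue
            has_in = {v for _, v, _ in chosen}
            if any(n not in has_in for n in need_support):
                continue
            if _has_cycle(chosen):
                continue
            best = cost
    return best


def _has_cycle(edges: Iterable[tuple[str, str, int]]) -> bool:
    """Kahn's algorithm on the selected edge set."""
    adj: dict[str, list[str]] = {}
    indeg: dict[str, int] = {}
    for u, v, _ in edges:
        adj.setdefault(u, []).append(v)
        indeg[v] = indeg.get(v, 0) + 1
        indeg.setdefault(u, 0)
    queue = [n for n, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for v in adj.get(n, []):
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    return seen < len(indeg)


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct combinatorial summation."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def nes_by_hand(signature: Mapping[str, float],
                targets: Sequence[tuple[str, float, float]]) -> float:
    """NES from first principles: average ranks → normal quantiles →
    weighted mode-signed sum / sqrt(sum w^2)."""
    from statistics import NormalDist

    items = sorted(signature.items(), key=lambda kv: kv[1])
    values = [v for _, v in items]
    ranks: dict[str, float] = {}
    for analyte, value in signature.items():
        less = sum(1 for v in values if v < value)
        equal = sum(1 for v in values if v == value)
        ranks[analyte] = less + (equal + 1) / 2.0
    nd = NormalDist()
    num = 0.0
    den = 0.0
    for analyte, mode, weight in targets:
        q = nd.inv_cdf(ranks[analyte] / (len(values) + 1))
        num += weight * mode * q
        den += weight ** 2
    return num / math.sqrt(den)


def zscores_by_hand(values: Sequence[float]) -> list[float]:
    """Sample-sd z-scores, direct formula."""
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    sd = math.sqrt(var)
    return [(v - mean) / sd for v in values]


def random_ilp_instance(seed: int, n_nodes: int = 6, n_edges: int = 8):
    """Seeded random instance for oracle-equivalence checks.

    Returns (edges, measured, sources, beta).
    """
    import random

    rng = random.Random(seed)
    nodes = [f"N{i}" for i in range(n_nodes)]
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    rng.shuffle(pairs)
    edges = [(u, v, rng.choice((-1, 1))) for u, v in pairs[:n_edges]]
    touched = sorted({u for u, _, _ in edges} | {v for _, v, _ in edges})
    source = rng.choice(touched)
    sources = {source: rng.choice((-1, 1))}
    n_measured = rng.randint(1, min(3, len(touched) - 1))
    candidates = [n for n in touched if n != source]
    measured = {n: rng.choice((-1, 1))
                for n in rng.sample(candidates, n_measured)}
    beta = rng.choice((0.0, 0.1, 0.2, 0.5))
    return edges, measured, sources, beta
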