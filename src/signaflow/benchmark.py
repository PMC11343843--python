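"""Gold-standard scoring, topological metrics and randomization suite.

Predictions are compared against a signed gold standard: an inferred
entity matching / diverging from the expected sign is a true / false
positive; inferable gold entities that were not inferred are false
negatives; entities flagged *not inferable* are excluded from all
counts. RMSE compares signed predictions (clipped to ±1) against
expected signs over the inferred ∩ gold intersection.

Two printed combined scores rank parameter settings:

    score_step2 = (precision·0.5 + recall·0.5 + SignRatio·0.5
                   + ClusteringCoefficient·0.5)
                  - (NormTime·0.2 + PowerLawFit)
    score_step3 = (precision + recall) - (normRMSE + normTime·0.5)

Robustness is probed by degree-preserving rewiring of the signed PKN
(double-edge swaps within each sign stratum) and by shuffling a
fraction of analyte statistics in the omics tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .pkn import CausalEdge, PKNGraph

logger = logging.getLogger("signaflow.benchmark")


@dataclass
class MetricBundle:
    """Container for quality, topology and cost metrics."""

    precision: float = math.nan
    recall: float = math.nan
    rmse: float = math.nan
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    sign_ratio: float = math.nan
    clustering_coefficient: float = math.nan
    power_law_fit: float = math.nan
    norm_time: float = math.nan
    norm_rmse: float = math.nan
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gold-standard comparison
# ---------------------------------------------------------------------------

def prf_rmse(predictions: pd.DataFrame, gold: pd.DataFrame) -> MetricBundle:
    """Precision, recall and RMSE of signed predictions vs a gold standard.

    ``predictions``: columns entity (or gene_name) and activity (±1).
    ``gold``: columns entity, expected (±1), inferable (boolean).
    True negatives follow the convention "opposite activity than
    expected and not inferred" and feed no downstream formula.
    """
    pcol = "entity" if "entity" in predictions.columns else "gene_name"
    pred = predictions.set_index(pcol)["activity"].astype(int)
    g = gold[gold["inferable"].astype(bool)].set_index("entity")
    expected = g["expected"].astype(int)

    inferred = set(pred.index) & set(expected.index)
    tp = sum(1 for e in inferred if pred[e] == expected[e])
    fp = sum(1 for e in inferred if pred[e] != expected[e])
    fn = len(set(expected.index) - set(pred.index))
    tn = fp  # literal definition: opposite activity than expected, not inferred
    bundle = MetricBundle(tp=tp, fp=fp, fn=fn, tn=tn)
    bundle.precision = tp / (tp + fp) if (tp + fp) else math.nan
    bundle.recall = tp / (tp + fn) if (tp + fn) else math.nan
    if inferred:
        sq = [(np.sign(pred[e]) - expected[e]) ** 2 for e in inferred]
        bundle.rmse = float(np.sqrt(np.mean(sq)))
    return bundle


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def _power_law_fit(degrees: np.ndarray) -> float:
    """KS distance between the degree distribution and an ML power law.

    A discrete power law p(k) ∝ k^-alpha (k >= 1) is fitted by maximum
    likelihood; the statistic is the Kolmogorov–Smirnov distance between
    the empirical and fitted CDFs over the observed degrees.
    """
    degrees = degrees[degrees >= 1]
    if len(degrees) < 2 or degrees.max() == degrees.min():
        return 0.0

    def nll(alpha: float) -> float:
        return len(degrees) * math.log(zeta(alpha)) + alpha * np.sum(np.log(degrees))

    res = minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    alpha = float(res.x)
    ks = np.arange(1, degrees.max() + 1)
    pmf = ks.astype(float) ** (-alpha) / zeta(alpha)
    cdf_fit = np.cumsum(pmf)
    cdf_emp = np.array([(degrees <= k).mean() for k in ks])
    return float(np.max(np.abs(cdf_emp - cdf_fit)))


def topology_metrics(graph: nx.DiGraph) -> MetricBundle:
    """Node/edge/component counts, clustering, diameter, power-law fit."""
    if graph.number_of_nodes() == 0:
        raise ValueError("topology metrics need a nonempty graph")
    und = graph.to_undirected()
    bundle = MetricBundle()
    bundle.extras["n_nodes"] = graph.number_of_nodes()
    bundle.extras["n_edges"] = graph.number_of_edges()
    comps = list(nx.connected_components(und))
    bundle.extras["n_components"] = len(comps)
    if graph.number_of_nodes() == 1:
        bundle.clustering_coefficient = 0.0
        bundle.extras["diameter"] = 0
    else:
        bundle.clustering_coefficient = float(nx.transitivity(und))
        largest = und.subgraph(max(comps, key=len))
        bundle.extras["diameter"] = int(nx.diameter(largest)) \
            if largest.number_of_nodes() > 1 else 0
    degrees = np.array([d for _, d in und.degree()])
    bundle.power_law_fit = _power_law_fit(degrees)
    return bundle


# ---------------------------------------------------------------------------
# combined scores
# ---------------------------------------------------------------------------

def combined_score_step2(bundle: MetricBundle) -> float:
    """Network-construction ranking score (higher is better)."""
    parts = {"precision": bundle.precision, "recall": bundle.recall,
             "sign_ratio": bundle.sign_ratio,
             "clustering_coefficient": bundle.clustering_coefficient,
             "norm_time": bundle.norm_time,
             "power_law_fit": bundle.power_law_fit}
    missing = [k for k, v in parts.items() if v is None or math.isnan(v)]
    if missing:
        raise ValueError(f"combined_score_step2 missing components: {missing}")
    return (parts["precision"] * 0.5 + parts["recall"] * 0.5
            + parts["sign_ratio"] * 0.5 + parts["clustering_coefficient"] * 0.5
            ) - (parts["norm_time"] * 0.2 + parts["power_law_fit"])


def combined_score_step3(bundle: MetricBundle) -> float:
    """Phenotype-inference ranking score (higher is better)."""
    parts = {"precision": bundle.precision, "recall": bundle.recall,
             "norm_rmse": bundle.norm_rmse, "norm_time": bundle.norm_time}
    missing = [k for k, v in parts.items() if v is None or math.isnan(v)]
    if missing:
        raise ValueError(f"combined_score_step3 missing components: {missing}")
    return (parts["precision"] + parts["recall"]) \
        - (parts["norm_rmse"] + parts["norm_time"] * 0.5)


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------

def _swap_edges(edges: list[CausalEdge], fraction: float,
                rng: np.random.Generator,
                forbidden: set[tuple[str, str]]) -> tuple[list[CausalEdge], int]:
    """Double-edge swaps until >= fraction of the stratum's edges moved.

    ``forbidden`` holds every (source, target) pair of the whole graph
    (both strata) and is kept current, so a swap never recreates an
    existing pair — including one of opposite sign, which would be
    dropped as a conflict at reassembly.
    """
    edges = list(edges)
    n = len(edges)
    target_moved = math.ceil(fraction * n)
    moved: set[int] = set()
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(moved) < target_moved and attempts < max_attempts:
        attempts += 1
        i, j = rng.choice(n, size=2, replace=False)
        a, b = edges[i], edges[j]
        # swap targets: a.source->b.target, b.source->a.target
        if a.source == b.target or b.source == a.target:
            continue
        old_a = (a.source, a.target)
        old_b = (b.source, b.target)
        new_a = (a.source, b.target)
        new_b = (b.source, a.target)
        if new_a == new_b or new_a == old_a or new_b == old_b:
            continue
        if new_a in forbidden or new_b in forbidden:
            continue
        forbidden.discard(old_a)
        forbidden.discard(old_b)
        forbidden.update((new_a, new_b))
        edges[i] = CausalEdge(a.source, b.target, a.sign, direct=a.direct,
                              mechanism=a.mechanism, residue=a.residue,
                              source_db=a.source_db)
        edges[j] = CausalEdge(b.source, a.target, b.sign, direct=b.direct,
                              mechanism=b.mechanism, residue=b.residue,
                              source_db=b.source_db)
        moved.update((int(i), int(j)))
    return edges, len(moved)


def rewire_network(pkn: PKNGraph, fraction: float, n_reps: int,
                   seed: int) -> list[PKNGraph]:
    """Degree-preserving randomizations of a signed PKN.

    Double-edge swaps are applied separately within the positive- and
    negative-edge strata until at least ``fraction`` of each stratum's
    edges have moved; every node's signed in- and out-degrees are
    preserved exactly. Reproducible from ``seed``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    pos = [e for e in pkn.edges if e.sign == 1]
    neg = [e for e in pkn.edges if e.sign == -1]
    if len(pos) < 2 and len(neg) < 2:
        raise ValueError("graph too small to swap: need >= 2 same-sign edges")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        new_edges: list[CausalEdge] = []
        forbidden = {(e.source, e.target) for e in pkn.edges}
        for stratum in (pos, neg):
            if len(stratum) >= 2:
                swapped, n_moved = _swap_edges(stratum, fraction, rng,
                                               forbidden)
                if n_moved < math.ceil(fraction * len(stratum)):
                    logger.warning("stratum saturated at %d/%d moved edges",
                                   n_moved, len(stratum))
                new_edges.extend(swapped)
            else:
                new_edges.extend(stratum)
        out.append(PKNGraph(edges=new_edges,
                            node_attrs={n: dict(a)
                                        for n, a in pkn.node_attrs.items()}))
    return out


def signed_degree_vector(pkn: PKNGraph) -> dict[str, tuple[int, int, int, int]]:
    """Per-node (out+, out-, in+, in-) degree counts."""
    vec: dict[str, list[int]] = {}
    for e in pkn.edges:
        vec.setdefault(e.source, [0, 0, 0, 0])
        vec.setdefault(e.target, [0, 0, 0, 0])
        vec[e.source][0 if e.sign == 1 else 1] += 1
        vec[e.target][2 if e.sign == 1 else 3] += 1
    return {n: tuple(v) for n, v in vec.items()}


def shuffle_regulons(regulons: Mapping[str, pd.DataFrame], fraction: float,
                     n_reps: int = 100, seed: int = 0
                     ) -> list[dict[str, pd.DataFrame]]:
    """Permute target assignments across regulators.

    A ``fraction`` of all (regulator, target) assignments is chosen and
    the target analytes permuted among those slots, so regulators end
    up with targets drawn from other regulons while regulon sizes,
    modes and weights stay fixed. Reproducible from seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    names = sorted(regulons)
    flat = [(r, i) for r in names for i in range(len(regulons[r]))]
    n = len(flat)
    k = math.ceil(fraction * n)
    out = []
    for _ in range(n_reps):
        slots = rng.choice(n, size=k, replace=False)
        perm = rng.permutation(k)
        targets = {s: regulons[flat[s][0]].iloc[flat[s][1]]["target"]
                   for s in slots}
        new = {r: regulons[r].copy() for r in names}
        for a, b in zip(slots, slots[perm]):
            r, i = flat[a]
            new[r].iloc[i, new[r].columns.get_loc("target")] = targets[b]
        out.append(new)
    return out


def shuffle_analytes(table: pd.DataFrame, fraction: float,
                     n_reps: int = 100, seed: int = 0) -> list[pd.DataFrame]:
    """Permute the statistic among a random fraction of table rows.

    For each repetition, ``ceil(fraction * n)`` rows are chosen and
    their ``difference`` (and ``significant``) values permuted among
    themselves; remaining rows are untouched. Reproducible from seed.
    """
    if table.empty:
        raise ValueError("cannot shuffle an empty table")
    rng = np.random.default_rng(seed)
    n = len(table)
    k = math.ceil(fraction * n)
    out = []
    for _ in range(n_reps):
        shuffled = table.copy().reset_index(drop=True)
        rows = rng.choice(n, size=k, replace=False)
        perm = rng.permutation(k)
        cols = [c for c in ("difference", "significant", "z")
                if c in shuffled.columns]
        shuffled.loc[rows, cols] = shuffled.loc[rows[perm], cols].to_numpy()
        out.append(shuffled)
    return out
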