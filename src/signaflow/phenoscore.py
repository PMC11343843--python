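"""Step 3 — phenotype proximity scoring and phenotype activity inference.

Model proteins are connected to phenotype nodes of a phenotype-augmented
causal graph through signed paths. For every (protein, phenotype,
aggregate path sign) triple, the *observed* score is the shortest path
length among paths of that sign with length <= ``max_len``; it is
compared against a null distribution of path lengths from degree-matched
random source nodes, giving

    z = (observed - stat(null)) / sd(null),   significant iff z <= -1.96

(a short path is *closer* than random, hence the left tail). The
*PhenoScore* of a phenotype is then the (optionally path-count-weighted)
mean over its significant upstream regulators of path sign × regulator
activity, a value in [-1, +1] when regulator activities are signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import SignalingModel

logger = logging.getLogger("signaflow.phenoscore")

Z_CUTOFF = -1.96


@dataclass(frozen=True)
class PhenotypePath:
    """Signed shortest-path proximity of one regulator to one phenotype."""

    regulator: str
    phenotype: str
    length: int
    path_sign: int
    z: float
    significant: bool


def build_phenotype_graph(base_graph: nx.DiGraph,
                          phenotype_edges: pd.DataFrame) -> nx.DiGraph:
    """Augment a causal graph with signed protein → phenotype edges.

    ``phenotype_edges`` has columns protein, phenotype, sign.
    """
    g = base_graph.copy()
    for _, row in phenotype_edges.iterrows():
        protein, phenotype = str(row["protein"]), str(row["phenotype"])
        if protein not in g:
            continue
        g.add_node(phenotype, entity_type="phenotype")
        g.add_edge(protein, phenotype, sign=int(row["sign"]),
                   mechanism="phenotype_regulation", residue="",
                   source_db="phenotype")
    return g


def _signed_shortest_length(g: nx.DiGraph, source: str, target: str,
                            sign_class: int, max_len: int) -> int | None:
    """Shortest length of a source→target path whose edge-sign product
    equals ``sign_class``, or None if none exists within ``max_len``.

    Runs BFS on the parity expansion of the graph: state (node, parity)
    with parity flipped by inhibiting edges.
    """
    if source not in g or target not in g:
        return None
    frontier = {(source, 1)}
    seen = {(source, 1)}
    for depth in range(1, max_len + 1):
        nxt = set()
        for node, parity in frontier:
            for _, v, data in g.out_edges(node, data=True):
                state = (v, parity * int(data["sign"]))
                if state in seen:
                    continue
                if v == target and state[1] == sign_class:
                    return depth
                seen.add(state)
                nxt.add(state)
        frontier = nxt
        if not frontier:
            break
    return None


def _degree_matched_pool(g: nx.DiGraph, node: str,
                         exclude: set[str]) -> list[str]:
    """Candidate null sources with out-degree closest to ``node``'s.

    The tolerance widens until at least 10 candidates are found (or the
    graph is exhausted), keeping the null degree-matched but non-empty
    on small graphs.
    """
    deg = g.out_degree(node)
    candidates = [(abs(g.out_degree(n) - deg), n) for n in g.nodes
                  if n != node and n not in exclude and g.out_degree(n) > 0]
    candidates.sort(key=lambda t: (t[0], t[1]))
    if not candidates:
        return []
    tol = 0
    while True:
        pool = [n for d, n in candidates if d <= tol]
        if len(pool) >= 10 or tol > candidates[-1][0]:
            return pool
        tol += 1


def proxpath_proximity(phenotype_graph: nx.DiGraph,
                       proteins: Iterable[str],
                       phenotypes: Iterable[str],
                       max_len: int = 4,
                       stat: str = "mean",
                       preprocess: bool = False,
                       quantified_analytes: Iterable[str] | None = None,
                       null_size: int = 100,
                       seed: int = 0) -> list[PhenotypePath]:
    """Score signed functional proximity of proteins to phenotypes.

    With ``preprocess``, paths traversing proteins absent from
    ``quantified_analytes`` are discarded before scoring (phenotype
    nodes and the query proteins themselves are exempt). The null draws
    ``null_size`` degree-matched random sources without replacement
    (the whole pool when smaller) and needs >= 3 path lengths of
    nonzero spread for a z to be defined; pairs without a path within
    ``max_len``, or without a defined z, are absent from the output.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    proteins = [p for p in proteins if p in phenotype_graph]
    phenotypes = [p for p in phenotypes if p in phenotype_graph]
    g = phenotype_graph
    if preprocess:
        if quantified_analytes is None:
            raise ValueError("preprocess=True requires quantified_analytes")
        allowed = set(quantified_analytes) | set(proteins) | set(phenotypes)
        allowed |= {n for n, d in g.nodes(data=True)
                    if d.get("entity_type") == "phenotype"}
        g = g.subgraph([n for n in g.nodes if n in allowed]).copy()

    rng = np.random.default_rng(seed)
    stat_fn = np.mean if stat == "mean" else np.median
    out: list[PhenotypePath] = []
    pools: dict[str, list[str]] = {}
    for protein in sorted(proteins):
        for phenotype in sorted(phenotypes):
            for sign_class in (1, -1):
                obs = _signed_shortest_length(g, protein, phenotype,
                                              sign_class, max_len)
                if obs is None:
                    continue
                if protein not in pools:
                    pools[protein] = _degree_matched_pool(
                        g, protein, exclude=set(phenotypes))
                pool = pools[protein]
                if len(pool) > null_size:
                    sampled = list(rng.choice(pool, size=null_size,
                                              replace=False))
                else:
                    sampled = pool
                null = [ln for src in sampled
                        if (ln := _signed_shortest_length(
                            g, src, phenotype, sign_class, max_len)) is not None]
                if len(null) < 3:
                    continue
                sd = float(np.std(null, ddof=1))
                if sd == 0.0:
                    continue
                z = (obs - float(stat_fn(null))) / sd
                out.append(PhenotypePath(protein, phenotype, obs, sign_class,
                                         z, z <= Z_CUTOFF))
    return out


# ---------------------------------------------------------------------------
# phenotype activity (PhenoScore)
# ---------------------------------------------------------------------------

def dominant_path_sign(paths: Sequence[PhenotypePath]) -> int:
    """Sign class with the more significant (smaller) z; tie → activating."""
    best_z = {1: np.inf, -1: np.inf}
    for p in paths:
        best_z[p.path_sign] = min(best_z[p.path_sign], p.z)
    return 1 if best_z[1] <= best_z[-1] else -1


def phenotype_activity(model: SignalingModel,
                       paths: Sequence[PhenotypePath],
                       remove_cascades: bool = True,
                       weight_by_paths: bool = True,
                       use_optimizer_states: bool = True,
                       inferred_activities: Mapping[str, int] | None = None,
                       ) -> pd.DataFrame:
    """Aggregate regulator activities into phenotype activities.

    Eligible regulators are model nodes with a significant proximity
    path to the phenotype. With ``use_optimizer_states`` every nonzero
    optimizer state counts; otherwise only Step-1-inferred proteins
    (``inferred_activities``) do. With ``remove_cascades`` a regulator
    reachable in the model from another eligible regulator of the same
    phenotype is dropped, keeping only independent regulators. Activity
    is the weighted mean of path_sign × regulator activity with weight
    = number of significant paths (or 1).

    Returns a frame (phenotype, activity, n_regulators, regulators).
    """
    if use_optimizer_states:
        reg_activity = {n: s for n, s in model.node_states.items() if s != 0}
    else:
        if inferred_activities is None:
            raise ValueError("use_optimizer_states=False requires "
                             "inferred_activities")
        reg_activity = {n: int(s) for n, s in inferred_activities.items()
                        if model.node_states.get(n, 0) != 0 or n in model.graph}
    sig = [p for p in paths if p.significant and p.regulator in reg_activity]
    by_pheno: dict[str, dict[str, list[PhenotypePath]]] = {}
    for p in sig:
        by_pheno.setdefault(p.phenotype, {}).setdefault(p.regulator, []).append(p)

    rows = []
    for phenotype in sorted(by_pheno):
        regs = by_pheno[phenotype]
        eligible = set(regs)
        if remove_cascades and model.graph.number_of_edges():
            dropped = set()
            for r in eligible:
                others = eligible - {r} - dropped
                for o in others:
                    if o in model.graph and r in model.graph and \
                            nx.has_path(model.graph, o, r):
                        dropped.add(r)
                        break
            eligible -= dropped
        if not eligible:
            continue
        num = den = 0.0
        for r in sorted(eligible):
            w = float(len(regs[r])) if weight_by_paths else 1.0
            num += w * dominant_path_sign(regs[r]) * reg_activity[r]
            den += w
        rows.append({"phenotype": phenotype, "activity": num / den,
                     "n_regulators": len(eligible),
                     "regulators": ";".join(sorted(eligible))})
    return pd.DataFrame(rows, columns=["phenotype", "activity",
                                       "n_regulators", "regulators"])


def attach_phenotypes(model: SignalingModel,
                      phenotype_activities: pd.DataFrame,
                      paths: Sequence[PhenotypePath]) -> SignalingModel:
    """Append phenotype nodes and regulator → phenotype edges to a model.

    One signed edge is drawn per (eligible regulator, phenotype) using
    the regulator's dominant path sign. The model is returned mutated.
    """
    by_pair: dict[tuple[str, str], list[PhenotypePath]] = {}
    for p in paths:
        if p.significant:
            by_pair.setdefault((p.regulator, p.phenotype), []).append(p)
    for _, row in phenotype_activities.iterrows():
        phenotype = str(row["phenotype"])
        model.graph.add_node(phenotype, entity_type="phenotype",
                             state=float(row["activity"]))
        for reg in str(row["regulators"]).split(";"):
            pair = by_pair.get((reg, phenotype))
            sign = dominant_path_sign(pair) if pair else 1
            model.graph.add_edge(reg, phenotype, sign=sign,
                                 mechanism="phenotype_regulation", residue="",
                                 source_db="phenoscore")
    model.phenotype_activities = phenotype_activities
    return model
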