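"""Step 2 — causal network construction and sign-coherent ILP optimization.

The prior-knowledge network is first reduced to a *naive network*: the
union of all shortest paths (bounded length) bridging perturbed source
nodes to the proteins inferred in Step 1, arranged in up to three
hierarchical layers (sources → kinases/phosphatases → other signaling
proteins → transcription factors).

The naive network is then optimized by integer linear programming into
the smallest sign-coherent subnetwork explaining as many measured
activities as possible:

    minimize   sum_m  w_m * |measured_m - state_m|  +  beta * |E_sel|

subject to: node states in {-1, 0, +1}; an edge may be selected only
if its source state is nonzero; a selected edge (u -> v, s) forces
state_v = s * state_u; every nonzero non-source state has at least one
selected incoming edge; the selected edge set is acyclic (integer
ordering variables). Two flavors are supported: *vanilla* (perturbed
sources carry fixed signs) and *inverse* (a free artificial
perturbation node feeds candidate receptors through edges of either
sign). Multi-shot composition solves one ILP per layer boundary and
merges the partial solutions.

The MILP is solved with the HiGHS backend of :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .pkn import PKNGraph

logger = logging.getLogger("signaflow.network")

PERTURBATION_NODE = "__PERTURBATION__"

LAYER_SOURCE = "source"
LAYER_KIN_PP = "kinase_phosphatase"
LAYER_OTHER = "other"
LAYER_TF = "TF"
LAYER_INTERMEDIATE = "intermediate"


# ---------------------------------------------------------------------------
# naive network
# ---------------------------------------------------------------------------

@dataclass
class NaiveNetwork:
    """Layered subgraph of the PKN spanned by bounded shortest paths."""

    graph: nx.DiGraph
    layers: dict[str, str]
    segments: list[nx.DiGraph] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def _layer_sets(activities: pd.DataFrame, layout: str) -> list[set[str]]:
    """Downstream layer node sets per layout, from molecular functions."""
    mf = activities.set_index("gene_name")["mf"]
    kin_pp = set(mf.index[mf.isin(["KIN", "PP"])])
    other = set(mf.index[mf == "OTHER"])
    tf = set(mf.index[mf == "TF"])
    if layout == "three":
        return [kin_pp, other, tf]
    if layout == "two":
        return [kin_pp, other | tf]
    return [kin_pp | other | tf]


def build_naive_network(pkn: PKNGraph,
                        sources: Iterable[str],
                        activities: pd.DataFrame,
                        layout: str = "three",
                        max_len: Sequence[int] | int = 4,
                        connect_all: bool = False) -> NaiveNetwork:
    """Bridge perturbed sources to inferred proteins through the PKN.

    For each consecutive layer pair the union of *all* shortest paths
    of length <= ``max_len`` (per boundary) from every upstream node to
    every downstream node is included. With ``connect_all``, every PKN
    edge whose endpoints both already appear in the network is added.
    Sources or inferred proteins absent from the PKN are skipped with a
    log entry.
    """
    g = pkn.to_networkx()
    g.remove_edges_from(nx.selfloop_edges(g))
    down_sets = _layer_sets(activities, layout)
    if isinstance(max_len, int):
        max_len = [max_len] * len(down_sets)
    if len(max_len) < len(down_sets):
        raise ValueError("need one max_len per layer boundary")

    src = [s for s in sources if s in g]
    missing = set(sources) - set(src)
    if missing:
        logger.info("sources absent from PKN, skipped: %s", sorted(missing))

    net = nx.DiGraph()
    layers: dict[str, str] = {s: LAYER_SOURCE for s in src}
    layer_names = [LAYER_KIN_PP, LAYER_OTHER, LAYER_TF][: len(down_sets)]
    if layout != "three":
        layer_names = [LAYER_KIN_PP, LAYER_TF][: len(down_sets)]

    upstream = list(src)
    segments: list[nx.DiGraph] = []
    for i, down in enumerate(down_sets):
        down_in_pkn = sorted(down & set(g.nodes))
        absent = down - set(down_in_pkn)
        if absent:
            logger.debug("inferred proteins absent from PKN: %s", sorted(absent))
        seg = nx.DiGraph()
        cutoff = int(max_len[i])
        for u in upstream:
            lengths = nx.single_source_shortest_path_length(g, u, cutoff=cutoff)
            for v in down_in_pkn:
                if v == u or v not in lengths:
                    continue
                for path in nx.all_shortest_paths(g, u, v):
                    for a, b in zip(path, path[1:]):
                        seg.add_edge(a, b, **g.edges[a, b])
        for n in seg.nodes:
            layers.setdefault(n, LAYER_INTERMEDIATE)
        for v in down_in_pkn:
            layers[v] = layer_names[i]
        net.update(seg)
        segments.append(seg)
        upstream = down_in_pkn

    if connect_all and net.number_of_nodes():
        present = set(net.nodes)
        for u, v, data in g.edges(data=True):
            if u in present and v in present and not net.has_edge(u, v):
                net.add_edge(u, v, **data)
                if segments:
                    segments[-1].add_edge(u, v, **data)

    if net.number_of_edges() == 0:
        logger.warning("naive network is empty: no admissible path between "
                       "any source and any inferred protein")
    return NaiveNetwork(graph=net, layers=layers, segments=segments)


# ---------------------------------------------------------------------------
# ILP instance and model
# ---------------------------------------------------------------------------

@dataclass
class ILPInstance:
    """Measured/source signs and weights for one optimization run.

    ``sources`` (vanilla) fixes node states; a node both fixed and
    measured follows the source sign (precedence rule, logged).
    ``receptors`` (inverse) lists the candidate entry points wired to
    the free artificial perturbation node.
    """

    measured: dict[str, int] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    sources: dict[str, int] = field(default_factory=dict)
    receptors: set[str] = field(default_factory=set)
    beta: float = 0.2

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        for d in (self.measured, self.sources):
            bad = {n: s for n, s in d.items() if s not in (-1, 1)}
            if bad:
                raise ValueError(f"signs must be -1 or +1: {bad}")


@dataclass
class SignalingModel:
    """Optimized sign-coherent subnetwork.

    ``graph`` holds only selected edges; ``node_states`` maps every
    instance node to {-1, 0, +1}. Nonzero-state isolated nodes are kept
    so unexplained measurements remain visible.
    """

    graph: nx.DiGraph
    node_states: dict[str, int]
    objective: float
    solver_status: str = "Optimal"
    sign_ratio: float | None = None
    phenotype_activities: pd.DataFrame | None = None

    def check_sign_coherence(self) -> bool:
        """Edge-by-edge check of state_target = sign × state_source.

        Edges into attached phenotype nodes are exempt: phenotype
        activities are continuous, not ternary states.
        """
        for u, v, data in self.graph.edges(data=True):
            if self.graph.nodes[v].get("entity_type") == "phenotype":
                continue
            if self.node_states.get(v, 0) != data["sign"] * self.node_states.get(u, 0):
                return False
        return True

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)


class SolverError(RuntimeError):
    """Raised when the MILP backend fails to prove optimality."""

    def __init__(self, status: str):
        super().__init__(f"MILP solver did not return an optimum: {status}")
        self.status = status


def ilp_optimize(naive: NaiveNetwork | nx.DiGraph,
                 instance: ILPInstance,
                 flavor: str = "vanilla",
                 timeout_s: float = 600.0) -> SignalingModel:
    """Extract the optimal sign-coherent subnetwork of a naive network.

    Vanilla flavor requires at least one fixed-sign source; inverse
    flavor ignores fixed sources and instead introduces an artificial
    perturbation node of unconstrained sign connected to every
    candidate receptor by one activating and one inhibiting edge.
    """
    g = naive.graph.copy() if isinstance(naive, NaiveNetwork) else naive.copy()
    g.remove_edges_from(nx.selfloop_edges(g))

    if flavor == "vanilla":
        fixed = {n: s for n, s in instance.sources.items() if n in g}
        if not fixed:
            raise ValueError("vanilla flavor requires >=1 fixed-sign source "
                             "present in the network")
    elif flavor == "inverse":
        candidates = (instance.receptors or set(instance.sources)) & set(g.nodes)
        if not candidates:
            raise ValueError("inverse flavor requires candidate receptors "
                             "present in the network")
        for r in sorted(candidates):
            g.add_edge(PERTURBATION_NODE, r, sign=1, mechanism="perturbation",
                       residue="", direct=True, source_db="artificial")
        fixed = {}
    else:
        raise ValueError(f"unknown flavor {flavor!r}")

    # edge list: inverse adds a parallel inhibiting edge per receptor
    edges: list[tuple[str, str, int, dict]] = []
    for u, v, data in g.edges(data=True):
        edges.append((u, v, int(data["sign"]), data))
        if u == PERTURBATION_NODE:
            inh = dict(data, sign=-1)
            edges.append((u, v, -1, inh))

    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n, m = len(nodes), len(edges)
    exempt = set(fixed) | {PERTURBATION_NODE}

    measured = {nd: s for nd, s in instance.measured.items()
                if nd in idx and nd not in fixed}
    dropped = set(instance.measured) & set(fixed)
    if dropped:
        logger.info("measured nodes overridden by fixed sources: %s",
                    sorted(dropped))

    # variable layout: up (n) | down (n) | edge (m) | order (n)
    n_var = 2 * n + m + n
    UP, DOWN, EDGE, ORDER = 0, n, 2 * n, 2 * n + m

    c = np.zeros(n_var)
    const = 0.0
    for nd, s in measured.items():
        w = float(instance.weights.get(nd, 1.0))
        i = idx[nd]
        # |s - (up-down)| = 1 - s*(up-down) for s in {-1,+1}, states in {-1,0,1}
        const += w
        c[UP + i] += -w * s
        c[DOWN + i] += w * s
    c[EDGE:EDGE + m] += instance.beta

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lbs: list[float] = []
    ubs: list[float] = []
    r = 0

    def add(coefs: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal r
        for j, v in coefs:
            rows.append(r)
            cols.append(j)
            vals.append(v)
        lbs.append(lo)
        ubs.append(hi)
        r += 1

    for i in range(n):  # up + down <= 1
        add([(UP + i, 1.0), (DOWN + i, 1.0)], -np.inf, 1.0)

    in_edges: dict[int, list[int]] = {i: [] for i in range(n)}
    for k, (u, v, s, _) in enumerate(edges):
        iu, iv = idx[u], idx[v]
        in_edges[iv].append(k)
        # source nonzero when selected
        add([(EDGE + k, 1.0), (UP + iu, -1.0), (DOWN + iu, -1.0)], -np.inf, 0.0)
        # coherence when selected: |state_v - s*state_u| <= 2(1 - e)
        add([(UP + iv, 1.0), (DOWN + iv, -1.0), (UP + iu, -s), (DOWN + iu, s),
             (EDGE + k, 2.0)], -np.inf, 2.0)
        add([(UP + iv, -1.0), (DOWN + iv, 1.0), (UP + iu, s), (DOWN + iu, -s),
             (EDGE + k, 2.0)], -np.inf, 2.0)
        # acyclicity: order_v >= order_u + 1 when selected
        add([(ORDER + idx[v], 1.0), (ORDER + iu, -1.0), (EDGE + k, -float(n))],
            1.0 - n, np.inf)

    for nd in nodes:  # support: nonzero non-source needs a selected in-edge
        if nd in exempt:
            continue
        i = idx[nd]
        coefs = [(UP + i, 1.0), (DOWN + i, 1.0)]
        coefs += [(EDGE + k, -1.0) for k in in_edges[i]]
        add(coefs, -np.inf, 0.0)

    lb = np.zeros(n_var)
    ub = np.ones(n_var)
    ub[ORDER:] = max(n - 1, 0)
    for nd, s in fixed.items():
        i = idx[nd]
        if s == 1:
            lb[UP + i] = 1.0
            ub[DOWN + i] = 0.0
        else:
            lb[DOWN + i] = 1.0
            ub[UP + i] = 0.0

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_var))
    res = milp(c=c,
               constraints=LinearConstraint(A, np.array(lbs), np.array(ubs)),
               integrality=np.ones(n_var),
               bounds=Bounds(lb, ub),
               options={"time_limit": timeout_s})
    if res.status != 0:
        raise SolverError(res.message)

    x = np.round(res.x).astype(int)
    states = {nd: int(x[UP + idx[nd]] - x[DOWN + idx[nd]]) for nd in nodes}
    sol = nx.DiGraph()
    for nd, st in states.items():
        if st != 0:
            sol.add_node(nd, state=st)
    for k, (u, v, s, data) in enumerate(edges):
        if x[EDGE + k] == 1:
            attrs = dict(data)
            attrs["sign"] = s
            sol.add_edge(u, v, **attrs)
    return SignalingModel(graph=sol, node_states=states,
                          objective=float(res.fun + const))


# ---------------------------------------------------------------------------
# multi-shot composition
# ---------------------------------------------------------------------------

def run_multishot(naive: NaiveNetwork,
                  instance: ILPInstance,
                  shots: int = 1,
                  flavor: str = "vanilla",
                  timeout_s: float = 600.0) -> SignalingModel:
    """Solve one ILP per layer-boundary group and merge the solutions.

    ``shots = 1`` reduces to a single ILP over the whole naive network.
    For more shots, the layer boundaries are split into ``shots``
    contiguous groups solved upstream-first; each downstream shot fixes
    the upstream layers' nodes as sources, using the solved state where
    the upstream shot assigned one and falling back to the node's
    measured sign where it did not — so a mid-layer protein whose
    upstream connection was pruned still seeds its own downstream
    layer. State conflicts at the union are resolved in favor of the
    more upstream shot (logged).
    """
    if shots not in (1, 2, 3):
        raise ValueError("shots must be 1, 2 or 3")
    if shots == 1 or len(naive.segments) <= 1:
        return ilp_optimize(naive, instance, flavor=flavor, timeout_s=timeout_s)

    n_seg = len(naive.segments)
    shots = min(shots, n_seg)
    groups = [list(chunk) for chunk in np.array_split(np.arange(n_seg), shots)]

    merged = nx.DiGraph()
    merged_states: dict[str, int] = {}
    objective = 0.0
    upstream_nodes: set[str] = set(instance.sources)
    for gi, group in enumerate(groups):
        sub = nx.DiGraph()
        for si in group:
            sub.update(naive.segments[si])
        if gi == 0:
            shot_sources = {nd: s for nd, s in instance.sources.items()
                            if nd in sub}
        else:
            # solved state wins; unexplained upstream nodes fall back to
            # their measured sign so they still drive their layer
            shot_sources = {}
            for nd in set(sub.nodes) & upstream_nodes:
                st = merged_states.get(nd, instance.measured.get(nd, 0))
                if st != 0:
                    shot_sources[nd] = st
        measured = {nd: s for nd, s in instance.measured.items()
                    if nd in sub and nd not in shot_sources}
        upstream_nodes |= set(sub.nodes)
        if not measured:
            logger.warning("shot %d has no measured nodes, skipped", gi + 1)
            continue
        shot_inst = ILPInstance(
            measured=measured,
            weights={nd: instance.weights.get(nd, 1.0) for nd in measured},
            sources=shot_sources,
            receptors=instance.receptors,
            beta=instance.beta)
        shot_flavor = flavor if gi == 0 else "vanilla"
        if shot_flavor == "vanilla" and not shot_inst.sources:
            logger.warning("shot %d has no upstream sources, skipped", gi + 1)
            continue
        model = ilp_optimize(NaiveNetwork(sub, naive.layers), shot_inst,
                             flavor=shot_flavor, timeout_s=timeout_s)
        objective += model.objective
        for nd, st in model.node_states.items():
            if st == 0:
                continue
            if nd in merged_states and merged_states[nd] != st:
                logger.info("multi-shot state conflict at %s: upstream %d kept, "
                            "downstream %d dropped", nd, merged_states[nd], st)
                continue
            merged_states[nd] = st
        for u, v, data in model.graph.edges(data=True):
            if not merged.has_edge(u, v):
                merged.add_edge(u, v, **data)

    for nd in list(merged.nodes):
        merged.nodes[nd]["state"] = merged_states.get(nd, 0)
    # drop edges whose coherence broke at a cross-shot conflict
    incoherent = [(u, v) for u, v, d in merged.edges(data=True)
                  if merged_states.get(v, 0) != d["sign"] * merged_states.get(u, 0)]
    if incoherent:
        logger.info("dropped %d cross-shot incoherent edges at union",
                    len(incoherent))
        merged.remove_edges_from(incoherent)
    all_states = {nd: merged_states.get(nd, 0)
                  for nd in set(naive.graph.nodes) | set(merged_states)}
    return SignalingModel(graph=merged, node_states=all_states,
                          objective=objective)


# ---------------------------------------------------------------------------
# phospho validation
# ---------------------------------------------------------------------------

def validate_edges_with_phospho(model: SignalingModel,
                                phospho_table: pd.DataFrame) -> SignalingModel:
    """Flag model edges confirmed by measured phosphosites.

    A post-translational edge is *quantified* when its (target gene,
    residue) appears in the phospho table and *significant* when that
    site is significantly modulated. The model's ``sign_ratio`` is the
    fraction of edges validated by significant phosphorylation events
    over all edges.
    """
    keyed = phospho_table.set_index(
        phospho_table["gene_name"].astype(str) + "_"
        + phospho_table["residue"].astype(str))
    n_sig = 0
    for u, v, data in model.graph.edges(data=True):
        data["phospho_quantified"] = False
        data["phospho_significant"] = False
        residue = data.get("residue") or ""
        if "phospho" not in str(data.get("mechanism", "")).lower() or not residue:
            continue
        key = f"{v}_{residue}"
        if key in keyed.index:
            data["phospho_quantified"] = True
            row = keyed.loc[key]
            sig = bool(row["significant"].any()) if isinstance(row, pd.DataFrame) \
                else bool(row["significant"])
            data["phospho_significant"] = sig
            n_sig += int(sig)
    total = model.graph.number_of_edges()
    model.sign_ratio = (n_sig / total) if total else 0.0
    return model
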