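"""Prior-knowledge network (PKN) construction.

A PKN is a directed, signed causal graph following the activity-flow
model: every edge has a regulator, a target, and a sign (+1 activation,
-1 inhibition). Edges are parsed from three tabular dialects —

* curated causal-interaction tables (SIGNOR-like): one row per
  interaction with a free-text ``effect`` label;
* regulatory-phosphosite tables (PhosphoSitePlus-like): a
  kinase–phosphosite table joined with a phosphosite regulatory-role
  table on (substrate gene, residue);
* substrate-specificity percentile matrices (kinome-atlas-like):
  kinase × phosphosite percentiles thresholded into regulon entries
  and high-confidence PKN edges.

Six presets mirror the cumulative filtering scheme used to publish
ready-made PKNs: no filter, direct interactions only, additionally no
atlas edges, additionally proteins only (and the two mouse analogues).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("signaflow.pkn")

MOLECULAR_FUNCTIONS = ("TF", "KIN", "PP", "OTHER")
ENTITY_TYPES = ("protein", "complex", "metabolite", "fusion")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalEdge:
    """One signed causal interaction.

    ``residue`` is a site token (one-letter amino acid + position, e.g.
    ``S473``) and is only present when ``mechanism`` is a
    post-translational modification.
    """

    source: str
    target: str
    sign: int
    direct: bool = True
    mechanism: str = ""
    residue: str | None = None
    source_db: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"edge sign must be -1 or +1, got {self.sign}")

    @property
    def key(self) -> tuple[str, str, str | None]:
        return (self.source, self.target, self.residue)


@dataclass
class PKNGraph:
    """Signed causal graph with per-node molecular-function annotation.

    ``node_attrs`` maps gene → {"molecular_function": TF/KIN/PP/OTHER,
    "entity_type": protein/complex/metabolite/fusion}. Nodes appearing
    only in edges default to protein/OTHER.
    """

    edges: list[CausalEdge] = field(default_factory=list)
    node_attrs: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = _collapse_duplicates(self.edges)

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        out = {e.source for e in self.edges} | {e.target for e in self.edges}
        out.update(self.node_attrs)
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def molecular_function(self, node: str) -> str:
        return self.node_attrs.get(node, {}).get("molecular_function", "OTHER")

    def entity_type(self, node: str) -> str:
        return self.node_attrs.get(node, {}).get("entity_type", "protein")

    def to_networkx(self) -> nx.DiGraph:
        """Collapse to a simple digraph (one edge per node pair).

        When several site-specific edges connect the same pair, the
        first one's attributes win; a mixed-sign pair keeps the curated
        record if any, else is dropped (logged).
        """
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n, **self.node_attrs.get(n, {}))
        by_pair: dict[tuple[str, str], list[CausalEdge]] = defaultdict(list)
        for e in self.edges:
            by_pair[(e.source, e.target)].append(e)
        n_dropped = 0
        for (u, v), es in by_pair.items():
            signs = {e.sign for e in es}
            if len(signs) == 1:
                chosen = es[0]
            else:
                curated = [e for e in es if _is_curated(e.source_db)]
                if curated and len({e.sign for e in curated}) == 1:
                    chosen = curated[0]
                else:
                    n_dropped += 1
                    continue
            g.add_edge(u, v, sign=chosen.sign, direct=chosen.direct,
                       mechanism=chosen.mechanism, residue=chosen.residue or "",
                       source_db=chosen.source_db)
        if n_dropped:
            logger.info("dropped %d mixed-sign node pairs at graph collapse", n_dropped)
        return g


def _is_curated(source_db: str) -> bool:
    return "atlas" not in source_db.lower()


def _collapse_duplicates(edges: Iterable[CausalEdge]) -> list[CausalEdge]:
    """Resolve duplicate (source, target, residue) records.

    Same sign → keep the first record. Opposite signs → keep the
    manually-curated (non-atlas) record; if the curated records still
    disagree, drop all and log.
    """
    grouped: dict[tuple, list[CausalEdge]] = defaultdict(list)
    for e in edges:
        grouped[e.key].append(e)
    out: list[CausalEdge] = []
    n_conflicts = 0
    for key, es in grouped.items():
        signs = {e.sign for e in es}
        if len(signs) == 1:
            out.append(es[0])
            continue
        curated = [e for e in es if _is_curated(e.source_db)]
        if curated and len({e.sign for e in curated}) == 1:
            out.append(curated[0])
        else:
            n_conflicts += 1
    if n_conflicts:
        logger.warning("dropped %d sign-conflicting duplicate edges", n_conflicts)
    return out


@dataclass(frozen=True)
class AtlasRelation:
    """Kinase → phosphosite substrate-specificity percentile."""

    kinase: str
    site: str  # "GENE_S473" style token
    percentile: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError(f"percentile {self.percentile} outside [0, 100]")

    @property
    def gene(self) -> str:
        return self.site.rsplit("_", 1)[0]

    @property
    def residue(self) -> str:
        return self.site.rsplit("_", 1)[1]


# ---------------------------------------------------------------------------
# parsing: curated causal tables
# ---------------------------------------------------------------------------

#: effect-label prefixes → signs; complex formation counts as activation
_EFFECT_SIGNS = (("up-regulates", 1), ("down-regulates", -1), ("form complex", 1))

SIGNOR_COLUMNS = {
    "source": "source", "target": "target", "effect": "effect",
    "type_source": "type_source", "type_target": "type_target",
    "mechanism": "mechanism", "residue": "residue", "direct": "direct",
}


def _effect_to_sign(effect: str) -> int | None:
    effect = str(effect).strip().lower()
    for prefix, sign in _EFFECT_SIGNS:
        if effect.startswith(prefix):
            return sign
    return None


def parse_signor_like(table: pd.DataFrame,
                      columns: Mapping[str, str] | None = None,
                      source_db: str = "curated") -> list[CausalEdge]:
    """Parse a curated causal-interaction table into signed edges.

    Effect labels starting with "up-regulates" map to +1,
    "down-regulates" to -1 and "form complex" to +1. Rows whose either
    entity is of type "protein family" are excluded, and rows with an
    unrecognized effect label are dropped with a logged count.
    """
    cols = dict(SIGNOR_COLUMNS)
    if columns:
        cols.update(columns)
    for role in ("source", "target", "effect"):
        if cols[role] not in table.columns:
            raise KeyError(f"missing mandatory column {cols[role]!r}")
    edges: list[CausalEdge] = []
    n_unrecognized = 0
    for _, row in table.iterrows():
        t_src = str(row.get(cols["type_source"], "protein")).lower()
        t_tgt = str(row.get(cols["type_target"], "protein")).lower()
        if t_src == "protein family" or t_tgt == "protein family":
            continue
        sign = _effect_to_sign(row[cols["effect"]])
        if sign is None:
            n_unrecognized += 1
            continue
        mechanism = str(row.get(cols["mechanism"], "") or "")
        residue = row.get(cols["residue"])
        residue = None if pd.isna(residue) or residue == "" else str(residue)
        direct = bool(row.get(cols["direct"], True))
        edges.append(CausalEdge(str(row[cols["source"]]), str(row[cols["target"]]),
                                sign, direct=direct, mechanism=mechanism,
                                residue=residue, source_db=source_db))
    if n_unrecognized:
        logger.info("dropped %d rows with unrecognized effect labels", n_unrecognized)
    return edges


# ---------------------------------------------------------------------------
# parsing: regulatory phosphosites
# ---------------------------------------------------------------------------

def map_regulatory_role(role: str) -> int:
    """Map a phosphosite regulatory-role annotation to {+1, -1, 0}.

    Roles inducing activity (or stabilizing the protein) score +1,
    roles inhibiting activity (or inducing degradation) score -1, and
    anything else — including unknown text — scores 0, i.e. no defined
    regulatory effect.
    """
    role = str(role).strip().lower()
    if "induced" in role or "stabilization" in role:
        return 1
    if "inhibited" in role or "degradation" in role:
        return -1
    return 0


def regulatory_role_class(role: str) -> str:
    """Classify a role annotation as affecting activity, abundance or both."""
    role = str(role).strip().lower()
    has_activity = "activity" in role
    has_abundance = any(t in role for t in ("stability", "stabilization",
                                            "degradation", "abundance"))
    if has_activity and has_abundance:
        return "both"
    if has_abundance:
        return "abundance"
    return "activity"


def parse_regulatory_sites(kinase_site_table: pd.DataFrame,
                           regulatory_role_table: pd.DataFrame,
                           source_db: str = "phosphosite") -> list[CausalEdge]:
    """Join kinase–site rows with site regulatory roles into signed edges.

    Both tables are keyed by (substrate gene, modified residue). The
    role text maps to {+1, -1, 0}; only edges with a defined regulatory
    effect (±1) are retained. The edge runs kinase → substrate with a
    phosphorylation mechanism and carries the modified residue.
    """
    for col in ("kinase", "gene", "residue"):
        if col not in kinase_site_table.columns:
            raise KeyError(f"kinase-site table missing column {col!r}")
    for col in ("gene", "residue", "role"):
        if col not in regulatory_role_table.columns:
            raise KeyError(f"regulatory-role table missing column {col!r}")
    joined = kinase_site_table.merge(regulatory_role_table, on=["gene", "residue"],
                                     how="inner")
    edges: list[CausalEdge] = []
    for _, row in joined.iterrows():
        sign = map_regulatory_role(row["role"])
        if sign == 0:
            continue
        edges.append(CausalEdge(str(row["kinase"]), str(row["gene"]), sign,
                                direct=True, mechanism="phosphorylation",
                                residue=str(row["residue"]), source_db=source_db))
    return edges


# ---------------------------------------------------------------------------
# parsing: kinome atlas percentiles
# ---------------------------------------------------------------------------

def atlas_weight(percentile: float, regulon_threshold: float) -> float:
    """Linear map of percentile from [threshold, 100] onto [0.5, 0.9]."""
    span = 100.0 - regulon_threshold
    w = 0.5 + 0.4 * (percentile - regulon_threshold) / span
    return min(0.9, max(0.5, w))  # guard against float spill at the ends


def parse_kinome_atlas(relations: Sequence[AtlasRelation],
                       regulatory_role_table: pd.DataFrame,
                       regulon_threshold: float = 88.0,
                       pkn_threshold: float = 99.0,
                       ) -> tuple[pd.DataFrame, list[CausalEdge]]:
    """Split atlas percentile relations into regulon entries and PKN edges.

    Relations with percentile strictly above ``regulon_threshold``
    become regulon entries weighted by a linear map of the percentile
    onto [0.5, 0.9]; relations strictly above ``pkn_threshold`` are
    joined to the regulatory-role table on the phosphosite to inherit a
    sign and enter the PKN.

    Returns (regulon entry frame with columns kinase/site/mode/weight,
    list of PKN CausalEdges).
    """
    for thr, name in ((regulon_threshold, "regulon"), (pkn_threshold, "pkn")):
        if not 0.0 <= thr <= 100.0:
            raise ValueError(f"{name} threshold {thr} outside [0, 100]")
    reg_rows = []
    for r in relations:
        if r.percentile > regulon_threshold:
            reg_rows.append({"kinase": r.kinase, "site": r.site, "mode": 1.0,
                             "weight": atlas_weight(r.percentile, regulon_threshold)})
    regulon_entries = pd.DataFrame(reg_rows,
                                   columns=["kinase", "site", "mode", "weight"])

    roles = {(str(row["gene"]), str(row["residue"])): map_regulatory_role(row["role"])
             for _, row in regulatory_role_table.iterrows()}
    pkn_edges: list[CausalEdge] = []
    for r in relations:
        if r.percentile <= pkn_threshold:
            continue
        sign = roles.get((r.gene, r.residue), 0)
        if sign == 0:
            continue
        pkn_edges.append(CausalEdge(r.kinase, r.gene, sign, direct=True,
                                    mechanism="phosphorylation", residue=r.residue,
                                    source_db="atlas"))
    return regulon_entries, pkn_edges


# ---------------------------------------------------------------------------
# assembly and preprocessing
# ---------------------------------------------------------------------------

#: cumulative preset filters, loosest to strictest; 5/6 are the mouse
#: analogues of 1/2 (organism is carried as a flag, not a casing rule)
PKN_PRESETS: dict[int, dict[str, bool | str]] = {
    2: {"organism": "human", "direct_only": False, "include_atlas": True,
        "proteins_only": False},
    1: {"organism": "human", "direct_only": True, "include_atlas": True,
        "proteins_only": False},
    4: {"organism": "human", "direct_only": True, "include_atlas": False,
        "proteins_only": False},
    3: {"organism": "human", "direct_only": True, "include_atlas": False,
        "proteins_only": True},
    6: {"organism": "mouse", "direct_only": False, "include_atlas": False,
        "proteins_only": False},
    5: {"organism": "mouse", "direct_only": True, "include_atlas": False,
        "proteins_only": False},
}


def assemble_pkn(edge_sets: Sequence[Iterable[CausalEdge]],
                 preset: int | None = None,
                 *,
                 direct_only: bool = False,
                 include_atlas: bool = True,
                 proteins_only: bool = False,
                 node_attrs: Mapping[str, Mapping[str, str]] | None = None,
                 ) -> PKNGraph:
    """Union the parsed edge sets and apply preset / custom filters.

    Filters are applied in order: drop indirect (transcriptional)
    edges when ``direct_only``; drop atlas edges when not
    ``include_atlas``; drop edges touching non-protein entities when
    ``proteins_only``. An empty result is a valid (warned) graph.
    """
    if preset is not None:
        if preset not in PKN_PRESETS:
            raise ValueError(f"unknown preset {preset}; valid: {sorted(PKN_PRESETS)}")
        p = PKN_PRESETS[preset]
        direct_only = bool(p["direct_only"])
        include_atlas = bool(p["include_atlas"])
        proteins_only = bool(p["proteins_only"])
    edges: list[CausalEdge] = [e for es in edge_sets for e in es]
    if direct_only:
        edges = [e for e in edges if e.direct]
    if not include_atlas:
        edges = [e for e in edges if _is_curated(e.source_db)]
    attrs = {n: dict(a) for n, a in (node_attrs or {}).items()}
    if proteins_only:
        non_protein = {n for n, a in attrs.items()
                       if a.get("entity_type", "protein") != "protein"}
        edges = [e for e in edges
                 if e.source not in non_protein and e.target not in non_protein]
    if not edges:
        logger.warning("assembled PKN is empty after filtering")
    return PKNGraph(edges=edges, node_attrs=attrs)


def preprocess_pkn(pkn: PKNGraph, quantified_analytes: Iterable[str]) -> PKNGraph:
    """Drop edges between proteins not quantified in the experiment.

    Only protein endpoints are subject to the filter: complexes,
    metabolites, fusions and phenotype nodes are exempt, since they are
    never directly quantified.
    """
    quantified = set(quantified_analytes)

    def keep(node: str) -> bool:
        if pkn.entity_type(node) != "protein":
            return True
        return node in quantified

    edges = [e for e in pkn.edges if keep(e.source) and keep(e.target)]
    kept_nodes = {e.source for e in edges} | {e.target for e in edges}
    attrs = {n: a for n, a in pkn.node_attrs.items() if n in kept_nodes}
    return PKNGraph(edges=edges, node_attrs=attrs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SIF_RELATIONS = {1: "activates", -1: "inhibits"}


def write_pkn(pkn: PKNGraph, directory: str | Path, stem: str = "pkn") -> dict[str, Path]:
    """Write a PKN as SIF plus edge- and node-attribute TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sif_path = directory / f"{stem}.sif"
    with sif_path.open("w") as fh:
        for e in pkn.edges:
            fh.write(f"{e.source}\t{SIF_RELATIONS[e.sign]}\t{e.target}\n")
    edge_path = directory / f"{stem}_edges.tsv"
    pd.DataFrame([{"source": e.source, "target": e.target, "sign": e.sign,
                   "direct": e.direct, "mechanism": e.mechanism,
                   "residue": e.residue or "", "source_db": e.source_db}
                  for e in pkn.edges]).to_csv(edge_path, sep="\t", index=False)
    node_path = directory / f"{stem}_nodes.tsv"
    pd.DataFrame([{"node": n,
                   "molecular_function": pkn.molecular_function(n),
                   "entity_type": pkn.entity_type(n)}
                  for n in sorted(pkn.nodes)]).to_csv(node_path, sep="\t", index=False)
    return {"sif": sif_path, "edges": edge_path, "nodes": node_path}


def read_pkn(directory: str | Path, stem: str = "pkn") -> PKNGraph:
    """Read back a PKN written by :func:`write_pkn`."""
    directory = Path(directory)
    edges_df = pd.read_csv(directory / f"{stem}_edges.tsv", sep="\t",
                           keep_default_na=False)
    edges = [CausalEdge(str(r["source"]), str(r["target"]), int(r["sign"]),
                        direct=bool(r["direct"]), mechanism=str(r["mechanism"]),
                        residue=str(r["residue"]) or None,
                        source_db=str(r["source_db"]))
             for _, r in edges_df.iterrows()]
    nodes_df = pd.read_csv(directory / f"{stem}_nodes.tsv", sep="\t")
    attrs = {str(r["node"]): {"molecular_function": str(r["molecular_function"]),
                              "entity_type": str(r["entity_type"])}
             for _, r in nodes_df.iterrows()}
    return PKNGraph(edges=edges, node_attrs=attrs)
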