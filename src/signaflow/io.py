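"""Tabular and graph I/O shared by all pipeline steps.

Omics tables travel as TSV with a header; column names are remappable
so foreign exports can be ingested without editing. Models are emitted
as SIF (``source  activates|inhibits  target``), node-state and
edge-attribute TSVs, and GraphML with all attributes embedded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .network import SignalingModel
from .pkn import PKNGraph, SIF_RELATIONS, read_pkn, write_pkn

logger = logging.getLogger("signaflow.io")

OMICS_REQUIRED = ("gene_name", "difference")


def read_omics_table(path: str | Path,
                     columns: Mapping[str, str] | None = None,
                     p_value_column: str | None = None,
                     p_threshold: float = 0.05) -> pd.DataFrame:
    """Read an omics contrast TSV into the canonical schema.

    ``columns`` maps canonical name → file column (e.g.
    ``{"difference": "logFC"}``). Significance comes from a boolean
    ``significant`` column, or from ``p_value_column`` < threshold.
    Type-coercion failures raise with the offending row numbers.
    """
    df = pd.read_csv(path, sep="\t")
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in OMICS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    coerced = pd.to_numeric(df["difference"], errors="coerce")
    bad = df.index[coerced.isna() & df["difference"].notna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric 'difference' at rows "
                         f"{[int(i) + 2 for i in bad]}")  # 1-based + header
    df["difference"] = coerced
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    elif p_value_column and p_value_column in df.columns:
        df["significant"] = pd.to_numeric(df[p_value_column]) < p_threshold
    else:
        raise ValueError(f"{path}: no 'significant' or p-value column")
    if "residue" in df.columns:
        df["residue"] = df["residue"].astype(str)
    return df


# ---------------------------------------------------------------------------
# model export
# ---------------------------------------------------------------------------

def write_model(model: SignalingModel, directory: str | Path,
                stem: str = "model") -> dict[str, Path]:
    """Write a solved model as SIF + node/edge TSVs + GraphML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = model.graph
    paths = {}

    sif = directory / f"{stem}.sif"
    with sif.open("w") as fh:
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{SIF_RELATIONS[int(data['sign'])]}\t{v}\n")
    paths["sif"] = sif

    nodes = directory / f"{stem}_nodes.tsv"
    pd.DataFrame([{"node": n,
                   "state": model.node_states.get(
                       n, g.nodes[n].get("state", 0)) if n in g else 0}
                  for n in sorted(set(g.nodes) | set(model.node_states))]
                 ).to_csv(nodes, sep="\t", index=False)
    paths["nodes"] = nodes

    edges = directory / f"{stem}_edges.tsv"
    pd.DataFrame([{"source": u, "target": v, "sign": int(d["sign"]),
                   "mechanism": d.get("mechanism", ""),
                   "residue": d.get("residue", "") or "",
                   "phospho_quantified": bool(d.get("phospho_quantified", False)),
                   "phospho_significant": bool(d.get("phospho_significant", False))}
                  for u, v, d in g.edges(data=True)]
                 ).to_csv(edges, sep="\t", index=False)
    paths["edges"] = edges

    gml = directory / f"{stem}.graphml"
    export = nx.DiGraph()
    for n, data in g.nodes(data=True):
        clean = {k: v for k, v in data.items() if v is not None}
        clean["state"] = float(model.node_states.get(n, clean.get("state", 0)))
        export.add_node(n, **clean)
    for u, v, data in g.edges(data=True):
        export.add_edge(u, v, **{k: ("" if val is None else val)
                                 for k, val in data.items()})
    nx.write_graphml(export, gml)
    paths["graphml"] = gml
    return paths


def read_model_graphml(path: str | Path) -> SignalingModel:
    """Re-import a GraphML model (round-trip of :func:`write_model`)."""
    g = nx.read_graphml(path)
    dg = nx.DiGraph()
    for n, data in g.nodes(data=True):
        dg.add_node(n, **data)
    for u, v, data in g.edges(data=True):
        data["sign"] = int(data["sign"])
        dg.add_edge(u, v, **data)
    states = {n: int(round(float(d.get("state", 0))))
              for n, d in dg.nodes(data=True)
              if d.get("entity_type") != "phenotype"}
    return SignalingModel(graph=dg, node_states=states, objective=float("nan"))


# ---------------------------------------------------------------------------
# input bundles
# ---------------------------------------------------------------------------

@dataclass
class InputBundle:
    """Everything one pipeline run consumes. Omics layers may be None."""

    pkn: PKNGraph
    sources: dict[str, int]
    regulons_tf: dict[str, pd.DataFrame] = field(default_factory=dict)
    regulons_kin: dict[str, pd.DataFrame] = field(default_factory=dict)
    transcriptomics: pd.DataFrame | None = None
    phospho: pd.DataFrame | None = None
    proteomics: pd.DataFrame | None = None
    regulatory_sites: pd.DataFrame | None = None
    phenotype_edges: pd.DataFrame | None = None
    gold: pd.DataFrame | None = None


def _regulons_to_frame(regulons: Mapping[str, pd.DataFrame],
                       kind: str) -> pd.DataFrame:
    rows = []
    for reg, df in regulons.items():
        for _, r in df.iterrows():
            rows.append({"regulator": reg, "target": r["target"],
                         "mode": float(r["mode"]), "weight": float(r["weight"]),
                         "kind": kind})
    return pd.DataFrame(rows, columns=["regulator", "target", "mode",
                                       "weight", "kind"])


def write_bundle(bundle: InputBundle, directory: str | Path) -> None:
    """Write a full input bundle as plain TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pkn(bundle.pkn, directory)
    pd.DataFrame({"node": list(bundle.sources),
                  "sign": list(bundle.sources.values())}
                 ).to_csv(directory / "sources.tsv", sep="\t", index=False)
    regs = pd.concat([_regulons_to_frame(bundle.regulons_tf, "tf"),
                      _regulons_to_frame(bundle.regulons_kin, "kin")],
                     ignore_index=True)
    regs.to_csv(directory / "regulons.tsv", sep="\t", index=False)
    for name, df in (("transcriptomics", bundle.transcriptomics),
                     ("phosphoproteomics", bundle.phospho),
                     ("proteomics", bundle.proteomics),
                     ("regulatory_sites", bundle.regulatory_sites),
                     ("phenotypes", bundle.phenotype_edges),
                     ("gold", bundle.gold)):
        if df is not None:
            df.to_csv(directory / f"{name}.tsv", sep="\t", index=False)


def read_bundle(directory: str | Path) -> InputBundle:
    """Read back a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    pkn = read_pkn(directory)
    src = pd.read_csv(directory / "sources.tsv", sep="\t")
    sources = {str(r["node"]): int(r["sign"]) for _, r in src.iterrows()}
    regs = pd.read_csv(directory / "regulons.tsv", sep="\t")
    regulons: dict[str, dict[str, pd.DataFrame]] = {"tf": {}, "kin": {}}
    for (kind, reg), grp in regs.groupby(["kind", "regulator"]):
        regulons[str(kind)][str(reg)] = grp[["target", "mode", "weight"]
                                            ].reset_index(drop=True)

    def maybe(name: str) -> pd.DataFrame | None:
        p = directory / f"{name}.tsv"
        if not p.exists():
            return None
        df = pd.read_csv(p, sep="\t")
        if "significant" in df.columns:
            df["significant"] = df["significant"].astype(bool)
        if "residue" in df.columns:
            df["residue"] = df["residue"].astype(str)
        return df

    return InputBundle(pkn=pkn, sources=sources,
                       regulons_tf=regulons["tf"], regulons_kin=regulons["kin"],
                       transcriptomics=maybe("transcriptomics"),
                       phospho=maybe("phosphoproteomics"),
                       proteomics=maybe("proteomics"),
                       regulatory_sites=maybe("regulatory_sites"),
                       phenotype_edges=maybe("phenotypes"),
                       gold=maybe("gold"))
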