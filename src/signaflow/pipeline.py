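"""End-to-end pipeline driver: Step 1 → Step 2 → Step 3.

``run_pipeline`` honors whichever omics layers are present: with only
transcriptomics, only TF activities are inferred; with only
phosphoproteomics, kinase/phosphatase footprints and PhosphoScore run;
network construction and phenotype inference proceed on whatever was
inferred. All randomness flows from ``config.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import activity, benchmark, network, phenoscore
from .config import PipelineConfig
from .io import InputBundle, write_model
from .network import ILPInstance, SignalingModel
from .pkn import preprocess_pkn

logger = logging.getLogger("signaflow.pipeline")


@dataclass
class PipelineResult:
    activities: pd.DataFrame
    model: SignalingModel
    phenotype_activities: pd.DataFrame
    metrics: dict[str, Any] = field(default_factory=dict)


def _phospho_signature(phospho: pd.DataFrame) -> pd.DataFrame:
    """Phospho table → signature keyed by gene_residue site tokens."""
    return pd.DataFrame({
        "analyte": phospho["gene_name"].astype(str) + "_"
        + phospho["residue"].astype(str),
        "difference": phospho["difference"],
        "significant": phospho["significant"],
    })


def _quantified_genes(bundle: InputBundle) -> set[str]:
    genes: set[str] = set(bundle.sources)
    for df in (bundle.transcriptomics, bundle.proteomics, bundle.phospho):
        if df is not None:
            genes.update(df["gene_name"].astype(str))
    return genes


def infer_activities(bundle: InputBundle, config: PipelineConfig) -> pd.DataFrame:
    """Step 1: footprint enrichment + PhosphoScore → activity table."""
    tables = []
    phospho = bundle.phospho
    if phospho is not None and config.normalize_phospho \
            and bundle.proteomics is not None:
        phospho = activity.normalize_phospho(phospho, bundle.proteomics,
                                             z_threshold=config.z_threshold)

    def footprint_route(signature: pd.DataFrame,
                        regulons: dict[str, pd.DataFrame]) -> pd.DataFrame:
        enr = activity.footprint_enrichment(signature, regulons,
                                            min_targets=config.min_targets)
        if enr.empty:
            return enr
        if config.hypergeometric_test:
            enr = activity.hypergeometric_weighting(enr, signature, regulons)
        if config.proteomics_correction and bundle.proteomics is not None:
            return activity.proteomics_correction(enr, bundle.proteomics,
                                                  p_threshold=config.p_threshold)
        return activity.enrichment_to_activity(enr,
                                               p_threshold=config.p_threshold)

    if bundle.transcriptomics is not None and bundle.regulons_tf:
        tables.append(footprint_route(bundle.transcriptomics,
                                      bundle.regulons_tf))
    if phospho is not None and bundle.regulons_kin:
        tables.append(footprint_route(_phospho_signature(phospho),
                                      bundle.regulons_kin))

    ps_table = None
    if phospho is not None and bundle.regulatory_sites is not None:
        ps_table = activity.phospho_score(
            phospho, bundle.regulatory_sites,
            activity_only=config.activity_only_sites)

    mf = {n: bundle.pkn.molecular_function(n) for n in bundle.pkn.nodes}
    return activity.combine_activities(tables, ps_table, mf)


def build_model(bundle: InputBundle, activities: pd.DataFrame,
                config: PipelineConfig) -> tuple[SignalingModel,
                                                 network.NaiveNetwork]:
    """Step 2: naive network + multi-shot ILP + phospho validation."""
    pkn = bundle.pkn
    if config.preprocess_pkn:
        pkn = preprocess_pkn(pkn, _quantified_genes(bundle))
    naive = network.build_naive_network(
        pkn, list(bundle.sources), activities, layout=config.layout,
        max_len=config.max_len, connect_all=config.connect_all)
    scores = activities.set_index("gene_name")["final_score"].abs()
    max_score = float(scores.max()) if len(scores) else 1.0
    weights = {g: float(s) / max_score if max_score > 0 else 1.0
               for g, s in scores.items()}
    measured = {str(r["gene_name"]): int(r["activity"])
                for _, r in activities.iterrows()
                if r["gene_name"] in naive.graph}
    instance = ILPInstance(measured=measured, weights=weights,
                           sources=dict(bundle.sources),
                           receptors=set(bundle.sources), beta=config.beta)
    model = network.run_multishot(naive, instance, shots=config.shots,
                                  flavor=config.flavor,
                                  timeout_s=config.solver_timeout_s)
    if bundle.phospho is not None:
        model = network.validate_edges_with_phospho(model, bundle.phospho)
    return model, naive


def infer_phenotypes(bundle: InputBundle, model: SignalingModel,
                     activities: pd.DataFrame,
                     config: PipelineConfig) -> pd.DataFrame:
    """Step 3: ProxPath proximity + PhenoScore, attached to the model."""
    if bundle.phenotype_edges is None or bundle.phenotype_edges.empty:
        return pd.DataFrame(columns=["phenotype", "activity", "n_regulators",
                                     "regulators"])
    pheno_graph = phenoscore.build_phenotype_graph(
        bundle.pkn.to_networkx(), bundle.phenotype_edges)
    proteins = [n for n, s in model.node_states.items() if s != 0]
    phenotypes = sorted(set(bundle.phenotype_edges["phenotype"].astype(str)))
    paths = phenoscore.proxpath_proximity(
        pheno_graph, proteins, phenotypes,
        max_len=config.phenotype_max_len, stat=config.proxpath_stat,
        preprocess=config.proxpath_preprocess,
        quantified_analytes=_quantified_genes(bundle),
        null_size=config.proxpath_null_size, seed=config.seed)
    inferred = {str(r["gene_name"]): int(r["activity"])
                for _, r in activities.iterrows()}
    pheno_acts = phenoscore.phenotype_activity(
        model, paths, remove_cascades=config.remove_cascades,
        weight_by_paths=config.weight_by_paths,
        use_optimizer_states=config.use_optimizer_states,
        inferred_activities=inferred)
    phenoscore.attach_phenotypes(model, pheno_acts, paths)
    return pheno_acts


def run_pipeline(bundle: InputBundle, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full three-step pipeline on an input bundle.

    Raises before any computation when mandatory inputs are missing:
    a PKN, at least one source node, and at least one omics layer with
    a matching regulon set (or a regulatory-site table).
    """
    config = config or PipelineConfig()
    if not bundle.pkn.edges:
        raise ValueError("input bundle has an empty PKN")
    if not bundle.sources:
        raise ValueError("input bundle has no perturbed source nodes")
    has_route = (
        (bundle.transcriptomics is not None and bundle.regulons_tf)
        or (bundle.phospho is not None and bundle.regulons_kin)
        or (bundle.phospho is not None and bundle.regulatory_sites is not None))
    if not has_route:
        raise ValueError("no omics layer with matching regulons or "
                         "regulatory sites; nothing to infer")

    logger.info("pipeline start: seed=%d layout=%s shots=%d flavor=%s",
                config.seed, config.layout, config.shots, config.flavor)
    acts = infer_activities(bundle, config)
    logger.info("step 1: inferred %d protein activities", len(acts))
    model, _ = build_model(bundle, acts, config)
    logger.info("step 2: model with %d nodes / %d edges, objective %.3f",
                model.graph.number_of_nodes(), model.graph.number_of_edges(),
                model.objective)
    pheno = infer_phenotypes(bundle, model, acts, config)
    logger.info("step 3: %d phenotype activities", len(pheno))

    metrics: dict[str, Any] = {
        "n_activities": int(len(acts)),
        "n_nodes": int(model.graph.number_of_nodes()),
        "n_edges": int(model.graph.number_of_edges()),
        "n_phenotypes": int(len(pheno)),
        "objective": float(model.objective),
        "sign_ratio": model.sign_ratio,
    }
    if bundle.gold is not None:
        pred = acts.rename(columns={"gene_name": "entity"})
        pr = benchmark.prf_rmse(pred, bundle.gold)
        metrics.update({"precision": pr.precision, "recall": pr.recall,
                        "rmse": pr.rmse, "tp": pr.tp, "fp": pr.fp,
                        "fn": pr.fn})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        acts.to_csv(out_dir / "activities.tsv", sep="\t", index=False)
        write_model(model, out_dir)
        pheno.to_csv(out_dir / "phenotype_activities.tsv", sep="\t",
                     index=False)
        pd.DataFrame([metrics]).to_csv(out_dir / "metrics.tsv", sep="\t",
                                       index=False)
        config.to_yaml(out_dir / "run_config.yaml")
    return PipelineResult(activities=acts, model=model,
                          phenotype_activities=pheno, metrics=metrics)
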