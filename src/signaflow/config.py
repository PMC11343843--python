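"""Pipeline configuration.

One dataclass holds every tunable of the three-step pipeline with the
defaults selected by the benchmarking of the method (protein-activity
inference, network construction, phenotype inference). A YAML file can
override any subset of fields; unknown keys are rejected so typos fail
loudly rather than silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("signaflow")


@dataclass
class PipelineConfig:
    """All user-facing parameters of the pipeline.

    Step 1 — protein activity inference
    -----------------------------------
    hypergeometric_test:
        Weight enrichment scores by a hypergeometric over-representation
        test on significantly modulated regulon targets.
    proteomics_correction:
        Rescue regulators that are non-significant by enrichment but
        significantly modulated in proteomics.
    normalize_phospho:
        Correct phosphosite fold-changes by the parent protein
        fold-change before inference.
    activity_only_sites:
        Restrict PhosphoScore to phosphosites that regulate protein
        activity (exclude abundance-only sites).
    min_targets:
        Minimum quantified targets for a regulon to be scored.
    z_threshold:
        Two-sided z cutoff used for phospho normalization significance.
    p_threshold:
        Significance cutoff on (weighted) enrichment p-values.

    Step 2 — network construction
    -----------------------------
    include_atlas:
        Keep kinome-atlas kinase-substrate edges in the PKN.
    direct_only:
        Drop indirect (transcriptional) PKN edges.
    preprocess_pkn:
        Remove PKN edges between proteins not quantified in the data.
    layout:
        Naive-network layering: "one", "two" or "three".
    max_len:
        Maximum shortest-path length per layer boundary (one int per
        boundary; a single int is broadcast).
    connect_all:
        Add PKN edges between nodes discovered on distinct paths.
    flavor:
        ILP flavor: "vanilla" (fixed-sign sources) or "inverse"
        (free artificial perturbation node).
    shots:
        Number of sequential per-layer ILP runs (1, 2 or 3).
    beta:
        Edge-inclusion penalty of the ILP objective.
    solver_timeout_s:
        Wall-clock limit handed to the MILP backend.

    Step 3 — phenotype inference
    ----------------------------
    proxpath_preprocess:
        Discard protein→phenotype paths traversing unquantified proteins.
    phenotype_max_len:
        Maximum path length between model proteins and phenotypes.
    proxpath_stat:
        Null-distribution statistic, "mean" or "median".
    proxpath_null_size:
        Number of degree-matched random sources per null.
    remove_cascades:
        Keep only regulators independently regulating a phenotype.
    weight_by_paths:
        Weight each regulator by its number of significant paths.
    use_optimizer_states:
        Use all optimizer-assigned node states (True) or only
        Step-1-inferred proteins (False) for phenotype activity.
    """

    # Step 1
    hypergeometric_test: bool = True
    proteomics_correction: bool = True
    normalize_phospho: bool = True
    activity_only_sites: bool = True
    min_targets: int = 5
    z_threshold: float = 1.96
    p_threshold: float = 0.05
    # Step 2
    include_atlas: bool = True
    direct_only: bool = False
    preprocess_pkn: bool = True
    layout: str = "three"
    max_len: tuple[int, ...] = (4, 4, 4)
    connect_all: bool = True
    flavor: str = "vanilla"
    shots: int = 3
    beta: float = 0.2
    solver_timeout_s: float = 600.0
    # Step 3
    proxpath_preprocess: bool = True
    phenotype_max_len: int = 4
    proxpath_stat: str = "mean"
    proxpath_null_size: int = 100
    remove_cascades: bool = True
    weight_by_paths: bool = True
    use_optimizer_states: bool = True
    # Global
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.max_len, int):
            self.max_len = (self.max_len,) * 3
        else:
            self.max_len = tuple(self.max_len)
        if self.layout not in ("one", "two", "three"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.flavor not in ("vanilla", "inverse"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.shots not in (1, 2, 3):
            raise ValueError("shots must be 1, 2 or 3")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.proxpath_stat not in ("mean", "median"):
            raise ValueError("proxpath_stat must be 'mean' or 'median'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["max_len"] = list(self.max_len)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def replace(self, **kw: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
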