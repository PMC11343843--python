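"""Synthetic fixtures: toy PKNs, regulons, omics contrasts, gold standards.

Every generator is a pure function of its parameters and a seed, so
fixtures regenerate bit-identically. The statistical structure mirrors
what the inference steps assume: a planted regulator with activity
a ∈ {-1, +1} modulates each of its targets by mode × a plus Gaussian
noise of standard deviation σ, and an analyte is significant when its
statistic exceeds 1.96 σ in absolute value — the same z-convention the
pipeline itself applies. Defaults (50 planted regulators, ≥10 targets
each, σ = 0.5) are the conditions under which footprint inference is
expected to recover ≥ 95% of planted signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pkn import CausalEdge, PKNGraph

DEFAULT_SIGMA = 0.5
DEFAULT_N_REGULATORS = 50
DEFAULT_N_TARGETS = 10

PHENOTYPE_LABELS = (
    "APOPTOSIS", "AUTOPHAGY", "PROLIFERATION", "CELL_CYCLE_PROGRESSION",
    "CELL_CYCLE_BLOCK", "GLYCOLYSIS", "PROTEIN_SYNTHESIS", "ADIPOGENESIS",
    "FATTY_ACID_BIOSYNTHESIS", "CELL_DEATH",
)


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth regulator activities with the generating noise level."""

    activities: dict[str, int]
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        bad = {r: a for r, a in self.activities.items() if a not in (-1, 1)}
        if bad:
            raise ValueError(f"planted activities must be ±1: {bad}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def plant_truth(regulators: Sequence[str], seed: int = 0,
                sigma: float = DEFAULT_SIGMA) -> PlantedTruth:
    """Assign each regulator a random activity in {-1, +1}."""
    rng = np.random.default_rng(seed)
    acts = {r: int(rng.choice([-1, 1])) for r in regulators}
    return PlantedTruth(activities=acts, sigma=sigma, seed=seed)


# ---------------------------------------------------------------------------
# toy PKN
# ---------------------------------------------------------------------------

def _role_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n nodes over role fractions.

    Each role gets floor(f * n); leftover slots go to the largest
    fractional remainders, earlier roles first on ties.
    """
    raw = [f * n for f in fractions]
    counts = [math.floor(x) for x in raw]
    leftover = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def make_toy_pkn(n_nodes: int = 20, edge_density: float = 0.15,
                 fractions: Sequence[float] = (0.25, 0.25, 0.10, 0.40),
                 seed: int = 0, phospho_fraction: float = 0.3) -> PKNGraph:
    """Random weakly-connected signed digraph with stratified roles.

    ``fractions`` are the TF/KIN/PP/OTHER shares of nodes (largest-
    remainder rounding). The first node is marked source-like. A
    ``phospho_fraction`` of edges carries a phosphorylation mechanism
    with a synthetic residue. At density → 1 the graph approaches the
    complete digraph minus self-loops.
    """
    if n_nodes < 4:
        raise ValueError("need n_nodes >= 4")
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"G{i:03d}" for i in range(n_nodes)]
    counts = _role_counts(n_nodes, fractions)
    roles: list[str] = []
    for role, c in zip(("TF", "KIN", "PP", "OTHER"), counts):
        roles += [role] * c
    perm = rng.permutation(n_nodes)
    node_role = {nodes[perm[i]]: roles[i] for i in range(n_nodes)}

    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    n_edges = max(1, round(edge_density * len(pairs)))
    if n_edges < 1:
        raise ValueError("parameters yield < 1 edge")
    chosen_idx = rng.choice(len(pairs), size=n_edges, replace=False)
    chosen = {pairs[i] for i in chosen_idx}
    # guarantee weak connectivity with a random chain
    chain = list(rng.permutation(nodes))
    for a, b in zip(chain, chain[1:]):
        chosen.add((a, b))

    chosen_sorted = sorted(chosen)
    n_phospho = round(phospho_fraction * len(chosen_sorted))
    phospho_idx = set(rng.choice(len(chosen_sorted), size=n_phospho,
                                 replace=False)) if n_phospho else set()
    edges = []
    for i, (u, v) in enumerate(chosen_sorted):
        sign = int(rng.choice([-1, 1]))
        if i in phospho_idx:
            edges.append(CausalEdge(u, v, sign, mechanism="phosphorylation",
                                    residue=f"S{100 + i}", source_db="toy"))
        else:
            edges.append(CausalEdge(u, v, sign, mechanism="binding",
                                    source_db="toy"))
    attrs = {n: {"molecular_function": node_role[n], "entity_type": "protein"}
             for n in nodes}
    attrs[nodes[0]]["source_like"] = "true"
    return PKNGraph(edges=edges, node_attrs=attrs)


def make_regulons(pkn: PKNGraph, atlas_fraction: float = 0.0,
                  seed: int = 0) -> dict[str, pd.DataFrame]:
    """Derive regulons from PKN edges.

    TF regulons target transcripts (target gene names); KIN/PP regulons
    target phosphosites (``gene_residue`` tokens; edges without a
    residue get a synthetic one). PKN-derived entries have mode = edge
    sign and weight 1; an ``atlas_fraction`` of each kinase regulon is
    replaced by atlas-style entries with percentile-derived weights in
    [0.5, 0.9].
    """
    rng = np.random.default_rng(seed)
    regulons: dict[str, list[dict]] = {}
    for i, e in enumerate(pkn.edges):
        mf = pkn.molecular_function(e.source)
        if mf not in ("TF", "KIN", "PP"):
            continue
        if mf == "TF":
            target = e.target
        else:
            residue = e.residue or f"S{900 + i}"
            target = f"{e.target}_{residue}"
        weight = 1.0
        if mf in ("KIN", "PP") and atlas_fraction > 0 \
                and rng.random() < atlas_fraction:
            percentile = rng.uniform(88.0, 100.0)
            weight = 0.5 + 0.4 * (percentile - 88.0) / 12.0
        regulons.setdefault(e.source, []).append(
            {"target": target, "mode": float(e.sign), "weight": weight})
    return {r: pd.DataFrame(rows).drop_duplicates(subset="target")
            for r, rows in regulons.items()}


def make_planted_regulons(n_regulators: int = DEFAULT_N_REGULATORS,
                          n_targets: int = DEFAULT_N_TARGETS,
                          seed: int = 0,
                          phosphosite_targets: bool = False,
                          ) -> dict[str, pd.DataFrame]:
    """Disjoint-target regulons for parameter-recovery experiments.

    Each regulator gets ``n_targets`` unique targets with random modes
    in {-1, +1} and weight 1. With ``phosphosite_targets`` the analytes
    are ``gene_residue`` site tokens rather than gene names.
    """
    rng = np.random.default_rng(seed)
    regulons = {}
    t = 0
    for i in range(n_regulators):
        rows = []
        for _ in range(n_targets):
            name = f"T{t:04d}_S{t + 1000}" if phosphosite_targets else f"T{t:04d}"
            rows.append({"target": name,
                         "mode": float(rng.choice([-1, 1])), "weight": 1.0})
            t += 1
        regulons[f"R{i:03d}"] = pd.DataFrame(rows)
    return regulons


# ---------------------------------------------------------------------------
# simulated omics
# ---------------------------------------------------------------------------

def simulate_omics(regulons: Mapping[str, pd.DataFrame],
                   truth: PlantedTruth,
                   n_background: int = 0,
                   seed: int | None = None) -> pd.DataFrame:
    """Simulate a contrast signature from planted regulator activities.

    Target statistic = mode × activity + Normal(0, σ); targets of
    regulators absent from the truth (inactive) and background analytes
    draw from Normal(0, σ). Significance: |statistic| > 1.96 σ.
    Returns columns analyte, difference, significant.
    """
    sigma = truth.sigma
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows: dict[str, float] = {}
    for regulator, reg in regulons.items():
        activity = truth.activities.get(regulator, 0)
        for _, r in reg.iterrows():
            analyte = str(r["target"])
            if analyte in rows:
                continue
            base = float(r["mode"]) * activity
            rows[analyte] = base + float(rng.normal(0.0, sigma)) if sigma > 0 \
                else base
    for b in range(n_background):
        rows[f"B{b:04d}"] = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
    df = pd.DataFrame({"analyte": list(rows), "difference": list(rows.values())})
    threshold = 1.96 * sigma if sigma > 0 else 0.0
    df["significant"] = np.abs(df["difference"]) > threshold
    return df


def signature_to_phospho_table(signature: pd.DataFrame) -> pd.DataFrame:
    """Split ``gene_residue`` analytes into a phospho table.

    Returns columns gene_name, residue, difference, significant.
    """
    parts = signature["analyte"].str.rsplit("_", n=1, expand=True)
    return pd.DataFrame({"gene_name": parts[0], "residue": parts[1],
                         "difference": signature["difference"],
                         "significant": signature["significant"]})


def simulate_proteomics(genes: Sequence[str], truth: PlantedTruth,
                        significant_fraction: float = 0.2,
                        seed: int = 0) -> pd.DataFrame:
    """Gene-level contrasts: planted genes follow their activity, the
    rest are noise; a random fraction of noise genes is flagged
    significant to exercise rescue logic."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        act = truth.activities.get(g)
        if act is not None:
            diff = act * (1.0 + abs(float(rng.normal(0.0, truth.sigma))))
            sig = True
        else:
            diff = float(rng.normal(0.0, truth.sigma))
            sig = bool(rng.random() < significant_fraction)
        rows.append({"gene_name": g, "difference": diff, "significant": sig})
    return pd.DataFrame(rows)


def make_gold_standard(truth: PlantedTruth, drop_fraction: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Expected activities with a seeded not-inferable subset.

    Returns columns entity, expected, inferable.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    entities = sorted(truth.activities)
    n_drop = round(drop_fraction * len(entities))
    dropped = set(rng.choice(entities, size=n_drop, replace=False)) \
        if n_drop else set()
    return pd.DataFrame({
        "entity": entities,
        "expected": [truth.activities[e] for e in entities],
        "inferable": [e not in dropped for e in entities],
    })


# ---------------------------------------------------------------------------
# coherent toy world for end-to-end runs
# ---------------------------------------------------------------------------

@dataclass
class ToyWorld:
    """A self-consistent bundle: PKN, regulons, omics, phenotypes, gold."""

    pkn: PKNGraph
    sources: dict[str, int]
    truth: PlantedTruth
    regulons_tf: dict[str, pd.DataFrame]
    regulons_kin: dict[str, pd.DataFrame]
    transcriptomics: pd.DataFrame
    phospho: pd.DataFrame
    proteomics: pd.DataFrame
    phenotype_edges: pd.DataFrame
    gold: pd.DataFrame
    node_states: dict[str, int] = field(default_factory=dict)


def make_toy_world(seed: int = 0, n_kinases: int = 6, n_others: int = 5,
                   n_tfs: int = 6, targets_per_regulator: int = 10,
                   sigma: float = DEFAULT_SIGMA,
                   n_phenotypes: int = 6) -> ToyWorld:
    """Layered signaling world with sign-coherent ground truth.

    A receptor R is fixed active (+1); kinases, other signaling
    proteins and TFs get random ±1 states; every layered edge's sign is
    chosen as state(child) × state(parent) so the whole cascade is
    sign-coherent and the ILP has a recoverable optimum. Regulons for
    TFs (transcripts) and kinases (phosphosites) drive simulated omics
    at noise σ; phenotype edges connect TFs and others to phenotype
    labels with random signs.
    """
    rng = np.random.default_rng(seed)
    receptor = "RCPT"
    kinases = [f"KIN{i:02d}" for i in range(n_kinases)]
    others = [f"OTH{i:02d}" for i in range(n_others)]
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    states: dict[str, int] = {receptor: 1}
    for n in kinases + others + tfs:
        states[n] = int(rng.choice([-1, 1]))

    edges: list[CausalEdge] = []
    site = 200

    def link(u: str, v: str, mechanism: str) -> None:
        nonlocal site
        sign = states[v] * states[u]
        residue = f"S{site}" if mechanism == "phosphorylation" else None
        site += 1
        edges.append(CausalEdge(u, v, sign, mechanism=mechanism,
                                residue=residue, source_db="toy"))

    for k in kinases:
        link(receptor, k, "phosphorylation")
    for i, o in enumerate(others):
        link(kinases[i % n_kinases], o, "phosphorylation")
        if rng.random() < 0.5:
            link(kinases[(i + 1) % n_kinases], o, "phosphorylation")
    for i, t in enumerate(tfs):
        link(others[i % n_others], t, "phosphorylation")
        if rng.random() < 0.5:
            link(others[(i + 2) % n_others], t, "binding")

    attrs = {receptor: {"molecular_function": "OTHER", "entity_type": "protein",
                        "source_like": "true"}}
    for k in kinases:
        attrs[k] = {"molecular_function": "KIN", "entity_type": "protein"}
    for o in others:
        attrs[o] = {"molecular_function": "OTHER", "entity_type": "protein"}
    for t in tfs:
        attrs[t] = {"molecular_function": "TF", "entity_type": "protein"}
    pkn = PKNGraph(edges=edges, node_attrs=attrs)

    truth = PlantedTruth(activities={n: s for n, s in states.items()
                                     if n != receptor},
                         sigma=sigma, seed=seed)

    t = 0
    regulons_tf: dict[str, pd.DataFrame] = {}
    for tf in tfs:
        rows = [{"target": f"TR{t + j:04d}",
                 "mode": float(rng.choice([-1, 1])), "weight": 1.0}
                for j in range(targets_per_regulator)]
        t += targets_per_regulator
        regulons_tf[tf] = pd.DataFrame(rows)
    regulons_kin: dict[str, pd.DataFrame] = {}
    for k in kinases:
        rows = [{"target": f"PS{t + j:04d}_S{t + j + 3000}",
                 "mode": float(rng.choice([-1, 1])), "weight": 1.0}
                for j in range(targets_per_regulator)]
        t += targets_per_regulator
        regulons_kin[k] = pd.DataFrame(rows)

    transcriptomics = simulate_omics(regulons_tf, truth, n_background=20,
                                     seed=seed + 1)
    transcriptomics = transcriptomics.rename(columns={"analyte": "gene_name"})
    phospho_sig = simulate_omics(regulons_kin, truth, n_background=0,
                                 seed=seed + 2)
    phospho = signature_to_phospho_table(phospho_sig)
    # null background sites dominate the table, as in real data, so the
    # corrected-distribution z-scores single out truly modulated sites
    bg = [{"gene_name": f"BGP{i:03d}", "residue": f"S{i + 5000}",
           "difference": float(rng.normal(0.0, sigma)), "significant": False}
          for i in range(150)]
    phospho = pd.concat([phospho, pd.DataFrame(bg)], ignore_index=True)
    # regulatory sites of others/TFs so PhosphoScore can reach them too;
    # modulation well above protein abundance so it survives
    # phospho-over-proteomics normalization
    extra_rows = []
    for i, n in enumerate(others + tfs):
        diff = states[n] * (6.0 + abs(float(rng.normal(0.0, sigma))))
        extra_rows.append({"gene_name": n, "residue": f"S{600 + i}",
                           "difference": diff, "significant": True})
    # sites matching PKN phospho edges, so edge validation finds them;
    # roughly half strongly modulated, the rest near baseline
    for e in edges:
        if e.mechanism != "phosphorylation" or e.residue is None:
            continue
        mag = 6.0 if rng.random() < 0.5 else 0.3
        extra_rows.append({"gene_name": e.target, "residue": e.residue,
                           "difference": states[e.target] * mag,
                           "significant": mag > 1.0})
    phospho = pd.concat([phospho, pd.DataFrame(extra_rows)], ignore_index=True)

    all_genes = [receptor] + kinases + others + tfs
    proteomics = simulate_proteomics(all_genes, truth, seed=seed + 3)

    labels = list(PHENOTYPE_LABELS[:n_phenotypes])
    ph_rows = []
    for lab in labels:
        for reg in rng.choice(tfs + others, size=3, replace=False):
            ph_rows.append({"protein": str(reg), "phenotype": lab,
                            "sign": int(rng.choice([-1, 1]))})
    phenotype_edges = pd.DataFrame(ph_rows).drop_duplicates(
        subset=["protein", "phenotype"])

    gold = make_gold_standard(truth, drop_fraction=0.1, seed=seed + 4)
    return ToyWorld(pkn=pkn, sources={receptor: 1}, truth=truth,
                    regulons_tf=regulons_tf, regulons_kin=regulons_kin,
                    transcriptomics=transcriptomics, phospho=phospho,
                    proteomics=proteomics, phenotype_edges=phenotype_edges,
                    gold=gold, node_states=states)


def regulatory_site_db_from_world(world: ToyWorld) -> pd.DataFrame:
    """Regulatory-site annotations matching the toy world's phospho rows.

    Sites of others/TFs regulate activity with the sign that makes the
    measured modulation concordant with the planted state.
    """
    rows = []
    for _, r in world.phospho.iterrows():
        gene = str(r["gene_name"])
        if gene not in world.node_states or gene.startswith("PS"):
            continue
        rows.append({"gene": gene, "residue": str(r["residue"]),
                     "sign": 1, "role_class": "activity"})
    return pd.DataFrame(rows).drop_duplicates(subset=["gene", "residue"])
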