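"""Step 1 — signed protein-activity inference from omics contrasts.

Two complementary routes:

* **Footprint enrichment** scores a regulator (TF, kinase or
  phosphatase) by the modulation of its known targets (transcripts or
  phosphosites). Signature statistics are rank-transformed to
  symmetric normal quantiles and combined per regulon into a
  normalized enrichment score (NES)

      NES = sum_i w_i * m_i * q_i / sqrt(sum_i w_i^2)

  with target mode m_i in [-1, 1] and weight w_i in (0, 1]; a
  two-sided p-value follows from the standard normal. Optionally the
  NES is damped by a hypergeometric over-representation test on the
  regulon's significant targets, and regulators missed by enrichment
  but significantly modulated in proteomics are rescued.

* **PhosphoScore** scores any protein carrying annotated regulatory
  phosphosites as the mean, over its significantly modulated sites, of
  the site fold-change times the site's regulatory sign.

Omics tables are pandas DataFrames with columns ``gene_name`` (phospho
tables additionally ``residue``), ``difference`` (the contrast
statistic) and ``significant`` (boolean).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("signaflow.activity")


# ---------------------------------------------------------------------------
# phospho-over-proteomics normalization
# ---------------------------------------------------------------------------

def normalize_phospho(phospho_table: pd.DataFrame,
                      proteomics_table: pd.DataFrame,
                      z_threshold: float = 1.96) -> pd.DataFrame:
    """Correct phosphosite fold-changes by parent-protein fold-changes.

    corrected = phospho difference - parent-protein difference; sites
    without a quantified parent protein pass through uncorrected and
    are flagged. z-scores are taken over the corrected distribution
    (mean / sample standard deviation); a site is significant iff
    |z| > ``z_threshold`` (strict).
    """
    prot = proteomics_table.set_index("gene_name")["difference"]
    out = phospho_table.copy()
    parent = out["gene_name"].map(prot)
    out["parent_quantified"] = parent.notna()
    corrected = out["difference"] - parent.fillna(0.0)
    sd = corrected.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError(
            "corrected phospho distribution has zero variance; z-scores are "
            "undefined — check that the phospho table holds real contrasts")
    z = (corrected - corrected.mean()) / sd
    out["difference"] = corrected
    out["z"] = z
    out["significant"] = np.abs(z) > z_threshold
    return out


# ---------------------------------------------------------------------------
# footprint enrichment
# ---------------------------------------------------------------------------

def _quantile_scores(stats_values: pd.Series) -> pd.Series:
    """Rank-transform statistics to symmetric standard-normal quantiles."""
    ranks = stats.rankdata(stats_values.to_numpy(), method="average")
    return pd.Series(stats.norm.ppf(ranks / (len(ranks) + 1)),
                     index=stats_values.index)


def footprint_enrichment(signature: pd.DataFrame,
                         regulons: Mapping[str, pd.DataFrame],
                         min_targets: int = 5) -> pd.DataFrame:
    """Score each regulon against a molecular signature.

    ``signature`` holds one row per analyte (column ``analyte`` or
    ``gene_name``) with its contrast statistic in ``difference``.
    ``regulons`` maps regulator → frame with columns ``target``,
    ``mode`` in [-1, 1] and ``weight`` in (0, 1]. Regulons with fewer
    than ``min_targets`` targets present in the signature are skipped.

    Returns a frame (regulator, nes, p_value, n_targets).
    """
    key = "analyte" if "analyte" in signature.columns else "gene_name"
    sig = signature.drop_duplicates(subset=key).set_index(key)
    quantiles = _quantile_scores(sig["difference"])
    rows = []
    for regulator, reg in regulons.items():
        present = reg[reg["target"].isin(quantiles.index)]
        if len(present) < min_targets:
            logger.debug("regulon %s below min_targets (%d < %d), skipped",
                         regulator, len(present), min_targets)
            continue
        q = quantiles.loc[present["target"]].to_numpy()
        w = present["weight"].to_numpy(dtype=float)
        m = present["mode"].to_numpy(dtype=float)
        nes = float(np.sum(w * m * q) / np.sqrt(np.sum(w ** 2)))
        p = float(2.0 * stats.norm.sf(abs(nes)))
        rows.append({"regulator": regulator, "nes": nes, "p_value": p,
                     "n_targets": len(present)})
    return pd.DataFrame(rows, columns=["regulator", "nes", "p_value", "n_targets"])


def hypergeometric_weighting(enrichment_table: pd.DataFrame,
                             signature: pd.DataFrame,
                             regulons: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Damp enrichment scores by significant-target over-representation.

    For each regulator: p = P[X >= k] under Hypergeometric(N, K, n)
    with N analytes in the signature, K significant analytes, n regulon
    targets present in the signature and k of them significant. The
    weighted score is NES * (1 - p). Regulators with n = 0 are dropped.
    """
    key = "analyte" if "analyte" in signature.columns else "gene_name"
    sig = signature.drop_duplicates(subset=key).set_index(key)
    all_analytes = set(sig.index)
    significant = set(sig.index[sig["significant"].astype(bool)])
    N, K = len(all_analytes), len(significant)
    out_rows = []
    for _, row in enrichment_table.iterrows():
        regulator = row["regulator"]
        targets = set(regulons[regulator]["target"]) & all_analytes
        n = len(targets)
        if n == 0:
            logger.debug("regulator %s has no targets in signature, dropped",
                         regulator)
            continue
        k = len(targets & significant)
        p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
        new = dict(row)
        new["p_hyper"] = p_hyper
        new["weighted_nes"] = row["nes"] * (1.0 - p_hyper)
        out_rows.append(new)
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# proteomics correction and PhosphoScore
# ---------------------------------------------------------------------------

def proteomics_correction(enrichment_table: pd.DataFrame,
                          proteomics_table: pd.DataFrame,
                          p_threshold: float = 0.05) -> pd.DataFrame:
    """Rescue regulators missed by enrichment but modulated in proteomics.

    A regulator whose (weighted) enrichment is non-significant but
    whose protein is significantly modulated in proteomics enters the
    activity table with activity = sign(proteomics statistic) and
    method "proteomics_rescue". Regulators significant in both keep
    their enrichment score; discordant signs keep the enrichment record
    with a flag.
    """
    prot = proteomics_table.set_index("gene_name")
    score_col = "weighted_nes" if "weighted_nes" in enrichment_table.columns else "nes"
    rows = []
    for _, row in enrichment_table.iterrows():
        gene = row["regulator"]
        score = float(row[score_col])
        enr_sig = float(row["p_value"]) < p_threshold and score != 0.0
        in_prot = gene in prot.index
        prot_sig = bool(prot.loc[gene, "significant"]) if in_prot else False
        prot_stat = float(prot.loc[gene, "difference"]) if in_prot else np.nan
        flags = []
        if enr_sig:
            if prot_sig and np.sign(prot_stat) != np.sign(score):
                flags.append("proteomics_discordant")
            rows.append({"gene_name": gene, "final_score": score,
                         "activity": int(np.sign(score)),
                         "p_value": float(row["p_value"]),
                         "method": "footprint", "flags": ";".join(flags)})
        elif prot_sig and prot_stat != 0.0:
            rows.append({"gene_name": gene, "final_score": prot_stat,
                         "activity": int(np.sign(prot_stat)),
                         "p_value": float(row["p_value"]),
                         "method": "proteomics_rescue", "flags": "rescued"})
    return pd.DataFrame(rows, columns=["gene_name", "final_score", "activity",
                                       "p_value", "method", "flags"])


def enrichment_to_activity(enrichment_table: pd.DataFrame,
                           p_threshold: float = 0.05) -> pd.DataFrame:
    """Keep significant enrichment records as a plain activity table."""
    score_col = "weighted_nes" if "weighted_nes" in enrichment_table.columns else "nes"
    keep = enrichment_table[(enrichment_table["p_value"] < p_threshold)
                            & (enrichment_table[score_col] != 0.0)]
    return pd.DataFrame({
        "gene_name": keep["regulator"],
        "final_score": keep[score_col].astype(float),
        "activity": np.sign(keep[score_col]).astype(int),
        "p_value": keep["p_value"].astype(float),
        "method": "footprint",
        "flags": "",
    }).reset_index(drop=True)


def phospho_score(phospho_table: pd.DataFrame,
                  regulatory_site_db: pd.DataFrame,
                  activity_only: bool = True,
                  significant_only: bool = True) -> pd.DataFrame:
    """Per-protein activity from regulatory-phosphosite modulation.

    ``regulatory_site_db`` has columns gene, residue, sign (±1) and
    role_class in {activity, abundance, both}. The score of a protein
    is the mean over its (significant) regulatory sites of
    site statistic × regulatory sign; with ``activity_only`` sites of
    role class "abundance" are excluded. Proteins with no eligible site
    are absent from the output.
    """
    db = regulatory_site_db
    if activity_only:
        db = db[db["role_class"] != "abundance"]
    sites = phospho_table
    if significant_only:
        sites = sites[sites["significant"].astype(bool)]
    joined = sites.merge(db, on=["gene_name", "residue"], how="inner") \
        if "gene_name" in db.columns else \
        sites.merge(db.rename(columns={"gene": "gene_name"}),
                    on=["gene_name", "residue"], how="inner")
    if joined.empty:
        return pd.DataFrame(columns=["gene_name", "final_score", "activity",
                                     "p_value", "method", "flags"])
    joined = joined.assign(contribution=joined["difference"] * joined["sign"])
    scores = joined.groupby("gene_name")["contribution"].mean()
    scores = scores[scores != 0.0]
    return pd.DataFrame({
        "gene_name": scores.index,
        "final_score": scores.to_numpy(),
        "activity": np.sign(scores.to_numpy()).astype(int),
        "p_value": np.nan,
        "method": "phosphoscore",
        "flags": "",
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def combine_activities(footprint_tables: Iterable[pd.DataFrame],
                       phosphoscore_table: pd.DataFrame | None,
                       mol_function_annotation: Mapping[str, str]) -> pd.DataFrame:
    """Union footprint and PhosphoScore activities into one table.

    When a protein appears in both, the footprint record wins and the
    agreement with PhosphoScore is recorded in ``flags``. Every record
    is annotated with its molecular function (TF/KIN/PP/OTHER); genes
    absent from the annotation are labeled OTHER with a log entry.
    """
    frames = [t for t in footprint_tables if t is not None and not t.empty]
    footprint = (pd.concat(frames, ignore_index=True)
                 .drop_duplicates(subset="gene_name", keep="first")
                 if frames else pd.DataFrame(columns=["gene_name", "final_score",
                                                      "activity", "p_value",
                                                      "method", "flags"]))
    records = {str(r["gene_name"]): dict(r) for _, r in footprint.iterrows()}
    if phosphoscore_table is not None:
        for _, r in phosphoscore_table.iterrows():
            gene = str(r["gene_name"])
            if gene in records:
                concordant = records[gene]["activity"] == r["activity"]
                flag = "phosphoscore_concordant" if concordant \
                    else "phosphoscore_discordant"
                old = records[gene].get("flags", "")
                records[gene]["flags"] = f"{old};{flag}".strip(";")
            else:
                records[gene] = dict(r)
    n_unannotated = 0
    for gene, rec in records.items():
        mf = mol_function_annotation.get(gene)
        if mf is None:
            mf = "OTHER"
            n_unannotated += 1
        rec["mf"] = mf
    if n_unannotated:
        logger.info("%d proteins missing molecular-function annotation, "
                    "labeled OTHER", n_unannotated)
    cols = ["gene_name", "mf", "final_score", "activity", "p_value",
            "method", "flags"]
    return pd.DataFrame(list(records.values()), columns=cols) \
        .sort_values("gene_name").reset_index(drop=True)
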