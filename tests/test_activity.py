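"""Protein-activity inference: normalization, enrichment, PhosphoScore."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hypergeom_sf_exact, nes_by_hand, zscores_by_hand
from signaflow import fixtures
from signaflow.activity import (combine_activities, enrichment_to_activity,
                                footprint_enrichment, hypergeometric_weighting,
                                normalize_phospho, phospho_score,
                                proteomics_correction)


def phospho_frame(genes, residues, diffs):
    return pd.DataFrame({"gene_name": genes, "residue": residues,
                         "difference": diffs,
                         "significant": [False] * len(genes)})


class TestNormalizePhospho:
    def test_equal_modulation_cancels(self):
        ph = phospho_frame(["A", "B", "C", "D", "E"],
                           [f"S{i}" for i in range(5)],
                           [2.0, 1.0, 3.0, 0.5, -1.0])
        prot = pd.DataFrame({"gene_name": ["A"], "difference": [2.0],
                             "significant": [True]})
        out = normalize_phospho(ph, prot)
        assert out.loc[out.gene_name == "A", "difference"].iloc[0] == 0.0

    def test_z_matches_hand_oracle(self):
        # corrected values [1,-1,2,0,3]: mean 1, sample sd ~1.581
        ph = phospho_frame(list("ABCDE"), [f"S{i}" for i in range(5)],
                           [1.0, -1.0, 2.0, 0.0, 3.0])
        prot = pd.DataFrame({"gene_name": [], "difference": [],
                             "significant": []})
        out = normalize_phospho(ph, prot)
        expected = zscores_by_hand([1.0, -1.0, 2.0, 0.0, 3.0])
        np.testing.assert_allclose(out["z"].to_numpy(), expected, atol=1e-12)
        assert not out["significant"].any()

    def test_threshold_is_strict(self):
        # engineer a site with |z| exactly at the threshold: not significant
        vals = [0.0, 1.0, -1.0, 2.0, -2.0]
        z = zscores_by_hand(vals)
        zmax = max(abs(x) for x in z)
        ph = phospho_frame(list("ABCDE"), [f"S{i}" for i in range(5)], vals)
        prot = pd.DataFrame({"gene_name": [], "difference": [],
                             "significant": []})
        out = normalize_phospho(ph, prot, z_threshold=zmax)
        assert not out["significant"].any()
        out2 = normalize_phospho(ph, prot, z_threshold=zmax - 1e-9)
        assert out2["significant"].any()

    def test_unquantified_parent_passes_through_flagged(self):
        ph = phospho_frame(["A", "B", "C"], ["S1", "S2", "S3"],
                           [1.0, 2.0, 3.0])
        prot = pd.DataFrame({"gene_name": ["A"], "difference": [0.5],
                             "significant": [True]})
        out = normalize_phospho(ph, prot)
        assert out["parent_quantified"].tolist() == [True, False, False]
        assert out.loc[1, "difference"] == 2.0

    def test_zero_variance_raises(self):
        ph = phospho_frame(["A", "B", "C"], ["S1", "S2", "S3"],
                           [1.0, 1.0, 1.0])
        prot = pd.DataFrame({"gene_name": [], "difference": [],
                             "significant": []})
        with pytest.raises(ValueError, match="zero variance"):
            normalize_phospho(ph, prot)


def signature_frame(stats, significant=None):
    n = len(stats)
    return pd.DataFrame({
        "analyte": [f"T{i}" for i in range(n)],
        "difference": stats,
        "significant": significant if significant is not None
        else [False] * n})


class TestFootprintEnrichment:
    def test_single_target_sign_follows_mode(self):
        sig = signature_frame([3.0, 1.0, 0.5, -0.5, -1.0])
        reg_pos = {"R": pd.DataFrame({"target": ["T0"], "mode": [1.0],
                                      "weight": [1.0]})}
        reg_neg = {"R": pd.DataFrame({"target": ["T0"], "mode": [-1.0],
                                      "weight": [1.0]})}
        up = footprint_enrichment(sig, reg_pos, min_targets=1)
        down = footprint_enrichment(sig, reg_neg, min_targets=1)
        assert up["nes"].iloc[0] > 0
        # antisymmetry in mode: equal magnitude, opposite sign
        assert down["nes"].iloc[0] == pytest.approx(-up["nes"].iloc[0])

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(5)
        stats = rng.normal(size=10)
        sig = signature_frame(list(stats))
        targets = [("T1", 1.0, 0.8), ("T4", -1.0, 0.6), ("T7", 1.0, 1.0)]
        regulons = {"R": pd.DataFrame(targets,
                                      columns=["target", "mode", "weight"])}
        out = footprint_enrichment(sig, regulons, min_targets=3)
        expected = nes_by_hand(dict(zip(sig["analyte"], sig["difference"])),
                               targets)
        assert out["nes"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_min_targets_skips_small_regulons(self):
        sig = signature_frame([1.0, 2.0, 3.0])
        regulons = {"R": pd.DataFrame({"target": ["T0", "T1"],
                                       "mode": [1.0, 1.0],
                                       "weight": [1.0, 1.0]})}
        assert footprint_enrichment(sig, regulons, min_targets=5).empty

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=6,
                    max_size=12, unique=True),
           st.integers(0, 2 ** 31 - 1))
    def test_negating_signature_negates_nes(self, stats, seed):
        """Antisymmetry: flipping every statistic flips every NES exactly."""
        rng = np.random.default_rng(seed)
        sig = signature_frame(stats)
        idx = rng.choice(len(stats), size=min(5, len(stats)), replace=False)
        regulons = {"R": pd.DataFrame({
            "target": [f"T{i}" for i in idx],
            "mode": rng.choice([-1.0, 1.0], size=len(idx)),
            "weight": rng.uniform(0.5, 1.0, size=len(idx))})}
        plus = footprint_enrichment(sig, regulons, min_targets=1)
        neg = sig.assign(difference=-sig["difference"])
        minus = footprint_enrichment(neg, regulons, min_targets=1)
        assert minus["nes"].iloc[0] == pytest.approx(-plus["nes"].iloc[0],
                                                     abs=1e-12)


class TestHypergeometricWeighting:
    def run(self, N, K, n, k):
        sig = pd.DataFrame({
            "analyte": [f"T{i}" for i in range(N)],
            "difference": [1.0] * N,
            "significant": [i < K for i in range(N)]})
        # first k targets significant, remaining n-k not
        targets = [f"T{i}" for i in range(k)] + \
            [f"T{K + i}" for i in range(n - k)]
        regulons = {"R": pd.DataFrame({"target": targets,
                                       "mode": [1.0] * n,
                                       "weight": [1.0] * n})}
        enr = pd.DataFrame({"regulator": ["R"], "nes": [2.0],
                            "p_value": [0.04], "n_targets": [n]})
        return hypergeometric_weighting(enr, sig, regulons)

    def test_exact_combinatorial_value(self):
        # N=10, K=4, n=3, k=3 -> p = C(4,3)C(6,0)/C(10,3) = 1/30
        out = self.run(10, 4, 3, 3)
        assert out["p_hyper"].iloc[0] == pytest.approx(1 / 30)
        assert out["weighted_nes"].iloc[0] == pytest.approx(2.0 * (29 / 30))

    def test_no_significant_analytes_zeroes_score(self):
        out = self.run(8, 0, 3, 0)
        assert out["p_hyper"].iloc[0] == pytest.approx(1.0)
        assert out["weighted_nes"].iloc[0] == 0.0

    def test_saturated_table_zeroes_score(self):
        out = self.run(6, 6, 6, 6)
        assert out["p_hyper"].iloc[0] == pytest.approx(1.0)
        assert out["weighted_nes"].iloc[0] == 0.0

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_exact_sum_for_small_tables(self, data):
        """Hypergeometric p equals the combinatorial-sum oracle, N <= 30."""
        N = data.draw(st.integers(2, 30))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(max(0, n - (N - K)), min(n, K)))
        out = self.run(N, K, n, k)
        assert out["p_hyper"].iloc[0] == pytest.approx(
            hypergeom_sf_exact(k, N, K, n), abs=1e-12)


class TestProteomicsCorrection:
    enr = pd.DataFrame({"regulator": ["R1", "R2", "R3"],
                        "nes": [0.5, 2.5, -2.5],
                        "p_value": [0.4, 0.01, 0.01],
                        "n_targets": [5, 5, 5]})

    def test_rescue_of_nonsignificant_regulator(self):
        prot = pd.DataFrame({"gene_name": ["R1"], "difference": [1.3],
                             "significant": [True]})
        out = proteomics_correction(self.enr, prot)
        r1 = out[out.gene_name == "R1"].iloc[0]
        assert r1["method"] == "proteomics_rescue"
        assert r1["activity"] == 1

    def test_significant_enrichment_kept_without_proteomics(self):
        prot = pd.DataFrame({"gene_name": [], "difference": [],
                             "significant": []})
        out = proteomics_correction(self.enr, prot)
        assert set(out["gene_name"]) == {"R2", "R3"}
        assert (out["method"] == "footprint").all()

    def test_discordant_signs_keep_enrichment_with_flag(self):
        prot = pd.DataFrame({"gene_name": ["R2"], "difference": [-3.0],
                             "significant": [True]})
        out = proteomics_correction(self.enr, prot)
        r2 = out[out.gene_name == "R2"].iloc[0]
        assert r2["activity"] == 1  # enrichment sign wins
        assert "proteomics_discordant" in r2["flags"]


class TestPhosphoScore:
    db = pd.DataFrame({
        "gene": ["P1", "P1", "P2"],
        "residue": ["S1", "S2", "S3"],
        "sign": [1, -1, 1],
        "role_class": ["activity", "activity", "abundance"]})

    def table(self, rows):
        return pd.DataFrame(rows, columns=["gene_name", "residue",
                                           "difference", "significant"])

    def test_single_activating_site(self):
        ph = self.table([("P1", "S1", 2.0, True)])
        out = phospho_score(ph, self.db)
        assert out["final_score"].iloc[0] == pytest.approx(2.0)
        assert out["activity"].iloc[0] == 1

    def test_mixed_sites_hand_mean(self):
        ph = self.table([("P1", "S1", 2.0, True), ("P1", "S2", 1.0, True)])
        out = phospho_score(ph, self.db)
        # (2*(+1) + 1*(-1)) / 2 = 0.5 -> active
        assert out["final_score"].iloc[0] == pytest.approx(0.5)
        assert out["activity"].iloc[0] == 1

    def test_abundance_site_excluded_when_activity_only(self):
        ph = self.table([("P2", "S3", 3.0, True)])
        assert phospho_score(ph, self.db, activity_only=True).empty
        assert not phospho_score(ph, self.db, activity_only=False).empty

    def test_nonsignificant_sites_ignored(self):
        ph = self.table([("P1", "S1", 2.0, False)])
        assert phospho_score(ph, self.db).empty


class TestCombineActivities:
    fp = pd.DataFrame({"gene_name": ["A", "B"], "final_score": [1.0, -2.0],
                       "activity": [1, -1], "p_value": [0.01, 0.02],
                       "method": "footprint", "flags": ""})
    ps = pd.DataFrame({"gene_name": ["B", "C"], "final_score": [-1.0, 0.5],
                       "activity": [-1, 1], "p_value": [np.nan] * 2,
                       "method": "phosphoscore", "flags": ""})

    def test_union_with_footprint_precedence(self):
        out = combine_activities([self.fp], self.ps, {"A": "TF", "B": "KIN"})
        assert len(out) == 3  # |footprint| + |phosphoscore-only|
        b = out[out.gene_name == "B"].iloc[0]
        assert b["method"] == "footprint"
        assert "phosphoscore_concordant" in b["flags"]
        c = out[out.gene_name == "C"].iloc[0]
        assert c["method"] == "phosphoscore"

    def test_unannotated_gene_labeled_other(self):
        out = combine_activities([self.fp], None, {"A": "TF"})
        assert out[out.gene_name == "B"]["mf"].iloc[0] == "OTHER"


class TestParameterRecovery:
    def test_planted_sign_recovery_above_95pct(self):
        """50 planted regulators, >=10 targets, sigma 0.5: footprint
        recovers >= 95% of the planted activity signs."""
        regulons = fixtures.make_planted_regulons(50, 10, seed=11)
        truth = fixtures.plant_truth(sorted(regulons), seed=11, sigma=0.5)
        sig = fixtures.simulate_omics(regulons, truth, n_background=100)
        enr = footprint_enrichment(sig, regulons, min_targets=5)
        nes = enr.set_index("regulator")["nes"]
        hits = sum(1 for r, a in truth.activities.items()
                   if np.sign(nes.get(r, 0.0)) == a)
        assert hits / len(truth.activities) >= 0.95
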