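from math import comb

import numpy as np
import pytest

from ecometab.annotation import (
    ADDUCTS,
    CompoundRecord,
    FormulaError,
    adduct_mz,
    build_report,
    enrichment_table,
    hypergeom_tail,
    load_compounds,
    load_pathways,
    match_features,
    monoisotopic_mass,
    parse_formula,
    pathway_enrichment,
    ppm_error,
)

# independent hand-summed oracle masses (atomic masses to >= 6 decimals)
H, C, N, O = 1.0078250, 12.0, 14.0030740, 15.9949146


class TestFormula:
    def test_parse_examples(self):
        assert parse_formula("C16H18O9") == {"C": 16, "H": 18, "O": 9}
        assert parse_formula("H2O") == {"H": 2, "O": 1}
        assert parse_formula("C_16_H_18_O_9_") == {"C": 16, "H": 18, "O": 9}

    def test_unknown_element_rejected(self):
        with pytest.raises(FormulaError):
            parse_formula("C16H18O9X")

    def test_empty_formula(self):
        assert parse_formula("") == {}
        assert monoisotopic_mass({}) == 0.0

    def test_two_letter_elements(self):
        assert parse_formula("NaCl") == {"Na": 1, "Cl": 1}


class TestMass:
    def test_cga_mass_hand_sum(self):
        expected = 16 * C + 18 * H + 9 * O
        assert monoisotopic_mass("C16H18O9") == pytest.approx(expected, abs=1e-4)
        assert monoisotopic_mass("C16H18O9") == pytest.approx(354.0951, abs=1e-4)

    def test_phenylalanine_mass_hand_sum(self):
        expected = 9 * C + 11 * H + N + 2 * O
        assert monoisotopic_mass("C9H11NO2") == pytest.approx(expected, abs=1e-4)
        assert monoisotopic_mass("C9H11NO2") == pytest.approx(165.0790, abs=1e-4)


class TestAdducts:
    def test_sodium_adduct_of_cga(self):
        assert adduct_mz(354.09508, "[M+Na]+") == pytest.approx(377.0843, abs=1e-4)

    def test_protonated_phenylalanine(self):
        assert adduct_mz(165.07898, "[M+H]+") == pytest.approx(166.0863, abs=1e-4)

    def test_shift_signs_match_polarity(self):
        for name, spec in ADDUCTS.items():
            mz = adduct_mz(300.0, name)
            if name == "[M+H-H2O]+":
                assert mz < 300.0  # water loss dominates the proton
            elif spec.charge > 0:
                assert mz > 300.0

    def test_ppm_error_examples(self):
        theo = adduct_mz(monoisotopic_mass("C16H18O9"), "[M+Na]+")
        assert ppm_error(377.0844, theo) == pytest.approx(0.26, abs=0.1)
        assert ppm_error(theo, theo) == 0.0
        theo_phe = adduct_mz(monoisotopic_mass("C9H11NO2"), "[M+H]+")
        assert abs(ppm_error(166.0865, theo_phe)) < 5


class TestMatching:
    @pytest.fixture
    def cga_ref(self):
        return [CompoundRecord("Caffeoylquinic acid", "C16H18O9", "C00852")]

    def test_cga_feature_matched(self, cga_ref):
        cand, unmatched = match_features(
            ["377.0844_2.9"], cga_ref, adducts=("[M+Na]+",)
        )
        assert len(cand) == 1
        assert cand.loc[0, "kegg_id"] == "C00852"
        assert abs(cand.loc[0, "ppm_error"]) < 1
        assert not unmatched

    def test_unrelated_feature_unmatched(self, cga_ref):
        cand, unmatched = match_features(["300.0000_1.0"], cga_ref)
        assert len(cand) == 0 and unmatched == ["300.0000_1.0"]

    def test_zero_tolerance_only_exact(self, cga_ref):
        theo = adduct_mz(monoisotopic_mass("C16H18O9"), "[M+Na]+")
        cand, _ = match_features(
            {"exact": theo, "near": theo * (1 + 1e-6)}, cga_ref,
            adducts=("[M+Na]+",), tol_ppm=0.0,
        )
        assert list(cand["feature"]) == ["exact"]

    def test_roundtrip_every_reference_compound(self):
        ref = load_compounds()
        for adduct in ("[M+H]+", "[M-H]-"):
            mzs = {
                c.kegg_id: adduct_mz(c.monoisotopic_mass, adduct) for c in ref
            }
            cand, unmatched = match_features(mzs, ref, adducts=(adduct,))
            assert not unmatched
            exact = cand[cand["ppm_error"].abs() < 1e-9]
            # every compound recovers itself at ppm == 0
            assert set(exact["kegg_id"]) == {c.kegg_id for c in ref}

    def test_empty_inputs_rejected(self, cga_ref):
        with pytest.raises(ValueError, match="adduct"):
            match_features(["100.0_1.0"], cga_ref, adducts=())
        with pytest.raises(ValueError, match="reference"):
            match_features(["100.0_1.0"], [])


class TestEnrichment:
    def test_hypergeometric_exact_fraction(self):
        # N=20, m=5, n_sig=8, k=4: exact tail by enumeration
        expected = sum(
            comb(5, x) * comb(15, 8 - x) for x in range(4, 6)
        ) / comb(20, 8)
        assert expected == pytest.approx(7280 / 125970)
        assert hypergeom_tail(4, 20, 5, 8) == pytest.approx(expected)

    def test_k_zero_boundary(self):
        assert hypergeom_tail(0, 20, 5, 8) == 1.0

    def test_enrichment_identifies_loaded_pathway(self):
        pathways = {
            "pwA": {"name": "A", "compounds": {f"C{i:05d}" for i in range(5)}},
            "pwB": {"name": "B", "compounds": {f"C{i:05d}" for i in range(5, 10)}},
        }
        universe = {f"C{i:05d}" for i in range(20)}
        hits = {"C00000", "C00001", "C00002", "C00003", "C00011"}
        res = pathway_enrichment(hits, pathways, universe)
        assert res[0].pathway_id == "pwA"
        assert res[0].k == 4
        assert res[0].p_exact < res[1].p_exact

    def test_empty_pathway_skipped(self, caplog):
        import logging

        pathways = {"empty": {"name": "E", "compounds": set()}}
        with caplog.at_level(logging.WARNING):
            res = pathway_enrichment({"C00001"}, pathways, {"C00001", "C00002"})
        assert res == []

    def test_permutation_p_tracks_exact_on_uniform_fixture(self):
        # when every feature annotates uniquely and uniformly, the
        # permutation null approaches the hypergeometric tail
        ref = [
            CompoundRecord(f"cmp{i}", f"C{10+i}H{20}O{2}", f"C{i:05d}")
            for i in range(6)
        ]
        # distinct masses guaranteed by varying C count
        universe = {c.kegg_id for c in ref}
        pathways = {"pw": {"name": "P", "compounds": {"C00000", "C00001", "C00002"}}}
        all_feats = {
            f"{adduct_mz(c.monoisotopic_mass, '[M+H]+'):.4f}_1.0": adduct_mz(
                c.monoisotopic_mass, "[M+H]+"
            )
            for c in ref
        }
        hits = {"C00000", "C00001"}
        res = pathway_enrichment(
            hits,
            pathways,
            universe,
            feature_mzs=all_feats,
            n_features_sig=2,
            reference=ref,
            adducts=("[M+H]+",),
            n_perm=3000,
            seed=0,
        )[0]
        assert res.p_perm == pytest.approx(res.p_exact, abs=0.05)

    def test_enrichment_table_shape(self):
        pathways = load_pathways()
        ref = load_compounds()
        universe = {c.kegg_id for c in ref}
        res = pathway_enrichment({"C00852", "C00079"}, pathways, universe)
        tab = enrichment_table(res)
        assert len(tab) == len(pathways)
        assert ((tab["p_exact"] > 0) & (tab["p_exact"] <= 1)).all()


class TestReport:
    def test_long_format_mapping(self):
        import pandas as pd

        annotations = pd.DataFrame(
            {
                "feature": ["f1", "f2", "f3"],
                "compound": ["a", "b", "c"],
                "kegg_id": ["C1", "C2", "C3"],
                "adduct": ["[M+H]+"] * 3,
                "ppm_error": [0.1, -0.2, 0.3],
            }
        )
        pathways = {
            "p1": {"name": "P1", "compounds": {"C1", "C2"}},
            "p2": {"name": "P2", "compounds": {"C2", "C3"}},
        }
        rep = build_report(annotations, pathways)
        assert len(rep) == 4  # C2 appears in both pathways
        assert (rep.groupby("pathway_id").size() == 2).all()
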