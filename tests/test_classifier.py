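import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuproscan.annotation_io import SimilarityHit
from cuproscan.catalog import ArchPattern
from cuproscan.classifier import (
    ClassifyOptions,
    assemble_complexes,
    classify_csp,
    classify_species,
    collapse_hits,
    detect_tat_signal,
    disambiguate_transporter,
    match_architecture,
    match_single_domain,
    resolve_complex_identity,
)

from .conftest import make_protein, subsequence_oracle

MCO_DOMAINS = ["Cu-oxidase_3", "Cu-oxidase", "Cu-oxidase_2", "Copper-bind"]


class TestSingleDomain:
    def test_sod_cu_hit_yields_call(self, catalog):
        rec = make_protein(["Sod_Cu"])
        call = match_single_domain(rec, catalog["Sod_Cu"])
        assert call is not None and call.type_name == "Sod_Cu"
        assert call.member_protein_ids == ("p1",)

    def test_two_hits_collapse_to_one_call(self, catalog):
        rec = make_protein(["HMA", "HMA"])
        call = match_single_domain(rec, catalog["HMA"])
        assert call is not None
        assert call.type_name == "HMA"

    def test_no_hits_no_call(self, catalog):
        rec = make_protein([])
        assert match_single_domain(rec, catalog["Sod_Cu"]) is None

    def test_match_by_accession(self, catalog):
        rec = make_protein(["unnamed"], accessions=["PF00080"])
        assert match_single_domain(rec, catalog["Sod_Cu"]) is not None


class TestCollapseHits:
    def test_overlapping_same_domain_hits_keep_best(self):
        from cuproscan.annotation_io import DomainHit

        h1 = DomainHit("p", "HMA", "PF00403", 10, 100, 1e-20, 180.0)
        h2 = DomainHit("p", "HMA", "PF00403", 50, 140, 1e-10, 90.0)
        h3 = DomainHit("p", "HMA", "PF00403", 200, 280, 1e-15, 120.0)
        kept = collapse_hits([h1, h2, h3])
        assert kept == [h1, h3]

    def test_different_domains_may_overlap(self):
        from cuproscan.annotation_io import DomainHit

        h1 = DomainHit("p", "A", "A", 10, 100, 1e-20, 180.0)
        h2 = DomainHit("p", "B", "B", 50, 140, 1e-10, 90.0)
        assert len(collapse_hits([h1, h2])) == 2


class TestArchitectureMatching:
    def test_full_mco_architecture_matches_longest_pattern(self, catalog):
        rec = make_protein(["Cu-oxidase_3", "Cu-oxidase", "Cu-oxidase_2"])
        same = [p for p in catalog.patterns_for("MCOs") if p.scope == "same_protein"]
        pat = match_architecture(rec, same)
        assert pat is not None and pat.specificity_rank == 3

    def test_wrong_domain_order_does_not_match(self, catalog):
        rec = make_protein(["Cu-oxidase_2", "Cu-oxidase_3"])
        same = [p for p in catalog.patterns_for("MCOs") if p.scope == "same_protein"]
        assert match_architecture(rec, same) is None

    def test_empty_domain_list_matches_nothing(self, catalog):
        same = [p for p in catalog.patterns_for("MCOs") if p.scope == "same_protein"]
        assert match_architecture(make_protein([]), same) is None

    def test_subsequence_not_contiguity(self):
        # accessory domain inserted between pattern elements still matches
        rec = make_protein(["Cu-oxidase_3", "HMA", "Cu-oxidase_2"])
        pat = ArchPattern(("Cu-oxidase_3", "Cu-oxidase_2"), "same_protein")
        assert match_architecture(rec, [pat]) == pat

    def test_split_pattern_rejected(self):
        pat = ArchPattern(("A", "B"), "split_complex")
        with pytest.raises(ValueError):
            match_architecture(make_protein(["A", "B"]), [pat])

    @settings(max_examples=300, derandomize=True)
    @given(
        domains=st.lists(st.sampled_from(MCO_DOMAINS), max_size=6),
        pattern=st.lists(st.sampled_from(MCO_DOMAINS), min_size=1, max_size=3),
    )
    def test_agrees_with_exhaustive_subsequence_oracle(self, domains, pattern):
        rec = make_protein(domains)
        pat = ArchPattern(tuple(pattern), "same_protein")
        got = match_architecture(rec, [pat])
        expect = subsequence_oracle(tuple(pattern), tuple(domains))
        assert (got is not None) == expect


class TestComplexAssembly:
    def test_adjacent_cox1_fixo_form_cbb3(self, catalog):
        recs = [
            make_protein(["COX1"], "a", locus_index=10),
            make_protein(["FixO"], "b", locus_index=11),
        ]
        calls, consumed = assemble_complexes(recs, catalog, window=5)
        assert len(calls) == 1
        assert calls[0].type_name == "Cyto_C_cbb3"
        assert set(calls[0].member_protein_ids) == {"a", "b"}
        assert consumed == {"a", "b"}

    def test_window_violation_blocks_complex(self, catalog):
        recs = [
            make_protein(["COX1"], "a", locus_index=10),
            make_protein(["FixO"], "b", locus_index=300),
        ]
        calls, _ = assemble_complexes(recs, catalog, window=5)
        assert calls == []

    def test_back_to_back_operons_give_two_complexes(self, catalog):
        recs = [
            make_protein(["COX1"], "a1", locus_index=10),
            make_protein(["FixO"], "b1", locus_index=11),
            make_protein(["COX1"], "a2", locus_index=12),
            make_protein(["FixO"], "b2", locus_index=13),
        ]
        calls, _ = assemble_complexes(recs, catalog, window=5)
        assert [c.type_name for c in calls] == ["Cyto_C_cbb3"] * 2
        # greedy nearest pairing: each COX1 takes its own FixO
        members = [set(c.member_protein_ids) for c in calls]
        assert {"a1", "b1"} in members and {"a2", "b2"} in members

    def test_each_protein_joins_at_most_one_complex(self, catalog):
        recs = [
            make_protein(["COX1"], "a", locus_index=10),
            make_protein(["FixO"], "b", locus_index=11),
            make_protein(["FixO"], "c", locus_index=12),
        ]
        calls, consumed = assemble_complexes(recs, catalog, window=5)
        assert len(calls) == 1
        assert "c" not in consumed

    def test_split_mco_assembled_from_subunits(self, catalog):
        recs = [
            make_protein(["Cu-oxidase_3"], "a", locus_index=5),
            make_protein(["Cu-oxidase_2"], "b", locus_index=6),
        ]
        calls, _ = assemble_complexes(recs, catalog, window=5)
        assert [c.type_name for c in calls] == ["MCOs"]

    def test_same_protein_mco_not_cannibalized_into_split_complex(self, catalog):
        # two complete single-chain MCOs next to each other stay two MCOs
        recs = [
            make_protein(["Cu-oxidase_3", "Cu-oxidase_2"], "a", locus_index=5),
            make_protein(["Cu-oxidase_3", "Cu-oxidase_2"], "b", locus_index=6),
        ]
        calls, consumed = assemble_complexes(recs, catalog, window=5)
        assert calls == [] and consumed == set()
        full = classify_species(recs, catalog)
        assert sorted(c.type_name for c in full) == ["MCOs", "MCOs"]

    def test_invalid_window_rejected(self, catalog):
        with pytest.raises(ValueError):
            assemble_complexes([], catalog, window=0)


class TestComplexIdentity:
    def test_qoxb_flag_gives_aa3(self):
        assert resolve_complex_identity(["a", "b"], {"a": "QoxB"}) == "Cyto_C_aa3"

    def test_cyob_flag_gives_bo(self):
        assert resolve_complex_identity(["a", "b"], {"b": "CyoB"}) == "Cyto_bo"

    def test_override_excludes_nitric_oxide_reductase(self):
        out = resolve_complex_identity(["a", "b"], {"a": "QoxB"}, {"a": "NOR"})
        assert out == "excluded_NOR"

    def test_no_flags_unresolved(self):
        assert resolve_complex_identity(["a", "b"]) == "unresolved_COX"

    def test_contradictory_flags_error(self):
        with pytest.raises(ValueError, match="contradictory"):
            resolve_complex_identity(["a", "b"], {"a": "QoxB", "b": "CyoB"})

    def test_unresolved_pair_not_in_profile(self, catalog):
        recs = [
            make_protein(["COX1"], "a", locus_index=1),
            make_protein(["COX2"], "b", locus_index=2),
        ]
        audit = []
        calls = classify_species(recs, catalog, audit=audit)
        assert calls == []
        assert any(a["outcome"] == "unresolved_COX" for a in audit)


class TestTransporterDisambiguation:
    def _atpase(self, pid="t1"):
        return make_protein(["E1-E2_ATPases"], pid)

    def test_zero_evalue_copper_label_accepted(self):
        hits = [SimilarityHit("t1", "r", 0.0, 900.0, "3.A.3.5")]
        d = disambiguate_transporter(self._atpase(), "P_type_ATPase", hits)
        assert d.verdict == "copper_ATPase"

    def test_biogenesis_category_excluded(self):
        hits = [SimilarityHit("t1", "r", 0.0, 900.0, "3.A.3.27")]
        d = disambiguate_transporter(self._atpase(), "P_type_ATPase", hits)
        assert d.verdict == "excluded_biogenesis_ATPase"

    def test_better_biogenesis_hit_outranks_copper_hit(self):
        hits = [
            SimilarityHit("t1", "r1", 0.0, 700.0, "3.A.3.5"),
            SimilarityHit("t1", "r2", 0.0, 900.0, "3.A.3.27"),
        ]
        d = disambiguate_transporter(self._atpase(), "P_type_ATPase", hits)
        assert d.verdict == "excluded_biogenesis_ATPase"

    def test_nonzero_evalue_hits_do_not_qualify(self):
        hits = [SimilarityHit("t1", "r", 1e-50, 400.0, "3.A.3.5")]
        d = disambiguate_transporter(self._atpase(), "P_type_ATPase", hits)
        assert d.verdict == "unclassified"

    def test_rnd_requires_hme_label(self):
        rnd = make_protein(["ACR_tran"], "r1")
        hme = [SimilarityHit("r1", "r", 0.0, 900.0, "2.A.6.1")]
        assert disambiguate_transporter(rnd, "RND", hme).verdict == "RND_HME"
        assert disambiguate_transporter(rnd, "RND", []).verdict == "unclassified"

    def test_verdict_family_consistency_enforced(self):
        from cuproscan.classifier import TransporterDecision

        with pytest.raises(ValueError):
            TransporterDecision("p", "RND", "copper_ATPase")


class TestTatDetection:
    def test_canonical_twin_arginine_motif(self):
        assert detect_tat_signal("MAYSRRGFLKAAGA" + "A" * 50)

    def test_poly_alanine_negative(self):
        assert not detect_tat_signal("A" * 80)

    def test_motif_outside_window_negative(self):
        seq = "M" + "A" * 59 + "SRRGFL" + "A" * 20
        assert not detect_tat_signal(seq, search_len=35)
        assert detect_tat_signal(seq, search_len=70)

    def test_non_amino_characters_rejected(self):
        with pytest.raises(ValueError):
            detect_tat_signal("MA1SRRGFL")
        with pytest.raises(ValueError):
            detect_tat_signal("")


class TestCspClassification:
    def test_tat_positive_is_extracytoplasmic(self, catalog):
        rec = make_protein(["DUF326"], sequence="MAYSRRGFLKAAGA" + "A" * 40)
        assert classify_csp(rec).type_name == "Csp1/2_Ecsp"

    def test_tat_negative_is_cytoplasmic(self, catalog):
        rec = make_protein(["DUF326"], sequence="M" + "AKLDGE" * 20)
        assert classify_csp(rec).type_name == "Csp3_Ccsp"

    def test_missing_sequence_falls_back_to_cytoplasmic_with_warning(self):
        rec = make_protein(["DUF326"])
        audit = []
        call = classify_csp(rec, audit=audit)
        assert call.type_name == "Csp3_Ccsp"
        assert audit and "no sequence" in audit[0]["reason"]


class TestClassifySpecies:
    def test_zero_copper_species_empty(self, catalog):
        recs = [make_protein(["ABC_tran"], f"p{i}", locus_index=i) for i in range(4)]
        assert classify_species(recs, catalog) == []

    def test_mco_beats_nitrite_reductase_on_longer_pattern(self, catalog):
        rec = make_protein(["Cu-oxidase_3", "Cu-oxidase", "Cu-oxidase_2"])
        calls = classify_species([rec], catalog)
        assert [c.type_name for c in calls] == ["MCOs"]

    def test_nirk_three_domain_beats_mco_two_domain(self, catalog):
        rec = make_protein(["Copper-bind", "Cu-oxidase_3", "Cu-oxidase_2"])
        calls = classify_species([rec], catalog)
        assert [c.type_name for c in calls] == ["Nitrite reductase"]

    def test_copper_bind_inside_nirk_not_recounted_as_plastocyanin(self, catalog):
        rec = make_protein(["Copper-bind", "Cu-oxidase_3"])
        calls = classify_species([rec], catalog)
        assert [c.type_name for c in calls] == ["Nitrite reductase"]

    def test_single_assignment_across_all_calls(self, catalog):
        recs = [
            make_protein(["COX1"], "a", locus_index=1),
            make_protein(["FixO"], "b", locus_index=2),
            make_protein(["HMA"], "c", locus_index=20),
            make_protein(["Sod_Cu", "HMA"], "d", locus_index=40),
        ]
        calls = classify_species(recs, catalog)
        members = [m for c in calls for m in c.member_protein_ids]
        assert len(members) == len(set(members))

    def test_permutation_invariance(self, catalog):
        recs = [
            make_protein(["COX1"], "a", locus_index=1),
            make_protein(["FixO"], "b", locus_index=2),
            make_protein(["Cu-oxidase_3", "Cu-oxidase_2"], "c", locus_index=30),
            make_protein(["HMA"], "d", locus_index=50),
            make_protein(["DUF326"], "e", locus_index=70,
                         sequence="M" + "AKLDGE" * 20),
        ]
        fwd = classify_species(recs, catalog)
        rev = classify_species(list(reversed(recs)), catalog)
        key = lambda c: (c.type_name, c.member_protein_ids)
        assert sorted(fwd, key=key) == sorted(rev, key=key)

    def test_multiple_species_rejected(self, catalog):
        recs = [
            make_protein(["HMA"], "a", species_id="s1"),
            make_protein(["HMA"], "b", species_id="s2"),
        ]
        with pytest.raises(ValueError, match="multiple species"):
            classify_species(recs, catalog)

    def test_atpase_accessory_hma_not_counted_separately(self, catalog):
        rec = make_protein(["HMA", "E1-E2_ATPases"], "t1")
        hits = [SimilarityHit("t1", "r", 0.0, 900.0, "3.A.3.27")]
        calls = classify_species([rec], catalog, similarity_hits=hits)
        assert calls == []
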