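import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalnet.causal_profile import (
    EXCLUDED,
    AssayRecord,
    KeywordRule,
    MoACategory,
    UnmappedTermError,
    annotate_assay,
    build_profile,
    load_keyword_rules,
    map_chembl_action,
    map_drugbank_action,
    map_iuphar_action,
)


class TestVocabularyMappings:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("ACTIVATOR", 1),
            ("AGONIST", 1),
            ("ANTAGONIST", 2),
            ("BINDING AGENT", 3),
            ("BLOCKER", 2),
            ("MODULATOR", 3),
            ("NEGATIVE ALLOSTERIC MODULATOR", 2),
            ("NEGATIVE MODULATOR", 2),
            ("POSITIVE MODULATOR", 1),
            ("RELEASING AGENT", 3),
            ("STABILISER", 3),
        ],
    )
    def test_curated_mechanism_terms(self, term, expected):
        assert map_chembl_action(term) == MoACategory(expected)

    @pytest.mark.parametrize(
        "term,expected",
        [
            ("Activation", 1),
            ("Biased agonist", 1),
            ("Binding", 3),
            ("Competitive", 3),
            ("Feedback inhibition", 2),
            ("Full agonist", 1),
            ("Inhibition", 2),
            ("Irreversible inhibition", 2),
            ("Mixed", 3),
            ("Neutral", 3),
        ],
    )
    def test_pharmacology_action_terms(self, term, expected):
        assert map_iuphar_action(term) == MoACategory(expected)

    @pytest.mark.parametrize("term,expected", [("agonist", 1), ("inhibitor", 2), ("binder", 3)])
    def test_drugbank_action_terms(self, term, expected):
        assert map_drugbank_action(term) == MoACategory(expected)

    def test_matching_trims_and_case_folds(self):
        assert map_chembl_action("  agonist ") == MoACategory.POSITIVE
        assert map_iuphar_action("ACTIVATION") == MoACategory.POSITIVE

    @pytest.mark.parametrize("mapper", [map_chembl_action, map_iuphar_action, map_drugbank_action])
    def test_unmapped_term_raises_carrying_the_term(self, mapper):
        with pytest.raises(UnmappedTermError) as excinfo:
            mapper("FROBNICATOR")
        assert "FROBNICATOR" in str(excinfo.value)


class TestAssayAnnotation:
    def test_inhibitor_keyword_above_cutoff_is_negative(self):
        record = AssayRecord("C1", "P1", "Inhibitor of CYP3A4 in human liver microsomes", 6.2)
        assert annotate_assay(record) == MoACategory.NEGATIVE

    def test_channel_opening_keyword_is_positive(self):
        record = AssayRecord("C1", "P1", "Channel opening activity at GABA-A receptor", 6.0)
        assert annotate_assay(record) == MoACategory.POSITIVE

    def test_below_cutoff_is_inactive_regardless_of_keyword(self):
        record = AssayRecord("C1", "P1", "Activation of PPAR gamma", 4.2)
        assert annotate_assay(record) == MoACategory.INACTIVE

    def test_active_measurement_with_inconclusive_comment_is_excluded(self):
        record = AssayRecord("C1", "P1", "Inhibitor of X", 6.0, activity_comment="inconclusive")
        assert annotate_assay(record) is EXCLUDED

    def test_contradictory_comment_excludes_in_both_directions(self):
        above = AssayRecord("C1", "P1", "Inhibitor of X", 6.0, activity_comment="Not Active")
        below = AssayRecord("C1", "P1", "Binding at X", 4.0, activity_comment="active")
        assert annotate_assay(above) is EXCLUDED
        assert annotate_assay(below) is EXCLUDED

    def test_consistent_comment_is_kept(self):
        record = AssayRecord("C1", "P1", "Inhibitor of X", 6.0, activity_comment="active")
        assert annotate_assay(record) == MoACategory.NEGATIVE

    def test_both_direction_keywords_without_resolution_excluded(self):
        record = AssayRecord("C1", "P1", "Assay measuring Inhibitors and Activation of X", 6.0)
        assert annotate_assay(record) is EXCLUDED

    def test_exclusion_phrase_voids_a_keyword_match(self):
        # "inactivation" contains "activation" but the packaged exclusion
        # prevents a spurious positive call; "inhibiting" still matches.
        record = AssayRecord("C1", "P1", "Compound inhibiting X via receptor inactivation", 6.0)
        assert annotate_assay(record) == MoACategory.NEGATIVE

    def test_no_keyword_above_cutoff_is_active_unspecified(self):
        record = AssayRecord("C1", "P1", "Binding affinity measured by SPR", 7.0)
        assert annotate_assay(record) == MoACategory.ACTIVE_UNSPECIFIED

    def test_missing_pchembl_is_excluded(self):
        record = AssayRecord("C1", "P1", "Inhibitor of X", None)
        assert annotate_assay(record) is EXCLUDED

    def test_cutoff_is_configurable(self):
        record = AssayRecord("C1", "P1", "Inhibitor of X", 5.5)
        assert annotate_assay(record, active_cutoff=6.0) == MoACategory.INACTIVE

    @given(
        pchembl=st.floats(min_value=0, max_value=12, allow_nan=False),
        description=st.text(max_size=60),
    )
    @settings(max_examples=200, derandomize=True)
    def test_direction_never_contradicts_activity_cutoff(self, pchembl, description):
        outcome = annotate_assay(AssayRecord("C", "P", description, pchembl))
        if pchembl < 5.0:
            assert outcome in (EXCLUDED, MoACategory.INACTIVE)
        else:
            assert outcome is not MoACategory.INACTIVE

    @given(data=st.data())
    @settings(max_examples=50, derandomize=True)
    def test_keyword_matching_is_order_independent(self, data):
        rules = load_keyword_rules()
        description = data.draw(
            st.lists(
                st.sampled_from(
                    ["inhibitor", "activation", "channel opening activity", "binding", "of", "X"]
                ),
                min_size=1,
                max_size=5,
            ).map(" ".join)
        )
        record = AssayRecord("C", "P", description, 6.5)
        permuted = data.draw(st.permutations(rules))
        assert annotate_assay(record, rules) == annotate_assay(record, permuted)


class TestBuildProfile:
    def test_same_triple_from_two_sources_merges(self):
        records = build_profile(
            mechanisms=[("CHEMBL1", "P1", "AGONIST")],
            iuphar=[("CHEMBL1", "P1", "Activation")],
        )
        assert len(records) == 1
        assert set(records[0].source.split(";")) == {"chembl_mechanism", "iuphar"}

    def test_compound_filter_drops_outsiders(self):
        records = build_profile(
            mechanisms=[("CHEMBL1", "P1", "AGONIST"), ("CHEMBL2", "P2", "BLOCKER")],
            compound_filter=["CHEMBL1"],
        )
        assert [r.compound_id for r in records] == ["CHEMBL1"]

    def test_excluded_assays_never_reach_the_profile(self):
        records = build_profile(
            assays=[
                AssayRecord("CHEMBL1", "P1", "Inhibitor of X", 6.0, "inconclusive"),
                AssayRecord("CHEMBL1", "P2", "Inhibitor of X", 6.0),
            ]
        )
        assert [(r.target_id, r.category) for r in records] == [("P2", MoACategory.NEGATIVE)]

    def test_output_has_no_duplicate_triples(self, small_fixture):
        from causalnet import io_formats

        outdir, _ = small_fixture
        records = build_profile(
            mechanisms=[
                (r.compound_id, r.target_id, r.action_type)
                for r in io_formats.read_chembl_mechanisms(outdir / "mechanisms.tsv")
            ],
            assays=io_formats.read_chembl_assays(outdir / "assays.tsv"),
        )
        triples = [(r.compound_id, r.target_id, r.category) for r in records]
        assert len(triples) == len(set(triples))

    def test_keyword_rule_requires_directional_category(self):
        with pytest.raises(ValueError):
            KeywordRule("binding", MoACategory.ACTIVE_UNSPECIFIED)
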