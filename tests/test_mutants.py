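"""Mutant grammar, editing, accounting, oligo design and table loading."""

import pytest
from hypothesis import given, settings, strategies as st

from tapemeasure.grammar import (
    Replacement,
    RepeatRange,
    ResidueRange,
    TmRange,
    format_components,
    parse_spec_text,
)
from tapemeasure.io import SequenceAnnotation
from tapemeasure.mutants import (
    OligoParams,
    aa_deleted,
    apply_mutant,
    audit_essential_elements,
    back_translate,
    design_recombineering_oligo,
    load_mutant_table,
    parse_mutant,
    verify_table_accounting,
)


class TestGrammar:
    @pytest.mark.parametrize("text,expected", [
        ("R3..3+5", (RepeatRange(3, 3, extra=5),)),
        ("R1..7+half", (RepeatRange(1, 7, half=True),)),
        ("res2..31", (ResidueRange(2, 31),)),
        ("tm1..6", (TmRange(1, 6),)),
        ("R4::AAAAAA", (Replacement(4, "AAAAAA"),)),
        ("R1..9;R20..26", (RepeatRange(1, 9), RepeatRange(20, 26))),
        ("", ()),
    ])
    def test_parse(self, text, expected):
        assert parse_spec_text(text) == expected

    def test_round_trip(self):
        for text in ("R1..7+half", "R1..29;res810..908", "R4::AAAAAAAAAAA", ""):
            assert format_components(parse_spec_text(text)) == text

    def test_ambiguous_fractional_form_rejected_with_guidance(self):
        with pytest.raises(ValueError, match=r"\+half"):
            parse_spec_text("R1..7.5")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_spec_text("delete everything")


class TestAccounting:
    @pytest.mark.parametrize("text,expected", [
        ("res2..31", 30),                     # inclusive of both endpoints
        ("R1..29;res810..908", 446),
        ("res62..141;R1..29;res810..908", 526),
        ("R1..7+half", 100),
        ("R3..3+5", 16),
        ("tm1..3", 71),
        ("tm4..6", 89),
        ("tm1..6", 160),                      # union of the two regions
        ("R4::AAAAAAAAAAA", 0),               # 11 deleted, 11 inserted
        ("R4::AAAAAA", 5),
        ("", 0),
    ])
    def test_examples(self, arch, text, expected):
        assert aa_deleted(parse_mutant(text, arch)) == expected

    def test_overlapping_components_rejected(self, arch):
        with pytest.raises(ValueError, match="overlap"):
            parse_mutant("R1..5;res470..480", arch)

    def test_out_of_range_rejected(self, arch):
        with pytest.raises(ValueError):
            parse_mutant("R1..30", arch)
        with pytest.raises(ValueError):
            parse_mutant("res900..999", arch)
        with pytest.raises(ValueError):
            parse_mutant("tm1..7", arch)

    def test_extra_beyond_next_repeat_rejected(self, arch):
        # repeat 2 is 11 residues in the reference assignment
        with pytest.raises(ValueError, match="exceeds"):
            parse_mutant("R1..1+12", arch)

    def test_full_tables_match_printed_sizes_except_flagged(self, arch, table1, table2):
        report = verify_table_accounting(table1 + table2, arch)
        flagged = set(report[report.convention_note != ""].name)
        assert flagged == {"DF31-I61", "DF31-L141"}
        for row in report.itertuples():
            if row.convention_note:
                # printed size is one short: first named residue retained
                assert row.computed == row.printed + 1
            elif row.printed is not None and not (row.printed != row.printed):
                assert row.matches, row.name

    def test_incremental_series_yields_41_to_51(self, arch, table2):
        series = [r for r in table2 if r.name.startswith("D1-3.")]
        assert len(series) == 11
        for k, record in enumerate(sorted(series, key=lambda r: int(r.name.split(".")[1])), 1):
            assert aa_deleted(parse_mutant(record.spec_text, arch)) == 40 + k == record.aa_deleted


class TestApply:
    def test_full_repeat_deletion_length(self, arch, reference_sequence):
        seq, ann = reference_sequence
        app = apply_mutant(seq, ann, parse_mutant("R1..29", arch, "D1-29"))
        assert len(app.sequence) == 937 - 347 == 590

    def test_identity_is_a_no_op(self, arch, reference_sequence):
        seq, ann = reference_sequence
        app = apply_mutant(seq, ann, parse_mutant("", arch))
        assert app.sequence == seq
        assert not app.destroyed and not app.truncated

    def test_tm_deletion_destroys_hydrophobic_regions(self, arch, reference_sequence):
        seq, ann = reference_sequence
        app = apply_mutant(seq, ann, parse_mutant("tm1..6", arch, "DTM1-6"))
        assert "hydrophobic_region_1" in app.destroyed
        assert "hydrophobic_region_2" in app.destroyed
        assert all(f.feature_id != "hydrophobic_region_1" for f in app.annotation.features)

    def test_replacement_preserves_length_and_writes_alanines(self, arch, reference_sequence):
        seq, ann = reference_sequence
        spec = parse_mutant("R4::AAAAAAAAAAA", arch)
        app = apply_mutant(seq, ann, spec)
        assert len(app.sequence) == len(seq)
        s, e = arch.repeat_spans()[3]
        assert app.sequence[s - 1 : e] == "A" * 11

    def test_coordinates_lift_past_deletions(self, arch, reference_sequence):
        seq, ann = reference_sequence
        app = apply_mutant(seq, ann, parse_mutant("res2..31", arch))
        cterm = app.annotation.get("cterm")
        assert (cterm.start, cterm.end) == (878 - 30, 937 - 30)
        assert cterm.attributes["status"] == "intact"

    def test_touching_initiator_rejected(self, arch, reference_sequence):
        seq, ann = reference_sequence
        with pytest.raises(ValueError, match="initiator"):
            apply_mutant(seq, ann, parse_mutant("res1..10", arch))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(start=st.integers(2, 930), extent=st.integers(0, 60))
    def test_length_conservation(self, arch, reference_sequence, start, extent):
        """length(mutant) + residues deleted == length(reference), always."""
        seq, ann = reference_sequence
        end = min(start + extent, 937)
        spec = parse_mutant(f"res{start}..{end}", arch)
        app = apply_mutant(seq, ann, spec)
        assert len(app.sequence) + aa_deleted(spec) == len(seq)


class TestOligoDesign:
    def test_internal_deletion_gives_90mer_with_flanking_arms(self, arch, reference_sequence):
        seq, _ = reference_sequence
        cds = back_translate(seq)
        spec = parse_mutant("res62..141", arch, "DI62-L141")
        design = design_recombineering_oligo(cds, spec)
        assert len(design.oligo) == 90
        assert not design.left_truncated and not design.right_truncated
        # string-search oracle: arms are exact substrings abutting the deletion
        d_start, d_end = design.deleted_nt
        assert cds[d_start - 46 : d_start - 1] == design.left_arm
        assert cds[d_end : d_end + 45] == design.right_arm
        assert cds.find(design.left_arm + cds[d_start - 1 : d_end] + design.right_arm) >= 0

    def test_deletion_at_cds_start_truncates_left_arm(self, arch, reference_sequence):
        seq, _ = reference_sequence
        cds = back_translate(seq)
        spec = parse_mutant("res2..31", arch)
        with pytest.warns(UserWarning, match="close to a CDS end"):
            design = design_recombineering_oligo(cds, spec)
        assert design.left_truncated and len(design.left_arm) == 3
        assert len(design.right_arm) == 45

    def test_non_contiguous_spec_rejected(self, arch, reference_sequence):
        seq, _ = reference_sequence
        cds = back_translate(seq)
        with pytest.raises(ValueError, match="contiguous"):
            design_recombineering_oligo(cds, parse_mutant("tm1..6", arch))

    def test_replacement_oligo_carries_backtranslated_insert(self, arch, reference_sequence):
        seq, _ = reference_sequence
        cds = back_translate(seq)
        design = design_recombineering_oligo(cds, parse_mutant("R4::AAAAAA", arch))
        assert design.oligo == design.left_arm + "GCT" * 6 + design.right_arm

    def test_arm_length_validation(self):
        with pytest.raises(ValueError, match="40-45"):
            OligoParams(arm_length=30)
        assert OligoParams(arm_length=30, validate=False).arm_length == 30

    def test_back_translation_is_three_nt_per_residue(self):
        assert back_translate("MW") == "ATGTGG"
        with pytest.raises(ValueError):
            back_translate("MX")


class TestTables:
    def test_row_counts(self, table1, table2):
        assert len(table1) == 43  # incl. the wild type
        assert len(table2) == 15

    def test_censored_eop_kept_as_bound(self, table1):
        by_name = {r.name: r for r in table1}
        assert by_name["D1-29"].eop == pytest.approx(1.5e-8)
        assert by_name["D1-29"].eop_censored
        assert not by_name["D1-9"].eop_censored

    def test_wild_type_row(self, table1):
        wt = table1[0]
        assert wt.name == "WT" and wt.aa_deleted == 0
        assert wt.tail_length_nm == 118.0
        assert wt.residue_count == 937

    def test_no_tails_rows_have_note_not_number(self, table1):
        by_name = {r.name: r for r in table1}
        assert by_name["DTM1-6"].tail_length_nm is None
        assert by_name["DTM1-6"].tail_note == "No tails"

    def test_malformed_numeric_cell_reported_with_row_label(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("name\tspec\taa_deleted\nDX\tR1..2\ttwenty\n")
        with pytest.raises(ValueError, match="DX"):
            load_mutant_table(bad)

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("name\tfoo\nWT\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_mutant_table(bad)


class TestAudit:
    def test_nterm_disruption_flagged(self, arch):
        audit = audit_essential_elements(parse_mutant("res142..154", arch, "DA142-E154"), arch)
        assert not audit.nterm_intact
        assert audit.cterm_intact and audit.hydrophobic_region_1_intact

    def test_identity_keeps_everything(self, arch):
        audit = audit_essential_elements(parse_mutant("", arch), arch)
        assert audit.nterm_intact and audit.cterm_intact
        assert audit.hydrophobic_region_1_intact
        assert audit.repeats_lost == () and audit.repeats_truncated == ()

    def test_repeat_losses_enumerated(self, arch):
        audit = audit_essential_elements(parse_mutant("R1..7+half", arch), arch)
        assert audit.repeats_lost == (1, 2, 3, 4, 5, 6, 7)
        assert audit.repeats_truncated == (8,)
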