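import pytest

from lucdesign import (
    EditOperation,
    PeptideBlock,
    ValidationError,
    VariantSeries,
    apply_edits,
    combine_series,
    derive_blocks,
    flexible_positions,
    generate_variant_series,
    nested_compensation_series,
    revert_variant,
    split_at_flexible,
)
from lucdesign.align import VacantRegion
from lucdesign.design import series_manifest, series_to_fasta

from conftest import DONOR1, DONOR1_CUTS, DONOR2, DONOR2_CUTS, SERIES_NAMES


class TestFlexibleSplitting:
    def test_positions(self):
        # G at 1, A at 4, G at 6, I at 7 in "GRCASGI"
        assert flexible_positions("GRCASGI") == [1, 4, 6, 7]

    def test_explicit_cuts_reproduce_worked_fragments(self):
        frags = split_at_flexible(DONOR1, explicit_cuts=DONOR1_CUTS)
        assert frags == ["GRCHSYEG", "DKDTGQG", "GIGEPI"]
        frags2 = split_at_flexible(DONOR2, explicit_cuts=DONOR2_CUTS)
        assert frags2 == ["DRCASFA", "DKIQKEV", "DYIKGLAG"]

    def test_greedy_matches_worked_fragments_for_donor1(self):
        # for this donor, the default greedy heuristic happens to recover
        # the same cut points as the curated ones
        assert split_at_flexible(DONOR1) == ["GRCHSYEG", "DKDTGQG", "GIGEPI"]

    def test_concatenation_restores_block(self):
        for block in (DONOR1, DONOR2, "KWLP", "GGGGGG"):
            assert "".join(split_at_flexible(block)) == block

    def test_cut_not_after_flexible_rejected(self):
        # position 2 of DONOR1 is after 'R', not a flexible residue
        with pytest.raises(ValidationError, match="not after a flexible"):
            split_at_flexible(DONOR1, explicit_cuts=[2])

    def test_no_flexible_residues_keeps_block_whole(self):
        assert split_at_flexible("KKRRDDEE") == ["KKRRDDEE"]

    def test_empty_block_rejected(self):
        with pytest.raises(ValidationError):
            split_at_flexible("")


class TestBlockDerivation:
    def _vacancy(self):
        return VacantRegion(
            target_row=0,
            col_start=51,
            col_end=71,
            anchor_residue=50,
            donors={1: DONOR1, 2: DONOR2},
        )

    def test_cumulative_prefixes_and_anchor(self):
        blocks = derive_blocks(self._vacancy(), 1, cuts=DONOR1_CUTS)
        assert [b.seq for b in blocks] == [
            "GRCHSYEG",
            "GRCHSYEGDKDTGQG",
            "GRCHSYEGDKDTGQGGIGEPI",
        ]
        assert all(b.anchor == 51 for b in blocks)
        assert [len(b.seq) for b in blocks] == [8, 15, 21]

    def test_second_donor_prefix_lengths(self):
        blocks = derive_blocks(self._vacancy(), 2, cuts=DONOR2_CUTS)
        assert [len(b.seq) for b in blocks] == [7, 14, 22]

    def test_empty_donor_rejected(self):
        v = VacantRegion(0, 51, 71, 50, donors={1: DONOR1})
        with pytest.raises(ValidationError, match="donor row 2"):
            derive_blocks(v, 2)


class TestApplyEdits:
    def test_insertion_between_residues(self):
        seq, span = apply_edits("ABCDEF"[:4] + "GH", [EditOperation("insertion", 3, 3, "XY")])
        # "ABCDGH" -> insert before residue 3
        assert seq == "ABXYCDGH"
        assert span == (3, 4)

    def test_substitution_same_length(self):
        seq, span = apply_edits("ABCDEF", [EditOperation("substitution", 2, 4, "XYZ")])
        assert seq == "AXYZEF" and span is None

    def test_substitution_then_insertion_offsets(self):
        # lengthening substitution shifts a later insertion anchor
        edits = [
            EditOperation("substitution", 2, 2, "XX", length_change_ok=True),
            EditOperation("insertion", 4, 4, "Q"),
        ]
        seq, span = apply_edits("ABCDE", edits)
        # after sub: A XX CDE (len 6); insertion at template pos 4 -> new pos 5
        assert seq == "AXXCQDE"
        assert span == (5, 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="out of range"):
            apply_edits("ABC", [EditOperation("substitution", 2, 9, "X", length_change_ok=True)])
        with pytest.raises(ValidationError, match="out of range"):
            apply_edits("ABC", [EditOperation("insertion", 9, 9, "X")])

    def test_mismatched_substitution_payload_rejected(self):
        with pytest.raises(ValidationError, match="length_change_ok"):
            EditOperation("substitution", 2, 4, "XY")


class TestVariantSeries:
    def test_insertion_variant_lengths_and_spans(self, template_194, group1_blocks):
        series = generate_variant_series(template_194, group1_blocks, naming=["a", "b", "c"])
        # template 194 + block + KDEL tag
        assert [len(v.seq) for v in series] == [194 + 8 + 4, 194 + 15 + 4, 194 + 21 + 4]
        assert [v.inserted_span for v in series] == [(51, 58), (51, 65), (51, 71)]
        for v, b in zip(series, group1_blocks):
            assert v.seq[50 : 50 + len(b.seq)] == b.seq
            assert v.seq.endswith("KDEL")

    def test_flanks_preserved(self, template_194, group1_blocks):
        series = generate_variant_series(template_194, group1_blocks[:1], naming=["a"])
        v = series.get("a")
        assert v.seq[:50] == template_194.seq[:50]
        assert v.seq[58:-4] == template_194.seq[50:]

    def test_substitution_only_variant(self, template_194, substitution_47_50):
        series = generate_variant_series(
            template_194, substitutions=[substitution_47_50], naming=["s"]
        )
        v = series.get("s")
        assert len(v.seq) == 194 + 4
        assert v.seq[46:50] == "KWLP"
        assert v.seq[:46] == template_194.seq[:46]

    def test_no_edits_yields_tagged_template(self, template_194):
        series = generate_variant_series(template_194, naming=["t"])
        assert len(series) == 1
        assert series.get("t").seq == template_194.seq + "KDEL"

    def test_duplicate_names_rejected(self, template_194, group1_blocks):
        with pytest.raises(ValidationError, match="unique"):
            generate_variant_series(template_194, group1_blocks, naming=["x", "x", "y"])

    def test_insufficient_names_rejected(self, template_194, group1_blocks):
        with pytest.raises(ValidationError, match="covers"):
            generate_variant_series(template_194, group1_blocks, naming=["only_one"])

    def test_revert_insertion_recovers_template(self, template_194, group1_blocks):
        series = generate_variant_series(template_194, group1_blocks, naming=["a", "b", "c"])
        for v in series:
            assert revert_variant(v) == template_194.seq


@pytest.fixture(scope="module")
def scheme(template_194, group1_blocks, group2_blocks, substitution_47_50):
    return nested_compensation_series(
        template_194, group1_blocks, group2_blocks, substitution_47_50, SERIES_NAMES
    )


class TestNestedScheme:
    def test_ten_variants_in_order(self, scheme):
        assert [v.name for v in scheme] == list(SERIES_NAMES)

    def test_lengths(self, scheme):
        base = 194 + 4  # template + tag
        expected = [base + d for d in (8, 15, 21, 7, 14, 22, 0, 8, 15, 21)]
        assert [len(v.seq) for v in scheme] == expected

    def test_inserted_spans(self, scheme):
        spans = [v.inserted_span for v in scheme]
        assert spans[:6] == [(51, 58), (51, 65), (51, 71), (51, 57), (51, 64), (51, 72)]
        assert spans[6] is None  # bare substitution
        assert spans[7:] == [(51, 58), (51, 65), (51, 71)]

    def test_substituted_variants_carry_both_edits(self, scheme, template_194):
        for name in SERIES_NAMES[7:]:
            v = scheme.get(name)
            assert v.seq[46:50] == "KWLP"
            assert v.seq[:46] == template_194.seq[:46]
        assert scheme.get(SERIES_NAMES[6]).seq[46:50] == "KWLP"

    def test_asymmetric_donor_block_counts(self, template_194, group1_blocks, group2_blocks, substitution_47_50):
        # 3 donor-1 blocks, 2 donor-2 blocks -> 3 + 2 + 1 + 3 = 9 variants
        names = [f"v{i}" for i in range(9)]
        series = nested_compensation_series(
            template_194, group1_blocks, group2_blocks[:2], substitution_47_50, names
        )
        assert len(series) == 9
        assert [v.name for v in series] == names

    def test_combining_mismatched_templates_rejected(self, template_194, group1_blocks):
        s1 = generate_variant_series(template_194, group1_blocks[:1], naming=["a"])
        from lucdesign import SequenceRecord

        other = SequenceRecord("other", template_194.seq)
        s2 = generate_variant_series(other, group1_blocks[:1], naming=["b"])
        with pytest.raises(ValidationError, match="different templates"):
            combine_series(s1, s2)


class TestExports:
    def test_fasta_and_manifest(self, template_194, group1_blocks):
        series = generate_variant_series(template_194, group1_blocks[:1], naming=["v1"])
        fasta = series_to_fasta(series)
        assert fasta.startswith(">v1\n")
        import json

        data = json.loads(series_manifest(series))
        assert data["template"] == "template"
        assert data["variants"][0]["inserted_span"] == [51, 58]
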